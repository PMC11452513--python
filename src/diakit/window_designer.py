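"""Equal-peptide-density variable isolation windows for DIA methods.

Fixed-width DIA windows waste cycle time where few peptide precursors fall
(notably above ~1000 m/z, where identifiable peptide density thins out) and
crowd many co-eluting precursors into single windows in the dense 450-700
m/z region.  The variable-window ("Variabele Vensters") design instead
places window boundaries at equal-count quantiles of the precursor m/z
distribution of a representative spectral library, so every window spans
roughly the same number of identifiable peptide ions.

Boundaries are rounded to integers — window i's stop is the boundary
rounded up, window i+1's start is the same boundary rounded down — which
makes manual entry into instrument control software less error-prone and
gives every pair of consecutive windows a 1-m/z overlap.

Cycle arithmetic: with ``n`` windows per cycle and an MS/MS acquisition
rate of ``r`` Hz, one cycle takes ``n / r`` seconds, and a chromatographic
peak of width ``w`` seconds is sampled ``w * r / n`` times.  The defaults
(30 windows, 30 s peaks, 10 Hz) give a 3-second cycle and 10 points per
peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class DesignError(ValueError):
    """Raised when no valid window scheme exists for the given input."""


@dataclass(frozen=True)
class DesignConfig:
    """Tunable parameters of the window design.

    n_windows:
        isolation windows per MS/MS cycle (default 30).
    peak_width_s:
        estimated chromatographic peak width in seconds (default 30).
    ms2_rate_hz:
        MS/MS acquisition rate in scans per second (default 10).
    mz_floor / mz_ceiling:
        optional m/z clamps; precursors outside the range are ignored.
    """

    n_windows: int = 30
    peak_width_s: float = 30.0
    ms2_rate_hz: float = 10.0
    mz_floor: Optional[float] = None
    mz_ceiling: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.peak_width_s <= 0 or self.ms2_rate_hz <= 0:
            raise ValueError("peak_width_s and ms2_rate_hz must be positive")
        if (
            self.mz_floor is not None
            and self.mz_ceiling is not None
            and self.mz_floor >= self.mz_ceiling
        ):
            raise ValueError(f"inverted m/z clamps: [{self.mz_floor}, {self.mz_ceiling}]")


@dataclass(frozen=True)
class Window:
    start_mz: int
    stop_mz: int

    @property
    def width(self) -> int:
        return self.stop_mz - self.start_mz


@dataclass
class WindowScheme:
    """An ordered set of integer isolation windows plus cycle timing.

    ``boundaries`` keeps the exact (unrounded) quantile boundaries
    b_0..b_n used to derive the windows; occupancy diagnostics attribute
    precursors by these exact boundaries, since the integer rounding only
    serves instrument entry and the 1-m/z overlaps.
    """

    windows: list[Window]
    cycle_time_s: float
    points_per_peak: float
    boundaries: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        starts = [w.start_mz for w in self.windows]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise DesignError("window starts must be strictly increasing")
        for w in self.windows:
            if w.stop_mz <= w.start_mz:
                raise DesignError(f"window [{w.start_mz}, {w.stop_mz}] has non-positive width")
        for a, b in zip(self.windows, self.windows[1:]):
            if b.start_mz != a.stop_mz - 1:
                raise DesignError(
                    f"consecutive windows must overlap by 1 m/z: "
                    f"[{a.start_mz},{a.stop_mz}] then [{b.start_mz},{b.stop_mz}]"
                )

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def mz_range(self) -> tuple[int, int]:
        return self.windows[0].start_mz, self.windows[-1].stop_mz


def design_windows(precursor_mzs: Sequence[float], cfg: DesignConfig = DesignConfig()) -> WindowScheme:
    """Place ``cfg.n_windows`` windows at equal-count quantiles of the input.

    Interior boundaries are the i/n empirical quantiles (type-1: the
    ceil(i*N/n)-th order statistic) of the clamped m/z multiset.  Window i
    spans [floor(b_{i-1}), ceil(b_i)], with b_0 the minimum and b_n the
    maximum usable m/z; an interior boundary landing exactly on an integer
    has the stop bumped to b_i + 1 so the 1-m/z overlap is preserved.
    """
    mzs = np.asarray(precursor_mzs, dtype=float)
    if mzs.size and (np.isnan(mzs).any() or (mzs <= 0).any()):
        raise DesignError("precursor m/z values must be positive and finite")
    lo = cfg.mz_floor if cfg.mz_floor is not None else -math.inf
    hi = cfg.mz_ceiling if cfg.mz_ceiling is not None else math.inf
    mzs = mzs[(mzs >= lo) & (mzs <= hi)]
    n = cfg.n_windows
    if np.unique(mzs).size < n:
        raise DesignError(
            f"need at least {n} distinct m/z values in range, got {np.unique(mzs).size}"
        )

    xs = np.sort(mzs)
    N = xs.size
    boundaries = [float(xs[0])]
    for i in range(1, n):
        k = math.ceil(i * N / n)  # 1-based order statistic
        boundaries.append(float(xs[k - 1]))
    boundaries.append(float(xs[-1]))

    windows: list[Window] = []
    for i in range(1, n + 1):
        start = math.floor(boundaries[i - 1])
        b = boundaries[i]
        if i < n and float(b).is_integer():
            stop = int(b) + 1
        else:
            stop = math.ceil(b)
        windows.append(Window(start_mz=start, stop_mz=stop))

    cycle_time = n / cfg.ms2_rate_hz
    return WindowScheme(
        windows=windows,
        cycle_time_s=cycle_time,
        points_per_peak=cfg.peak_width_s / cycle_time,
        boundaries=tuple(boundaries),
    )


def window_occupancy(scheme: WindowScheme, precursor_mzs: Sequence[float]) -> list[int]:
    """Precursors per window, attributed by the exact quantile boundaries.

    Each m/z in (b_{i-1}, b_i] counts toward window i (values below b_0 or
    above b_n are ignored); a value equal to a boundary belongs to the
    lower window.  With integer windows only (no stored boundaries),
    attribution falls back to the half-open integer partition
    [start_i, start_{i+1}) — there the rounding itself can shift
    boundary-adjacent ions between windows.
    """
    mzs = np.sort(np.asarray(precursor_mzs, dtype=float))
    if scheme.boundaries:
        edges = np.asarray(scheme.boundaries)
        inside = (mzs >= edges[0]) & (mzs <= edges[-1])
        mzs = mzs[inside]
        # bin i collects (b_{i-1}, b_i]; put the minimum itself in bin 1
        idx = np.searchsorted(edges[1:-1], mzs, side="left")
        counts = np.bincount(idx, minlength=scheme.n_windows)
        return [int(c) for c in counts]
    starts = [w.start_mz for w in scheme.windows] + [scheme.windows[-1].stop_mz]
    edges = np.asarray(starts, dtype=float)
    inside = (mzs >= edges[0]) & (mzs <= edges[-1])
    idx = np.clip(np.searchsorted(edges, mzs[inside], side="right") - 1, 0, scheme.n_windows - 1)
    return [int(c) for c in np.bincount(idx, minlength=scheme.n_windows)]


def scheme_report(scheme: WindowScheme) -> pd.DataFrame:
    """Instrument-ready table: Window, Start m/z, Stop m/z, Width."""
    return pd.DataFrame(
        {
            "Window": range(1, scheme.n_windows + 1),
            "Start m/z": [w.start_mz for w in scheme.windows],
            "Stop m/z": [w.stop_mz for w in scheme.windows],
            "Width": [w.width for w in scheme.windows],
        }
    )


def write_scheme_tsv(scheme: WindowScheme, path: str | Path) -> None:
    scheme_report(scheme).to_csv(path, sep="\t", index=False)


def read_scheme_tsv(
    path: str | Path,
    *,
    cycle_time_s: float = float("nan"),
    points_per_peak: float = float("nan"),
) -> WindowScheme:
    """Read a scheme table written by :func:`write_scheme_tsv`.

    The table carries no timing metadata; pass it explicitly if needed.
    """
    df = pd.read_csv(path, sep="\t")
    windows = [
        Window(start_mz=int(s), stop_mz=int(e)) for s, e in zip(df["Start m/z"], df["Stop m/z"])
    ]
    return WindowScheme(
        windows=windows, cycle_time_s=cycle_time_s, points_per_peak=points_per_peak
    )
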