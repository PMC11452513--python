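import numpy as np
import pytest

from diakit.library_io import LibraryEntry, LibraryProvenance, SpectralLibrary
from diakit.synthetic_data import (
    CohortPlan,
    SimConfig,
    generate_universe,
    simulate_libraries,
    simulate_quant,
    write_fixtures,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=7, n_proteins=60, peptides_per_protein=(3, 6))


@pytest.fixture(scope="session")
def universe(small_cfg):
    return generate_universe(small_cfg)


@pytest.fixture(scope="session")
def libraries(universe, small_cfg):
    libs, truth = simulate_libraries(universe, small_cfg)
    return libs, truth


@pytest.fixture(scope="session")
def quant(universe, small_cfg):
    return simulate_quant(universe, small_cfg, "LEF")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, universe, small_cfg, libraries, quant):
    """All eight dialect files written from one synthetic study."""
    libs, _ = libraries
    qm, _ = quant
    out = tmp_path_factory.mktemp("fixtures")
    matrices = {e: qm for e in ("DIANN", "FragPipe", "MaxQuant", "Spectronaut")}
    paths = write_fixtures(libs, matrices, out)
    return paths


def precursor_multiset(lib: SpectralLibrary):
    """Sortable (stripped, modified, charge, mz) records for comparison."""
    return sorted(
        (e.stripped_sequence, e.modified_sequence, e.charge, e.precursor_mz)
        for e in lib.entries
    )


def assert_same_precursors(a: SpectralLibrary, b: SpectralLibrary, mz_tol=1e-5):
    ma, mb = precursor_multiset(a), precursor_multiset(b)
    assert len(ma) == len(mb)
    assert [r[:3] for r in ma] == [r[:3] for r in mb]
    np.testing.assert_allclose(
        [r[3] for r in ma], [r[3] for r in mb], atol=mz_tol, rtol=0
    )


def make_library(name, sequences, acquisition="DIA", engine="Spectronaut", charge=2):
    """Tiny hand-built library: one entry per stripped sequence."""
    entries = [
        LibraryEntry(
            stripped_sequence=s,
            modified_sequence=s,
            charge=charge,
            precursor_mz=400.0 + i,
        )
        for i, s in enumerate(sequences)
    ]
    return SpectralLibrary(
        entries=entries,
        provenance=LibraryProvenance(engine=engine, acquisition=acquisition),
        name=name,
    )


@pytest.fixture
def null_plan():
    """Intensity-independent CV, no missingness: the vote's null model."""
    return CohortPlan(
        n_runs=4,
        run_missing_scale=(0.0, 0.0, 0.0, 0.0),
        cv_a=0.15,
        cv_b=0.0,
    )
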