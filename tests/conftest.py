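import numpy as np
import pandas as pd
import pytest

import tilmotif as tm
from tilmotif.repertoire import COLUMNS


def make_table(counts, sample_id="s1", tissue="other", aa=None, v=None, j=None,
               productive=None):
    """Build a small in-memory clonotype table from a count vector."""
    n = len(counts)
    aa = aa or [f"CASS{'ADE'[i % 3] * 6}QYF"[:14] for i in range(n)]
    aa = [a if len(a) >= 5 else a + "X" * (5 - len(a)) for a in aa]
    df = pd.DataFrame({
        "cdr3_nt": ["".join("ACGT"[(i + k) % 4] for k in range(12)) for i in range(n)],
        "cdr3_aa": aa,
        "v_gene": v or [f"TRBV{i % 5 + 1}" for i in range(n)],
        "j_gene": j or [f"TRBJ{i % 3 + 1}" for i in range(n)],
        "count": list(counts),
        "productive": productive or [True] * n,
    })
    return tm.ClonotypeTable(df[COLUMNS], sample_id=sample_id, tissue=tissue)


@pytest.fixture
def small_table():
    return make_table([10, 5, 1], aa=["CASSLAPGATNEK", "CASSIRSSYEQYF", "CASSPGQGDTQYF"])


@pytest.fixture(scope="session")
def default_config():
    return tm.GeneratorConfig()


@pytest.fixture(scope="session")
def reference_counts():
    """Deterministic naive background, shared across discovery tests."""
    return tm.MotifCounts(tm.naive_reference())


@pytest.fixture(scope="session")
def cohort(default_config):
    """One default synthetic cohort, generated once per session."""
    return tm.generate_cohort(default_config, seed=101)


@pytest.fixture(scope="session")
def discovery_run(cohort, reference_counts):
    """Discovery + classification + pruning on the session cohort."""
    idx = {
        "tumor": tm.discover_cohort_motifs(cohort.tumor, reference_counts, tissue="tumor"),
        "healthy_kidney": tm.discover_cohort_motifs(
            cohort.healthy, reference_counts, tissue="healthy_kidney"),
        "pb": tm.discover_cohort_motifs(cohort.pb, reference_counts, tissue="pb"),
    }
    assoc = tm.classify_motifs(
        idx["tumor"], {k: v for k, v in idx.items() if k != "tumor"},
        cohort.tumor, {"healthy_kidney": cohort.healthy, "pb": cohort.pb})
    assoc = tm.prune_against_controls(
        assoc, sorted((n, set(m)) for n, m in cohort.manifest.control_sets.items()))
    return idx, assoc


@pytest.fixture(scope="session")
def cell_data(default_config):
    cells, expr, manifest = tm.generate_cell_table(default_config, seed=202)
    return cells, expr, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(0)
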