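import numpy as np
import pytest

import lipivar as lv


@pytest.fixture(scope="session")
def small_panel() -> lv.GenePanel:
    return lv.GenePanel(
        [
            ("GENEA", [lv.GenomicInterval("1", 1000, 5000, "GENEA")]),
            ("GENEB", [lv.GenomicInterval("2", 2000, 9000, "GENEB")]),
        ],
        flank=300,
    )


@pytest.fixture(scope="session")
def small_cohort(small_panel) -> lv.SyntheticCohort:
    """A tiny deterministic cohort shared across read-only tests."""
    cfg = lv.SimulationConfig(n_samples=20, n_sites=200, seed=11)
    return lv.simulate_cohort(cfg, panel=small_panel)


@pytest.fixture
def toy_matrix() -> lv.GenotypeMatrix:
    """Three samples x four hand-built sites (2 transitions, 1 transversion,
    1 indel) with one missing call."""
    sites = [
        lv.VariantSite("1", 100, "A", ("G",), rsid="rs1"),   # transition
        lv.VariantSite("1", 200, "C", ("T",), rsid="rs2"),   # transition
        lv.VariantSite("1", 300, "A", ("C",), rsid="rs3"),   # transversion
        lv.VariantSite("2", 400, "A", ("AT",), rsid=None),   # indel, novel
    ]
    codes = np.array(
        [
            [1, 1, 1, 0],
            [2, 0, 2, 1],
            [0, lv.MISSING, 0, 2],
        ],
        dtype=np.int8,
    )
    return lv.GenotypeMatrix(["s1", "s2", "s3"], sites, codes)
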