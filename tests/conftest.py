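import numpy as np
import pandas as pd
import pytest

from mistrans_sga.io import PSMRecord, PRO_SER_DELTA
from mistrans_sga.simulate import (
    ScreenScenario,
    plate_border_mask,
    simulate_screen,
)


@pytest.fixture(scope="session")
def border_mask():
    return plate_border_mask()


@pytest.fixture(scope="session")
def small_screen():
    """One-plate screen (345 alleles), 20 planted interactions at -0.4."""
    sc = ScreenScenario(
        seed=11, n_alleles=345,
        interactions={i: -0.4 for i in range(20)},
        noise_sd=0.05,
    )
    return sc, simulate_screen(sc)


def make_psm(peptide, mods=(), q=0.001, count=1, protein="p1"):
    return PSMRecord(peptide=peptide, mod_sites=list(mods), psm_q=q,
                     count=count, protein_id=protein)


@pytest.fixture
def psm_factory():
    return make_psm


@pytest.fixture
def pro_ser():
    return PRO_SER_DELTA


@pytest.fixture
def spot_frame():
    """Minimal valid spot table: one strain, 4 constructs, 3 replicates."""
    rows = []
    for construct, mean in [("WT-tS", 100.0), ("3'-tS(UGG)", 71.0),
                            ("5'-tS(UGG)", 55.0), ("tS(UGG)", 37.0)]:
        for rep in range(1, 4):
            rows.append(("BY4742", construct, rep, mean))
    return pd.DataFrame(rows, columns=["strain", "construct", "replicate",
                                       "intensity"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
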