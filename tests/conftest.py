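import numpy as np
import pandas as pd
import pytest

from latisoy.io_formats import GenotypeMatrix
from latisoy.simdata import SimConfig, simulate_panel


def make_gm(dosages, chrom="Gm01", positions=None, refs=None, alts=None):
    """Small GenotypeMatrix from a dosage array (rows = accessions)."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    positions = positions if positions is not None else list(range(0, 10 * m, 10))
    refs = refs or ["A"] * m
    alts = alts or ["T"] * m
    variants = pd.DataFrame({
        "chrom": [chrom] * m, "pos": positions,
        "id": [f"v{j}" for j in range(m)], "ref": refs, "alt": alts})
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, d)


@pytest.fixture(scope="session")
def small_panel():
    """~300-accession panel with the default signal structure."""
    cfg = SimConfig(n_wild=30, n_landrace=120, n_cultivar=150,
                    n_background_snps=120, seed=11)
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def big_panel():
    """n=2000 panel at the stated validation world (effect -6, noise 3)."""
    cfg = SimConfig(n_wild=70, n_landrace=720, n_cultivar=1210,
                    n_background_snps=100, seed=29)
    return simulate_panel(cfg)
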