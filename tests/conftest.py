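import numpy as np
import pandas as pd
import pytest

from pathprs.io import GenotypePanel, HarmonizedStudy, SummaryStats


def make_panel(dosages, chrom=None, pos=None, a1=None, a2=None, ids=None):
    """Build a GenotypePanel from a raw dosage array with simple metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    ids = ids or [f"rs{j+1}" for j in range(m)]
    meta = pd.DataFrame(
        {
            "chrom": chrom or ["1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "a1": a1 or ["A"] * m,
            "a2": a2 or ["G"] * m,
        },
        index=pd.Index(ids, name="snp"),
    )
    return GenotypePanel([f"s{i+1}" for i in range(n)], meta, dosages)


def make_study(dosages, beta, p, **panel_kw):
    """HarmonizedStudy with stats matching the panel's allele orientation."""
    panel = make_panel(dosages, **panel_kw)
    table = panel.snps.rename(columns={"a1": "effect_allele", "a2": "other_allele"}).copy()
    table["beta"] = np.asarray(beta, dtype=float)
    table["p"] = np.asarray(p, dtype=float)
    stats = SummaryStats(table)
    return HarmonizedStudy(panel, stats, pd.DataFrame(columns=["snp", "reason"]))


@pytest.fixture
def small_panel():
    rng = np.random.default_rng(11)
    return make_panel(rng.integers(0, 3, size=(40, 6)).astype(float))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
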