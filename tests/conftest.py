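import numpy as np
import pandas as pd
import pytest

from mrmediate.harmonize import HarmonizedSet
from mrmediate.sumstats import SummaryStatTable


def make_hset(gamma, se_x, Gamma, se_y, ids=None, n_x=100_000, n_y=200_000):
    """Build a HarmonizedSet directly from effect arrays (A/G coding)."""
    gamma = np.asarray(gamma, float)
    n = gamma.size
    ids = list(ids) if ids is not None else [f"rs{i+1}" for i in range(n)]
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": ["1"] * n,
            "pos": np.arange(1, n + 1) * 1_000_000,
            "effect_allele": ["A"] * n,
            "other_allele": ["G"] * n,
            "gamma": gamma,
            "se_x": np.asarray(se_x, float),
            "eaf_x": [0.3] * n,
            "p_x": [1e-10] * n,
            "n_x": [float(n_x)] * n,
            "Gamma": np.asarray(Gamma, float),
            "se_y": np.asarray(se_y, float),
            "eaf_y": [0.3] * n,
            "p_y": [0.5] * n,
            "n_y": [float(n_y)] * n,
            "action": ["kept"] * n,
        }
    )
    return HarmonizedSet(df, "exposure", "outcome")


def make_table(rows, trait_name="trait", trait_type="continuous"):
    """SummaryStatTable from a list of dicts with canonical keys."""
    defaults = {
        "chrom": "1",
        "pos": 1,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.01,
        "pvalue": 1e-10,
        "n": 100_000.0,
        "n_cases": np.nan,
        "n_controls": np.nan,
    }
    recs = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.setdefault("variant_id", f"rs{i+1}")
        rec.update(row)
        recs.append(rec)
    columns = ["variant_id"] + list(defaults)
    df = pd.DataFrame(recs, columns=columns)
    return SummaryStatTable(df, trait_name, trait_type)


@pytest.fixture
def rng():
    return np.random.default_rng(20240815)
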