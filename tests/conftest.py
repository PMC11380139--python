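import numpy as np
import pandas as pd
import pytest

from mrpipe.gwas_io import HarmonizedSet, SummaryTable, table_from_dataframe
from mrpipe.synthgwas import SimulationConfig, simulate_pair


def make_table(rows, trait_id="trait", **kw) -> SummaryTable:
    """Build a SummaryTable from a list of dicts with canonical keys."""
    return table_from_dataframe(pd.DataFrame(rows), trait_id=trait_id, **kw)


def make_harmonized(bx, by, sx=None, sy=None, snps=None) -> HarmonizedSet:
    """Directly assemble a HarmonizedSet from effect arrays (unit SEs default)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    J = len(bx)
    sx = np.ones(J) if sx is None else np.asarray(sx, dtype=float)
    sy = np.ones(J) if sy is None else np.asarray(sy, dtype=float)
    snps = snps or [f"rs{i}" for i in range(J)]
    data = pd.DataFrame({
        "snp": snps, "effect_allele": "A", "other_allele": "G",
        "beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy,
        "eaf": 0.3, "flipped": False, "palindromic": False,
    })
    return HarmonizedSet("exp", "out", data)


@pytest.fixture
def basic_tables():
    exposure = make_table([
        {"snp": "rs1", "chr": "1", "pos": 1000, "effect_allele": "A",
         "other_allele": "G", "eaf": 0.3, "beta": 0.10, "se": 0.01,
         "pval": 1e-20, "n": 10000},
        {"snp": "rs2", "chr": "2", "pos": 2000, "effect_allele": "C",
         "other_allele": "T", "eaf": 0.4, "beta": -0.20, "se": 0.02,
         "pval": 1e-18, "n": 10000},
        {"snp": "rs3", "chr": "3", "pos": 3000, "effect_allele": "T",
         "other_allele": "G", "eaf": 0.2, "beta": 0.15, "se": 0.015,
         "pval": 1e-15, "n": 10000},
    ], trait_id="exp")
    outcome = make_table([
        {"snp": "rs1", "chr": "1", "pos": 1000, "effect_allele": "A",
         "other_allele": "G", "eaf": 0.3, "beta": 0.02, "se": 0.01,
         "pval": 0.05, "n": 50000},
        {"snp": "rs2", "chr": "2", "pos": 2000, "effect_allele": "T",
         "other_allele": "C", "eaf": 0.6, "beta": 0.04, "se": 0.02,
         "pval": 0.04, "n": 50000},
        {"snp": "rs3", "chr": "3", "pos": 3000, "effect_allele": "T",
         "other_allele": "G", "eaf": 0.2, "beta": 0.03, "se": 0.012,
         "pval": 0.01, "n": 50000},
    ], trait_id="out")
    return exposure, outcome


@pytest.fixture
def sim_pair():
    return simulate_pair(SimulationConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
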