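"""Multivariable MR: joint direct effects of several exposures on one outcome.

With K exposures and J instruments, beta_outcome is regressed on the J x K
matrix of exposure effects without an intercept, weighted by 1/se_outcome^2.
Each exposure's coefficient is its direct effect conditional on the others.
Variance estimates carry a multiplicative overdispersion floored at 1 and
inference is Student-t with J - K df.  An Egger-style variant adds an
intercept (after orienting rows so the primary exposure's effects are
non-negative) to test directional pleiotropy, and a Q statistic with J - K df
measures residual heterogeneity.

Instrument assembly follows the union rule: each exposure's independently
selected instruments are pooled, re-extracted from every exposure and the
outcome table, harmonized onto a shared effect allele, and kept complete-case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ConfigError, EstimationError
from .estimators import MRResult
from .gwas_io import HarmonizedSet, SummaryTable, harmonize
from .instruments import select_instruments
from .sensitivity import HeterogeneityResult

__all__ = [
    "MVHarmonizedSet", "MVMRModel", "mvmr_ivw", "mvmr_egger_intercept",
    "mvmr_q", "assemble_mvmr",
]


@dataclass
class MVHarmonizedSet:
    """Jointly harmonized effects for K >= 2 exposures and one outcome.

    ``data`` columns: snp, beta_exp_<id> and se_exp_<id> for each exposure id
    (in ``exposure_ids`` order), beta_out, se_out.
    """

    outcome_id: str
    exposure_ids: list[str]
    data: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )

    def __post_init__(self) -> None:
        if len(self.exposure_ids) < 1:
            raise ConfigError("MVMR needs at least one exposure")

    @property
    def n_snp(self) -> int:
        return len(self.data)

    @property
    def K(self) -> int:
        return len(self.exposure_ids)

    @property
    def X(self) -> np.ndarray:
        cols = [f"beta_exp_{e}" for e in self.exposure_ids]
        return self.data[cols].to_numpy(dtype=float)

    @property
    def by(self) -> np.ndarray:
        return self.data["beta_out"].to_numpy(dtype=float)

    @property
    def sy(self) -> np.ndarray:
        return self.data["se_out"].to_numpy(dtype=float)


def _check_rank(m: MVHarmonizedSet, X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        worst, pair = 0.0, (m.exposure_ids[0], m.exposure_ids[-1])
        for i in range(m.K):
            for j in range(i + 1, m.K):
                if abs(corr[i, j]) > worst:
                    worst = abs(corr[i, j])
                    pair = (m.exposure_ids[i], m.exposure_ids[j])
        raise EstimationError(
            f"collinear exposures: design is rank deficient "
            f"(worst pair {pair[0]!r} vs {pair[1]!r}, |r| = {worst:.3f})"
        )


def mvmr_ivw(m: MVHarmonizedSet) -> list[MRResult]:
    """Per-exposure direct effects from the no-intercept weighted regression."""
    J, K = m.n_snp, m.K
    if J <= K + 1:
        raise EstimationError(f"MVMR needs n_snp > K + 1 (J={J}, K={K})")
    X = m.X
    _check_rank(m, X)
    w = 1.0 / m.sy**2
    fit = sm.WLS(m.by, X, weights=w).fit()
    scale = float(fit.scale)  # weighted RSS / (J - K)
    cov = np.asarray(fit.normalized_cov_params) * max(1.0, scale)
    df = J - K
    out = []
    for k, exp_id in enumerate(m.exposure_ids):
        beta = float(fit.params[k])
        se = float(np.sqrt(cov[k, k]))
        pval = float(2.0 * stats.t.sf(abs(beta) / se, df))
        out.append(MRResult(
            "mvmr_ivw", J, beta, se, pval,
            extras={"exposure": exp_id, "df": df,
                    "overdispersion": max(1.0, scale)},
        ))
    return out


def mvmr_egger_intercept(m: MVHarmonizedSet,
                         primary: str | None = None) -> tuple[float, float, float]:
    """(intercept, se, p) from the MVMR regression with an intercept.

    Rows are oriented so the primary exposure's effects are non-negative
    before fitting, mirroring the univariable Egger convention.
    """
    J, K = m.n_snp, m.K
    if J <= K + 2:
        raise EstimationError(f"MVMR-Egger needs n_snp > K + 2 (J={J}, K={K})")
    primary = primary or m.exposure_ids[0]
    kcol = m.exposure_ids.index(primary)
    X = m.X
    s = np.where(X[:, kcol] < 0, -1.0, 1.0)
    Xo = X * s[:, None]
    yo = m.by * s
    _check_rank(m, Xo)
    w = 1.0 / m.sy**2
    fit = sm.WLS(yo, sm.add_constant(Xo), weights=w).fit()
    scale = float(fit.scale)
    cov = np.asarray(fit.normalized_cov_params) * max(1.0, scale)
    intercept = float(fit.params[0])
    se = float(np.sqrt(cov[0, 0]))
    df = J - K - 1
    pval = float(2.0 * stats.t.sf(abs(intercept) / se, df))
    return intercept, se, pval


def mvmr_q(m: MVHarmonizedSet) -> HeterogeneityResult:
    """Residual heterogeneity of the no-intercept MVMR fit (chi-square, J-K df)."""
    J, K = m.n_snp, m.K
    if J <= K:
        raise EstimationError(f"MVMR Q needs n_snp > K (J={J}, K={K})")
    X = m.X
    _check_rank(m, X)
    w = 1.0 / m.sy**2
    fit = sm.WLS(m.by, X, weights=w).fit()
    resid = m.by - X @ np.asarray(fit.params)
    q = float(np.sum(w * resid**2))
    df = J - K
    return HeterogeneityResult(Q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def assemble_mvmr(
    exposures: dict[str, SummaryTable],
    outcome: SummaryTable,
    p_threshold: float = 5e-8,
    palindrome_policy: str = "infer_by_eaf",
    **select_kw,
) -> MVHarmonizedSet:
    """Build an MVHarmonizedSet by the union-of-instruments rule.

    Each exposure's instruments are selected independently; the union of ids
    is re-extracted from every exposure table and the outcome table,
    harmonized pairwise onto the first exposure's allele orientation, and
    restricted to SNPs observed in all tables (complete case).
    """
    if len(exposures) < 1:
        raise ConfigError("assemble_mvmr needs at least one exposure table")
    exposure_ids = list(exposures)
    union: list[str] = []
    for exp_id, table in exposures.items():
        inst = select_instruments(table, p_threshold=p_threshold, **select_kw)
        for s in inst.snp_ids:
            if s not in union:
                union.append(s)

    ref_id = exposure_ids[0]
    ref = exposures[ref_id]
    ref_rows = ref.data[ref.data["snp"].isin(union)]
    ref_sub = SummaryTable(ref.trait_id, ref_rows.reset_index(drop=True),
                           ref.trait_type, ref.n_case, ref.n_control)

    merged = ref_sub.data[["snp", "effect_allele", "other_allele", "beta", "se"]].rename(
        columns={"beta": f"beta_exp_{ref_id}", "se": f"se_exp_{ref_id}"}
    )
    dropped_all: list[pd.DataFrame] = []
    for other_id in exposure_ids[1:]:
        hset = harmonize(ref_sub, exposures[other_id],
                         palindrome_policy=palindrome_policy)
        dropped_all.append(hset.dropped)
        part = hset.data[["snp", "beta_out", "se_out"]].rename(
            columns={"beta_out": f"beta_exp_{other_id}",
                     "se_out": f"se_exp_{other_id}"}
        )
        merged = merged.merge(part, on="snp", how="inner")
    hout = harmonize(ref_sub, outcome, palindrome_policy=palindrome_policy)
    dropped_all.append(hout.dropped)
    merged = merged.merge(
        hout.data[["snp", "beta_out", "se_out"]], on="snp", how="inner"
    )
    dropped = (pd.concat(dropped_all, ignore_index=True)
               if dropped_all else pd.DataFrame(columns=["snp", "reason"]))
    return MVHarmonizedSet(
        outcome_id=outcome.trait_id,
        exposure_ids=exposure_ids,
        data=merged.drop(columns=["effect_allele", "other_allele"]).reset_index(drop=True),
        dropped=dropped,
    )


class MVMRModel:
    """Statsmodels-style facade over the multivariable-MR operations."""

    def __init__(self, mv: MVHarmonizedSet):
        self.m = mv

    @classmethod
    def from_tables(cls, exposures, outcome, **kw) -> "MVMRModel":
        return cls(assemble_mvmr(exposures, outcome, **kw))

    def fit(self) -> list[MRResult]:
        return mvmr_ivw(self.m)

    def egger_intercept(self, primary: str | None = None):
        return mvmr_egger_intercept(self.m, primary=primary)

    def heterogeneity(self) -> HeterogeneityResult:
        return mvmr_q(self.m)


def univariable_from_mv(m: MVHarmonizedSet, exposure_id: str) -> HarmonizedSet:
    """Extract one exposure's rows as a univariable HarmonizedSet."""
    df = pd.DataFrame({
        "snp": m.data["snp"],
        "effect_allele": "A", "other_allele": "G",
        "beta_exp": m.data[f"beta_exp_{exposure_id}"],
        "se_exp": m.data[f"se_exp_{exposure_id}"],
        "beta_out": m.data["beta_out"],
        "se_out": m.data["se_out"],
        "eaf": np.nan, "flipped": False, "palindromic": False,
    })
    return HarmonizedSet(exposure_id, m.outcome_id, df)
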