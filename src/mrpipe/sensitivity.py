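"""Heterogeneity, pleiotropy and outlier diagnostics for two-sample MR.

- Cochran's Q: weighted sum of squared ratio deviations from the pooled
  estimate, chi-square reference with J - 1 df (J - 2 for the Egger fit).
- Egger intercept test: directional-pleiotropy t-test from the MR-Egger fit.
- MR-PRESSO: Monte-Carlo residual-sum-of-squares test.  The global test
  compares the observed leave-one-out weighted RSS to its distribution under
  simulated pleiotropy-free data; the outlier test compares each SNP's
  residual to its own simulated distribution (Bonferroni across SNPs); the
  distortion test compares the raw-vs-outlier-corrected estimate shift to
  shifts from removing random same-size subsets in the simulated null.
  Monte-Carlo p-values use the add-one estimator, so their resolution is
  1 / (n_sim + 1) and they are never exactly zero.
- Leave-one-out: J re-estimates each omitting one SNP, with flags for
  omissions that change the estimate's sign or its significance at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, EstimationError
from .estimators import MRResult, egger, ivw
from .gwas_io import HarmonizedSet

__all__ = [
    "HeterogeneityResult", "PressoReport", "cochran_q", "egger_intercept_test",
    "mr_presso", "leave_one_out", "loo_frame", "funnel_data",
]


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    pval: float

    def summary(self) -> str:
        return f"Cochran's Q = {self.Q:.3f} on {self.df} df (p = {self.pval:.3g})"


def cochran_q(
    h: HarmonizedSet,
    theta: float | None = None,
    weights: np.ndarray | None = None,
    df_loss: int = 1,
) -> HeterogeneityResult:
    """Cochran's Q about ``theta`` (default: the IVW fixed-effect estimate)."""
    if h.n_snp < 2:
        raise EstimationError("Cochran's Q needs at least 2 instruments")
    ratios = h.by / h.bx
    w = weights if weights is not None else h.bx**2 / h.sy**2
    if theta is None:
        theta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - theta) ** 2))
    df = h.n_snp - df_loss
    return HeterogeneityResult(Q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """(intercept, se, p) from the MR-Egger fit; two-sided t with J - 2 df."""
    res = egger(h)
    return (res.extras["intercept"], res.extras["intercept_se"],
            res.extras["intercept_pval"])


@dataclass
class PressoReport:
    """MR-PRESSO global / outlier / distortion results."""

    observed_rss: float
    global_pval: float
    n_sim: int
    per_snp_pvals: dict[str, float]
    outliers: list[str]
    raw_estimate: MRResult
    corrected_estimate: MRResult | None = None
    distortion_pval: float | None = None
    seed: int = 0
    outlier_alpha: float = 0.05
    adjusted_pvals: dict[str, float] = field(default_factory=dict)

    @property
    def resolution(self) -> float:
        return 1.0 / (self.n_sim + 1)

    def summary(self) -> str:
        lines = [
            "MR-PRESSO",
            f"  global RSS p : {self.global_pval:.4g} "
            f"({self.n_sim} simulations, resolution {self.resolution:.2g})",
            f"  outliers     : {', '.join(self.outliers) if self.outliers else 'none'}",
        ]
        if self.distortion_pval is not None:
            lines.append(f"  distortion p : {self.distortion_pval:.4g}")
        return "\n".join(lines)


def _loo_ivw_estimates(bx, by, w):
    """Leave-one-out IVW estimates computed in one vectorized pass."""
    theta = by / bx
    s_wt = np.sum(w * theta, axis=-1, keepdims=True)
    s_w = np.sum(w, axis=-1, keepdims=True)
    return (s_wt - w * theta) / (s_w - w)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 3000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoReport:
    """Simulation-based pleiotropy residual sum and outlier test.

    Observed RSS uses, for each SNP, the leave-one-out IVW prediction
    theta_hat^(-j) * bx_j with weight 1/sy_j^2.  Simulated datasets draw
    by*_j ~ N(theta_hat^(-j) bx_j, sy_j) and recompute the RSS with their own
    leave-one-out estimates, so observed and simulated statistics are
    exchangeable under the no-pleiotropy null.
    """
    if h.n_snp < 4:
        raise EstimationError("MR-PRESSO is undefined for fewer than 4 instruments")
    if n_sim < 1:
        raise ConfigError("n_sim must be positive")
    rng = np.random.default_rng(seed)
    bx, by, sy = h.bx, h.by, h.sy
    snps = h.snp_ids
    J = h.n_snp
    w_ratio = bx**2 / sy**2
    w_res = 1.0 / sy**2

    theta_loo = _loo_ivw_estimates(bx, by, w_ratio)
    resid_obs = by - theta_loo * bx
    rss_j_obs = w_res * resid_obs**2
    rss_obs = float(np.sum(rss_j_obs))

    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, J))
    theta_loo_sim = _loo_ivw_estimates(bx[None, :], by_sim, w_ratio[None, :])
    resid_sim = by_sim - theta_loo_sim * bx[None, :]
    rss_j_sim = w_res[None, :] * resid_sim**2
    rss_sim = rss_j_sim.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    exceed = (rss_j_sim >= rss_j_obs[None, :]).sum(axis=0)
    per_snp = (1 + exceed) / (n_sim + 1)
    adjusted = np.minimum(1.0, per_snp * J)
    outlier_mask = adjusted < outlier_alpha
    outliers = [s for s, flag in zip(snps, outlier_mask) if flag]

    raw = ivw(h, mode="auto")
    corrected = None
    distortion_pval = None
    if outliers:
        kept = h.drop_snps(outliers)
        if kept.n_snp >= 2:
            corrected = ivw(kept, mode="auto")
            d_obs = abs(corrected.beta - raw.beta)
            # Null reference: remove a random same-size subset from each
            # simulated pleiotropy-free dataset and record the estimate shift.
            k = len(outliers)
            d_null = np.empty(n_sim)
            theta_sim = by_sim / bx[None, :]
            full_est = (w_ratio[None, :] * theta_sim).sum(axis=1) / w_ratio.sum()
            for i in range(n_sim):
                drop = rng.choice(J, size=k, replace=False)
                keep_mask = np.ones(J, dtype=bool)
                keep_mask[drop] = False
                sub_w = w_ratio[keep_mask]
                sub_est = float(np.sum(sub_w * theta_sim[i, keep_mask]) / sub_w.sum())
                d_null[i] = abs(sub_est - full_est[i])
            distortion_pval = float((1 + np.sum(d_null >= d_obs)) / (n_sim + 1))

    return PressoReport(
        observed_rss=rss_obs,
        global_pval=global_pval,
        n_sim=n_sim,
        per_snp_pvals=dict(zip(snps, per_snp.astype(float))),
        outliers=outliers,
        raw_estimate=raw,
        corrected_estimate=corrected,
        distortion_pval=distortion_pval,
        seed=seed,
        outlier_alpha=outlier_alpha,
        adjusted_pvals=dict(zip(snps, adjusted.astype(float))),
    )


def leave_one_out(h: HarmonizedSet) -> list[tuple[str, MRResult]]:
    """IVW re-estimates each omitting one SNP (J results for J instruments)."""
    if h.n_snp < 3:
        raise EstimationError("leave-one-out needs at least 3 instruments")
    out = []
    for snp in h.snp_ids:
        out.append((snp, ivw(h.drop_snps([snp]), mode="auto")))
    return out


def loo_frame(loo: list[tuple[str, MRResult]], full: MRResult) -> pd.DataFrame:
    """Tabulate leave-one-out results, flagging influential omissions.

    An omission is flagged when it changes the sign of the estimate or its
    significance status at alpha = 0.05 relative to the full-set result.
    """
    rows = []
    for snp, res in loo:
        flagged = (np.sign(res.beta) != np.sign(full.beta)
                   or (res.pval < 0.05) != (full.pval < 0.05))
        d = res.to_dict()
        d["excluded_snp"] = snp
        d["flagged"] = bool(flagged)
        rows.append(d)
    cols = ["excluded_snp", "method", "n_snp", "beta", "se", "or",
            "ci_low", "ci_high", "pval", "flagged"]
    return pd.DataFrame(rows, columns=cols)


def funnel_data(h: HarmonizedSet) -> tuple[pd.DataFrame, dict]:
    """Per-SNP ratio estimates with precisions, plus reference-line parameters.

    Returns (table, lines) where ``table`` has one row per SNP (ratio, and
    precision = |bx| / sy, the reciprocal first-order ratio se) and ``lines``
    carries the IVW estimate and, when J >= 3, the Egger slope/intercept.
    """
    if h.n_snp < 1:
        raise EstimationError("funnel data needs at least 1 instrument")
    table = pd.DataFrame({
        "snp": h.snp_ids,
        "ratio": h.by / h.bx,
        "precision": np.abs(h.bx) / h.sy,
    })
    lines: dict = {}
    if h.n_snp >= 2:
        lines["ivw_beta"] = ivw(h, mode="auto").beta
    if h.n_snp >= 3:
        e = egger(h)
        lines["egger_beta"] = e.beta
        lines["egger_intercept"] = e.extras["intercept"]
    return table, lines
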