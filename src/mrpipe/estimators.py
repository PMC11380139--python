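"""Two-sample MR estimators on harmonized summary statistics.

Given J harmonized instruments with exposure effects bx_j (se sx_j) and
outcome effects by_j (se sy_j), the per-SNP Wald ratio is theta_j = by_j /
bx_j with first-order variance sy_j^2 / bx_j^2.  The estimators:

- IVW: precision-weighted mean of the ratios, equivalent to the no-intercept
  weighted regression of by on bx with weights 1/sy^2.  The random-effects
  variant inflates the fixed-effect variance by the multiplicative
  overdispersion max(1, Q/(J-1)); ``mode="auto"`` picks random effects when
  Cochran's Q has p < 0.05 and records the choice.
- MR-Egger: the same regression with an intercept after orienting all rows to
  bx >= 0; the slope remains a causal estimate under InSIDE and the intercept
  measures directional pleiotropy.  Inference is Student-t with J - 2 df and a
  multiplicative overdispersion floored at 1.
- Weighted median: the 50th weighted percentile of the ratios; robust when up
  to half the weight sits on invalid instruments.  SE by parametric bootstrap.
- Weighted mode: the maximizer of a weighted Gaussian kernel density over the
  ratios (bandwidth = phi x Silverman); robust when the largest group of
  instruments sharing one ratio is valid.  SE by parametric bootstrap.

Binary-outcome effects are log odds ratios throughout, so exp(beta) with its
normal-theory interval is the odds-ratio report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .exceptions import ConfigError, EstimationError
from .gwas_io import HarmonizedSet

__all__ = [
    "MRResult", "MRModel", "wald_ratio", "ivw", "egger",
    "weighted_median", "weighted_mode", "or_ci",
]

Z95 = stats.norm.ppf(0.975)


def or_ci(beta: float, se: float, level: float = 0.95):
    """Odds ratio with normal-theory CI and two-sided normal p.

    Returns ``(or_, ci_low, ci_high, pval)`` with OR = exp(beta) and
    CI = exp(beta -/+ z * se) at the given level.
    """
    if not 0 < level < 1:
        raise ConfigError(f"confidence level must lie in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    pval = 2.0 * stats.norm.sf(abs(beta) / se)
    return (np.exp(beta), np.exp(beta - z * se), np.exp(beta + z * se), pval)


@dataclass
class MRResult:
    """A single MR estimate: causal beta, uncertainty, and OR-scale report."""

    method: str
    n_snp: int
    beta: float
    se: float
    pval: float
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.or_, self.ci_low, self.ci_high, _ = or_ci(self.beta, self.se)

    def summary(self) -> str:
        lines = [
            f"MR estimate ({self.method})",
            "-" * 44,
            f"  instruments : {self.n_snp}",
            f"  beta        : {self.beta:+.6f} (se {self.se:.6f})",
            f"  OR (95% CI) : {self.or_:.3f} ({self.ci_low:.3f}-{self.ci_high:.3f})",
            f"  p-value     : {self.pval:.3g}",
        ]
        for key, val in self.extras.items():
            lines.append(f"  {key:<12}: {val}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "method": self.method, "n_snp": self.n_snp, "beta": self.beta,
            "se": self.se, "pval": self.pval, "or": self.or_,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        }


def _check(h: HarmonizedSet, minimum: int, method: str) -> None:
    if h.n_snp < minimum:
        hint = "; use wald_ratio for a single instrument" if minimum == 2 else ""
        raise EstimationError(
            f"{method} needs at least {minimum} instruments, got {h.n_snp}{hint}"
        )
    if np.any(h.bx == 0):
        raise EstimationError(f"{method}: null instrument (bx = 0) in set")


def wald_ratio(bx: float, by: float, sx: float, sy: float,
               second_order: bool = False) -> MRResult:
    """Single-SNP causal estimate by/bx with (first-order) delta-method se."""
    if bx == 0:
        raise EstimationError("null instrument: bx = 0")
    beta = by / bx
    var = sy**2 / bx**2
    if second_order:
        var += by**2 * sx**2 / bx**4
    se = float(np.sqrt(var))
    pval = 2.0 * stats.norm.sf(abs(beta) / se)
    return MRResult("wald_ratio", 1, float(beta), se, float(pval),
                    extras={"second_order": second_order})


def _ratio_weights(h: HarmonizedSet, second_order: bool = False) -> np.ndarray:
    """Inverse first-order ratio variances: w_j = bx_j^2 / sy_j^2."""
    var = h.sy**2 / h.bx**2
    if second_order:
        var += h.by**2 * h.sx**2 / h.bx**4
    return 1.0 / var


def ivw(h: HarmonizedSet, mode: str = "auto", second_order: bool = False) -> MRResult:
    """Inverse-variance weighted estimate with fixed/random/auto variance.

    ``auto`` applies random effects exactly when Cochran's Q for the fit has
    p < 0.05, mirroring the switch used in applied MR pipelines.
    """
    if mode not in ("fixed", "random", "auto"):
        raise ConfigError(f"unknown IVW mode {mode!r}")
    _check(h, 2, "ivw")
    theta = h.by / h.bx
    w = _ratio_weights(h, second_order=second_order)
    sw = float(np.sum(w))
    beta = float(np.sum(w * theta) / sw)
    se_fixed = float(np.sqrt(1.0 / sw))
    J = h.n_snp
    q = float(np.sum(w * (theta - beta) ** 2))
    q_df = J - 1
    q_pval = float(stats.chi2.sf(q, q_df))
    overdispersion = max(1.0, q / q_df)
    if mode == "auto":
        chosen = "random" if q_pval < 0.05 else "fixed"
    else:
        chosen = mode
    se = se_fixed * np.sqrt(overdispersion) if chosen == "random" else se_fixed
    pval = 2.0 * stats.norm.sf(abs(beta) / se)
    return MRResult(
        f"ivw_{chosen}" if mode != "auto" else "ivw_auto", J, beta, float(se),
        float(pval),
        extras={"mode_used": chosen, "Q": q, "Q_df": q_df, "Q_pval": q_pval,
                "overdispersion": overdispersion, "se_fixed": se_fixed},
    )


def _oriented(h: HarmonizedSet):
    """Flip rows so every exposure effect is non-negative (Egger convention)."""
    s = np.where(h.bx < 0, -1.0, 1.0)
    return s * h.bx, s * h.by


def egger(h: HarmonizedSet) -> MRResult:
    """MR-Egger: weighted regression of by on bx with an intercept.

    The slope is the causal estimate; the intercept estimates the average
    directional pleiotropic effect.  Both use Student-t inference with J - 2
    df and residual overdispersion floored at 1.
    """
    _check(h, 3, "egger")
    bx, by = _oriented(h)
    w = 1.0 / h.sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    J = h.n_snp
    scale = float(fit.scale)  # weighted RSS / (J - 2)
    # (X'WX)^-1 times overdispersion floored at 1 (robust to exact fits)
    cov = np.asarray(fit.normalized_cov_params) * max(1.0, scale)
    intercept, slope = (float(v) for v in fit.params)
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    df = J - 2
    p_slope = 2.0 * stats.t.sf(abs(slope) / se_slope, df)
    p_int = 2.0 * stats.t.sf(abs(intercept) / se_int, df)
    return MRResult(
        "egger", J, slope, se_slope, float(p_slope),
        extras={"intercept": intercept, "intercept_se": se_int,
                "intercept_pval": float(p_int), "df": df,
                "overdispersion": max(1.0, scale)},
    )


def weighted_percentile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Weighted percentile with linear interpolation between order statistics.

    Uses the midpoint convention: the k-th sorted value sits at cumulative
    weight (sum of weights below it) + w_k / 2, all normalized to 1.
    """
    order = np.argsort(values, kind="mergesort")
    v, w = np.asarray(values, float)[order], np.asarray(weights, float)[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(q, cum, v))


def _bootstrap_se(h: HarmonizedSet, stat, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: resample (bx, by) from their sampling normals."""
    rng = np.random.default_rng(seed)
    J = h.n_snp
    bx = rng.normal(h.bx, h.sx, size=(n_boot, J))
    by = rng.normal(h.by, h.sy, size=(n_boot, J))
    est = np.empty(n_boot)
    for i in range(n_boot):
        est[i] = stat(bx[i], by[i], h.sy)
    return float(np.std(est, ddof=1))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of the ratio estimates; bootstrap standard error."""
    if n_boot <= 0:
        raise ConfigError("n_boot must be positive")
    _check(h, 3, "weighted_median")

    def stat(bx, by, sy):
        theta = by / bx
        w = bx**2 / sy**2
        return weighted_percentile(theta, w, 0.5)

    beta = stat(h.bx, h.by, h.sy)
    se = _bootstrap_se(h, stat, n_boot, seed)
    pval = 2.0 * stats.norm.sf(abs(beta) / se)
    return MRResult("weighted_median", h.n_snp, beta, se, float(pval),
                    extras={"n_boot": n_boot, "seed": seed})


def _silverman_bandwidth(theta: np.ndarray, w: np.ndarray) -> float:
    """Silverman's rule on the weighted ratio distribution."""
    w = w / w.sum()
    mean = np.sum(w * theta)
    sd = float(np.sqrt(np.sum(w * (theta - mean) ** 2)))
    iqr = weighted_percentile(theta, w, 0.75) - weighted_percentile(theta, w, 0.25)
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread == 0:
        return 0.0
    return 0.9 * spread * len(theta) ** (-0.2)


def _mode_estimate(theta: np.ndarray, w: np.ndarray, phi: float) -> float:
    h = phi * _silverman_bandwidth(theta, w)
    if h == 0:  # all ratios identical (up to weighting): the mode is that value
        return float(theta[0])
    wn = w / w.sum()

    def neg_density(x):
        return -np.sum(wn * np.exp(-0.5 * ((x - theta) / h) ** 2))

    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 1024)
    dens = (np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2) * wn).sum(axis=1)
    i = int(np.argmax(dens))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_density, bounds=(lo, hi), method="bounded")
    return float(res.x)


def weighted_mode(h: HarmonizedSet, phi: float = 1.0, n_boot: int = 1000,
                  seed: int = 0) -> MRResult:
    """Mode of the weighted kernel density over ratios; bootstrap se."""
    if phi <= 0:
        raise ConfigError("phi (bandwidth multiplier) must be positive")
    if n_boot <= 0:
        raise ConfigError("n_boot must be positive")
    _check(h, 3, "weighted_mode")

    def stat(bx, by, sy):
        theta = by / bx
        w = bx**2 / sy**2
        return _mode_estimate(theta, w, phi)

    beta = stat(h.bx, h.by, h.sy)
    se = _bootstrap_se(h, stat, n_boot, seed)
    pval = 2.0 * stats.norm.sf(abs(beta) / se)
    return MRResult("weighted_mode", h.n_snp, beta, se, float(pval),
                    extras={"phi": phi, "n_boot": n_boot, "seed": seed})


_METHODS = {
    "ivw": ivw,
    "egger": egger,
    "weighted_median": weighted_median,
    "weighted_mode": weighted_mode,
}
_MIN_SNPS = {"ivw": 2, "egger": 3, "weighted_median": 3, "weighted_mode": 3}


class MRModel:
    """Two-sample MR model for one harmonized exposure-outcome pair.

    Statsmodels-style facade: build from a :class:`HarmonizedSet` (or from raw
    exposure/outcome tables via :meth:`from_tables`), then ``fit`` a method to
    obtain an :class:`MRResult`, or ``fit_all`` for the standard four-method
    battery.  Sensitivity diagnostics are exposed as methods so a full
    analysis can hang off one object.
    """

    def __init__(self, harmonized: HarmonizedSet):
        self.h = harmonized

    @classmethod
    def from_tables(cls, exposure, outcome, **harmonize_kw) -> "MRModel":
        from .gwas_io import harmonize
        return cls(harmonize(exposure, outcome, **harmonize_kw))

    @property
    def n_snp(self) -> int:
        return self.h.n_snp

    def fit(self, method: str = "ivw", **kw) -> MRResult:
        if method == "wald_ratio":
            if self.h.n_snp != 1:
                raise EstimationError("wald_ratio applies to a single instrument")
            row = self.h.data.iloc[0]
            return wald_ratio(row.beta_exp, row.beta_out, row.se_exp, row.se_out)
        if method not in _METHODS:
            raise ConfigError(f"unknown MR method {method!r}")
        return _METHODS[method](self.h, **kw)

    def fit_all(self, methods=("ivw", "egger", "weighted_median", "weighted_mode"),
                seed: int = 0, n_boot: int = 1000) -> dict[str, MRResult]:
        out: dict[str, MRResult] = {}
        for i, m in enumerate(methods):
            if self.h.n_snp < _MIN_SNPS.get(m, 2):
                continue
            kw = {}
            if m in ("weighted_median", "weighted_mode"):
                kw = {"seed": seed + i, "n_boot": n_boot}
            out[m] = self.fit(m, **kw)
        return out

    # -- diagnostics (delegating to the sensitivity module) ------------------

    def heterogeneity(self):
        from .sensitivity import cochran_q
        return cochran_q(self.h)

    def pleiotropy_test(self):
        from .sensitivity import egger_intercept_test
        return egger_intercept_test(self.h)

    def presso(self, n_sim: int = 3000, outlier_alpha: float = 0.05, seed: int = 0):
        from .sensitivity import mr_presso
        return mr_presso(self.h, n_sim=n_sim, outlier_alpha=outlier_alpha, seed=seed)

    def leave_one_out(self):
        from .sensitivity import leave_one_out
        return leave_one_out(self.h)

    def funnel(self):
        from .sensitivity import funnel_data
        return funnel_data(self.h)


def results_frame(results: dict[str, MRResult], exposure_id: str = "",
                  outcome_id: str = "") -> pd.DataFrame:
    rows = []
    for res in results.values():
        d = res.to_dict()
        d["exposure"], d["outcome"] = exposure_id, outcome_id
        rows.append(d)
    cols = ["exposure", "outcome", "method", "n_snp", "beta", "se",
            "or", "ci_low", "ci_high", "pval"]
    return pd.DataFrame(rows, columns=cols)
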