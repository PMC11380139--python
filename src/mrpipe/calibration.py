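"""Seeded simulation studies validating the estimators' statistical behavior.

Each study runs the full generator -> harmonize -> estimate path over many
independent replicates and summarizes frequency properties: bias of the IVW
estimate, confidence-interval coverage, type-I error, the size and power of
the Egger intercept test, the calibration of the MR-PRESSO global p-value and
its outlier-detection power, and recovery of a mediated effect through the
two-step decomposition.  ``oracle_agreement`` cross-checks the closed-form
estimators against independent textbook computations (normal equations,
cumulative-weight percentile scan, chi-square survival function).

Every study takes a single integer seed; replicate seeds are derived from it
deterministically, so results are exactly reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .estimators import ivw, egger, weighted_median, weighted_percentile
from .gwas_io import harmonize
from .mediation import two_step_mediation
from .sensitivity import cochran_q, egger_intercept_test, mr_presso
from .synthgwas import (
    MediatorChain, OutlierConfig, PleiotropyConfig, SimulationConfig,
    simulate_pair, simulate_mediation_chain,
)

__all__ = [
    "ivw_recovery_study", "ivw_type1_study", "egger_intercept_study",
    "presso_null_calibration", "presso_outlier_power",
    "mediation_recovery_study", "oracle_agreement", "pipeline_determinism",
]

Z95 = stats.norm.ppf(0.975)


def _rep_seed(seed: int, i: int) -> int:
    return (seed * 100_003 + i) % (2**31 - 1)


def _pair_hset(config: SimulationConfig):
    exposure, outcome, truth = simulate_pair(config)
    return harmonize(exposure, outcome), truth


def ivw_recovery_study(theta: float = 0.2, n_snp: int = 30, n_rep: int = 500,
                       seed: int = 0) -> dict:
    """Bias and 95% CI coverage of IVW (auto) under a known causal effect."""
    estimates, covered = [], 0
    for i in range(n_rep):
        cfg = SimulationConfig(theta=theta, n_snp=n_snp,
                               seed=_rep_seed(seed, i))
        h, _ = _pair_hset(cfg)
        res = ivw(h, mode="auto")
        estimates.append(res.beta)
        lo, hi = res.beta - Z95 * res.se, res.beta + Z95 * res.se
        covered += lo <= theta <= hi
    estimates = np.asarray(estimates)
    return {
        "theta": theta,
        "n_rep": n_rep,
        "mean_estimate": float(estimates.mean()),
        "sd_estimate": float(estimates.std(ddof=1)),
        "mc_se": float(estimates.std(ddof=1) / np.sqrt(n_rep)),
        "coverage": covered / n_rep,
    }


def ivw_type1_study(n_snp: int = 30, n_rep: int = 1000, seed: int = 0,
                    alpha: float = 0.05) -> dict:
    """Rejection rate of IVW (auto) when the true causal effect is zero."""
    rejections = 0
    for i in range(n_rep):
        cfg = SimulationConfig(theta=0.0, n_snp=n_snp, seed=_rep_seed(seed, i))
        h, _ = _pair_hset(cfg)
        rejections += ivw(h, mode="auto").pval < alpha
    return {"n_rep": n_rep, "rejection_rate": rejections / n_rep}


def egger_intercept_study(mu_alpha: float, sd_alpha: float = 0.05,
                          n_snp: int = 30, n_rep: int = 500, seed: int = 0,
                          alpha: float = 0.05) -> dict:
    """Rejection rate of the Egger intercept test under balanced
    (mu_alpha = 0) or directional (mu_alpha != 0) pleiotropy."""
    rejections = 0
    for i in range(n_rep):
        cfg = SimulationConfig(
            theta=0.2, n_snp=n_snp, seed=_rep_seed(seed, i),
            pleiotropy=PleiotropyConfig(mu=mu_alpha, sd=sd_alpha, fraction=1.0))
        h, _ = _pair_hset(cfg)
        _, _, pval = egger_intercept_test(h)
        rejections += pval < alpha
    return {"n_rep": n_rep, "mu_alpha": mu_alpha,
            "rejection_rate": rejections / n_rep}


def presso_null_calibration(n_runs: int = 200, n_sim: int = 1000,
                            n_snp: int = 30, seed: int = 0) -> dict:
    """Distribution of the MR-PRESSO global p under the no-pleiotropy null.

    Returns the Kolmogorov-Smirnov p-value against Uniform(0, 1).
    """
    pvals = []
    for i in range(n_runs):
        cfg = SimulationConfig(theta=0.2, n_snp=n_snp, seed=_rep_seed(seed, i))
        h, _ = _pair_hset(cfg)
        rep = mr_presso(h, n_sim=n_sim, seed=_rep_seed(seed + 1, i))
        pvals.append(rep.global_pval)
    ks = stats.kstest(pvals, "uniform")
    return {"n_runs": n_runs, "n_sim": n_sim, "ks_pval": float(ks.pvalue),
            "global_pvals": pvals}


def presso_outlier_power(n_runs: int = 200, n_sim: int = 1000,
                         n_snp: int = 30, seed: int = 0) -> dict:
    """Detection rate for one planted outlier with a pleiotropic offset of
    10x the median |outcome effect|, and how often the outlier-corrected
    estimate lands closer to the truth than the raw one."""
    detected, improved, with_correction = 0, 0, 0
    for i in range(n_runs):
        base_cfg = SimulationConfig(theta=0.2, n_snp=n_snp,
                                    seed=_rep_seed(seed, i))
        _, outcome_clean, _ = simulate_pair(base_cfg)
        offset = 10.0 * float(np.median(np.abs(outcome_clean.data["beta"])))
        cfg = SimulationConfig(theta=0.2, n_snp=n_snp,
                               seed=_rep_seed(seed, i),
                               outliers=OutlierConfig(count=1, offset=offset))
        exposure, outcome, truth = simulate_pair(cfg)
        h = harmonize(exposure, outcome)
        rep = mr_presso(h, n_sim=n_sim, seed=_rep_seed(seed + 1, i))
        detected += truth.outlier_ids[0] in rep.outliers
        if rep.corrected_estimate is not None:
            with_correction += 1
            improved += (abs(rep.corrected_estimate.beta - truth.theta)
                         < abs(rep.raw_estimate.beta - truth.theta))
    return {
        "n_runs": n_runs, "n_sim": n_sim,
        "detection_rate": detected / n_runs,
        "improvement_rate": improved / max(with_correction, 1),
        "n_with_correction": with_correction,
    }


def mediation_recovery_study(beta1: float = 0.3, beta2: float = 0.5,
                             direct: float = 0.1, n_rep: int = 200,
                             seed: int = 0) -> dict:
    """Recovery of the mediated effect beta1 x beta2 through the full
    two-step pipeline, plus the worst additivity violation observed."""
    mediated, additivity_err = [], 0.0
    for i in range(n_rep):
        cfg = SimulationConfig(
            seed=_rep_seed(seed, i),
            mediator_chain=MediatorChain(beta1=beta1, beta2=beta2,
                                         direct=direct))
        exposure, mediator, outcome, _ = simulate_mediation_chain(cfg)
        r = two_step_mediation(exposure, mediator, outcome)
        mediated.append(r.mediated_beta)
        additivity_err = max(additivity_err,
                             abs(r.direct_beta + r.mediated_beta - r.beta3))
    mediated = np.asarray(mediated)
    return {
        "n_rep": n_rep,
        "true_mediated": beta1 * beta2,
        "mean_mediated": float(mediated.mean()),
        "mc_se": float(mediated.std(ddof=1) / np.sqrt(n_rep)),
        "max_additivity_error": float(additivity_err),
    }


def _median_scan_oracle(values: np.ndarray, weights: np.ndarray) -> float:
    """Brute-force cumulative-weight scan with the same midpoint convention."""
    order = np.argsort(values)
    v, w = values[order], weights[order] / weights.sum()
    mids = np.cumsum(w) - 0.5 * w
    for i in range(len(v)):
        if mids[i] >= 0.5:
            if i == 0:
                return float(v[0])
            frac = (0.5 - mids[i - 1]) / (mids[i] - mids[i - 1])
            return float(v[i - 1] + frac * (v[i] - v[i - 1]))
    return float(v[-1])


def oracle_agreement(n_instances: int = 100, seed: int = 0) -> dict:
    """Cross-check estimators against independent textbook computations.

    IVW and Egger vs weighted normal equations solved with numpy; the
    weighted median vs a cumulative-weight percentile scan; Cochran's Q
    p-value vs the chi-square survival function.  Returns the maximum
    absolute discrepancy per check over ``n_instances`` random instances.
    """
    rng = np.random.default_rng(seed)
    d_ivw = d_egger = d_median = d_q = 0.0
    for _ in range(n_instances):
        J = int(rng.integers(4, 15))
        h = _random_hset(rng, J)
        w = 1.0 / h.sy**2

        # IVW vs closed-form no-intercept weighted least squares
        slope = np.sum(w * h.bx * h.by) / np.sum(w * h.bx**2)
        d_ivw = max(d_ivw, abs(ivw(h, mode="fixed").beta - slope))

        # Egger vs normal equations on the oriented design
        s = np.where(h.bx < 0, -1.0, 1.0)
        X = np.column_stack([np.ones(J), s * h.bx])
        W = np.diag(w)
        coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ (s * h.by))
        res = egger(h)
        d_egger = max(d_egger, abs(res.extras["intercept"] - coef[0]),
                      abs(res.beta - coef[1]))

        # weighted median vs the percentile scan
        theta = h.by / h.bx
        wm = h.bx**2 / h.sy**2
        d_median = max(d_median, abs(weighted_percentile(theta, wm, 0.5)
                                     - _median_scan_oracle(theta, wm)))

        # Cochran's Q p-value vs the chi-square survival oracle
        qres = cochran_q(h)
        d_q = max(d_q, abs(qres.pval - stats.chi2.sf(qres.Q, J - 1)))
    return {
        "n_instances": n_instances,
        "ivw_max_abs_diff": float(d_ivw),
        "egger_max_abs_diff": float(d_egger),
        "weighted_median_max_abs_diff": float(d_median),
        "cochran_q_pval_max_abs_diff": float(d_q),
    }


def _random_hset(rng, J):
    from .gwas_io import HarmonizedSet
    import pandas as pd
    bx = rng.normal(0, 0.3, J)
    bx[np.abs(bx) < 0.02] = 0.1
    by = rng.normal(0, 0.1, J)
    sx = rng.uniform(0.005, 0.05, J)
    sy = rng.uniform(0.01, 0.1, J)
    data = pd.DataFrame({
        "snp": [f"rs{i}" for i in range(J)],
        "effect_allele": "A", "other_allele": "G",
        "beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy,
        "eaf": 0.3, "flipped": False, "palindromic": False,
    })
    return HarmonizedSet("exp", "out", data)


def pipeline_determinism(seed: int = 0, outdir=None) -> bool:
    """Run the seeded end-to-end pipeline twice; True iff outputs are
    byte-identical."""
    import tempfile
    from pathlib import Path
    from .pipeline import PipelineConfig, run_forward, write_report

    exposure, outcome, _ = simulate_pair(SimulationConfig(seed=_rep_seed(seed, 0)))
    cfg = PipelineConfig(seed=seed, presso_n_sim=500, n_boot=200)
    blobs = []
    with tempfile.TemporaryDirectory(dir=outdir) as tmp:
        for i in range(2):
            report = run_forward({"exp": exposure}, {"out": outcome}, cfg)
            run_dir = Path(tmp) / f"run{i}"
            written = write_report(report, run_dir)
            blobs.append({k: p.read_bytes() for k, p in written.items()})
    return blobs[0] == blobs[1]
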