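"""Synthetic GWAS summary statistics with known causal truth.

The generator emulates the statistical structure of the consortium summary
data a two-sample MR study consumes: per-SNP effect estimates with sampling
noise whose scale follows the standardized-trait formula
se = 1 / sqrt(2 n eaf (1 - eaf)), exposure and outcome effects measured in
non-overlapping samples, binary outcomes on the log-OR scale with heavy
case/control imbalance, horizontal pleiotropy (balanced or directional),
planted outliers, palindromic variants, and an optional
exposure -> mediator -> outcome chain.

Defaults mirror the consortium designs the pipeline targets: exposure GWAS of
18,340 individuals (a gut-microbiome-scale meta-analysis), a binary outcome
with 287 cases vs 360,143 controls (a biobank disease endpoint, for which the
log-OR sampling error uses the effective sample size 4/(1/n_case +
1/n_control)), a mediator GWAS of 8,293 (a cytokine panel), 30 instruments
with per-allele effect scale 0.35 (instrument F statistics from ~10 into the
hundreds), and a true causal effect of 0.2.

Pleiotropic effects are drawn independently of instrument strength (InSIDE
holds by construction); ``inside_violation`` correlates them with the true
exposure effects to stress-test MR-Egger.  All randomness flows from a single
seed through deterministic substreams, so a fixed configuration reproduces
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .gwas_io import SummaryTable, table_from_dataframe

__all__ = [
    "PleiotropyConfig", "OutlierConfig", "MediatorChain", "SimulationConfig",
    "SimulationTruth", "simulate_pair", "simulate_mediation_chain",
]

_PVAL_FLOOR = 1e-300  # keeps extreme z-scores inside the (0, 1] invariant


@dataclass
class PleiotropyConfig:
    """Direct (horizontal) SNP-outcome effects: alpha ~ N(mu, sd^2)."""

    mu: float = 0.0
    sd: float = 0.0
    fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError("pleiotropy sd must be non-negative")
        if not 0 <= self.fraction <= 1:
            raise ConfigError("pleiotropy fraction must lie in [0, 1]")


@dataclass
class OutlierConfig:
    """Planted outliers: ``offset`` added to the outcome effect of ``count`` SNPs."""

    count: int = 0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ConfigError("outlier count must be non-negative")


@dataclass
class MediatorChain:
    """Path coefficients for exposure -> mediator -> outcome simulations."""

    beta1: float = 0.3
    beta2: float = 0.5
    direct: float = 0.1


@dataclass
class SimulationConfig:
    n_snp: int = 30
    theta: float = 0.2
    n_exposure: int = 18_340
    n_outcome: int = 360_430
    n_case: int | None = 287
    n_control: int | None = 360_143
    n_mediator: int = 8_293
    eaf_range: tuple[float, float] = (0.1, 0.9)
    exposure_effect_scale: float = 0.35
    # Per-variant effect scale for the mediator's own instruments in chain
    # simulations.  Cytokine-panel GWAS of ~8k individuals report instrument
    # F statistics in the hundreds, implying per-allele effects near 0.5.
    mediator_effect_scale: float = 0.5
    # Chain instruments emulate already-ascertained genome-wide-significant
    # loci: |effect| is truncated below at this value so instrument selection
    # in downstream analyses never conditions on sampling noise (no winner's
    # curse baked into the benchmark).
    chain_min_effect: float = 0.1
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    outliers: OutlierConfig = field(default_factory=OutlierConfig)
    palindromic_fraction: float = 0.0
    mediator_chain: MediatorChain | None = None
    binary_outcome: bool = True
    inside_violation: float = 0.0  # corr(alpha, true exposure effect)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ConfigError("n_snp must be positive")
        lo, hi = self.eaf_range
        if not (0 < lo < hi < 1):
            raise ConfigError("eaf_range must satisfy 0 < lo < hi < 1")
        if self.exposure_effect_scale <= 0:
            raise ConfigError("exposure_effect_scale must be positive")
        if not 0 <= self.palindromic_fraction <= 1:
            raise ConfigError("palindromic_fraction must lie in [0, 1]")
        if not -1 <= self.inside_violation <= 1:
            raise ConfigError("inside_violation must lie in [-1, 1]")


@dataclass
class SimulationTruth:
    theta: float
    alpha: dict[str, float]
    outlier_ids: list[str]
    palindromic_ids: list[str]
    snp_effects: dict[str, float]
    chain: MediatorChain | None = None
    exposure_instrument_ids: list[str] = field(default_factory=list)
    mediator_instrument_ids: list[str] = field(default_factory=list)


def _analytic_se(n: float, eaf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def effective_n(n_case: int, n_control: int) -> float:
    """Effective sample size for log-OR sampling error under imbalance."""
    return 4.0 / (1.0 / n_case + 1.0 / n_control)


def _outcome_n(config: SimulationConfig) -> float:
    if config.binary_outcome and config.n_case and config.n_control:
        return effective_n(config.n_case, config.n_control)
    return float(config.n_outcome)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, _PVAL_FLOOR, 1.0)


_NONPALIN_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALIN_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def _variant_scaffold(rng: np.random.Generator, config: SimulationConfig):
    """SNP ids, alleles, positions and frequencies shared by all tables."""
    J = config.n_snp
    snps = [f"rs{1_000_000 + i}" for i in range(J)]
    # Deterministic spacing > the default 10,000 kb clump window, so LD-free
    # synthetic instruments survive distance-only clumping intact.
    chrom = [str(i % 22 + 1) for i in range(J)]
    pos = [10_000_000 + (i // 22) * 25_000_000 for i in range(J)]
    eaf = rng.uniform(*config.eaf_range, size=J)
    n_palin = int(round(config.palindromic_fraction * J))
    palin_idx = rng.choice(J, size=n_palin, replace=False) if n_palin else np.array([], int)
    alleles = []
    for i in range(J):
        pool = _PALIN_PAIRS if i in palin_idx else _NONPALIN_PAIRS
        alleles.append(pool[rng.integers(len(pool))])
    ea = [a for a, _ in alleles]
    oa = [b for _, b in alleles]
    return snps, chrom, pos, eaf, ea, oa, [snps[i] for i in sorted(palin_idx)]


def _summary_frame(snps, chrom, pos, ea, oa, eaf, beta, se, n,
                   n_case=None, n_control=None) -> pd.DataFrame:
    return pd.DataFrame({
        "snp": snps, "chr": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se, "pval": _pvals(beta, se),
        "n": int(n) if n_case is None else int(n_case + n_control),
        "n_case": n_case if n_case is not None else pd.NA,
        "n_control": n_control if n_control is not None else pd.NA,
    })


def _draw_alpha(rng, config: SimulationConfig, b: np.ndarray) -> np.ndarray:
    J = config.n_snp
    pl = config.pleiotropy
    alpha = np.zeros(J)
    n_affected = int(round(pl.fraction * J))
    if n_affected and (pl.sd > 0 or pl.mu != 0):
        affected = rng.choice(J, size=n_affected, replace=False)
        z = rng.normal(size=n_affected)
        rho = config.inside_violation
        if rho != 0:
            zb = (b[affected] - b[affected].mean())
            sd_b = zb.std() or 1.0
            z = rho * zb / sd_b + np.sqrt(1 - rho**2) * z
        alpha[affected] = pl.mu + pl.sd * z
    return alpha


def simulate_pair(config: SimulationConfig):
    """Simulate one exposure GWAS and one outcome GWAS over shared SNPs.

    Returns ``(exposure_table, outcome_table, truth)``.  Per SNP j: true
    exposure effect b_j ~ N(0, scale^2); observed bx_j ~ N(b_j, se_x,j^2)
    with the analytic standardized-trait se; direct outcome effect
    alpha_j from the pleiotropy config; true outcome effect theta b_j +
    alpha_j, observed with the outcome-side analytic se (effective sample
    size under case/control imbalance); planted outliers add their offset to
    the observed outcome effect.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_snp
    snps, chrom, pos, eaf, ea, oa, palin_ids = _variant_scaffold(rng, config)

    b = rng.normal(0.0, config.exposure_effect_scale, size=J)
    se_x = _analytic_se(config.n_exposure, eaf)
    bx = rng.normal(b, se_x)

    # Pleiotropic effects are expressed relative to the exposure-increasing
    # allele: after orienting instruments to bx >= 0 (the frame in which the
    # Egger intercept is defined), a directional mean mu stays directional
    # instead of being symmetrized away by random allele orientation.
    alpha = np.sign(b) * _draw_alpha(rng, config, b)
    se_y = _analytic_se(_outcome_n(config), eaf)
    true_out = config.theta * b + alpha
    by = rng.normal(true_out, se_y)

    outlier_ids: list[str] = []
    if config.outliers.count:
        idx = rng.choice(J, size=min(config.outliers.count, J), replace=False)
        by = by.copy()
        by[idx] += config.outliers.offset
        outlier_ids = [snps[i] for i in sorted(idx)]

    exposure = table_from_dataframe(
        _summary_frame(snps, chrom, pos, ea, oa, eaf, bx, se_x, config.n_exposure),
        trait_id="sim_exposure",
    )
    if config.binary_outcome and config.n_case and config.n_control:
        out_frame = _summary_frame(snps, chrom, pos, ea, oa, eaf, by, se_y,
                                   None, config.n_case, config.n_control)
        outcome = table_from_dataframe(out_frame, trait_id="sim_outcome",
                                       trait_type="binary",
                                       n_case=config.n_case,
                                       n_control=config.n_control)
    else:
        out_frame = _summary_frame(snps, chrom, pos, ea, oa, eaf, by, se_y,
                                   config.n_outcome)
        outcome = table_from_dataframe(out_frame, trait_id="sim_outcome")

    truth = SimulationTruth(
        theta=config.theta,
        alpha=dict(zip(snps, alpha.astype(float))),
        outlier_ids=outlier_ids,
        palindromic_ids=palin_ids,
        snp_effects=dict(zip(snps, b.astype(float))),
    )
    return exposure, outcome, truth


def _truncated_effects(rng: np.random.Generator, scale: float, minimum: float,
                       size: int) -> np.ndarray:
    """Signed effects with |b| ~ half-normal(scale) truncated below at minimum."""
    lo = stats.norm.cdf(minimum / scale)  # of the folded distribution: 2*lo-1
    u = rng.uniform(2 * lo - 1, 1.0, size=size)
    magnitude = scale * stats.norm.ppf((1 + u) / 2)
    sign = rng.choice([-1.0, 1.0], size=size)
    return sign * magnitude


def simulate_mediation_chain(config: SimulationConfig):
    """Simulate exposure, mediator and outcome GWAS linked by a causal chain.

    The exposure and the mediator each carry ``n_snp`` instruments with
    disjoint SNP sets.  The mediator inherits beta1 x (exposure effect) at
    exposure instruments; the outcome receives beta2 x (mediator effect) +
    direct x (exposure effect).  Returns
    ``(exposure_table, mediator_table, outcome_table, truth)``.
    """
    if config.mediator_chain is None:
        raise ConfigError("simulate_mediation_chain requires a mediator_chain")
    chain = config.mediator_chain
    rng = np.random.default_rng(config.seed)
    wide = replace(config, n_snp=2 * config.n_snp, mediator_chain=None)
    J = wide.n_snp
    snps, chrom, pos, eaf, ea, oa, palin_ids = _variant_scaffold(rng, wide)

    half = config.n_snp
    b_exp = np.zeros(J)
    b_med_own = np.zeros(J)
    b_exp[:half] = _truncated_effects(rng, config.exposure_effect_scale,
                                      config.chain_min_effect, half)
    b_med_own[half:] = _truncated_effects(rng, config.mediator_effect_scale,
                                          config.chain_min_effect, half)

    med_true = chain.beta1 * b_exp + b_med_own
    out_true = chain.beta2 * med_true + chain.direct * b_exp

    se_x = _analytic_se(config.n_exposure, eaf)
    se_m = _analytic_se(config.n_mediator, eaf)
    se_y = _analytic_se(_outcome_n(config), eaf)
    bx = rng.normal(b_exp, se_x)
    bm = rng.normal(med_true, se_m)
    by = rng.normal(out_true, se_y)

    exposure = table_from_dataframe(
        _summary_frame(snps, chrom, pos, ea, oa, eaf, bx, se_x, config.n_exposure),
        trait_id="sim_exposure")
    mediator = table_from_dataframe(
        _summary_frame(snps, chrom, pos, ea, oa, eaf, bm, se_m, config.n_mediator),
        trait_id="sim_mediator")
    if config.binary_outcome and config.n_case and config.n_control:
        outcome = table_from_dataframe(
            _summary_frame(snps, chrom, pos, ea, oa, eaf, by, se_y, None,
                           config.n_case, config.n_control),
            trait_id="sim_outcome", trait_type="binary",
            n_case=config.n_case, n_control=config.n_control)
    else:
        outcome = table_from_dataframe(
            _summary_frame(snps, chrom, pos, ea, oa, eaf, by, se_y,
                           config.n_outcome),
            trait_id="sim_outcome")

    truth = SimulationTruth(
        theta=chain.direct + chain.beta1 * chain.beta2,
        alpha={s: 0.0 for s in snps},
        outlier_ids=[],
        palindromic_ids=palin_ids,
        snp_effects=dict(zip(snps, b_exp.astype(float))),
        chain=chain,
        exposure_instrument_ids=snps[:half],
        mediator_instrument_ids=snps[half:],
    )
    return exposure, mediator, outcome, truth
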