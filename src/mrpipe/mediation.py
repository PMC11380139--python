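"""Two-step mediation MR: product-of-coefficients decomposition.

Three univariable MR legs give beta1 (exposure -> mediator), beta2
(mediator -> outcome) and beta3 (exposure -> outcome, the total effect).  The
mediated effect is beta1 * beta2, the direct effect beta3 - beta1 * beta2,
and the proportion mediated beta1 * beta2 / beta3.  On the log-OR scale the
decomposition is exactly additive, so the OR-scale identity
OR_direct * OR_mediated = OR_total holds to machine precision.

The mediated-effect variance uses the delta method,
var = beta2^2 se1^2 + beta1^2 se2^2 (a parametric bootstrap is available
behind a flag); the direct effect's variance treats the legs as independent
(they are estimated from disjoint instrument sets and, for beta3 vs beta1,
from different outcome GWAS).  The proportion is flagged undefined when the
total effect is numerically zero, and flagged uninterpretable when mediated
and total effects have opposite signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ConfigError, EstimationError, InstrumentError
from .estimators import MRModel, MRResult, ivw, or_ci
from .gwas_io import SummaryTable, harmonize
from .instruments import select_instruments

__all__ = ["MediationResult", "decompose", "two_step_mediation", "MediationModel"]

Z95 = stats.norm.ppf(0.975)


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition with delta-method intervals."""

    beta1: float
    se1: float
    beta2: float
    se2: float
    beta3: float
    se3: float
    exposure_id: str = ""
    mediator_id: str = ""
    outcome_id: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, se in (("se1", self.se1), ("se2", self.se2), ("se3", self.se3)):
            if se <= 0:
                raise ConfigError(f"{name} must be positive, got {se}")
        self.mediated_beta = self.beta1 * self.beta2
        self.direct_beta = self.beta3 - self.mediated_beta
        self.se_mediated = float(np.sqrt(
            self.beta2**2 * self.se1**2 + self.beta1**2 * self.se2**2
        ))
        self.se_direct = float(np.sqrt(self.se3**2 + self.se_mediated**2))
        if self.se_mediated > 0:
            self.pval_mediated = float(
                2.0 * stats.norm.sf(abs(self.mediated_beta) / self.se_mediated))
        else:
            self.pval_mediated = 1.0

        self.proportion_undefined = abs(self.beta3) < 1e-8
        if self.proportion_undefined:
            self.proportion = np.nan
            self.se_proportion = np.nan
        else:
            self.proportion = self.mediated_beta / self.beta3
            # Delta method treating mediated and total as independent:
            # var(m/t) ~ var_m / t^2 + m^2 var_t / t^4
            self.se_proportion = float(np.sqrt(
                (self.se_mediated / self.beta3) ** 2
                + (self.mediated_beta * self.se3 / self.beta3**2) ** 2
            ))
        self.proportion_uninterpretable = (
            self.proportion_undefined
            or self.mediated_beta * self.beta3 < 0
        )

    # -- OR-scale views ------------------------------------------------------

    @property
    def total_or(self) -> float:
        return float(np.exp(self.beta3))

    @property
    def direct_or(self) -> float:
        return float(np.exp(self.direct_beta))

    @property
    def mediated_or(self) -> float:
        return float(np.exp(self.mediated_beta))

    def total_or_ci(self):
        or_, lo, hi, _ = or_ci(self.beta3, self.se3)
        return or_, lo, hi

    def direct_or_ci(self):
        or_, lo, hi, _ = or_ci(self.direct_beta, self.se_direct)
        return or_, lo, hi

    def mediated_or_ci(self):
        if self.se_mediated == 0:
            return self.mediated_or, self.mediated_or, self.mediated_or
        or_, lo, hi, _ = or_ci(self.mediated_beta, self.se_mediated)
        return or_, lo, hi

    def summary(self) -> str:
        t, tl, th = self.total_or_ci()
        d, dl, dh = self.direct_or_ci()
        m, ml, mh = self.mediated_or_ci()
        prop = ("undefined" if self.proportion_undefined
                else f"{self.proportion:.3f}")
        return "\n".join([
            f"Mediation: {self.exposure_id} -> {self.mediator_id} -> {self.outcome_id}",
            "-" * 52,
            f"  total     OR {t:.3f} ({tl:.3f}-{th:.3f})",
            f"  direct    OR {d:.3f} ({dl:.3f}-{dh:.3f})",
            f"  mediated  OR {m:.3f} ({ml:.3f}-{mh:.3f})  p = {self.pval_mediated:.3g}",
            f"  proportion mediated: {prop}",
        ])


def decompose(beta1: float, se1: float, beta2: float, se2: float,
              beta3: float, se3: float, **ids) -> MediationResult:
    """Point decomposition of a total effect into direct and mediated parts."""
    return MediationResult(beta1, se1, beta2, se2, beta3, se3, **ids)


def _leg(exposure: SummaryTable, outcome: SummaryTable, config: dict,
         leg_name: str, exclude=None) -> tuple[MRResult, list[str]]:
    """One univariable MR leg: select instruments, harmonize, IVW-auto."""
    try:
        inst = select_instruments(
            exposure,
            p_threshold=config.get("p_threshold", 5e-8),
            ld=config.get("ld"),
            r2_max=config.get("r2_max", 0.001),
            window_kb=config.get("window_kb", 10_000.0),
            exclusion_list=(set(config.get("exclusion_list") or ()) | set(exclude or ())),
            f_min=config.get("f_min", 10.0),
        )
    except InstrumentError as err:
        raise InstrumentError(f"mediation leg {leg_name!r}: {err}") from err
    h = harmonize(inst.table, outcome,
                  palindrome_policy=config.get("palindrome_policy", "infer_by_eaf"))
    if h.n_snp == 0:
        raise InstrumentError(f"mediation leg {leg_name!r}: no harmonized instruments")
    if h.n_snp == 1:
        res = MRModel(h).fit("wald_ratio")
    else:
        res = ivw(h, mode="auto")
    return res, h.snp_ids


def two_step_mediation(
    exposure: SummaryTable,
    mediator: SummaryTable,
    outcome: SummaryTable,
    config: dict | None = None,
) -> MediationResult:
    """Full two-step mediation analysis from three summary tables.

    Legs: (1) exposure -> mediator, (2) mediator -> outcome, (3) exposure ->
    outcome.  Every leg runs the primary pipeline method (IVW with the
    automatic fixed/random switch; single-instrument legs fall back to the
    Wald ratio).  SNPs instrumenting the exposure in leg 1 are excluded from
    the mediator's instrument set in leg 2 so the two steps rest on disjoint
    instruments.
    """
    config = dict(config or {})
    leg1, leg1_snps = _leg(exposure, mediator, config, "exposure->mediator")
    leg2, _ = _leg(mediator, outcome, config, "mediator->outcome",
                   exclude=leg1_snps)
    leg3, _ = _leg(exposure, outcome, config, "exposure->outcome")
    return decompose(
        leg1.beta, leg1.se, leg2.beta, leg2.se, leg3.beta, leg3.se,
        exposure_id=exposure.trait_id, mediator_id=mediator.trait_id,
        outcome_id=outcome.trait_id,
        extras={"leg1": leg1.to_dict(), "leg2": leg2.to_dict(),
                "leg3": leg3.to_dict()},
    )


class MediationModel:
    """Facade: build from the three tables, ``fit`` returns a MediationResult."""

    def __init__(self, exposure: SummaryTable, mediator: SummaryTable,
                 outcome: SummaryTable, config: dict | None = None):
        self.exposure, self.mediator, self.outcome = exposure, mediator, outcome
        self.config = dict(config or {})

    def fit(self) -> MediationResult:
        return two_step_mediation(self.exposure, self.mediator, self.outcome,
                                  self.config)
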