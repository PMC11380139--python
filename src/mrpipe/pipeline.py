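"""Orchestration of the full study design: forward MR, sensitivity suite,
reverse MR, MVMR and mediation, with Bonferroni significance banding and
deterministic report generation.

For each exposure-outcome pair the pipeline selects instruments at the
primary genome-wide threshold (falling back to a relaxed locus-wide threshold
when too few SNPs survive), harmonizes, runs the configured estimator
battery, the sensitivity suite (Cochran's Q, Egger intercept, MR-PRESSO,
leave-one-out, funnel data), re-runs the estimators once after removing any
MR-PRESSO outliers, and classifies the primary (IVW) p-value into
significant / suggestive / not significant bands at alpha / N and alpha.

Reports are plain TSV + JSON with no timestamps, so a fixed configuration and
seed reproduce byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, EstimationError, InstrumentError
from .estimators import MRModel, MRResult, results_frame
from .gwas_io import SummaryTable, harmonize
from .instruments import LDMatrix, select_instruments
from .sensitivity import cochran_q, egger_intercept_test, funnel_data, \
    leave_one_out, loo_frame, mr_presso

__all__ = [
    "PipelineConfig", "PairReport", "StudyReport", "analyze_pair",
    "run_forward", "run_reverse", "bonferroni_classify",
    "bonferroni_threshold", "sample_overlap_percent", "write_report",
]


@dataclass
class PipelineConfig:
    p_threshold_primary: float = 5e-8
    p_threshold_fallback: float | None = 5e-6
    min_instruments: int = 3  # below this, the fallback threshold applies
    r2_max: float = 0.001
    window_kb: float = 10_000.0
    f_min: float = 10.0
    methods: tuple = ("ivw", "egger", "weighted_median", "weighted_mode")
    alpha: float = 0.05
    n_methods_bonferroni: int = 4
    presso_n_sim: int = 3000
    presso_alpha: float = 0.05
    n_boot: int = 1000
    palindrome_policy: str = "infer_by_eaf"
    exclusion_list: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_threshold_primary", "p_threshold_fallback"):
            val = getattr(self, name)
            if val is not None and not 0 < val < 1:
                raise ConfigError(f"{name} must lie in (0, 1), got {val}")
        if self.n_methods_bonferroni < 1:
            raise ConfigError("n_methods_bonferroni must be >= 1")


def bonferroni_threshold(alpha: float = 0.05, n_methods: int = 4) -> float:
    """Multiple-testing threshold alpha / N across the estimator battery."""
    if n_methods < 1:
        raise ConfigError("n_methods must be >= 1")
    return alpha / n_methods


def bonferroni_classify(pvals, alpha: float = 0.05, n_methods: int = 4):
    """Band p-values: < alpha/N significant, [alpha/N, alpha) suggestive."""
    cut = bonferroni_threshold(alpha, n_methods)
    labels = []
    for p in np.atleast_1d(pvals):
        if p < cut:
            labels.append("significant")
        elif p < alpha:
            labels.append("suggestive")
        else:
            labels.append("not significant")
    return labels


def sample_overlap_percent(n_overlap: int, n_total: int, digits: int = 1) -> float:
    """Maximum exposure/outcome sample-overlap rate, in percent."""
    if n_total <= 0:
        raise ConfigError("n_total must be positive")
    return round(100.0 * n_overlap / n_total, digits)


@dataclass
class PairReport:
    """Everything computed for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    direction: str  # "forward" or "reverse"
    results: dict[str, MRResult]
    n_snp: int
    threshold_used: float
    fallback_applied: bool
    heterogeneity: dict | None = None
    egger_intercept: tuple | None = None
    presso: object | None = None
    loo: pd.DataFrame | None = None
    funnel: pd.DataFrame | None = None
    funnel_lines: dict = field(default_factory=dict)
    outliers_removed: list[str] = field(default_factory=list)
    results_after_removal: dict[str, MRResult] = field(default_factory=dict)
    significance: str = "not significant"
    direction_consistent: bool | None = None
    selection_log: list = field(default_factory=list)
    error: str | None = None

    @property
    def primary(self) -> MRResult | None:
        final = self.results_after_removal or self.results
        return final.get("ivw") or final.get("wald_ratio")


@dataclass
class StudyReport:
    config: PipelineConfig
    pairs: list[PairReport] = field(default_factory=list)
    mvmr: pd.DataFrame | None = None
    mediation: list = field(default_factory=list)


def _run_battery(h, config: PipelineConfig, seed: int) -> dict[str, MRResult]:
    model = MRModel(h)
    if h.n_snp == 1:
        return {"wald_ratio": model.fit("wald_ratio")}
    return model.fit_all(methods=config.methods, seed=seed, n_boot=config.n_boot)


def analyze_pair(
    exposure: SummaryTable,
    outcome: SummaryTable,
    config: PipelineConfig | None = None,
    ld: LDMatrix | None = None,
    direction: str = "forward",
) -> PairReport:
    """Run the full single-pair workflow (selection through sensitivity)."""
    config = config or PipelineConfig()
    threshold = config.p_threshold_primary
    fallback_applied = False
    inst = None
    try:
        inst = select_instruments(
            exposure, p_threshold=threshold, ld=ld, r2_max=config.r2_max,
            window_kb=config.window_kb, exclusion_list=config.exclusion_list,
            f_min=config.f_min,
        )
    except InstrumentError:
        pass
    if ((inst is None or inst.n_snp < config.min_instruments)
            and config.p_threshold_fallback is not None):
        fallback_applied = True
        threshold = config.p_threshold_fallback
        inst = select_instruments(
            exposure, p_threshold=threshold, ld=ld, r2_max=config.r2_max,
            window_kb=config.window_kb, exclusion_list=config.exclusion_list,
            f_min=config.f_min,
        )
    log = list(inst.selection_log)
    if fallback_applied:
        log.append({"step": "fallback_threshold", "threshold": threshold})

    h = harmonize(inst.table, outcome, palindrome_policy=config.palindrome_policy)
    if h.n_snp == 0:
        raise InstrumentError(
            f"{exposure.trait_id} -> {outcome.trait_id}: "
            "no instruments survive harmonization"
        )
    results = _run_battery(h, config, config.seed)

    report = PairReport(
        exposure_id=exposure.trait_id, outcome_id=outcome.trait_id,
        direction=direction, results=results, n_snp=h.n_snp,
        threshold_used=threshold, fallback_applied=fallback_applied,
        selection_log=log,
    )

    if h.n_snp >= 2:
        het = cochran_q(h)
        report.heterogeneity = {"Q": het.Q, "df": het.df, "pval": het.pval}
    if h.n_snp >= 3:
        report.egger_intercept = egger_intercept_test(h)
        full = results.get("ivw")
        if full is not None:
            report.loo = loo_frame(leave_one_out(h), full)
    funnel, lines = funnel_data(h)
    report.funnel, report.funnel_lines = funnel, lines

    if h.n_snp >= 4:
        presso = mr_presso(h, n_sim=config.presso_n_sim,
                           outlier_alpha=config.presso_alpha, seed=config.seed)
        report.presso = presso
        if presso.outliers:
            # Single outlier-removal pass, then one re-estimation.
            h2 = h.drop_snps(presso.outliers)
            if h2.n_snp >= 1:
                report.outliers_removed = list(presso.outliers)
                report.results_after_removal = _run_battery(h2, config, config.seed)

    primary = report.primary
    if primary is not None:
        report.significance = bonferroni_classify(
            [primary.pval], alpha=config.alpha,
            n_methods=config.n_methods_bonferroni,
        )[0]
    final = report.results_after_removal or report.results
    signs = {np.sign(r.beta) for r in final.values() if r.beta != 0}
    report.direction_consistent = len(signs) <= 1
    return report


def run_forward(
    exposures: dict[str, SummaryTable],
    outcomes: dict[str, SummaryTable],
    config: PipelineConfig | None = None,
    ld: LDMatrix | None = None,
    direction: str = "forward",
) -> StudyReport:
    """Run every exposure x outcome pair; failures are recorded, not fatal."""
    config = config or PipelineConfig()
    report = StudyReport(config=config)
    for exp_id, exposure in exposures.items():
        for out_id, outcome in outcomes.items():
            try:
                pair = analyze_pair(exposure, outcome, config, ld=ld,
                                    direction=direction)
            except (InstrumentError, EstimationError) as err:
                pair = PairReport(
                    exposure_id=exp_id, outcome_id=out_id, direction=direction,
                    results={}, n_snp=0,
                    threshold_used=config.p_threshold_primary,
                    fallback_applied=False, error=str(err),
                )
            report.pairs.append(pair)
    return report


def run_reverse(
    exposures: dict[str, SummaryTable],
    outcomes: dict[str, SummaryTable],
    config: PipelineConfig | None = None,
    ld: LDMatrix | None = None,
) -> StudyReport:
    """Reverse MR: identical machinery with exposure and outcome roles swapped."""
    return run_forward(outcomes, exposures, config, ld=ld, direction="reverse")


# ---------------------------------------------------------------------------
# report serialization


def _pairs_results_frame(report: StudyReport) -> pd.DataFrame:
    frames = []
    for pair in report.pairs:
        if pair.error:
            continue
        final = pair.results_after_removal or pair.results
        df = results_frame(final, pair.exposure_id, pair.outcome_id)
        df.insert(2, "direction", pair.direction)
        df["significance"] = [
            bonferroni_classify([p], report.config.alpha,
                                report.config.n_methods_bonferroni)[0]
            for p in df["pval"]
        ]
        df["direction_consistent"] = pair.direction_consistent
        df["outliers_removed"] = ",".join(pair.outliers_removed)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=[
            "exposure", "outcome", "direction", "method", "n_snp", "beta",
            "se", "or", "ci_low", "ci_high", "pval", "significance",
            "direction_consistent", "outliers_removed"])
    return pd.concat(frames, ignore_index=True)


def _sensitivity_frame(report: StudyReport) -> pd.DataFrame:
    rows = []
    for pair in report.pairs:
        if pair.error:
            continue
        egger_int = pair.egger_intercept or (np.nan, np.nan, np.nan)
        rows.append({
            "exposure": pair.exposure_id,
            "outcome": pair.outcome_id,
            "egger_intercept": egger_int[0],
            "intercept_se": egger_int[1],
            "egger_pval": egger_int[2],
            "presso_global_pval": (pair.presso.global_pval
                                   if pair.presso is not None else np.nan),
            "cochran_q": (pair.heterogeneity or {}).get("Q", np.nan),
            "cochran_q_pval": (pair.heterogeneity or {}).get("pval", np.nan),
        })
    return pd.DataFrame(rows, columns=[
        "exposure", "outcome", "egger_intercept", "intercept_se", "egger_pval",
        "presso_global_pval", "cochran_q", "cochran_q_pval"])


def _loo_frames(report: StudyReport) -> pd.DataFrame:
    frames = []
    for pair in report.pairs:
        if pair.loo is None:
            continue
        df = pair.loo.copy()
        df.insert(0, "exposure", pair.exposure_id)
        df.insert(1, "outcome", pair.outcome_id)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["exposure", "outcome", "excluded_snp",
                                     "method", "n_snp", "beta", "se", "or",
                                     "ci_low", "ci_high", "pval", "flagged"])
    return pd.concat(frames, ignore_index=True)


def mediation_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        t, tl, th = r.total_or_ci()
        d, dl, dh = r.direct_or_ci()
        m, ml, mh = r.mediated_or_ci()
        rows.append({
            "outcome": r.outcome_id, "mediator": r.mediator_id,
            "exposure": r.exposure_id,
            "total_or": t, "total_ci_low": tl, "total_ci_high": th,
            "direct_or": d, "direct_ci_low": dl, "direct_ci_high": dh,
            "mediated_or": m, "mediated_ci_low": ml, "mediated_ci_high": mh,
            "proportion": r.proportion, "pval_mediated": r.pval_mediated,
        })
    return pd.DataFrame(rows, columns=[
        "outcome", "mediator", "exposure", "total_or", "total_ci_low",
        "total_ci_high", "direct_or", "direct_ci_low", "direct_ci_high",
        "mediated_or", "mediated_ci_low", "mediated_ci_high",
        "proportion", "pval_mediated"])


def write_report(report: StudyReport, outdir, plots: bool = False) -> dict:
    """Emit results/sensitivity/loo/mvmr/mediation TSVs plus a JSON summary.

    Output is free of timestamps and unordered containers, so repeated runs
    with the same configuration and seed are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    results = _pairs_results_frame(report)
    results.to_csv(outdir / "results.tsv", sep="\t", index=False)
    written["results"] = outdir / "results.tsv"

    sens = _sensitivity_frame(report)
    sens.to_csv(outdir / "sensitivity.tsv", sep="\t", index=False)
    written["sensitivity"] = outdir / "sensitivity.tsv"

    loo = _loo_frames(report)
    loo.to_csv(outdir / "leave_one_out.tsv", sep="\t", index=False)
    written["leave_one_out"] = outdir / "leave_one_out.tsv"

    mvmr_df = report.mvmr if report.mvmr is not None else pd.DataFrame(
        columns=["exposure", "adjusted_for", "n_snp", "beta", "se", "or",
                 "ci_low", "ci_high", "pval"])
    mvmr_df.to_csv(outdir / "mvmr.tsv", sep="\t", index=False)
    written["mvmr"] = outdir / "mvmr.tsv"

    med_df = mediation_frame(report.mediation)
    med_df.to_csv(outdir / "mediation.tsv", sep="\t", index=False)
    written["mediation"] = outdir / "mediation.tsv"

    summary = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(report.config).items()},
        "n_pairs": len(report.pairs),
        "pairs": [
            {
                "exposure": p.exposure_id, "outcome": p.outcome_id,
                "direction": p.direction, "n_snp": p.n_snp,
                "threshold_used": p.threshold_used,
                "fallback_applied": p.fallback_applied,
                "significance": p.significance,
                "direction_consistent": p.direction_consistent,
                "outliers_removed": p.outliers_removed,
                "error": p.error,
            }
            for p in report.pairs
        ],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["summary"] = outdir / "summary.json"

    audit_path = outdir / "audit.jsonl"
    with open(audit_path, "w") as fh:
        for pair in report.pairs:
            fh.write(json.dumps({
                "exposure": pair.exposure_id, "outcome": pair.outcome_id,
                "selection_log": pair.selection_log,
            }, sort_keys=True) + "\n")
    written["audit"] = audit_path

    if plots:
        from . import plots as _plots
        for pair in report.pairs:
            if pair.funnel is None or pair.error:
                continue
            stem = f"{pair.exposure_id}__{pair.outcome_id}"
            _plots.funnel_plot(pair.funnel, pair.funnel_lines,
                               outdir / f"funnel_{stem}.png")
        if len(results):
            _plots.forest_plot(results, outdir / "forest.png")
    return written
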