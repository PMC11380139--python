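"""Instrumental-variable selection for two-sample MR.

Selection proceeds in a fixed order: p-value thresholding, LD clumping,
user-supplied confounder exclusion, then weak-instrument (F statistic)
filtering.  Each step appends to an audit log so the final instrument set is
reproducible from the counts alone.

Two instrument-strength measures are provided: the per-SNP squared Wald
statistic F = (beta/se)^2, and a group F statistic built from the
variance-explained approximation R^2 = sum_j 2 eaf_j (1 - eaf_j) beta_j^2 for
standardized traits, F = ((n - k - 1) / k) * R^2 / (1 - R^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InstrumentError
from .gwas_io import SummaryTable

__all__ = [
    "LDMatrix", "InstrumentSet", "select_by_pvalue", "clump", "exclude_snps",
    "per_snp_f", "group_f", "filter_weak", "select_instruments",
]


@dataclass
class LDMatrix:
    """Square symmetric matrix of pairwise r^2 values with SNP labels."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ConfigError("LD matrix shape does not match label count")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ConfigError("LD matrix diagonal must be 1")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ConfigError("LD matrix must be symmetric")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-12).any():
            raise ConfigError("LD r^2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def read_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(snp_ids=[str(s) for s in df.index], r2=df.to_numpy(dtype=float))

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t"
        )


@dataclass
class InstrumentSet:
    """Selected instruments with per-SNP and group F and a selection audit."""

    table: SummaryTable
    f_stats: pd.Series
    group_f_stat: float | None = None
    selection_log: list[dict] = field(default_factory=list)

    @property
    def snp_ids(self) -> list[str]:
        return self.table.data["snp"].tolist()

    @property
    def n_snp(self) -> int:
        return len(self.table.data)


def _with_rows(table: SummaryTable, data: pd.DataFrame) -> SummaryTable:
    return SummaryTable(
        trait_id=table.trait_id,
        data=data.reset_index(drop=True),
        trait_type=table.trait_type,
        n_case=table.n_case,
        n_control=table.n_control,
        rejections=table.rejections,
    )


def select_by_pvalue(table: SummaryTable, threshold: float) -> SummaryTable:
    """Retain rows with pval strictly below ``threshold`` (order preserved)."""
    if not 0 < threshold < 1:
        raise ConfigError(f"p-value threshold must lie in (0, 1), got {threshold}")
    return _with_rows(table, table.data[table.data["pval"] < threshold])


def clump(
    table: SummaryTable,
    ld: LDMatrix | None = None,
    r2_max: float = 0.001,
    window_kb: float = 10_000.0,
) -> SummaryTable:
    """Greedy LD clumping seeded by ascending p-value.

    Candidates are visited in order of ascending p (ties broken by snp id) and
    kept unless an already-kept SNP within ``window_kb`` (same chromosome,
    |pos difference| <= window_kb * 1000) has r^2 >= ``r2_max`` with them.
    Without an LD matrix the distance criterion alone excludes; positions are
    then required.  Deterministic given its input.
    """
    df = table.data
    if len(df) == 0:
        return _with_rows(table, df)
    have_pos = df["chr"].notna().all() and df["pos"].notna().all()
    if ld is None and not have_pos:
        raise InstrumentError("cannot clump: no LD matrix and missing chr/pos")
    if ld is not None:
        missing = [s for s in df["snp"] if s not in ld._index]
        if missing:
            raise InstrumentError(f"LD matrix does not cover SNPs {missing[:5]}")

    order = df.sort_values(["pval", "snp"], kind="mergesort").index
    window_bp = window_kb * 1000.0
    kept: list[int] = []
    for idx in order:
        row = df.loc[idx]
        conflict = False
        for kidx in kept:
            krow = df.loc[kidx]
            if have_pos:
                same_locus = (row["chr"] == krow["chr"]
                              and abs(int(row["pos"]) - int(krow["pos"])) <= window_bp)
            else:
                same_locus = True  # LD given without positions: window unbounded
            if not same_locus:
                continue
            if ld is None or ld.lookup(row["snp"], krow["snp"]) >= r2_max:
                conflict = True
                break
        if not conflict:
            kept.append(idx)
    keep_mask = df.index.isin(kept)
    return _with_rows(table, df[keep_mask])  # original row order preserved


def exclude_snps(
    table: SummaryTable,
    exclusion_list,
    reason: str = "user exclusion",
    log: list | None = None,
) -> SummaryTable:
    """Remove listed SNPs (e.g. confounder-associated instruments)."""
    excl = set(exclusion_list)
    present = [s for s in table.data["snp"] if s in excl]
    absent = sorted(excl - set(table.data["snp"]))
    if log is not None:
        for s in present:
            log.append({"step": "exclude", "snp": s, "reason": reason})
        for s in absent:
            log.append({"step": "exclude", "snp": s, "reason": "not in table (no-op)"})
    return _with_rows(table, table.data[~table.data["snp"].isin(excl)])


def per_snp_f(beta: float, se: float) -> float:
    """Squared Wald statistic (beta/se)^2: instrument strength of one SNP."""
    if se <= 0:
        raise ConfigError(f"se must be positive, got {se}")
    return (beta / se) ** 2


def group_f(table: SummaryTable, n: int, k: int | None = None) -> float:
    """Group F from the variance-explained approximation.

    R^2 = sum_j 2 eaf_j (1 - eaf_j) beta_j^2 (standardized traits, capped just
    below 1); F = ((n - k - 1) / k) * R^2 / (1 - R^2).
    """
    df = table.data
    if k is None:
        k = len(df)
    if k < 1:
        raise ConfigError("group F needs at least one instrument")
    if n <= k + 1:
        raise ConfigError(f"group F needs n > k + 1 (n={n}, k={k})")
    if df["eaf"].isna().any():
        raise ConfigError(
            "group F requires eaf for every instrument; use per_snp_f instead"
        )
    eaf = df["eaf"].to_numpy(dtype=float)
    beta = df["beta"].to_numpy(dtype=float)
    r2 = float(np.sum(2.0 * eaf * (1.0 - eaf) * beta**2))
    r2 = min(r2, 1.0 - 1e-12)
    return (n - k - 1) / k * r2 / (1.0 - r2)


def filter_weak(instruments: InstrumentSet, f_min: float = 10.0) -> InstrumentSet:
    """Drop instruments with per-SNP F below ``f_min`` (weak-instrument rule)."""
    weak = instruments.f_stats[instruments.f_stats < f_min].index.tolist()
    keep = instruments.table.data[~instruments.table.data["snp"].isin(weak)]
    if len(keep) == 0:
        raise InstrumentError("no valid instruments remain after F filtering")
    log = list(instruments.selection_log)
    log.append({"step": "filter_weak", "f_min": f_min,
                "removed": len(weak), "retained": len(keep)})
    return InstrumentSet(
        table=_with_rows(instruments.table, keep),
        f_stats=instruments.f_stats.drop(index=weak),
        group_f_stat=instruments.group_f_stat,
        selection_log=log,
    )


def select_instruments(
    table: SummaryTable,
    p_threshold: float = 5e-8,
    ld: LDMatrix | None = None,
    r2_max: float = 0.001,
    window_kb: float = 10_000.0,
    exclusion_list=None,
    f_min: float = 10.0,
    n: int | None = None,
) -> InstrumentSet:
    """Full selection pipeline: threshold -> clump -> exclude -> F filter.

    ``n`` (trait sample size) enables the group F statistic when eaf is
    available; it is reported but the per-SNP F drives the weak filter.
    """
    log: list[dict] = [{"step": "input", "count": len(table.data)}]
    sig = select_by_pvalue(table, p_threshold)
    log.append({"step": "pvalue", "threshold": p_threshold, "count": len(sig.data)})
    if len(sig.data) == 0:
        raise InstrumentError(
            f"no SNP passes p < {p_threshold} for {table.trait_id!r}"
        )
    clumped = clump(sig, ld=ld, r2_max=r2_max, window_kb=window_kb)
    log.append({"step": "clump", "r2_max": r2_max, "window_kb": window_kb,
                "count": len(clumped.data)})
    if exclusion_list:
        clumped = exclude_snps(clumped, exclusion_list,
                               reason="confounder-associated", log=log)
        log.append({"step": "post_exclude", "count": len(clumped.data)})
    f_stats = pd.Series(
        {row.snp: per_snp_f(row.beta, row.se)
         for row in clumped.data.itertuples(index=False)},
        dtype=float,
    )
    gf = None
    if n is not None and len(clumped.data) and clumped.data["eaf"].notna().all():
        if n > len(clumped.data) + 1:
            gf = group_f(clumped, n=n)
    inst = InstrumentSet(table=clumped, f_stats=f_stats,
                         group_f_stat=gf, selection_log=log)
    return filter_weak(inst, f_min=f_min)
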