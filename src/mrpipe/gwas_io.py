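"""Reading, validating, writing GWAS summary statistics, and allele harmonization.

The canonical on-disk format is a tab-delimited table with columns

    snp  chr  pos  effect_allele  other_allele  eaf  beta  se  pval  n  n_case  n_control

of which ``snp, effect_allele, other_allele, beta, se, pval`` are mandatory.
``beta`` is the per-effect-allele regression coefficient; for binary traits it
is a log odds ratio.  A *dialect* (mapping canonical -> file column name) lets
callers read tables with arbitrary headers.  Reading is gzip-transparent.

Harmonization aligns an outcome table onto the exposure's effect alleles so
that every downstream estimator sees both effects expressed per copy of one
shared allele.  Palindromic (A/T, C/G) variants cannot be oriented from allele
strings alone; the default policy infers orientation from allele frequencies
and drops variants whose frequency is too close to 0.5 to be informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, HarmonizationError, SchemaError

CANONICAL_COLUMNS = [
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "n_case", "n_control",
]
MANDATORY_COLUMNS = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]
_NUMERIC_COLUMNS = ["eaf", "beta", "se", "pval"]
_INT_COLUMNS = ["pos", "n", "n_case", "n_control"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class VariantAssociation:
    """One SNP's summary association with one trait."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos_bp: int | None = None
    eaf: float | None = None
    n: int | None = None


@dataclass
class SummaryTable:
    """A validated per-trait table of variant associations.

    ``data`` holds the retained rows in canonical column order; ``rejections``
    records every row that failed validation together with the reason, so a
    run's exclusions are auditable.
    """

    trait_id: str
    data: pd.DataFrame
    trait_type: str = "quantitative"
    n_case: int | None = None
    n_control: int | None = None
    rejections: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ConfigError(f"unknown trait_type {self.trait_type!r}")

    @property
    def n_variants(self) -> int:
        return len(self.data)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def records(self) -> list[VariantAssociation]:
        out = []
        for row in self.data.itertuples(index=False):
            out.append(
                VariantAssociation(
                    snp_id=row.snp,
                    effect_allele=row.effect_allele,
                    other_allele=row.other_allele,
                    beta=row.beta,
                    se=row.se,
                    pval=row.pval,
                    chrom=None if pd.isna(row.chr) else str(row.chr),
                    pos_bp=None if pd.isna(row.pos) else int(row.pos),
                    eaf=None if pd.isna(row.eaf) else float(row.eaf),
                    n=None if pd.isna(row.n) else int(row.n),
                )
            )
        return out


def _empty_canonical() -> pd.DataFrame:
    df = pd.DataFrame(columns=CANONICAL_COLUMNS)
    return _cast_canonical(df)


def _cast_canonical(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("snp", "chr", "effect_allele", "other_allele"):
        df[col] = df[col].astype("string")
    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    for col in _INT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df[CANONICAL_COLUMNS]


def validate_rows(
    df: pd.DataFrame,
    n_case: int | None = None,
    n_control: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a canonical-form frame into (valid rows, rejections with reasons)."""
    df = _cast_canonical(df)
    reasons = pd.Series([""] * len(df), index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        fresh = mask.fillna(False).astype(bool) & (reasons == "")
        reasons[fresh] = reason

    flag(df["snp"].isna() | (df["snp"].str.strip() == ""), "empty snp id")
    flag(df["snp"].duplicated(keep="first"), "duplicate snp id")
    ea = df["effect_allele"].str.upper()
    oa = df["other_allele"].str.upper()
    flag(ea.isna() | oa.isna() | (ea == "") | (oa == ""), "missing allele")
    flag(ea == oa, "effect allele equals other allele")
    flag(df["beta"].isna() | ~np.isfinite(df["beta"].to_numpy(dtype=float, na_value=np.nan)),
         "unparseable beta")
    flag(df["se"].isna(), "unparseable se")
    flag(df["se"] <= 0, "non-positive se")
    flag(df["pval"].isna(), "unparseable pval")
    flag((df["pval"] <= 0) | (df["pval"] > 1), "pval outside (0, 1]")
    flag(df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1)), "eaf outside (0, 1)")
    flag(df["n"].notna() & (df["n"] <= 0), "non-positive n")
    if n_case is not None and n_control is not None:
        flag(df["n"].notna() & (df["n"] != n_case + n_control),
             "n inconsistent with n_case + n_control")

    bad = reasons != ""
    rejections = pd.DataFrame({"snp": df.loc[bad, "snp"], "reason": reasons[bad]})
    clean = df.loc[~bad].reset_index(drop=True)
    clean["effect_allele"] = clean["effect_allele"].str.upper()
    clean["other_allele"] = clean["other_allele"].str.upper()
    return clean, rejections.reset_index(drop=True)


def table_from_dataframe(
    df: pd.DataFrame,
    trait_id: str,
    trait_type: str = "quantitative",
    n_case: int | None = None,
    n_control: int | None = None,
) -> SummaryTable:
    """Build a validated SummaryTable from a frame with canonical column names."""
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df = df.copy()
            df[col] = pd.NA
    clean, rejections = validate_rows(df, n_case=n_case, n_control=n_control)
    return SummaryTable(
        trait_id=trait_id,
        data=clean,
        trait_type=trait_type,
        n_case=n_case,
        n_control=n_control,
        rejections=rejections,
    )


def read_summary_stats(
    path,
    dialect: dict[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
    n_case: int | None = None,
    n_control: int | None = None,
    sep: str = "\t",
) -> SummaryTable:
    """Read a summary-statistics table, validating every row.

    ``dialect`` maps canonical column names to the file's column names, e.g.
    ``{"snp": "SNP", "effect_allele": "EA", ...}``.  A missing mandatory column
    raises :class:`SchemaError`; rows with unparseable or invariant-violating
    values are rejected individually and logged in ``table.rejections``.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    rename = {}
    if dialect:
        for canonical, actual in dialect.items():
            if canonical not in CANONICAL_COLUMNS:
                raise ConfigError(f"unknown canonical column {canonical!r} in dialect")
            rename[actual] = canonical
    raw = raw.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return table_from_dataframe(
        raw,
        trait_id=trait_id if trait_id is not None else str(path),
        trait_type=trait_type,
        n_case=n_case,
        n_control=n_control,
    )


def write_summary_stats(table: SummaryTable, path) -> None:
    """Write a table in the canonical TSV layout (gzip if the path ends .gz).

    ``read_summary_stats(write(x))`` reproduces ``x.data`` field for field.
    """
    df = table.data if len(table.data) else _empty_canonical()
    df.to_csv(path, sep="\t", index=False, na_rep="")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    pair = {effect_allele.upper(), other_allele.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _strand_flip(allele: str) -> str | None:
    """Complement a single-base allele; indels are never strand-flipped."""
    return _COMPLEMENT.get(allele.upper())


@dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to one shared effect allele.

    ``data`` columns: snp, effect_allele, other_allele, beta_exp, se_exp,
    beta_out, se_out, eaf, flipped, palindromic.  ``dropped`` records the
    variants excluded during harmonization with a per-SNP reason.
    """

    exposure_id: str
    outcome_id: str
    data: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )

    @property
    def n_snp(self) -> int:
        return len(self.data)

    @property
    def snp_ids(self) -> list[str]:
        return self.data["snp"].tolist()

    @property
    def bx(self) -> np.ndarray:
        return self.data["beta_exp"].to_numpy(dtype=float)

    @property
    def by(self) -> np.ndarray:
        return self.data["beta_out"].to_numpy(dtype=float)

    @property
    def sx(self) -> np.ndarray:
        return self.data["se_exp"].to_numpy(dtype=float)

    @property
    def sy(self) -> np.ndarray:
        return self.data["se_out"].to_numpy(dtype=float)

    def subset(self, keep_snps) -> "HarmonizedSet":
        keep = set(keep_snps)
        data = self.data[self.data["snp"].isin(keep)].reset_index(drop=True)
        return HarmonizedSet(self.exposure_id, self.outcome_id, data, self.dropped)

    def drop_snps(self, snps) -> "HarmonizedSet":
        drop = set(snps)
        return self.subset([s for s in self.snp_ids if s not in drop])


PALINDROME_POLICIES = ("drop", "infer_by_eaf", "keep")


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    palindrome_policy: str = "infer_by_eaf",
    eaf_ambiguity: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect alleles.

    For non-palindromic variants the outcome row is kept as-is when its alleles
    match the exposure's, sign-flipped (and eaf complemented) when they are
    swapped, and the same logic is retried after strand complementation for
    single-base alleles.  Palindromic variants are handled per
    ``palindrome_policy``:

    - ``drop``: always excluded;
    - ``keep``: oriented by literal allele match only (strand trusted);
    - ``infer_by_eaf`` (default): oriented by comparing effect-allele
      frequencies, excluded when either frequency is missing or within
      ``eaf_ambiguity`` of 0.5.

    Raises :class:`HarmonizationError` when no SNP is shared.
    """
    if palindrome_policy not in PALINDROME_POLICIES:
        raise ConfigError(f"unknown palindrome policy {palindrome_policy!r}")

    exp = exposure.data.set_index("snp")
    out = outcome.data.set_index("snp")
    shared = [s for s in exposure.data["snp"] if s in out.index]
    if not shared:
        raise HarmonizationError(
            f"no shared instruments between {exposure.trait_id!r} and {outcome.trait_id!r}"
        )

    rows, dropped = [], []
    for snp in shared:
        e, o = exp.loc[snp], out.loc[snp]
        e_ea, e_oa = e["effect_allele"], e["other_allele"]
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        palin = is_palindromic(e_ea, e_oa)

        orientation = None  # "same" keeps the outcome row, "swap" flips it
        if (o_ea, o_oa) == (e_ea, e_oa):
            orientation = "same"
        elif (o_ea, o_oa) == (e_oa, e_ea):
            orientation = "swap"
        elif not palin:
            c_ea, c_oa = _strand_flip(o_ea), _strand_flip(o_oa)
            if c_ea is not None and c_oa is not None:
                if (c_ea, c_oa) == (e_ea, e_oa):
                    orientation = "same"
                elif (c_ea, c_oa) == (e_oa, e_ea):
                    orientation = "swap"
        if orientation is None:
            dropped.append((snp, f"allele mismatch ({e_ea}/{e_oa} vs {o_ea}/{o_oa})"))
            continue

        beta_out = float(o["beta"])
        eaf_out = float(o["eaf"]) if pd.notna(o["eaf"]) else np.nan
        flipped = orientation == "swap"
        if flipped:
            beta_out = -beta_out
            if not np.isnan(eaf_out):
                eaf_out = 1.0 - eaf_out

        if palin:
            if palindrome_policy == "drop":
                dropped.append((snp, "palindromic (policy drop)"))
                continue
            if palindrome_policy == "infer_by_eaf":
                eaf_exp = float(e["eaf"]) if pd.notna(e["eaf"]) else np.nan
                if np.isnan(eaf_exp) or np.isnan(eaf_out):
                    dropped.append((snp, "palindromic with missing eaf"))
                    continue
                if (abs(eaf_exp - 0.5) <= eaf_ambiguity
                        or abs(eaf_out - 0.5) <= eaf_ambiguity):
                    dropped.append((snp, "palindromic with ambiguous eaf"))
                    continue
                if (eaf_exp - 0.5) * (eaf_out - 0.5) < 0:
                    # Frequencies disagree: the outcome is reported on the
                    # opposite strand orientation, so flip once more.
                    beta_out = -beta_out
                    eaf_out = 1.0 - eaf_out
                    flipped = not flipped

        rows.append({
            "snp": snp,
            "effect_allele": e_ea,
            "other_allele": e_oa,
            "beta_exp": float(e["beta"]),
            "se_exp": float(e["se"]),
            "beta_out": beta_out,
            "se_out": float(o["se"]),
            "eaf": float(e["eaf"]) if pd.notna(e["eaf"]) else np.nan,
            "flipped": bool(flipped),
            "palindromic": bool(palin),
        })

    data = pd.DataFrame(
        rows,
        columns=["snp", "effect_allele", "other_allele", "beta_exp", "se_exp",
                 "beta_out", "se_out", "eaf", "flipped", "palindromic"],
    )
    dropped_df = pd.DataFrame(dropped, columns=["snp", "reason"])
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, data, dropped_df)
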