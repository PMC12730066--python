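"""GWAS / pQTL summary statistics: reading, validation, region filters,
LD clumping, instrument selection and exposure–outcome harmonization.

Tables are held as pandas DataFrames with canonical columns
``snp_id, chrom, pos, effect_allele, other_allele, eaf, beta, se, pval, n``.
``beta`` is per effect-allele copy: log-odds for binary traits, SD units for
protein levels. Coordinates are 1-based inclusive on GRCh37.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "DEFAULT_DIALECT",
    "MHC_GRCH37",
    "RegionSpec",
    "SumStatsTable",
    "InstrumentSet",
    "HarmonizedSet",
    "read_sumstats",
    "make_table",
    "exclude_region",
    "ld_clump",
    "select_instruments",
    "harmonize",
]

CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

#: column-mapping config keys -> canonical names (the file may use any header
#: names; the dialect maps config key to the header actually present)
DEFAULT_DIALECT = {
    "snp": "snp_id", "chr": "chrom", "pos": "pos", "ea": "effect_allele",
    "oa": "other_allele", "eaf": "eaf", "beta": "beta", "se": "se",
    "p": "pval", "n": "n",
}

_REQUIRED_KEYS = ("snp", "chr", "pos", "ea", "oa", "beta", "se", "p")
_OPTIONAL_KEYS = ("eaf", "n")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class RegionSpec:
    """A genomic interval, 1-based and inclusive at both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def contains(self, chrom, pos) -> np.ndarray:
        """Vectorized membership test for arrays of chrom / pos."""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos)
        return (chrom == self.chrom) & (pos >= self.start) & (pos <= self.end)


#: major histocompatibility complex on hg19, excluded from instrument selection
MHC_GRCH37 = RegionSpec("6", 26_000_000, 34_000_000)


@dataclass
class SumStatsTable:
    """One trait's validated summary statistics (snp_id unique)."""

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    df: pd.DataFrame
    validation_log: list = field(default_factory=list)

    def __post_init__(self):
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snps(self) -> list:
        return list(self.df["snp_id"])

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class InstrumentSet:
    """Instruments selected for one exposure, with the audit trail of drops."""

    exposure_id: str
    table: SumStatsTable
    selection_log: list = field(default_factory=list)
    status: str = "ok"  # "ok" | "empty"

    @property
    def n_instruments(self) -> int:
        return len(self.table)


@dataclass
class HarmonizedSet:
    """Exposure/outcome rows aligned to a common effect allele.

    ``df`` columns: snp_id, effect_allele, other_allele, beta_exp, se_exp,
    pval_exp, eaf_exp, n_exp, beta_out, se_out, pval_out, eaf_out, n_out.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    dropped: list = field(default_factory=list)
    status: str = "ok"  # "ok" | "empty"

    @property
    def nsnp(self) -> int:
        return len(self.df)


def _validate(df: pd.DataFrame, log: list) -> pd.DataFrame:
    """Enforce row invariants, dropping violators with logged reasons."""
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    def drop(mask: pd.Series, reason: str):
        nonlocal df
        for sid in df.loc[mask, "snp_id"]:
            log.append((sid, reason))
        df = df.loc[~mask]

    drop(df[["pos", "beta", "se", "pval"]].isna().any(axis=1),
         "missing required field")
    drop(~df["effect_allele"].isin(_VALID_ALLELES)
         | ~df["other_allele"].isin(_VALID_ALLELES), "non-ACGT allele")
    drop(df["effect_allele"] == df["other_allele"], "identical alleles")
    drop(df["se"] <= 0, "nonpositive SE")
    drop((df["pval"] <= 0) | (df["pval"] > 1), "p-value outside (0,1]")
    drop(df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1)),
         "EAF outside [0,1]")
    drop(df["snp_id"].duplicated(keep="first"), "duplicate snp_id")
    df["pos"] = df["pos"].astype(np.int64)
    return df.reset_index(drop=True)


def make_table(df: pd.DataFrame, trait_id: str,
               trait_type: str = "quantitative") -> SumStatsTable:
    """Build a validated SumStatsTable from a canonical-column DataFrame."""
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns
               and c not in ("eaf", "n")]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    for opt in ("eaf", "n"):
        if opt not in df.columns:
            df[opt] = np.nan
    log: list = []
    return SumStatsTable(trait_id, trait_type,
                         _validate(df[CANONICAL_COLUMNS], log), log)


def read_sumstats(path, dialect=None, trait_id=None,
                  trait_type: str = "quantitative",
                  sep=None) -> SumStatsTable:
    """Read a delimited summary-statistics file.

    Parameters
    ----------
    dialect
        Mapping from config keys (snp, chr, pos, ea, oa, eaf, beta, se, p, n)
        to the column names present in the file header. Defaults to the
        canonical names. Required keys missing from the file are a hard error.
    sep
        Field delimiter; inferred (tab vs comma) when None.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if raw.empty:
        raise ValueError(f"empty summary-statistics file: {path}")
    for key in _REQUIRED_KEYS:
        if dialect[key] not in raw.columns:
            raise ValueError(
                f"required column {dialect[key]!r} (for {key!r}) "
                f"not found in {path}")
    out = pd.DataFrame()
    for key, canon in DEFAULT_DIALECT.items():
        col = dialect[key]
        out[canon] = raw[col] if col in raw.columns else np.nan
    return make_table(out, trait_id or str(path), trait_type)


def exclude_region(table: SumStatsTable, region: RegionSpec) -> SumStatsTable:
    """Remove every record lying inside ``region`` (inclusive bounds)."""
    mask = region.contains(table.df["chrom"].to_numpy(),
                           table.df["pos"].to_numpy())
    return SumStatsTable(table.trait_id, table.trait_type,
                         table.df.loc[~mask].reset_index(drop=True),
                         list(table.validation_log))


def _clump_order(df: pd.DataFrame) -> pd.DataFrame:
    # deterministic: ascending p, ties by position then snp_id
    return df.sort_values(["pval", "pos", "snp_id"], kind="mergesort")


def ld_clump(table: SumStatsTable, ld: pd.DataFrame, r2_max: float,
             missing: str = "drop", log: list | None = None) -> SumStatsTable:
    """Greedy LD clumping: keep the most significant SNP, drop everything in
    LD (r² >= r2_max) with any kept SNP, repeat.

    ``ld`` is a square r² matrix with snp ids as index and columns.
    ``missing`` controls SNPs absent from the matrix: "drop" (logged) or
    "error".
    """
    if not 0 < r2_max < 1:
        raise ValueError("r2_max must be in (0,1)")
    if log is None:
        log = []
    df = _clump_order(table.df)
    ids = df["snp_id"].to_numpy()
    known = np.isin(ids, ld.index)
    if missing == "error" and not known.all():
        absent = ids[~known]
        raise KeyError(f"SNP(s) absent from LD matrix: {', '.join(absent)}")
    for sid in ids[~known]:
        log.append((sid, "missing-from-ld"))
    ids = ids[known]
    kept: list = []
    if len(ids):
        sub = ld.loc[ids, ids].to_numpy(dtype=float)
        alive = np.ones(len(ids), dtype=bool)
        for i in range(len(ids)):
            if not alive[i]:
                continue
            kept.append(ids[i])
            shadow = alive & (sub[i] >= r2_max)
            shadow[i] = False
            for sid in ids[shadow]:
                log.append((sid, "ld-clumped"))
            alive &= ~shadow
    out = df[df["snp_id"].isin(kept)]
    return SumStatsTable(table.trait_id, table.trait_type,
                         out.reset_index(drop=True),
                         list(table.validation_log))


def select_instruments(table: SumStatsTable, p_max: float = 5e-8,
                       cis: RegionSpec | None = None,
                       mhc: RegionSpec | None = MHC_GRCH37,
                       ld: pd.DataFrame | None = None,
                       r2_max: float = 0.001,
                       ld_missing: str = "drop") -> InstrumentSet:
    """Select MR instruments: genome-wide significant (p < p_max), cis-only
    when a cis window is given, outside the MHC, then LD-clumped.

    Every exclusion is recorded in ``selection_log`` as (snp_id, reason).
    """
    if table.df.empty:
        raise ValueError("instrument selection requires a nonempty table")
    log: list = []
    df = table.df

    weak = df["pval"] >= p_max
    log.extend((s, "above-p-threshold") for s in df.loc[weak, "snp_id"])
    df = df.loc[~weak]

    if cis is not None:
        trans = ~cis.contains(df["chrom"].to_numpy(), df["pos"].to_numpy())
        log.extend((s, "trans") for s in df.loc[trans, "snp_id"])
        df = df.loc[~trans]

    if mhc is not None:
        inmhc = mhc.contains(df["chrom"].to_numpy(), df["pos"].to_numpy())
        log.extend((s, "mhc") for s in df.loc[inmhc, "snp_id"])
        df = df.loc[~inmhc]

    sub = SumStatsTable(table.trait_id, table.trait_type,
                        df.reset_index(drop=True))
    if ld is not None and len(sub):
        sub = ld_clump(sub, ld, r2_max, missing=ld_missing, log=log)
    else:
        sub = SumStatsTable(sub.trait_id, sub.trait_type,
                            _clump_order(sub.df).reset_index(drop=True))
    status = "ok" if len(sub) else "empty"
    return InstrumentSet(table.trait_id, sub, log, status)


def _complement(alleles: np.ndarray) -> np.ndarray:
    return np.array([_COMPLEMENT.get(a, "?") for a in alleles], dtype=object)


def harmonize(exposure: SumStatsTable, outcome: SumStatsTable,
              palindrome_eaf_limit: float = 0.42) -> HarmonizedSet:
    """Align outcome associations to the exposure's effect allele.

    Matching alleles are kept as-is; swapped alleles flip the outcome beta
    sign and reflect its EAF; strand flips (complementary alleles) are
    complemented first. Palindromic SNPs (A/T, C/G) are resolved by allele
    frequency only: both EAFs must be outside
    [palindrome_eaf_limit, 1 - palindrome_eaf_limit] and on the same side of
    0.5, else the row is dropped as "palindromic-ambiguous" (missing EAF on
    either side also drops).
    """
    m = exposure.df.merge(outcome.df, on="snp_id", suffixes=("_exp", "_out"))
    if m.empty:
        return HarmonizedSet(exposure.trait_id, outcome.trait_id,
                             _empty_harmonized(), [], "empty")

    ea_e = m["effect_allele_exp"].to_numpy(dtype=object)
    oa_e = m["other_allele_exp"].to_numpy(dtype=object)
    ea_o = m["effect_allele_out"].to_numpy(dtype=object)
    oa_o = m["other_allele_out"].to_numpy(dtype=object)
    cea_e, coa_e = _complement(ea_e), _complement(oa_e)

    pal = oa_e == cea_e  # exposure allele pair is its own complement
    exact = (ea_o == ea_e) & (oa_o == oa_e)
    swap = (ea_o == oa_e) & (oa_o == ea_e)
    flip_exact = (ea_o == cea_e) & (oa_o == coa_e)
    flip_swap = (ea_o == coa_e) & (oa_o == cea_e)

    keep = np.zeros(len(m), dtype=bool)
    flip = np.zeros(len(m), dtype=bool)
    reason = np.full(len(m), "", dtype=object)

    np_mask = ~pal
    keep |= np_mask & (exact | flip_exact)
    flip |= np_mask & ~(exact | flip_exact) & (swap | flip_swap)
    keep |= flip
    reason[np_mask & ~keep] = "incompatible alleles"

    # palindromic rows: a textual swap cannot be told apart from a strand
    # flip, so after textual alignment the orientation must be confirmed by
    # allele frequency: both EAFs extreme and on the same side of 0.5
    if pal.any():
        compatible = pal & (exact | swap)
        reason[pal & ~compatible] = "incompatible alleles"
        flip |= pal & swap & compatible

    beta_out = m["beta_out"].to_numpy(dtype=float).copy()
    eaf_out = m["eaf_out"].to_numpy(dtype=float).copy()
    beta_out[flip] = -beta_out[flip]
    eaf_out[flip] = 1.0 - eaf_out[flip]

    if pal.any():
        eaf_e = m["eaf_exp"].to_numpy(dtype=float)
        lo, hi = palindrome_eaf_limit, 1.0 - palindrome_eaf_limit
        informative = (np.isfinite(eaf_e) & np.isfinite(eaf_out)
                       & ((eaf_e < lo) | (eaf_e > hi))
                       & ((eaf_out < lo) | (eaf_out > hi)))
        same_side = (eaf_e < 0.5) == (eaf_out < 0.5)
        ok = compatible & informative & same_side
        keep |= ok
        reason[pal & compatible & ~ok] = "palindromic-ambiguous"

    dropped = [(sid, r) for sid, r in zip(m["snp_id"], reason) if r]
    out = pd.DataFrame({
        "snp_id": m["snp_id"],
        "effect_allele": ea_e,
        "other_allele": oa_e,
        "beta_exp": m["beta_exp"].to_numpy(dtype=float),
        "se_exp": m["se_exp"].to_numpy(dtype=float),
        "pval_exp": m["pval_exp"].to_numpy(dtype=float),
        "eaf_exp": m["eaf_exp"].to_numpy(dtype=float),
        "n_exp": m["n_exp"].to_numpy(dtype=float),
        "beta_out": beta_out,
        "se_out": m["se_out"].to_numpy(dtype=float),
        "pval_out": m["pval_out"].to_numpy(dtype=float),
        "eaf_out": eaf_out,
        "n_out": m["n_out"].to_numpy(dtype=float),
    }).loc[keep].reset_index(drop=True)
    status = "ok" if len(out) else "empty"
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, out,
                         dropped, status)


def _empty_harmonized() -> pd.DataFrame:
    cols = ["snp_id", "effect_allele", "other_allele",
            "beta_exp", "se_exp", "pval_exp", "eaf_exp", "n_exp",
            "beta_out", "se_out", "pval_out", "eaf_out", "n_out"]
    return pd.DataFrame({c: [] for c in cols})
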