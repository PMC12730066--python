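"""Directionality checks: Steiger filtering and bidirectional MR.

Both guard the protein -> disease interpretation. Steiger filtering drops
instruments that explain more trait variance on the outcome side than on
the exposure side; bidirectional (reverse) MR re-runs the whole pipeline
with the disease GWAS as exposure and the pQTL study as outcome, flagging
reverse causation when that reverse estimate is nominally significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import (HarmonizedSet, RegionSpec, SumStatsTable, harmonize,
                       select_instruments)
from .mr import MREstimate, ivw, wald_ratio

__all__ = ["SteigerRecord", "ReverseMRResult", "variance_explained",
           "steiger_filter", "reverse_mr"]


@dataclass
class SteigerRecord:
    snp_id: str
    r2_exposure: float
    r2_outcome: float
    direction_ok: bool
    steiger_pval: float


@dataclass
class ReverseMRResult:
    status: str  # "ok" | "untestable"
    estimate: MREstimate | None = None
    reverse_causal: bool | None = None


def variance_explained(beta: float, se: float, n: float,
                       eaf: float | None = None,
                       method: str = "tstat") -> float:
    """Trait variance explained by one SNP, from summary statistics.

    Default ``tstat`` form r² = t²/(t² + n − 2) with t = beta/se works for
    both quantitative and binary traits (the latter on the observed scale).
    ``method="af"`` uses 2·eaf·(1−eaf)·beta², valid for standardized
    quantitative traits only.
    """
    if method == "af":
        if eaf is None or not np.isfinite(eaf):
            raise ValueError("allele-frequency r2 requires a finite EAF")
        return float(2.0 * eaf * (1.0 - eaf) * beta ** 2)
    if n is None or not np.isfinite(n) or n <= 2:
        raise ValueError("t-statistic r2 requires n > 2")
    t2 = (beta / se) ** 2
    return float(t2 / (t2 + n - 2.0))


def _steiger_p(r2_exp, r2_out, n_exp, n_out):
    # z-test on the difference of Fisher-transformed |correlations|
    z = (np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))) / \
        np.sqrt(1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0))
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def steiger_filter(h: HarmonizedSet, method: str = "tstat"
                   ) -> tuple[HarmonizedSet, list]:
    """Retain instruments explaining more variance in the exposure than in
    the outcome; a pure row filter (retained rows are untouched).

    Rows lacking a sample size on either side are dropped with reason
    "missing-n". Returns the filtered set plus one SteigerRecord per row
    that had the data to be evaluated.
    """
    records: list[SteigerRecord] = []
    keep = np.zeros(h.nsnp, dtype=bool)
    dropped = list(h.dropped)
    for i, row in h.df.iterrows():
        try:
            r2e = variance_explained(row["beta_exp"], row["se_exp"],
                                     row["n_exp"], row["eaf_exp"], method)
            r2o = variance_explained(row["beta_out"], row["se_out"],
                                     row["n_out"], row["eaf_out"], method)
        except ValueError:
            dropped.append((row["snp_id"], "missing-n"))
            continue
        ok = bool(r2e > r2o)
        records.append(SteigerRecord(
            row["snp_id"], r2e, r2o, ok,
            _steiger_p(r2e, r2o, row["n_exp"], row["n_out"])))
        keep[i] = ok
        if not ok:
            dropped.append((row["snp_id"], "steiger-reversed"))
    out_df = h.df.loc[keep].reset_index(drop=True)
    status = "ok" if len(out_df) else "empty"
    return (HarmonizedSet(h.exposure_id, h.outcome_id, out_df, dropped,
                          status), records)


def reverse_mr(outcome_as_exposure: SumStatsTable,
               protein_as_outcome: SumStatsTable,
               p_max: float = 5e-8,
               ld: pd.DataFrame | None = None,
               r2_max: float = 0.001,
               mhc: RegionSpec | None = None,
               alpha: float = 0.05) -> ReverseMRResult:
    """Bidirectional check: disease GWAS as exposure, pQTL as outcome.

    Selects genome-wide-significant disease instruments, harmonizes against
    the protein study, and runs IVW (Wald for a single instrument). The
    protein is flagged ``reverse_causal`` when the reverse estimate reaches
    p < alpha; zero usable instruments yields status "untestable" — an
    explicit non-result, not a pass.
    """
    inst = select_instruments(outcome_as_exposure, p_max=p_max, cis=None,
                              mhc=mhc, ld=ld, r2_max=r2_max)
    if inst.n_instruments == 0:
        return ReverseMRResult("untestable")
    h = harmonize(inst.table, protein_as_outcome)
    if h.nsnp == 0:
        return ReverseMRResult("untestable")
    if h.nsnp == 1:
        row = h.df.iloc[0]
        est = wald_ratio(row["beta_exp"], row["se_exp"],
                         row["beta_out"], row["se_out"])
    else:
        est = ivw(h)
    return ReverseMRResult("ok", est, bool(est.pval < alpha))
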