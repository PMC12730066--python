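"""Bayesian colocalization of two association signals in one region.

Per-SNP approximate Bayes factors (Wakefield's closed form from a beta, its
SE and a Gaussian effect-size prior) are combined over the region's shared
SNPs into posterior probabilities for the five standard hypotheses:

* H0 — no association with either trait;
* H1 / H2 — association with trait 1 / trait 2 only;
* H3 — both traits associated, distinct causal variants;
* H4 — both traits associated, one shared causal variant.

All hypothesis arithmetic is done in log space (logsumexp / logdiffexp) so
that regions with |z| well above 30 cannot underflow. The single-causal-
variant-per-trait assumption of this decomposition is inherited as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .sumstats import RegionSpec, SumStatsTable

__all__ = ["ColocPriors", "ColocResult", "wakefield_labf", "coloc_abf",
           "coloc_all_hits"]


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities and effect-size prior SDs.

    Defaults are the standard single-variant colocalization priors:
    p1 = p2 = 1e-4 (SNP associated with one trait), p12 = 1e-5 (shared),
    prior effect SD 0.15 for a quantitative trait 1 and 0.2 for a binary
    trait 2 (log-odds scale).
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    sd1: float = 0.15
    sd2: float = 0.2

    def __post_init__(self):
        if not 0 < self.p12 <= min(self.p1, self.p2):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("prior SDs must be positive")


@dataclass
class ColocResult:
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    nsnps: int
    priors: ColocPriors
    support: str = field(init=False)
    strong_threshold: float = 0.75
    moderate_low: float = 0.60
    notes: list = field(default_factory=list)

    def __post_init__(self):
        if self.pph4 >= self.strong_threshold:
            self.support = "strong"
        elif self.pph4 >= self.moderate_low:
            self.support = "moderate"
        else:
            self.support = "none"

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3,
                         self.pph4])

    @property
    def modal_hypothesis(self) -> int:
        return int(np.argmax(self.posteriors))


def wakefield_labf(beta, se, prior_sd) -> np.ndarray | float:
    """Log approximate Bayes factor for one association.

    With V = se², W = prior_sd², r = W/(V+W) and z = beta/se:
    lABF = ½·[log(1 − r) + r·z²]. Vectorized over beta/se.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or prior_sd <= 0:
        raise ValueError("se and prior_sd must be positive")
    v = se ** 2
    r = prior_sd ** 2 / (v + prior_sd ** 2)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z ** 2)
    return float(out) if out.ndim == 0 else out


def _logdiffexp(a: float, b: float) -> float:
    # log(exp(a) - exp(b)) for a > b
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(region1: SumStatsTable, region2: SumStatsTable,
              priors: ColocPriors = ColocPriors(),
              strong_threshold: float = 0.75,
              moderate_low: float = 0.60) -> ColocResult:
    """Five-hypothesis posterior decomposition over the shared SNPs of two
    regional summary-statistics tables.

    Raises ValueError when the regions share no SNPs. A single-SNP region
    makes H3 (distinct variants) impossible; its weight is set to -inf and
    a note recorded.
    """
    m = region1.df.merge(region2.df, on="snp_id", suffixes=("_1", "_2"))
    if m.empty:
        raise ValueError("colocalization requires >= 1 shared SNP")
    l1 = wakefield_labf(m["beta_1"].to_numpy(), m["se_1"].to_numpy(),
                        priors.sd1)
    l2 = wakefield_labf(m["beta_2"].to_numpy(), m["se_2"].to_numpy(),
                        priors.sd2)
    l1 = np.atleast_1d(l1)
    l2 = np.atleast_1d(l2)
    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))

    notes: list = []
    if s1 + s2 <= s12:
        # exactly one shared SNP (or numerically indistinguishable): no
        # off-diagonal mass for H3
        h3 = -np.inf
        notes.append("H3 impossible: single effective SNP in region")
    else:
        h3 = np.log(priors.p1) + np.log(priors.p2) + _logdiffexp(s1 + s2, s12)

    weights = np.array([
        0.0,
        np.log(priors.p1) + s1,
        np.log(priors.p2) + s2,
        h3,
        np.log(priors.p12) + s12,
    ])
    post = np.exp(weights - logsumexp(weights))
    post /= post.sum()
    return ColocResult(*map(float, post), nsnps=len(m), priors=priors,
                       strong_threshold=strong_threshold,
                       moderate_low=moderate_low, notes=notes)


def _restrict(table: SumStatsTable, region: RegionSpec) -> SumStatsTable:
    mask = region.contains(table.df["chrom"].to_numpy(),
                           table.df["pos"].to_numpy())
    return SumStatsTable(table.trait_id, table.trait_type,
                         table.df.loc[mask].reset_index(drop=True))


def coloc_all_hits(hits: list, pqtl_tables: dict, gwas: SumStatsTable,
                   anchors: dict, window: int = 500_000,
                   priors: ColocPriors = ColocPriors(),
                   strong_threshold: float = 0.75,
                   moderate_low: float = 0.60) -> dict:
    """Colocalize every MR-significant protein's cis region (anchor
    position ± window) against the outcome GWAS.

    ``anchors`` maps protein id -> (chrom, position) of the cis anchor
    (gene transcription start). Regions with no shared SNPs are recorded as
    None (untestable) rather than omitted.
    """
    results: dict = {}
    for pid in hits:
        chrom, pos = anchors[pid]
        region = RegionSpec(str(chrom), max(1, pos - window), pos + window)
        t1 = _restrict(pqtl_tables[pid], region)
        t2 = _restrict(gwas, region)
        try:
            results[pid] = coloc_abf(t1, t2, priors, strong_threshold,
                                     moderate_low)
        except ValueError:
            results[pid] = None
    return results
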