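"""Two-step MR mediation: protein -> modifiable risk factor -> outcome.

Step 1 estimates each protein's effect on each candidate risk factor; step
2 estimates each factor's effect on the outcome. The indirect effect is the
product of the two path coefficients (Product method) with a first-order
delta-method SE, and the proportion mediated divides it by the protein's
total effect from the primary screen. A factor qualifies as a mediator when
both steps are nominally significant (p < 0.05) and the indirect effect
shares the sign of the total effect; FDR-adjusted step-1 p-values are
always reported alongside the nominal ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sumstats import SumStatsTable, harmonize
from .mr import mr_all_methods

__all__ = ["MediationResult", "mediate", "step1_protein_to_factors",
           "step2_factors_to_outcome", "screen_mediators", "run_two_step"]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MediationResult:
    protein_id: str
    mediator_id: str
    beta1: float
    se1: float
    p1: float
    beta2: float
    se2: float
    p2: float
    total_beta: float
    total_se: float
    indirect_beta: float = field(init=False)
    indirect_se: float = field(init=False)
    indirect_ci: tuple = field(init=False)
    proportion_mediated: float = field(init=False)  # fraction, sign kept
    proportion_defined: bool = field(init=False)
    passes_screen: bool = field(init=False)

    def __post_init__(self):
        self.indirect_beta = self.beta1 * self.beta2
        self.indirect_se = float(np.sqrt(self.beta1 ** 2 * self.se2 ** 2
                                         + self.beta2 ** 2 * self.se1 ** 2))
        half = _Z95 * self.indirect_se
        self.indirect_ci = (self.indirect_beta - half,
                            self.indirect_beta + half)
        self.proportion_defined = self.total_beta != 0
        self.proportion_mediated = (
            self.indirect_beta / self.total_beta
            if self.proportion_defined else float("nan"))
        self.passes_screen = bool(
            self.p1 < 0.05 and self.p2 < 0.05
            and np.sign(self.indirect_beta) == np.sign(self.total_beta)
            and self.indirect_beta != 0)

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion_mediated

    @property
    def inconsistent(self) -> bool:
        """Proportion outside [0, 100]% (flagged, never clamped)."""
        return self.proportion_defined and not \
            0.0 <= self.proportion_mediated <= 1.0


def mediate(beta1, se1, beta2, se2, total_beta, total_se,
            protein_id: str = "", mediator_id: str = "") -> MediationResult:
    """Product-method indirect effect beta1*beta2 with delta-method SE
    sqrt(beta1²·se2² + beta2²·se1²) and a 95% Wald CI. Deterministic, exact
    arithmetic. Path p-values are two-sided normal."""
    p1 = float(min(1.0, 2.0 * stats.norm.sf(abs(beta1 / se1)))) if se1 > 0 else 0.0
    p2 = float(min(1.0, 2.0 * stats.norm.sf(abs(beta2 / se2)))) if se2 > 0 else 0.0
    return MediationResult(protein_id, mediator_id, beta1, se1, p1,
                           beta2, se2, p2, total_beta, total_se)


def _mr_grid(exposures: dict, outcomes: dict, seed: int = 0) -> pd.DataFrame:
    """MR of every exposure InstrumentSet on every outcome table; one row
    per cell, untestable cells kept with status."""
    rows = []
    for i, (eid, inst) in enumerate(exposures.items()):
        for oid, table in outcomes.items():
            if inst.n_instruments == 0:
                rows.append({"exposure": eid, "outcome": oid,
                             "status": "untestable"})
                continue
            h = harmonize(inst.table, table)
            if h.nsnp == 0:
                rows.append({"exposure": eid, "outcome": oid,
                             "status": "untestable"})
                continue
            est, _, _ = mr_all_methods(h, methods="primary", seed=seed + i)
            rows.append({"exposure": eid, "outcome": oid, "status": "ok",
                         "method": est.method, "beta": est.beta,
                         "se": est.se, "pval": est.pval, "nsnp": est.nsnp})
    cols = ["exposure", "outcome", "status", "method", "beta", "se",
            "pval", "nsnp"]
    df = pd.DataFrame(rows, columns=cols)
    ok = df["status"] == "ok"
    df["pval_fdr"] = np.nan
    if ok.any():
        df.loc[ok, "pval_fdr"] = multipletests(
            df.loc[ok, "pval"], method="fdr_bh")[1]
    return df


def step1_protein_to_factors(proteins: dict, factors: dict,
                             seed: int = 0) -> pd.DataFrame:
    """Protein -> risk-factor MR grid (proteins as exposures); nominal and
    BH-adjusted p-values both reported."""
    return _mr_grid(proteins, factors, seed)


def step2_factors_to_outcome(factors: dict, outcome: SumStatsTable,
                             seed: int = 0) -> pd.DataFrame:
    """Risk-factor -> outcome MR (factors as exposures)."""
    return _mr_grid(factors, {outcome.trait_id: outcome}, seed)


def screen_mediators(results: list) -> list:
    """Keep results passing the two-step screen, sorted by descending
    |proportion mediated|."""
    kept = [r for r in results if r.passes_screen]
    return sorted(kept, key=lambda r: -abs(r.proportion_mediated)
                  if np.isfinite(r.proportion_mediated) else 0.0)


def run_two_step(proteins: dict, factor_instruments: dict,
                 factor_tables: dict, outcome: SumStatsTable,
                 totals: dict, seed: int = 0):
    """Full mediation pass.

    Parameters
    ----------
    proteins
        protein id -> InstrumentSet (protein instruments).
    factor_instruments
        factor id -> InstrumentSet (factor instruments, for step 2).
    factor_tables
        factor id -> SumStatsTable (factor GWAS, outcome side of step 1).
    totals
        protein id -> (total_beta, total_se) from the primary screen.

    Returns (all MediationResults, screened list, step1 frame, step2 frame).
    """
    s1 = step1_protein_to_factors(proteins, factor_tables, seed)
    s2 = step2_factors_to_outcome(factor_instruments, outcome, seed)
    s2_ok = s2[s2["status"] == "ok"].set_index("exposure")
    results = []
    for _, row in s1[s1["status"] == "ok"].iterrows():
        fid = row["outcome"]
        pid = row["exposure"]
        if fid not in s2_ok.index or pid not in totals:
            continue
        f = s2_ok.loc[fid]
        tb, tse = totals[pid]
        results.append(MediationResult(
            pid, fid, row["beta"], row["se"], row["pval"],
            float(f["beta"]), float(f["se"]), float(f["pval"]), tb, tse))
    return results, screen_mediators(results), s1, s2


def mediation_frame(results: list) -> pd.DataFrame:
    rows = [{
        "protein": r.protein_id, "mediator": r.mediator_id,
        "beta1": r.beta1, "se1": r.se1, "p1": r.p1,
        "beta2": r.beta2, "se2": r.se2, "p2": r.p2,
        "total_beta": r.total_beta, "indirect_beta": r.indirect_beta,
        "indirect_se": r.indirect_se,
        "ci_low": r.indirect_ci[0], "ci_high": r.indirect_ci[1],
        "proportion_pct": r.proportion_pct,
        "passes_screen": r.passes_screen,
        "inconsistent": r.inconsistent,
    } for r in results]
    return pd.DataFrame(rows)
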