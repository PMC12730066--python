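"""Evidence integration: PPI edge filtering, drug-target connectivity, and
the four-tier candidate classification.

A protein must first be MR-significant to be tiered at all; the tier then
counts four orthogonal supports — strong colocalization (PPH4 strictly
above 0.75), significant differential expression, a PPI edge to a known
drug target, and documented druggability. All four gives tier 1, three
tier 2, two tier 3, and at most one tier 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["EvidenceProfile", "filter_ppi_edges", "ppi_connectivity",
           "assign_tier", "evidence_matrix"]

PPH4_TIER_CUTOFF = 0.75  # strict: pph4 must exceed this
PPI_MIN_SCORE = 0.40     # inclusive


@dataclass(frozen=True)
class EvidenceProfile:
    protein_id: str
    mr_significant: bool
    coloc_strong: bool
    de_significant: bool
    ppi_connected: bool
    druggable: bool


def filter_ppi_edges(edges, min_score: float = PPI_MIN_SCORE) -> pd.DataFrame:
    """Keep interaction edges with confidence score >= min_score
    (inclusive). ``edges`` is a DataFrame or iterable of (a, b, score)."""
    df = pd.DataFrame(edges, columns=None)
    if df.shape[1] != 3:
        raise ValueError("edge list must have columns (a, b, score)")
    df.columns = ["a", "b", "score"]
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    return df[df["score"] >= min_score].reset_index(drop=True)


def ppi_connectivity(protein: str, edges: pd.DataFrame,
                     drug_targets) -> bool:
    """True iff a (filtered) edge links the protein directly to any known
    drug target."""
    targets = set(drug_targets)
    hits = edges[((edges["a"] == protein) & edges["b"].isin(targets))
                 | ((edges["b"] == protein) & edges["a"].isin(targets))]
    return not hits.empty


def assign_tier(p: EvidenceProfile) -> int:
    """Tier from the count of supporting evidence flags.

    Raises ValueError for proteins without a significant MR association —
    they are not candidates and are never tiered.
    """
    if not p.mr_significant:
        raise ValueError(f"{p.protein_id or 'protein'}: not a candidate "
                         "(no significant MR association)")
    c = sum((p.coloc_strong, p.de_significant, p.ppi_connected, p.druggable))
    return {4: 1, 3: 2, 2: 3}.get(c, 4)


def evidence_matrix(profiles: list) -> pd.DataFrame:
    """Tidy evidence table with the tier column appended."""
    rows = []
    for p in profiles:
        rows.append({
            "protein": p.protein_id,
            "mr_significant": p.mr_significant,
            "coloc_strong": p.coloc_strong,
            "de_significant": p.de_significant,
            "ppi_connected": p.ppi_connected,
            "druggable": p.druggable,
            "tier": assign_tier(p) if p.mr_significant else None,
        })
    return pd.DataFrame(rows)
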