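"""Directional drug–gene interaction filtering and candidate tiering.

Candidate genes are kept only if some drug interacts with them with known
directionality (inhibitor, activator, ...).  Druggable candidates are then
tiered: tier 1 if the gene appeared in both the eukaryote-wide and the
clade-restricted candidate sets, tier 2 if in exactly one; genes lying in a
significantly clustered karyotype band are flagged as additional evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .io_formats import DEFAULT_DIRECTIONAL_TYPES
from .ranking import CandidateSet


@dataclass
class DruggableCandidate:
    """A candidate gene with at least one directional drug interaction."""

    gene_id: str
    drugs: list[tuple[str, str, str]]  # (drug, interaction_type, source)
    tier: int | None = None
    in_enriched_band: bool | None = None


def filter_druggable(
    candidates: Iterable[str],
    drug_table: pd.DataFrame,
    allowed_types: Iterable[str] = DEFAULT_DIRECTIONAL_TYPES,
) -> list[DruggableCandidate]:
    """Candidates having >= 1 interaction of an allowed (directional) type.

    Drug entries are deduplicated by (drug, type, source) and sorted; output
    gene order is deterministic (sorted by gene_id) and invariant to the row
    order of the interaction table.
    """
    allowed = set(allowed_types)
    if not allowed:
        raise ValidationError("allowed_types must be non-empty")
    cand = set(candidates)
    rows = drug_table[
        drug_table["gene_id"].isin(cand)
        & drug_table["interaction_type"].isin(allowed)
    ]
    out = []
    for gene_id, group in rows.groupby("gene_id", sort=True):
        triples = sorted(
            set(zip(group["drug"], group["interaction_type"], group["source"]))
        )
        out.append(DruggableCandidate(gene_id=str(gene_id), drugs=triples))
    return out


def tier_candidates(
    druggable: Sequence[DruggableCandidate],
    e_set: CandidateSet,
    m_set: CandidateSet,
    enriched_bands: Iterable[str],
    genes: pd.DataFrame,
) -> list[DruggableCandidate]:
    """Assign tiers and enriched-band flags; tier-1 genes sort first.

    Tier 1 = present in both candidate sets; tier 2 = exactly one.  A gene
    outside both sets is a contract violation.
    """
    in_e, in_m = set(e_set.genes), set(m_set.genes)
    enriched = set(enriched_bands)
    band_of = genes.set_index("gene_id")["band"]
    out = []
    for c in druggable:
        e, m = c.gene_id in in_e, c.gene_id in in_m
        if not (e or m):
            raise ValidationError(
                f"druggable gene {c.gene_id!r} outside both candidate sets"
            )
        band = band_of.get(c.gene_id)
        out.append(DruggableCandidate(
            gene_id=c.gene_id,
            drugs=list(c.drugs),
            tier=1 if (e and m) else 2,
            in_enriched_band=bool(pd.notna(band) and band in enriched),
        ))
    return sorted(out, key=lambda c: (c.tier, c.gene_id))


def druggable_frame(druggable: Sequence[DruggableCandidate]) -> pd.DataFrame:
    """TSV-ready view: one row per gene, drugs semicolon-joined."""
    return pd.DataFrame(
        [{"gene_id": c.gene_id,
          "tier": c.tier if c.tier is not None else "",
          "in_enriched_band": c.in_enriched_band
          if c.in_enriched_band is not None else "",
          "n_drugs": len(c.drugs),
          "drugs": ";".join("|".join(t) for t in c.drugs)}
         for c in druggable]
    )
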