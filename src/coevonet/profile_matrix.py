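"""The best-hit bit-score matrix: genes x species, thresholded.

Each entry holds the best BLASTP bit score between a query gene and any
protein of the target species; entries below the minimal-homology threshold
(20.4 bits, the bit score equivalent to a BLAST e-value of 0.05 on the
proteome scale used here) are set to 0.  Absence is encoded as 0 bits rather
than missing so downstream statistics treat gene loss as informative signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import BlastHit

#: Bit score corresponding to a BLAST e-value of 0.05; the default minimal
#: similarity threshold.
DEFAULT_BIT_MIN = 20.4


@dataclass
class RawScoreMatrix:
    """Genes x species best-hit bit scores after thresholding.

    ``values`` is a DataFrame indexed by gene id with species-id columns.
    Every entry is either 0 (no homolog at or above threshold) or
    >= ``bit_min``.
    """

    values: pd.DataFrame
    bit_min: float

    def __post_init__(self):
        if self.bit_min < 0:
            raise ValidationError(f"bit_min must be >= 0, got {self.bit_min}")
        if self.values.index.duplicated().any() or self.values.columns.duplicated().any():
            raise ValidationError("duplicate gene or species ids in matrix")
        v = self.values.to_numpy(dtype=float)
        if (v < 0).any():
            raise ValidationError("bit scores must be non-negative")
        if ((v > 0) & (v < self.bit_min)).any():
            raise ValidationError(
                f"entries in (0, {self.bit_min}) violate the threshold contract"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g",
                   lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path, bit_min: float) -> "RawScoreMatrix":
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.set_index("gene_id")
        df.index = df.index.astype(str)
        return cls(values=df.astype(float), bit_min=bit_min)


def best_hits(
    hits: Iterable[BlastHit],
    genes: pd.DataFrame,
    species: pd.DataFrame,
    bit_min: float = DEFAULT_BIT_MIN,
) -> RawScoreMatrix:
    """Reduce BLAST hits to the best score per (gene, species), thresholded.

    The matrix covers the full gene x species grid of the annotation tables;
    pairs with no hit, or whose best hit falls below ``bit_min``, are 0.
    Hits naming unknown gene or species ids raise a validation error listing
    the offenders.  The result is invariant to the order of ``hits``.
    """
    if bit_min < 0:
        raise ValidationError(f"bit_min must be >= 0, got {bit_min}")
    gene_ids = list(genes["gene_id"])
    species_ids = list(species["species_id"])
    hits = list(hits)

    known_g, known_s = set(gene_ids), set(species_ids)
    bad_g = sorted({h.query_gene for h in hits} - known_g)
    bad_s = sorted({h.species_id for h in hits} - known_s)
    if bad_g or bad_s:
        raise ValidationError(
            f"hits reference unknown ids: genes {bad_g}, species {bad_s}"
        )

    full = pd.DataFrame(0.0, index=pd.Index(gene_ids, name="gene_id"),
                        columns=species_ids)
    if hits:
        df = pd.DataFrame(
            {"g": [h.query_gene for h in hits],
             "s": [h.species_id for h in hits],
             "b": [h.bitscore for h in hits]}
        )
        best = df.groupby(["g", "s"], sort=True)["b"].max()
        mat = best.unstack(fill_value=0.0)
        full.loc[mat.index, mat.columns] = mat
    full = full.where(full >= bit_min, 0.0)
    return RawScoreMatrix(values=full, bit_min=bit_min)


def apply_threshold(m: RawScoreMatrix, bit_min: float = DEFAULT_BIT_MIN) -> RawScoreMatrix:
    """Zero out entries below ``bit_min`` (used on unthresholded simulator output)."""
    if bit_min < m.bit_min:
        raise ValidationError(
            f"cannot lower threshold from {m.bit_min} to {bit_min}"
        )
    values = m.values.where(m.values >= bit_min, 0.0)
    return RawScoreMatrix(values=values, bit_min=bit_min)


def matrix_summary(m: RawScoreMatrix) -> dict:
    """Structural summary: dimensions, zero fraction, per-species nonzero counts."""
    v = m.values.to_numpy(dtype=float)
    nonzero_per_species = (v > 0).sum(axis=0)
    return {
        "n_genes": v.shape[0],
        "n_species": v.shape[1],
        "zero_fraction": float((v == 0).mean()) if v.size else 0.0,
        "per_species_nonzero": {
            s: int(c) for s, c in zip(m.species, nonzero_per_species)
        },
    }
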