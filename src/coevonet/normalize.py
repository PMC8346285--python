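"""Normalized Phylogenetic Profiles (NPP).

Raw best-hit bit scores confound three things: how conserved the gene really
is, how long its protein is (longer alignments score more bits), and how far
the target species sits from the reference (everything scores fewer bits in
distant species).  The NPP transform removes the last two: scores are divided
by query protein length (bits per residue), then standardized within each
species column.  Per-species standardization removes any per-species location
and scale shift — exactly the effect a distance-dependent decay induces — so
downstream correlations compare conservation relative to expectation, not
absolute similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .profile_matrix import RawScoreMatrix

_METHODS = ("zscore", "rank")


@dataclass(frozen=True)
class NormalizationConfig:
    """How species columns are standardized.

    ``method='zscore'`` subtracts the column mean and divides by the sample
    (n-1) standard deviation; ``method='rank'`` maps each column to fractional
    ranks in (0, 1].  ``include_zeros`` keeps absence entries (0 bits) in the
    column statistics — absence is signal in phylogenetic profiling.
    ``log_transform`` applies log2(1+x) to bits-per-residue first (off by
    default).  Degenerate (zero-variance) columns are dropped with a record
    rather than erroring when ``drop_degenerate_species`` is set.
    """

    method: str = "zscore"
    include_zeros: bool = True
    drop_degenerate_species: bool = True
    log_transform: bool = False

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValidationError(f"method must be one of {_METHODS}, got {self.method!r}")


@dataclass
class NPPMatrix:
    """Genes x species dimensionless normalized profiles."""

    values: pd.DataFrame
    config: NormalizationConfig
    dropped_species: list[str] = field(default_factory=list)

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


def length_normalize(m: RawScoreMatrix, genes: pd.DataFrame) -> pd.DataFrame:
    """Bits per residue: each gene's row divided by its protein length.

    Zeros (absent homologs) stay zero.
    """
    lengths = genes.set_index("gene_id")["protein_length"]
    missing = [g for g in m.genes if g not in lengths.index]
    if missing:
        raise ValidationError(f"genes missing from gene table: {missing[:10]}")
    L = lengths.reindex(m.genes).to_numpy(dtype=float)
    return pd.DataFrame(
        m.values.to_numpy(dtype=float) / L[:, None],
        index=m.values.index, columns=m.values.columns,
    )


def species_standardize(
    m: pd.DataFrame,
    config: NormalizationConfig = NormalizationConfig(),
) -> NPPMatrix:
    """Standardize each species column; drop (or reject) degenerate columns.

    zscore: (x - column mean) / column sample sd, statistics over all genes
    (zeros included when ``include_zeros``).  rank: fractional ranks in
    (0, 1], average rank for ties.  Columns whose sd is 0 (or whose values
    are all tied) carry no comparative signal and are dropped when
    ``drop_degenerate_species``, else raise.
    """
    if len(m.index) < 2:
        raise ValidationError("need at least 2 genes to standardize")
    x = m.to_numpy(dtype=float)
    if config.log_transform:
        x = np.log2(1.0 + x)

    dropped: list[str] = []
    if config.method == "zscore":
        if config.include_zeros:
            mean = x.mean(axis=0)
            sd = x.std(axis=0, ddof=1)
        else:
            masked = np.ma.masked_equal(x, 0.0)
            mean = masked.mean(axis=0).filled(0.0)
            sd = masked.std(axis=0, ddof=1).filled(0.0)
        degenerate = ~(sd > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (x - mean) / sd
    else:  # rank
        df = pd.DataFrame(x, index=m.index, columns=m.columns)
        ranked = df.rank(axis=0, method="average") / len(df.index)
        out = ranked.to_numpy()
        degenerate = (x.max(axis=0) - x.min(axis=0)) == 0

    if degenerate.any():
        dropped = [c for c, bad in zip(m.columns, degenerate) if bad]
        if not config.drop_degenerate_species:
            raise ValidationError(f"degenerate species columns: {dropped}")
    keep = ~degenerate
    if not keep.any():
        raise ValidationError("no informative species")
    values = pd.DataFrame(out[:, keep], index=m.index, columns=m.columns[keep])
    if not np.isfinite(values.to_numpy()).all():
        raise ValidationError("non-finite values after standardization")
    return NPPMatrix(values=values, config=config, dropped_species=dropped)


def npp(
    m: RawScoreMatrix,
    genes: pd.DataFrame,
    config: NormalizationConfig = NormalizationConfig(),
) -> NPPMatrix:
    """Full NPP transform: length-normalize, then standardize per species."""
    return species_standardize(length_normalize(m, genes), config)
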