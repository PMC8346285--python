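"""Readers and writers for the external tables the pipeline touches.

Every tabular input is tab-separated UTF-8 with a header row; lines starting
with ``#`` are comments.  BLAST results are consumed in the standard 12-column
tabular layout (``qseqid sseqid pident length mismatch gapopen qstart qend
sstart send evalue bitscore``), one file per target species by default, with
the species identifier taken from the filename stem unless a column mapping
says otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

#: Column order of BLAST tabular output ("outfmt 6").
BLAST_OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

#: Interaction-type tokens treated as "known directionality" by default.
#: The whitelist is configuration-exposed; this default covers the common
#: directional annotations in DGIdb / Open Targets exports.
DEFAULT_DIRECTIONAL_TYPES = frozenset(
    {"inhibitor", "activator", "agonist", "antagonist", "blocker", "modulator"}
)


@dataclass(frozen=True)
class BlastHit:
    """One row of BLAST tabular output, reduced to the fields the pipeline uses."""

    query_gene: str
    subject: str
    bitscore: float
    evalue: float
    species_id: str

    def __post_init__(self):
        if not self.query_gene:
            raise ValidationError("BlastHit.query_gene must be non-empty")
        if not self.species_id:
            raise ValidationError("BlastHit.species_id must be non-empty")
        if self.bitscore < 0:
            raise ValidationError(f"negative bitscore {self.bitscore}")
        if self.evalue < 0:
            raise ValidationError(f"negative evalue {self.evalue}")


@dataclass(frozen=True)
class BlastDialect:
    """Which 0-based columns hold each field of a BLAST tabular file.

    ``species_col`` is ``None`` when the species identifier is not a column
    (the per-file convention); it is then supplied per file or derived from
    the filename stem.
    """

    query_col: int = 0
    subject_col: int = 1
    evalue_col: int = 10
    bitscore_col: int = 11
    species_col: int | None = None


def read_blast_tab(
    path: str | Path,
    dialect: BlastDialect = BlastDialect(),
    species_id: str | None = None,
) -> list[BlastHit]:
    """Parse one BLAST tabular file into :class:`BlastHit` records.

    Comment lines (leading ``#``) and blank lines are skipped; row order is
    preserved.  An empty file yields an empty list.  Unparsable bitscore or
    evalue fields raise :class:`FormatError` naming the line number.
    """
    path = Path(path)
    if species_id is None and dialect.species_col is None:
        species_id = path.stem
    hits: list[BlastHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            try:
                query = fields[dialect.query_col]
                subject = fields[dialect.subject_col]
                raw_evalue = fields[dialect.evalue_col]
                raw_bitscore = fields[dialect.bitscore_col]
                sp = (
                    fields[dialect.species_col]
                    if dialect.species_col is not None
                    else species_id
                )
            except IndexError:
                raise FormatError(
                    f"{path.name}:{lineno}: expected at least "
                    f"{max(dialect.bitscore_col, dialect.evalue_col) + 1} columns, "
                    f"got {len(fields)}"
                ) from None
            try:
                bitscore = float(raw_bitscore)
                evalue = float(raw_evalue)
            except ValueError:
                raise FormatError(
                    f"{path.name}:{lineno}: unparsable bitscore/evalue "
                    f"({raw_bitscore!r}, {raw_evalue!r})"
                ) from None
            hits.append(BlastHit(query, subject, bitscore, evalue, sp))
    return hits


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    return df


def read_species_table(path: str | Path) -> pd.DataFrame:
    """Read the species metadata table.

    Columns: ``species_id`` (unique), ``clade``, ``phylo_distance`` (>= 0,
    evolutionary distance from the reference species in arbitrary units).
    """
    df = _read_tsv(path, ("species_id", "clade", "phylo_distance"))
    df = df[["species_id", "clade", "phylo_distance"]].copy()
    df["phylo_distance"] = pd.to_numeric(df["phylo_distance"], errors="raise")
    dups = df["species_id"][df["species_id"].duplicated()].unique()
    if len(dups):
        raise ValidationError(f"duplicate species_id: {sorted(dups)}")
    if df["species_id"].isna().any() or (df["species_id"] == "").any():
        raise ValidationError("empty species_id")
    if df["clade"].isna().any() or (df["clade"] == "").any():
        raise ValidationError("every species needs a clade label")
    if (df["phylo_distance"] < 0).any():
        bad = df.loc[df["phylo_distance"] < 0, "species_id"].tolist()
        raise ValidationError(f"negative phylo_distance for {bad}")
    return df.reset_index(drop=True)


def collapse_gene_table(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse duplicate gene rows, keeping the longest protein per gene.

    Ties on protein length are broken by the lexicographically smallest
    symbol.  Returns the collapsed table and the number of rows removed.
    The operation is idempotent.
    """
    n_before = len(df)
    # sort so the row to keep is first within each gene_id group
    ordered = df.sort_values(
        ["gene_id", "protein_length", "symbol"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    collapsed = ordered.drop_duplicates("gene_id", keep="first")
    collapsed = collapsed.sort_index().reset_index(drop=True)
    return collapsed, n_before - len(collapsed)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read the gene annotation table.

    Columns: ``gene_id``, ``symbol``, ``protein_length`` (amino acids, >= 1),
    ``chromosome``, ``band`` (karyotype band, may be missing).  Duplicate
    gene_id rows are collapsed to the longest protein (the longest-isoform
    rule); a warning reports how many rows were dropped.
    """
    df = _read_tsv(path, ("gene_id", "symbol", "protein_length", "chromosome", "band"))
    df = df[["gene_id", "symbol", "protein_length", "chromosome", "band"]].copy()
    df["protein_length"] = pd.to_numeric(df["protein_length"], errors="raise").astype(int)
    if (df["protein_length"] < 1).any():
        bad = df.loc[df["protein_length"] < 1, "gene_id"].tolist()
        raise ValidationError(f"protein_length < 1 for {bad}")
    df, n_dropped = collapse_gene_table(df)
    if n_dropped:
        warnings.warn(f"collapsed {n_dropped} duplicate gene row(s) to longest isoform")
    return df


def read_drug_table(
    path: str | Path,
    vocabulary: Iterable[str] = DEFAULT_DIRECTIONAL_TYPES,
) -> tuple[pd.DataFrame, int]:
    """Read the drug–gene interaction table, keeping only vocabulary types.

    Columns: ``gene_id``, ``drug``, ``interaction_type``, ``source``.
    Duplicates are allowed (the same interaction may come from several
    sources).  Rows whose interaction_type is outside ``vocabulary`` are
    dropped; the dropped count is returned alongside the table.
    """
    vocabulary = set(vocabulary)
    if not vocabulary:
        raise ValidationError("interaction-type vocabulary must be non-empty")
    df = _read_tsv(path, ("gene_id", "drug", "interaction_type", "source"))
    df = df[["gene_id", "drug", "interaction_type", "source"]].copy()
    keep = df["interaction_type"].isin(vocabulary)
    dropped = int((~keep).sum())
    return df[keep].reset_index(drop=True), dropped


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    sort_by: Sequence[str] | None = None,
) -> None:
    """Write a table as deterministic TSV.

    Header row first, then records (sorted by ``sort_by`` when given), floats
    rendered with 6 significant digits so repeated writes are byte-identical.
    """
    out = df.copy()
    if sort_by:
        out = out.sort_values(list(sort_by), kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
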