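"""Rank genes by Pearson correlation of NPP vectors with a query gene.

Profiles may be compared over the full species panel ("all") or restricted
to one clade (e.g. Mammalia); the two scales capture co-evolution over
billions versus hundreds of millions of years.  The top-k most correlated
genes form a candidate set (the analogue of the study's E200/M200 sets), and
pairs above a strict correlation threshold form co-evolution network edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .normalize import NPPMatrix


@dataclass
class CoevRanking:
    """All genes ranked by correlation with one query over one species subset.

    ``records`` columns: gene_id, r, rank (1-based, no gaps), flagged.
    Sorted by r descending with ties broken by gene_id ascending; genes whose
    filtered profile has zero variance get a -inf sentinel, are placed last
    and flagged.  The query itself is excluded.
    """

    query: str
    clade: str
    records: pd.DataFrame
    n_species_used: int


@dataclass(frozen=True)
class CandidateSet:
    """Top-k genes of a ranking, in rank order."""

    genes: tuple[str, ...]
    k: int
    r_min_observed: float
    label: str


@dataclass(frozen=True)
class CoevEdge:
    """Unordered co-evolution edge; gene_a < gene_b lexicographically."""

    gene_a: str
    gene_b: str
    r: float


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3).

    Raises on zero variance; callers decide the policy for degenerate
    profiles.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson needs two equal-length 1-d vectors")
    if len(x) < 3:
        raise ValidationError("pearson needs length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise ValidationError("undefined correlation: zero variance")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def _filter_species(
    npp: NPPMatrix,
    species: pd.DataFrame | None,
    clade: str,
) -> list[str]:
    if clade == "all":
        return list(npp.values.columns)
    if species is None:
        raise ValidationError("clade filtering requires a species table")
    members = set(species.loc[species["clade"] == clade, "species_id"])
    cols = [c for c in npp.values.columns if c in members]
    if not cols:
        raise ValidationError(f"no species of clade {clade!r} in the matrix")
    return cols


def rank_by_coevolution(
    npp: NPPMatrix,
    query: str,
    species: pd.DataFrame | None = None,
    clade: str = "all",
) -> CoevRanking:
    """Correlate every other gene's profile with the query's over one clade.

    Genes with zero variance on the filtered species cannot be correlated;
    they are flagged and ranked last (r = -inf sentinel) rather than dropped,
    so downstream set sizes stay predictable.
    """
    cols = _filter_species(npp, species, clade)
    if len(cols) < 3:
        raise ValidationError(f"need >= 3 species after clade filter, got {len(cols)}")
    if query not in npp.values.index:
        raise ValidationError(f"query gene {query!r} not in matrix")

    X = npp.values[cols].to_numpy(dtype=float)
    genes = np.asarray(npp.values.index)
    q = X[npp.values.index.get_loc(query)]
    qc = q - q.mean()
    qnorm = np.sqrt((qc ** 2).sum())
    if qnorm == 0:
        raise ValidationError("query profile has zero variance on the filtered species")

    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc ** 2).sum(axis=1))
    flagged = norms == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ qc) / (norms * qnorm)
    r = np.clip(r, -1.0, 1.0)
    r[flagged] = -np.inf

    df = pd.DataFrame({"gene_id": genes, "r": r, "flagged": flagged})
    df = df[df["gene_id"] != query]
    df = df.sort_values(["r", "gene_id"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df = df[["gene_id", "r", "rank", "flagged"]]
    return CoevRanking(query=query, clade=clade, records=df,
                       n_species_used=len(cols))


def top_k(ranking: CoevRanking, k: int, label: str | None = None) -> CandidateSet:
    """The first k (non-flagged) genes of a ranking."""
    eligible = ranking.records[~ranking.records["flagged"]]
    if len(eligible) < k:
        raise ValidationError(
            f"cannot take top {k}: only {len(eligible)} eligible genes "
            f"(shortfall {k - len(eligible)})"
        )
    head = eligible.iloc[:k]
    return CandidateSet(
        genes=tuple(head["gene_id"]),
        k=k,
        r_min_observed=float(head["r"].iloc[-1]),
        label=label or f"{ranking.clade}-top{k}",
    )


def build_edges(
    genes: set[str] | list[str],
    npp: NPPMatrix,
    species: pd.DataFrame | None = None,
    clade: str = "all",
    r_min: float = 0.7,
) -> list[CoevEdge]:
    """All unordered gene pairs with Pearson r strictly above ``r_min``.

    Pairs involving a zero-variance profile are skipped (their correlation is
    undefined).  Output sorted by (gene_a, gene_b).
    """
    gene_list = sorted(set(genes))
    missing = [g for g in gene_list if g not in npp.values.index]
    if missing:
        raise ValidationError(f"genes not in matrix: {missing[:10]}")
    cols = _filter_species(npp, species, clade)
    X = npp.values.loc[gene_list, cols].to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc ** 2).sum(axis=1))
    ok = norms > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (Xc @ Xc.T) / np.outer(norms, norms)
    C = np.clip(C, -1.0, 1.0)
    edges = []
    n = len(gene_list)
    for i in range(n):
        if not ok[i]:
            continue
        for j in range(i + 1, n):
            if ok[j] and C[i, j] > r_min:
                edges.append(CoevEdge(gene_list[i], gene_list[j], float(C[i, j])))
    return edges
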