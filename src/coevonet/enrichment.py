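"""Gene-list overlap statistics and karyotype-band clustering enrichment.

Two candidate lists drawn from the same gene universe are compared with the
hypergeometric null (expected overlap k1*k2/N, exact upper-tail p).  Genomic
clustering of a candidate set is tested per karyotype band against a
permutation null that redraws same-size candidate sets uniformly from the
band-annotated universe; empirical p-values use the add-one (phantom
permutation) convention and are adjusted across bands with Benjamini-
Hochberg.  The same resampling machinery yields the "expected by chance"
count of property-positive genes (e.g. druggable genes) in random sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .ranking import CandidateSet


@dataclass(frozen=True)
class OverlapResult:
    k1: int
    k2: int
    N: int
    observed: int
    expected: float
    p_upper: float
    union_size: int


@dataclass(frozen=True)
class BandEnrichmentResult:
    band: str
    observed: int
    perm_mean: float
    perm_sd: float
    p_emp: float
    q: float
    fold: float


@dataclass(frozen=True)
class ChanceExpectation:
    n_candidates: int
    mean: float
    sd: float
    B: int
    seed: int


def _check_sizes(k1: int, k2: int, N: int) -> None:
    if N < 1:
        raise ValidationError("universe size N must be >= 1")
    if not (0 <= k1 <= N and 0 <= k2 <= N):
        raise ValidationError(f"list sizes must be in [0, N]: k1={k1}, k2={k2}, N={N}")


def expected_overlap(k1: int, k2: int, N: int) -> float:
    """Hypergeometric mean overlap of two independent size-k1/k2 lists from N genes."""
    _check_sizes(k1, k2, N)
    return k1 * k2 / N


def overlap_pvalue(k1: int, k2: int, N: int, observed: int) -> float:
    """Exact hypergeometric upper tail P(X >= observed)."""
    _check_sizes(k1, k2, N)
    if not (0 <= observed <= min(k1, k2)):
        raise ValidationError(f"observed={observed} outside [0, min(k1,k2)]")
    if observed == 0:
        return 1.0
    return float(hypergeom.sf(observed - 1, N, k1, k2))


def combine_sets(
    a: CandidateSet,
    b: CandidateSet,
    N: int,
) -> tuple[list[str], list[str], OverlapResult]:
    """Intersection, union, and overlap statistics of two candidate sets."""
    sa, sb = set(a.genes), set(b.genes)
    inter = sorted(sa & sb)
    union = sorted(sa | sb)
    result = OverlapResult(
        k1=len(sa), k2=len(sb), N=N, observed=len(inter),
        expected=expected_overlap(len(sa), len(sb), N),
        p_upper=overlap_pvalue(len(sa), len(sb), N, len(inter)),
        union_size=len(union),
    )
    return inter, union, result


def empirical_p(null_values: np.ndarray, observed: float) -> float:
    """Add-one empirical p: (1 + #{null >= observed}) / (B + 1)."""
    null_values = np.asarray(null_values)
    return float((1 + (null_values >= observed).sum()) / (len(null_values) + 1))


def _random_index_chunks(
    rng: np.random.Generator, N: int, n: int, B: int
) -> Iterator[np.ndarray]:
    """B uniform without-replacement size-n index draws from range(N), chunked.

    Each yielded array is (rows, n).  Chunk size is a fixed function of N so
    runs are reproducible.
    """
    if n == 0:
        yield np.empty((B, 0), dtype=int)
        return
    chunk = max(1, 4_000_000 // max(N, 1))
    done = 0
    while done < B:
        rows = min(chunk, B - done)
        keys = rng.random((rows, N))
        if n == N:
            idx = np.broadcast_to(np.arange(N), (rows, N))
        else:
            idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        yield idx
        done += rows


def candidates_without_band(candidates: Iterable[str], genes: pd.DataFrame) -> list[str]:
    """Candidates excluded from band enrichment for lack of a band annotation."""
    annotated = set(genes.loc[genes["band"].notna(), "gene_id"])
    return sorted(set(candidates) - annotated)


def band_enrichment(
    candidates: Iterable[str],
    genes: pd.DataFrame,
    B: int,
    seed: int,
    include_empty_bands: bool = False,
) -> list[BandEnrichmentResult]:
    """Permutation test of candidate clustering per karyotype band.

    The universe is every gene with a band annotation; candidates without a
    band are excluded (see :func:`candidates_without_band`).  The null
    redraws ``|candidates ∩ universe|`` genes uniformly without replacement
    B times.  Bands with at least one observed candidate are tested (all
    bands when ``include_empty_bands``); q is Benjamini-Hochberg across the
    tested bands.  Deterministic given ``seed``; results sorted by
    (p_emp, band).
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    universe = genes.loc[genes["band"].notna(), ["gene_id", "band"]].reset_index(drop=True)
    if universe.empty:
        raise ValidationError("no genes with band annotations in the universe")
    cand = sorted(set(candidates) & set(universe["gene_id"]))
    if not cand:
        raise ValidationError("no candidate carries a band annotation")
    n = len(cand)
    N = len(universe)

    codes, bands = pd.factorize(universe["band"], sort=True)
    n_bands = len(bands)
    in_cand = universe["gene_id"].isin(cand).to_numpy()
    observed = np.bincount(codes[in_cand], minlength=n_bands)

    rng = np.random.default_rng(seed)
    ge = np.zeros(n_bands, dtype=np.int64)
    s1 = np.zeros(n_bands)
    s2 = np.zeros(n_bands)
    for idx in _random_index_chunks(rng, N, n, B):
        rows = idx.shape[0]
        sampled = codes[idx]  # (rows, n)
        flat = sampled + np.arange(rows)[:, None] * n_bands
        counts = np.bincount(flat.ravel(), minlength=rows * n_bands)
        counts = counts.reshape(rows, n_bands)
        ge += (counts >= observed[None, :]).sum(axis=0)
        s1 += counts.sum(axis=0)
        s2 += (counts.astype(np.int64) ** 2).sum(axis=0)

    perm_mean = s1 / B
    perm_var = (s2 - B * perm_mean ** 2) / (B - 1) if B > 1 else np.zeros(n_bands)
    perm_sd = np.sqrt(np.maximum(perm_var, 0.0))
    p_emp = (1 + ge) / (B + 1)

    tested = np.arange(n_bands) if include_empty_bands else np.flatnonzero(observed > 0)
    _, q, _, _ = multipletests(p_emp[tested], method="fdr_bh")

    results = []
    for pos, b_idx in enumerate(tested):
        mean_b = perm_mean[b_idx]
        obs_b = int(observed[b_idx])
        if mean_b > 0:
            fold = obs_b / mean_b
        else:
            fold = float("inf") if obs_b > 0 else float("nan")
        results.append(BandEnrichmentResult(
            band=str(bands[b_idx]), observed=obs_b,
            perm_mean=float(mean_b), perm_sd=float(perm_sd[b_idx]),
            p_emp=float(p_emp[b_idx]), q=float(q[pos]), fold=float(fold),
        ))
    return sorted(results, key=lambda r: (r.p_emp, r.band))


def band_results_frame(results: Sequence[BandEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"band": r.band, "observed": r.observed, "perm_mean": r.perm_mean,
          "perm_sd": r.perm_sd, "fold": r.fold, "p_emp": r.p_emp, "q": r.q}
         for r in results]
    )


def chance_expectation(
    n_candidates: int,
    positive_set: Iterable[str],
    genes: pd.DataFrame,
    B: int,
    seed: int,
) -> ChanceExpectation:
    """Mean +/- sd of |random same-size set ∩ positive_set| over B draws.

    The universe is the full gene table.  This is the null for questions of
    the form "how many druggable genes would a random candidate list of this
    size contain".
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    universe = list(genes["gene_id"])
    N = len(universe)
    if N == 0:
        raise ValidationError("empty gene universe")
    positives = set(positive_set)
    stray = positives - set(universe)
    if stray:
        raise ValidationError(f"positives outside the universe: {sorted(stray)[:10]}")
    if n_candidates > N:
        raise ValidationError(f"n_candidates {n_candidates} exceeds universe size {N}")
    if n_candidates == 0:
        return ChanceExpectation(0, 0.0, 0.0, B, seed)

    indicator = np.array([g in positives for g in universe], dtype=np.int64)
    rng = np.random.default_rng(seed)
    counts = np.empty(B, dtype=np.int64)
    done = 0
    for idx in _random_index_chunks(rng, N, n_candidates, B):
        rows = idx.shape[0]
        counts[done:done + rows] = indicator[idx].sum(axis=1)
        done += rows
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if B > 1 else 0.0
    return ChanceExpectation(n_candidates, mean, sd, B, seed)
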