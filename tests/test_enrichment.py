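"""Overlap statistics, band-clustering permutation test, chance expectation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import coevonet as cn
from coevonet.errors import ValidationError


def gene_universe(n, bands):
    """n genes spread cyclically over the given band labels."""
    return pd.DataFrame({
        "gene_id": [f"G{i:04d}" for i in range(n)],
        "symbol": [f"G{i:04d}" for i in range(n)],
        "protein_length": [100] * n,
        "chromosome": ["1"] * n,
        "band": [bands[i % len(bands)] for i in range(n)],
    })


class TestExpectedOverlap:
    @pytest.mark.parametrize("k1,k2,N,expected", [
        (0, 200, 20192, 0.0),
        (10, 10, 10, 10.0),   # k = N forces complete overlap
        (3, 4, 12, 1.0),
    ])
    def test_closed_form(self, k1, k2, N, expected):
        assert cn.expected_overlap(k1, k2, N) == pytest.approx(expected)

    def test_oversized_list_rejected(self):
        with pytest.raises(ValidationError):
            cn.expected_overlap(11, 5, 10)


class TestOverlapPvalue:
    def test_exact_enumeration_example(self):
        assert cn.overlap_pvalue(3, 3, 10, 2) == pytest.approx(22 / 120)

    def test_zero_observed_is_one(self):
        assert cn.overlap_pvalue(5, 5, 100, 0) == 1.0

    def test_forced_overlap_is_one(self):
        assert cn.overlap_pvalue(10, 4, 10, 4) == pytest.approx(1.0)

    def test_matches_brute_force_enumeration_small_universe(self):
        """Exhaustive check against direct subset enumeration (N <= 7 here;
        the full N <= 12 sweep is in the acceptance suite)."""
        for N in range(1, 8):
            universe = list(range(N))
            for k1 in range(N + 1):
                for k2 in range(N + 1):
                    set2 = set(universe[:k2])
                    inters = [len(set(c) & set2)
                              for c in itertools.combinations(universe, k1)]
                    total = len(inters)
                    for obs in range(min(k1, k2) + 1):
                        expected = sum(i >= obs for i in inters) / total
                        assert cn.overlap_pvalue(k1, k2, N, obs) == \
                            pytest.approx(expected, abs=1e-12)


class TestCombineSets:
    def make(self, ids, label):
        return cn.CandidateSet(genes=tuple(ids), k=len(ids),
                               r_min_observed=0.5, label=label)

    def test_disjoint_sets(self):
        _, union, res = cn.combine_sets(self.make(["a", "b", "c"], "A"),
                                        self.make(["d", "e", "f", "g"], "B"),
                                        N=100)
        assert res.observed == 0 and res.union_size == 7
        assert res.p_upper == 1.0
        assert union == sorted(union)

    def test_identical_sets(self):
        s = self.make(["a", "b"], "A")
        inter, union, res = cn.combine_sets(s, s, N=50)
        assert res.observed == 2 and res.union_size == 2
        assert inter == union == ["a", "b"]

    def test_expected_matches_monte_carlo_mean(self):
        """k1*k2/N equals the simulated mean overlap of random sets."""
        rng = np.random.default_rng(42)
        N, k1, k2, B = 60, 12, 20, 20000
        overlaps = np.empty(B)
        for i in range(B):
            a = set(rng.choice(N, k1, replace=False))
            b = set(rng.choice(N, k2, replace=False))
            overlaps[i] = len(a & b)
        se = overlaps.std(ddof=1) / math.sqrt(B)
        assert abs(overlaps.mean() - cn.expected_overlap(k1, k2, N)) < 3 * se


class TestBandEnrichment:
    def test_extreme_clustering_hits_empirical_floor(self):
        """5 candidates all in one 10-gene band of a 100-gene universe: no
        seed-1 permutation reaches 5, so p_emp is the add-one floor 1/1000."""
        genes = gene_universe(100, [f"b{i}" for i in range(1, 11)])
        genes.loc[:9, "band"] = "b1"
        genes.loc[10:, "band"] = [f"b{2 + i % 9}" for i in range(90)]
        cands = list(genes["gene_id"][:5])
        res = cn.band_enrichment(cands, genes, B=999, seed=1)
        top = res[0]
        assert top.band == "b1" and top.observed == 5
        assert top.p_emp == pytest.approx(1 / 1000)

    def test_p_never_below_floor_and_monotone_in_observed(self):
        null = np.array([0, 1, 1, 2, 3, 5, 2, 1, 0, 4])
        ps = [cn.empirical_p(null, obs) for obs in range(7)]
        assert min(ps) >= 1 / (len(null) + 1)
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_deterministic_under_seed(self):
        genes = gene_universe(80, ["b1", "b2", "b3", "b4"])
        cands = list(genes["gene_id"][::7])
        a = cn.band_enrichment(cands, genes, B=10, seed=5)
        b = cn.band_enrichment(cands, genes, B=10, seed=5)
        assert a == b

    def test_candidates_without_band_are_excluded(self):
        genes = gene_universe(20, ["b1", "b2"])
        genes.loc[0, "band"] = pd.NA
        excluded = cn.candidates_without_band(["G0000", "G0001"], genes)
        assert excluded == ["G0000"]
        res = cn.band_enrichment(["G0000", "G0001"], genes, B=10, seed=1)
        assert sum(r.observed for r in res) == 1

    def test_validation(self):
        genes = gene_universe(10, ["b1"])
        with pytest.raises(ValidationError, match="B must be"):
            cn.band_enrichment(["G0000"], genes, B=0, seed=1)
        genes_none = genes.assign(band=pd.NA)
        with pytest.raises(ValidationError, match="band annotations"):
            cn.band_enrichment(["G0000"], genes_none, B=10, seed=1)


class TestBenjaminiHochberg:
    def test_band_q_matches_hand_computed_bh(self):
        """q-values on a 5-band table agree with the hand-applied step-up
        rule q_i = min_{j>=i} p_(j) * m / j."""
        genes = gene_universe(200, [f"b{i}" for i in range(1, 6)])
        cands = list(genes["gene_id"][:25])
        res = cn.band_enrichment(cands, genes, B=200, seed=9)
        ps = np.array([r.p_emp for r in res])
        order = np.argsort(ps)
        m = len(ps)
        q_hand = np.empty(m)
        running = np.inf
        for pos in range(m - 1, -1, -1):
            running = min(running, ps[order[pos]] * m / (pos + 1))
            q_hand[order[pos]] = running
        assert np.allclose([r.q for r in res], q_hand)


class TestChanceExpectation:
    def test_mean_tracks_hypergeometric(self):
        genes = gene_universe(500, ["b1"])
        positives = list(genes["gene_id"][:50])
        res = cn.chance_expectation(40, positives, genes, B=4000, seed=2)
        exact_mean = 40 * 50 / 500
        se = res.sd / math.sqrt(res.B)
        assert abs(res.mean - exact_mean) < 3 * se

    def test_positives_equal_universe(self):
        genes = gene_universe(30, ["b1"])
        res = cn.chance_expectation(7, list(genes["gene_id"]), genes,
                                    B=50, seed=1)
        assert res.mean == 7.0 and res.sd == 0.0

    def test_zero_candidates(self):
        genes = gene_universe(10, ["b1"])
        res = cn.chance_expectation(0, [], genes, B=10, seed=1)
        assert res.mean == 0.0 and res.sd == 0.0

    def test_stray_positives_rejected(self):
        genes = gene_universe(10, ["b1"])
        with pytest.raises(ValidationError, match="outside the universe"):
            cn.chance_expectation(2, ["nope"], genes, B=10, seed=1)
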