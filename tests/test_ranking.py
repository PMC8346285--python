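"""Pearson ranking, top-k selection, and co-evolution edges."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coevonet as cn
from coevonet.errors import ValidationError
from coevonet.normalize import NormalizationConfig, NPPMatrix


def npp_from(values, genes, species=None):
    values = np.asarray(values, dtype=float)
    species = species or [f"sp{j}" for j in range(values.shape[1])]
    return NPPMatrix(values=pd.DataFrame(values, index=genes, columns=species),
                     config=NormalizationConfig())


class TestPearson:
    def test_self_correlation_is_one(self):
        assert cn.pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert cn.pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=12),
           st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_formula(self, x, data):
        """Agreement with a direct covariance/variance evaluation."""
        y = data.draw(st.lists(st.floats(-50, 50), min_size=len(x),
                               max_size=len(x)))
        x, y = np.array(x), np.array(y)
        n = len(x)
        sxy = sum((x[i] - x.mean()) * (y[i] - y.mean()) for i in range(n))
        sxx = sum((xi - x.mean()) ** 2 for xi in x)
        syy = sum((yi - y.mean()) ** 2 for yi in y)
        if sxx == 0 or syy == 0:
            with pytest.raises(ValidationError):
                cn.pearson(x, y)
        else:
            expected = np.clip(sxy / np.sqrt(sxx * syy), -1, 1)
            assert cn.pearson(x, y) == pytest.approx(expected, abs=1e-9)

    def test_zero_variance_raises(self):
        with pytest.raises(ValidationError, match="zero variance"):
            cn.pearson([1, 1, 1], [1, 2, 3])


class TestRankByCoevolution:
    def test_planted_partners_fill_top_ranks(self):
        params = cn.SimulationParams(
            n_genes=80, clade_plan={"Mammalia": (10, 0.05, 0.45),
                                    "Fungi": (10, 1.4, 2.0)},
            module_sizes=(6,), sigma=0.01, seed=13)
        raw, genes, truth = cn.simulate_scores(params)
        nppm = cn.npp(cn.apply_threshold(raw, 20.4), genes)
        members = truth.module_members(0)
        ranking = cn.rank_by_coevolution(nppm, members[0])
        top = set(ranking.records.head(len(members) - 1)["gene_id"])
        assert top == set(members) - {members[0]}

    def test_clade_filter_uses_exactly_clade_columns(self, small_sim, small_npp):
        _, _, truth, panel = small_sim
        q = truth.module_members(0)[0]
        ranking = cn.rank_by_coevolution(small_npp, q, species=panel,
                                         clade="Mammalia")
        n_mam = (panel["clade"] == "Mammalia").sum()
        assert ranking.n_species_used == n_mam

    def test_clade_ranking_matches_manual_slice(self, small_sim, small_npp):
        _, _, truth, panel = small_sim
        q = truth.module_members(0)[0]
        clade_r = cn.rank_by_coevolution(small_npp, q, species=panel,
                                         clade="Mammalia")
        mam = set(panel.loc[panel["clade"] == "Mammalia", "species_id"])
        sliced = NPPMatrix(
            values=small_npp.values[[c for c in small_npp.values.columns
                                     if c in mam]],
            config=small_npp.config)
        manual = cn.rank_by_coevolution(sliced, q)
        pd.testing.assert_frame_equal(clade_r.records, manual.records)

    def test_constant_gene_flagged_and_last(self):
        m = npp_from([[1, 2, 3, 4], [1, 2, 3, 5], [2, 2, 2, 2]],
                     genes=["Q", "G1", "Gflat"])
        ranking = cn.rank_by_coevolution(m, "Q")
        last = ranking.records.iloc[-1]
        assert last["gene_id"] == "Gflat" and last["flagged"]
        assert last["r"] == -np.inf

    def test_identical_profile_ranks_first_with_r_one(self):
        m = npp_from([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]],
                     genes=["Q", "Twin", "Anti"])
        ranking = cn.rank_by_coevolution(m, "Q")
        assert ranking.records.iloc[0]["gene_id"] == "Twin"
        assert ranking.records.iloc[0]["r"] == pytest.approx(1.0)

    def test_query_missing_or_too_few_species(self, small_npp):
        with pytest.raises(ValidationError, match="not in matrix"):
            cn.rank_by_coevolution(small_npp, "nope")
        m = npp_from([[1, 2], [2, 1]], genes=["Q", "G"])
        with pytest.raises(ValidationError, match=">= 3 species"):
            cn.rank_by_coevolution(m, "Q")

    def test_ranks_are_gapless_and_deterministic(self, small_npp, small_sim):
        _, _, truth, _ = small_sim
        q = truth.module_members(0)[0]
        a = cn.rank_by_coevolution(small_npp, q).records
        b = cn.rank_by_coevolution(small_npp, q).records
        pd.testing.assert_frame_equal(a, b)
        assert list(a["rank"]) == list(range(1, len(a) + 1))
        assert q not in set(a["gene_id"])


class TestTopK:
    def ranking_with(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "r"])
        df["flagged"] = False
        df["rank"] = range(1, len(df) + 1)
        return cn.CoevRanking(query="Q", clade="all",
                              records=df[["gene_id", "r", "rank", "flagged"]],
                              n_species_used=10)

    def test_boundary_tie_broken_lexicographically(self):
        ranking = self.ranking_with(
            [("Gtop", 0.9), ("GA", 0.8), ("GB", 0.8), ("GC", 0.7)])
        cand = cn.top_k(ranking, 3)
        assert cand.genes == ("Gtop", "GA", "GB")
        assert cand.r_min_observed == pytest.approx(0.8)

    def test_k_equal_to_eligible_returns_whole_list(self):
        ranking = self.ranking_with([("GA", 0.5), ("GB", 0.4)])
        assert cn.top_k(ranking, 2).genes == ("GA", "GB")

    def test_shortfall_reported(self):
        ranking = self.ranking_with([(f"G{i}", 0.5) for i in range(100)])
        with pytest.raises(ValidationError, match="shortfall 100"):
            cn.top_k(ranking, 200)


class TestBuildEdges:
    def geometric_profiles(self):
        """Three profiles with pairwise r of exactly 0.9, 0.7 and ~0.94."""
        n = 6
        v1 = np.array([1, -1, 1, -1, 1, -1], dtype=float)
        v2 = np.array([1, 1, -1, -1, 1, -1], dtype=float)
        v1 /= np.linalg.norm(v1)
        v2 -= v2 @ v1 * v1
        v2 /= np.linalg.norm(v2)
        x = v1
        y = 0.7 * v1 + np.sqrt(1 - 0.49) * v2
        z = 0.9 * v1 + np.sqrt(1 - 0.81) * v2
        return npp_from([x, y, z], genes=["X", "Y", "Z"])

    def test_threshold_is_strict(self):
        m = self.geometric_profiles()
        assert cn.pearson(m.values.loc["X"], m.values.loc["Y"]) == \
            pytest.approx(0.7, abs=1e-12)
        all_edges = cn.build_edges(["X", "Y", "Z"], m, r_min=-1.0)
        assert len(all_edges) == 3
        r_xy = next(e.r for e in all_edges
                    if (e.gene_a, e.gene_b) == ("X", "Y"))
        # a pair sitting exactly at the threshold is excluded (strict >)
        pairs = {(e.gene_a, e.gene_b)
                 for e in cn.build_edges(["X", "Y", "Z"], m, r_min=r_xy)}
        assert pairs == {("X", "Z"), ("Y", "Z")}
        # nudging the threshold below readmits it
        pairs_eps = {(e.gene_a, e.gene_b)
                     for e in cn.build_edges(["X", "Y", "Z"], m,
                                             r_min=r_xy - 1e-12)}
        assert ("X", "Y") in pairs_eps

    def test_r_min_one_pairs_nothing_noisy(self, small_npp):
        genes = list(small_npp.values.index[:20])
        assert cn.build_edges(genes, small_npp, r_min=1.0) == []

    def test_noise_free_module_is_complete_graph(self):
        params = cn.SimulationParams(
            n_genes=30, clade_plan={"Mammalia": (6, 0.05, 0.45),
                                    "Fungi": (6, 1.4, 2.0)},
            module_sizes=(5,), sigma=0.0, seed=8)
        raw, genes, truth = cn.simulate_scores(params)
        nppm = cn.npp(cn.apply_threshold(raw, 20.4), genes)
        members = truth.module_members(0)
        edges = cn.build_edges(members, nppm, r_min=0.999)
        k = len(members)
        assert len(edges) == k * (k - 1) // 2

    def test_unknown_gene_rejected(self, small_npp):
        with pytest.raises(ValidationError, match="not in matrix"):
            cn.build_edges(["nope"], small_npp)
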