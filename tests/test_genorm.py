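import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heteromir import (CqMatrix, GeNormStability, log_ratio_vector,
                       nf_pairwise_variation, nf_stability,
                       normalization_factor, pairwise_variation, rank_genes,
                       stability_m)
from heteromir.exceptions import InsufficientDataError

from _oracles import (brute_iterative_ranking, brute_m, brute_nf_stability,
                      brute_nf_variation, brute_pairwise_v)


def _rows(cq):
    return {g: list(cq.row(g)) for g in cq.genes}


@st.composite
def cq_matrices(draw, max_genes=6, max_samples=8):
    k = draw(st.integers(3, max_genes))
    s = draw(st.integers(3, max_samples))
    vals = draw(st.lists(
        st.lists(st.floats(15.0, 38.0, allow_nan=False), min_size=s,
                 max_size=s),
        min_size=k, max_size=k))
    return CqMatrix.from_arrays([f"g{i}" for i in range(k)],
                                [f"s{i}" for i in range(s)], vals)


class TestLogRatioVector:
    def test_reduces_to_cycle_difference(self):
        cq = CqMatrix.from_arrays(["j", "k"], ["s1", "s2", "s3"],
                                  [[20.0, 21.0, 22.0], [20.0, 20.0, 20.0]])
        assert list(log_ratio_vector(cq, "j", "k")) == [0.0, -1.0, -2.0]

    def test_identical_profiles_give_zero_vector(self):
        cq = CqMatrix.from_arrays(["j", "k"], ["s1", "s2"],
                                  [[25.0, 26.0], [25.0, 26.0]])
        assert list(log_ratio_vector(cq, "j", "k")) == [0.0, 0.0]

    def test_antisymmetric_under_swap(self, random_cq):
        a = log_ratio_vector(random_cq, "g0", "g1")
        b = log_ratio_vector(random_cq, "g1", "g0")
        assert np.allclose(a, -b)

    def test_same_gene_rejected(self, random_cq):
        with pytest.raises(ValueError, match="distinct"):
            log_ratio_vector(random_cq, "g0", "g0")

    def test_too_few_complete_samples(self):
        cq = CqMatrix.from_arrays(["j", "k"], ["s1", "s2"],
                                  [[20.0, np.nan], [21.0, 22.0]])
        with pytest.raises(InsufficientDataError):
            log_ratio_vector(cq, "j", "k")


class TestPairwiseVariation:
    @pytest.mark.parametrize("vec, expected", [
        ([0.0, -1.0, -2.0], 1.0),
        ([3.5, 3.5, 3.5, 3.5], 0.0),
        ([2.0, 5.0], 3.0 / math.sqrt(2.0)),  # two-point closed form
    ])
    def test_sample_standard_deviation(self, vec, expected):
        assert pairwise_variation(vec) == pytest.approx(expected, abs=1e-12)

    def test_single_element_rejected(self):
        with pytest.raises(InsufficientDataError):
            pairwise_variation([1.0])


class TestStabilityM:
    def test_three_gene_hand_example(self, three_gene_cq):
        # V_AB = 0, V_AC = V_BC = 1 -> M_A = M_B = 0.5, M_C = 1.0
        assert stability_m(three_gene_cq, "A") == pytest.approx(0.5)
        assert stability_m(three_gene_cq, "B") == pytest.approx(0.5)
        assert stability_m(three_gene_cq, "C") == pytest.approx(1.0)

    def test_constant_offset_gene_has_zero_m(self):
        cq = CqMatrix.from_arrays(
            ["a", "b", "c"], ["s1", "s2", "s3"],
            [[20.0, 22.0, 24.0], [21.0, 23.0, 25.0], [19.0, 21.0, 23.0]])
        for g in ("a", "b", "c"):
            assert stability_m(cq, g) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_double_loop(self, random_cq):
        rows = _rows(random_cq)
        for g in random_cq.genes:
            assert stability_m(random_cq, g) == pytest.approx(
                brute_m(rows, g, random_cq.genes), abs=1e-12)


class TestRanking:
    def test_three_gene_exclusion_order(self, three_gene_cq):
        rep = rank_genes(three_gene_cq, mode="iterative")
        assert rep.ranking == ["A", "B", "C"]
        assert rep.m_values["C"] == pytest.approx(1.0)
        # terminal pair shares its mutual M and the final exclusion step
        assert rep.m_values["A"] == rep.m_values["B"] == pytest.approx(0.0)
        assert rep.exclusion_step["A"] == rep.exclusion_step["B"]

    def test_all_identical_profiles_rank_lexicographically(self):
        cq = CqMatrix.from_arrays(
            ["b", "a", "c"], ["s1", "s2", "s3"],
            [[20.0, 21.0, 22.0], [23.0, 24.0, 25.0], [18.0, 19.0, 20.0]])
        rep = rank_genes(cq, mode="iterative")
        assert rep.ranking == ["a", "b", "c"]
        assert all(m == pytest.approx(0.0, abs=1e-12)
                   for m in rep.m_values.values())

    def test_single_pass_agrees_on_least_stable(self, three_gene_cq):
        it = rank_genes(three_gene_cq, mode="iterative")
        sp = rank_genes(three_gene_cq, mode="single_pass")
        assert it.ranking[-1] == sp.ranking[-1] == "C"

    def test_fewer_than_three_candidates_rejected(self, three_gene_cq):
        with pytest.raises(ValueError, match="at least 3"):
            rank_genes(three_gene_cq, candidates=["A", "B"])

    @pytest.mark.parametrize("seed", range(6))
    def test_iterative_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        k, s = rng.integers(3, 9), rng.integers(3, 13)
        cq = CqMatrix.from_arrays(
            [f"g{i}" for i in range(k)], [f"s{i}" for i in range(s)],
            rng.uniform(16.0, 36.0, (k, s)))
        rep = rank_genes(cq, mode="iterative")
        ranking, m_vals = brute_iterative_ranking(_rows(cq), cq.genes)
        assert rep.ranking == ranking
        for g in cq.genes:
            assert rep.m_values[g] == pytest.approx(m_vals[g], abs=1e-12)


class TestNormalizationFactor:
    def test_geometric_mean_examples(self):
        cq = CqMatrix.from_arrays(["a", "b", "c"], ["s1"],
                                  [[4.0], [9.0], [16.0]])
        assert normalization_factor(cq, ["a", "b"])["s1"] == pytest.approx(6.0)
        cq2 = CqMatrix.from_arrays(["a", "b", "c"], ["s1"],
                                   [[2.0], [4.0], [8.0]])
        assert normalization_factor(cq2, ["a", "b", "c"])["s1"] == \
            pytest.approx(4.0)

    def test_idempotent_on_equal_cycles(self):
        cq = CqMatrix.from_arrays(["a", "b"], ["s1", "s2"],
                                  [[25.0, 27.0], [25.0, 27.0]])
        nf = normalization_factor(cq, ["a", "b"])
        assert list(nf) == pytest.approx([25.0, 27.0])

    def test_missing_gene_value_gives_missing_nf(self):
        cq = CqMatrix.from_arrays(["a", "b"], ["s1", "s2"],
                                  [[25.0, np.nan], [26.0, 27.0]])
        nf = normalization_factor(cq, ["a", "b"])
        assert np.isnan(nf["s2"]) and not np.isnan(nf["s1"])

    def test_unknown_gene_rejected(self, random_cq):
        with pytest.raises(ValueError, match="unknown"):
            normalization_factor(random_cq, ["nope"])


class TestNfVariation:
    def test_proportional_nfs_give_zero(self):
        # second gene = first gene scaled: NF1/NF2 constant across samples
        cq = CqMatrix.from_arrays(["a", "b", "c"], ["s1", "s2", "s3"],
                                  [[20.0, 24.0, 28.0],
                                   [10.0, 12.0, 14.0],
                                   [30.0, 30.0, 30.0]])
        v = nf_pairwise_variation(cq, ["a", "b", "c"], 1)
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_recomputation(self, random_cq):
        ranking = rank_genes(random_cq).ranking
        rows = _rows(random_cq)
        for n in range(1, len(ranking)):
            assert nf_pairwise_variation(random_cq, ranking, n) == \
                pytest.approx(brute_nf_variation(rows, ranking, n, 9),
                              abs=1e-12)

    def test_cq_scale_nf_not_translation_invariant(self, random_cq):
        """Unlike M, the cq-scale V(n/n+1) changes when one member gene's
        cycles are shifted by a constant; the shifted value must equal a
        direct recomputation from the definition."""
        ranking = rank_genes(random_cq).ranking
        shifted = random_cq.values.copy()
        shifted.loc[ranking[0]] += 3.0
        cq2 = CqMatrix(shifted)
        v1 = nf_pairwise_variation(random_cq, ranking, 2)
        v2 = nf_pairwise_variation(cq2, ranking, 2)
        assert v1 != pytest.approx(v2, abs=1e-9)
        assert v2 == pytest.approx(
            brute_nf_variation(_rows(cq2), ranking, 2, 9), abs=1e-12)

    def test_n_out_of_range(self, random_cq):
        with pytest.raises(ValueError, match="out of range"):
            nf_pairwise_variation(random_cq, random_cq.genes, 6)


class TestNfStability:
    def test_full_panel_has_no_remaining_candidates(self, random_cq):
        ranking = rank_genes(random_cq).ranking
        assert math.isnan(nf_stability(random_cq, ranking, len(ranking)))

    def test_single_remaining_candidate_equals_pairwise_term(self, random_cq):
        ranking = rank_genes(random_cq).ranking
        n = len(ranking) - 1
        got = nf_stability(random_cq, ranking, n)
        rows = _rows(random_cq)
        expected = brute_nf_stability(rows, ranking, n, random_cq.genes, 9)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_oracle(self, random_cq):
        ranking = rank_genes(random_cq).ranking
        rows = _rows(random_cq)
        for n in range(1, len(ranking)):
            assert nf_stability(random_cq, ranking, n) == pytest.approx(
                brute_nf_stability(rows, ranking, n, random_cq.genes, 9),
                abs=1e-12)


class TestStabilityProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(cq_matrices())
    def test_v_symmetric_and_m_nonnegative(self, cq):
        from heteromir.genorm import pairwise_variation_matrix
        V = pairwise_variation_matrix(cq).to_numpy()
        off = ~np.eye(len(cq.genes), dtype=bool)
        assert np.allclose(V, V.T, equal_nan=True)
        assert np.all(V[off] >= 0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(cq_matrices(), st.floats(-5.0, 5.0, allow_nan=False))
    def test_m_translation_invariant(self, cq, delta):
        """Adding a constant to one gene's cycles cancels in every log
        ratio's s.d., so all M values are unchanged."""
        shifted = cq.values.copy()
        shifted.iloc[0] = np.clip(shifted.iloc[0] + delta, 1.0, None)
        if not np.allclose(shifted.iloc[0], cq.values.iloc[0] + delta):
            return  # clipped: translation no longer exact
        cq2 = CqMatrix(shifted)
        for g in cq.genes:
            assert stability_m(cq2, g) == pytest.approx(
                stability_m(cq, g), abs=1e-9)


class TestModelObject:
    def test_fit_produces_full_report(self, random_cq):
        rep = GeNormStability(random_cq).fit()
        K = len(random_cq.genes)
        assert sorted(rep.ranking) == sorted(random_cq.genes)
        assert set(rep.nf_variation) == set(range(1, K))
        assert set(rep.nf_stability) == set(range(1, K + 1))
        frame = rep.to_frame()
        assert list(frame.index) == rep.ranking
        assert "reconstructed" in rep.summary()

    def test_expression_scale_nf_mode(self, random_cq):
        rep = GeNormStability(random_cq, nf_scale="expression").fit()
        assert rep.nf_scale == "expression"
        assert all(v >= 0 for v in rep.nf_variation.values())
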