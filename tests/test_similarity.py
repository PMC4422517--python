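import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenosim.cohort import CasePhenotype
from phenosim.ontology import Ontology, Term
from phenosim.similarity import (
    SimilarityMatrix,
    case_similarity,
    fit_frequencies,
    group_distance,
    rank_distance,
    rank_distance_matrix,
    similarity_matrix,
    term_similarity,
)
from phenosim.simulate import (
    PlantedGroup,
    SimulationConfig,
    simulate_cohort,
    simulate_ontology,
)

from conftest import (
    oracle_case_sim,
    oracle_group_distance,
    oracle_ic,
    oracle_rank_distance,
)

LN2 = math.log(2.0)
LN43 = math.log(4.0 / 3.0)


class TestFitFrequencies:
    def test_c4_frequencies(self, c4_model):
        assert c4_model.freq["T0"] == 1.0
        assert c4_model.freq["T1"] == 0.75
        assert c4_model.freq["T4"] == 0.25

    def test_c4_ic_values(self, c4_model):
        assert c4_model.ic["T0"] == 0.0
        assert c4_model.ic["T1"] == pytest.approx(LN43, abs=1e-12)
        assert c4_model.ic["T4"] == pytest.approx(math.log(4), abs=1e-12)

    def test_matches_brute_force_oracle(self, c4_cases, c4_model, onto):
        expected = oracle_ic(c4_cases, onto)
        assert set(expected) == set(c4_model.ic)
        for t, v in expected.items():
            assert c4_model.ic[t] == pytest.approx(v, abs=1e-12)

    def test_ic_monotone_along_edges(self, c4_cases, c4_model, onto):
        for tid, term in onto.terms.items():
            if tid not in c4_model.ic:
                continue
            for p in term.parents:
                assert c4_model.ic[p] <= c4_model.ic[tid] + 1e-12

    def test_empty_cohort_raises(self, onto):
        with pytest.raises(ValueError):
            fit_frequencies([], onto)


class TestTermSimilarity:
    def test_sibling_mica(self, c4_model, onto):
        assert term_similarity("T3", "T4", c4_model, onto) == pytest.approx(LN43, abs=1e-12)

    def test_root_only_common_ancestor(self, c4_model, onto):
        assert term_similarity("T3", "T5", c4_model, onto) == 0.0

    def test_self_similarity_is_own_ic(self, c4_model, onto):
        assert term_similarity("T4", "T4", c4_model, onto) == pytest.approx(
            math.log(4), abs=1e-12
        )

    def test_bounded_by_min_ic(self, c4_model, onto):
        terms = list(c4_model.ic)
        for s, t in itertools.combinations(terms, 2):
            sim = term_similarity(s, t, c4_model, onto)
            assert sim <= min(c4_model.ic[s], c4_model.ic[t]) + 1e-12

    def test_ancestor_pair_attains_bound(self, c4_model, onto):
        assert term_similarity("T1", "T3", c4_model, onto) == pytest.approx(
            c4_model.ic["T1"], abs=1e-12
        )

    def test_undefined_ic_raises(self, c4_model, onto):
        model = fit_frequencies([CasePhenotype("x", {"T3"})], onto)
        with pytest.raises(KeyError):
            term_similarity("T5", "T3", model, onto)

    def test_disjoint_roots_zero(self):
        onto2 = Ontology([Term("R1"), Term("R2")])
        model = fit_frequencies(
            [CasePhenotype("a", {"R1"}), CasePhenotype("b", {"R1", "R2"})], onto2
        )
        assert term_similarity("R1", "R2", model, onto2) == 0.0


class TestCaseSimilarity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"T3"}, {"T3", "T5"}, 0.75 * LN2),  # 0.51986
            ({"T3"}, {"T4"}, LN43),  # 0.28768
            ({"T3"}, {"T5"}, 0.0),
            ({"T3", "T5"}, {"T4"}, 0.75 * LN43),  # 0.21576
        ],
    )
    def test_c4_pairs(self, a, b, expected, c4_model, onto):
        assert case_similarity(a, b, c4_model, onto) == pytest.approx(expected, abs=1e-12)

    def test_symmetric(self, c4_model, onto):
        a, b = {"T3", "T5"}, {"T4"}
        assert case_similarity(a, b, c4_model, onto) == case_similarity(
            b, a, c4_model, onto
        )

    def test_self_similarity_is_mean_ic(self, c4_model, onto):
        d = {"T3", "T5"}
        assert case_similarity(d, d, c4_model, onto) == pytest.approx(LN2, abs=1e-12)

    def test_empty_set_raises(self, c4_model, onto):
        with pytest.raises(ValueError):
            case_similarity(set(), {"T3"}, c4_model, onto)

    def test_matches_oracle_on_random_cohorts(self):
        config = SimulationConfig(n_terms=30, n_cases=12, seed=7)
        onto = simulate_ontology(config)
        cases, _ = simulate_cohort(onto, config)
        model = fit_frequencies(cases, onto)
        ic = oracle_ic(cases, onto)
        for a, b in itertools.combinations(cases[:8], 2):
            got = case_similarity(a.terms, b.terms, model, onto)
            want = oracle_case_sim(list(a.terms), list(b.terms), ic, onto)
            assert got == pytest.approx(want, abs=1e-12)


class TestSimilarityMatrix:
    def test_c4_offdiagonal_values(self, c4_simmat):
        v = c4_simmat.values
        expect = {
            ("c1", "c2"): 0.75 * LN2,
            ("c1", "c3"): LN43,
            ("c1", "c4"): 0.0,
            ("c2", "c3"): 0.75 * LN43,
            ("c2", "c4"): 0.75 * LN2,
            ("c3", "c4"): 0.0,
        }
        for (a, b), val in expect.items():
            assert c4_simmat.sim(a, b) == pytest.approx(val, abs=1e-12)

    def test_exact_symmetry(self, c4_simmat):
        assert np.array_equal(c4_simmat.values, c4_simmat.values.T)

    def test_diagonal_is_mean_ic(self, c4_simmat, c4_model):
        assert c4_simmat.sim("c2", "c2") == pytest.approx(
            (c4_model.ic["T3"] + c4_model.ic["T5"]) / 2, abs=1e-12
        )

    def test_constant_for_identical_single_term_cohort(self, onto):
        cases = [CasePhenotype(f"c{i}", {"T3"}) for i in range(3)]
        model = fit_frequencies(cases, onto)
        sm = similarity_matrix(cases, model, onto)
        assert np.allclose(sm.values, sm.values[0, 0])

    def test_tsv_roundtrip(self, c4_simmat, tmp_path):
        p = tmp_path / "sim.tsv"
        c4_simmat.to_tsv(p)
        back = SimilarityMatrix.from_tsv(p)
        assert back.case_ids == c4_simmat.case_ids
        assert np.allclose(back.values, c4_simmat.values)

    def test_requires_two_cases(self, c4_cases, c4_model, onto):
        with pytest.raises(ValueError):
            similarity_matrix(c4_cases[:1], c4_model, onto)


class TestRankDistance:
    def test_c4_tied_pair(self, c4_simmat):
        # c4 ties c2's threshold and is counted inclusively
        assert rank_distance("c1", "c2", c4_simmat) == 0.5

    def test_most_similar_pair_without_ties_is_zero(self, onto):
        cases = [
            CasePhenotype("a", {"T3"}),
            CasePhenotype("b", {"T3"}),
            CasePhenotype("c", {"T5"}),
            CasePhenotype("d", {"T4"}),
        ]
        model = fit_frequencies(cases, onto)
        sm = similarity_matrix(cases, model, onto)
        assert rank_distance("a", "b", sm) == 0.0

    def test_zero_similarity_pair_hits_maximum(self, c4_simmat):
        n = len(c4_simmat.case_ids)
        assert rank_distance("c3", "c4", c4_simmat) == n - 2

    def test_same_case_raises(self, c4_simmat):
        with pytest.raises(ValueError):
            rank_distance("c1", "c1", c4_simmat)

    def test_matrix_matches_scalar_everywhere(self, c4_simmat):
        d = rank_distance_matrix(c4_simmat)
        ids = c4_simmat.case_ids
        for i, j in itertools.combinations(range(len(ids)), 2):
            assert d[i, j] == rank_distance(ids[i], ids[j], c4_simmat)

    def test_matches_oracle_on_random_matrix(self):
        rng = np.random.default_rng(3)
        n = 15
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.5)
        sm = SimilarityMatrix([f"x{i}" for i in range(n)], v)
        d = rank_distance_matrix(sm)
        for a, b in itertools.combinations(range(n), 2):
            assert d[a, b] == oracle_rank_distance(a, b, v)

    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_free(self, scale):
        rng = np.random.default_rng(11)
        v = rng.random((8, 8))
        v = (v + v.T) / 2
        ids = [f"x{i}" for i in range(8)]
        d1 = rank_distance_matrix(SimilarityMatrix(ids, v))
        d2 = rank_distance_matrix(SimilarityMatrix(ids, v * scale))
        assert np.array_equal(d1, d2)


class TestGroupDistance:
    def test_pair_group_equals_rank_distance(self, c4_simmat):
        assert group_distance(["c1", "c2"], c4_simmat) == 0.5

    def test_matches_oracle(self, c4_simmat):
        got = group_distance(["c1", "c2", "c3"], c4_simmat)
        want = oracle_group_distance([0, 1, 2], c4_simmat.values)
        assert got == pytest.approx(want, abs=1e-12)

    def test_exact_clones_tie_each_other(self, onto):
        # with inclusive (>=) tie counting, each pair of exact clones counts
        # the third clone as a tie, so the group distance is exactly 1
        clones = [CasePhenotype(f"z{i}", {"T3", "T4"}) for i in range(3)]
        background = [CasePhenotype(f"b{i}", {"T5"}) for i in range(10)]
        cases = clones + background
        model = fit_frequencies(cases, onto)
        sm = similarity_matrix(cases, model, onto)
        got = group_distance([c.case_id for c in clones], sm)
        assert got == oracle_group_distance([0, 1, 2], sm.values)
        assert got == 1.0

    def test_clone_pair_in_null_background_reaches_zero(self, onto):
        clones = [CasePhenotype(f"z{i}", {"T3", "T4"}) for i in range(2)]
        background = [CasePhenotype(f"b{i}", {"T5"}) for i in range(10)]
        cases = clones + background
        model = fit_frequencies(cases, onto)
        sm = similarity_matrix(cases, model, onto)
        assert group_distance(["z0", "z1"], sm) == 0.0

    def test_planted_noisy_clones_small_distance(self):
        # seeded simulation: a planted trio sharing rare core terms sits far
        # below the background's typical group distance; oracle-verified
        config = SimulationConfig(
            n_terms=80,
            n_cases=40,
            planted_groups=[
                PlantedGroup("g", 3, tuple(f"SYN:{i:07d}" for i in range(74, 80)))
            ],
            seed=5,
        )
        onto = simulate_ontology(config)
        cases, truth = simulate_cohort(onto, config)
        model = fit_frequencies(cases, onto)
        sm = similarity_matrix(cases, model, onto)
        group = [cid for cid, lab in truth.items() if lab == "g"]
        idx = [sm.case_ids.index(c) for c in group]
        got = group_distance(group, sm)
        assert got == pytest.approx(oracle_group_distance(idx, sm.values), abs=1e-12)
        assert got < len(cases) / 10

    def test_relabelling_invariance(self, c4_simmat):
        a = group_distance(["c1", "c2", "c3"], c4_simmat)
        b = group_distance(["c3", "c1", "c2"], c4_simmat)
        assert a == b

    def test_singleton_raises(self, c4_simmat):
        with pytest.raises(ValueError):
            group_distance(["c1"], c4_simmat)

    def test_dist_matrix_shortcut_agrees(self, c4_simmat):
        d = rank_distance_matrix(c4_simmat)
        assert group_distance(["c1", "c2", "c4"], c4_simmat) == group_distance(
            ["c1", "c2", "c4"], c4_simmat, dist_matrix=d
        )
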