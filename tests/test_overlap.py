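import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nichelegacy as nl
from nichelegacy.niche_density import build_availability_density, build_occupancy
from nichelegacy.overlap import _translate, dagger


def brute_force_d(z1, z2):
    """Independent total-variation computation: explicit cell loop."""
    acc = 0.0
    for i in range(z1.shape[0]):
        for j in range(z1.shape[1]):
            acc += abs(z1[i, j] - z2[i, j])
    return 1.0 - 0.5 * acc


def random_simplex_grid(rng, shape=(5, 5)):
    z = rng.exponential(size=shape)
    return z / z.sum()


class TestSchoenersD:
    def test_identical_surfaces_give_full_overlap(self):
        rng = np.random.default_rng(0)
        z = random_simplex_grid(rng)
        assert nl.schoeners_d(z, z) == 1.0

    def test_disjoint_supports_give_zero(self):
        z1 = np.zeros((10, 10)); z1[0, 0] = 1.0
        z2 = np.zeros((10, 10)); z2[9, 9] = 1.0
        assert nl.schoeners_d(z1, z2) == 0.0

    def test_hand_example_half_overlap(self):
        z1 = np.array([[0.5, 0.5, 0.0, 0.0]])
        z2 = np.array([[0.0, 0.5, 0.5, 0.0]])
        assert nl.schoeners_d(z1, z2) == pytest.approx(0.5)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = random_simplex_grid(rng), random_simplex_grid(rng)
            assert nl.schoeners_d(a, b) == nl.schoeners_d(b, a)

    def test_triangle_type_bound(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b, c = (random_simplex_grid(rng) for _ in range(3))
            assert nl.schoeners_d(a, b) >= nl.schoeners_d(a, c) + nl.schoeners_d(c, b) - 1 - 1e-12

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b = random_simplex_grid(rng), random_simplex_grid(rng)
            assert nl.schoeners_d(a, b) == pytest.approx(brute_force_d(a, b), abs=1e-12)

    def test_rejects_unnormalized_input(self):
        z = np.full((4, 4), 1.0)
        with pytest.raises(ValueError, match="normalized"):
            nl.schoeners_d(z, z)

    def test_rejects_mismatched_grids(self):
        with pytest.raises(ValueError, match="shape"):
            nl.schoeners_d(np.full((2, 2), 0.25), np.full((1, 4), 0.25))

    def test_hellinger_affinity_brackets_d(self):
        # I >= D on any pair; equality at the extremes
        rng = np.random.default_rng(4)
        a, b = random_simplex_grid(rng), random_simplex_grid(rng)
        assert nl.hellinger_affinity(a, b) >= nl.schoeners_d(a, b)
        assert nl.hellinger_affinity(a, a) == 1.0


class TestTranslate:
    @given(di=st.integers(-6, 6), dj=st.integers(-6, 6))
    @settings(deadline=None, max_examples=30)
    def test_shift_moves_mass_without_creating_any(self, di, dj):
        rng = np.random.default_rng(abs(di) * 13 + abs(dj))
        z = random_simplex_grid(rng, shape=(6, 6))
        out = _translate(z, di, dj)
        assert out.sum() <= z.sum() + 1e-12
        if di == dj == 0:
            np.testing.assert_array_equal(out, z)


@pytest.fixture(scope="module")
def niche_pair():
    rng = np.random.default_rng(5)
    bg = rng.uniform(0, 1, size=(600, 2))
    avail = build_availability_density(bg, R=60)
    occ_a = rng.normal([0.4, 0.5], 0.1, size=(80, 2))
    occ_b = rng.normal([0.45, 0.5], 0.1, size=(80, 2))
    return (build_occupancy(occ_a, avail), build_occupancy(occ_b, avail), bg)


class TestSimilarityTest:
    def test_rank_formula_when_observed_beats_every_null(self, niche_pair):
        ga, gb, _ = niche_pair
        res = nl.similarity_test(ga, gb, B=199, seed=0)
        if np.all(res.null_d < res.d_obs):
            assert res.p_similarity == pytest.approx(1 / 200)
        # both tails always satisfy the add-one bounds
        for p in (res.p_similarity, res.p_difference):
            assert 1 / 200 <= p <= 1.0
        assert len(res.null_d) == 199

    def test_deterministic_given_seed(self, niche_pair):
        ga, gb, bg = niche_pair
        for strategy in ("shift", "resample"):
            r1 = nl.similarity_test(ga, gb, B=99, seed=42, strategy=strategy,
                                    background_scores=bg)
            r2 = nl.similarity_test(ga, gb, B=99, seed=42, strategy=strategy,
                                    background_scores=bg)
            np.testing.assert_array_equal(r1.null_d, r2.null_d)
            assert r1.p_similarity == r2.p_similarity

    def test_tails_are_complementary(self, niche_pair):
        ga, gb, _ = niche_pair
        res = nl.similarity_test(ga, gb, B=199, seed=1)
        # inclusive ties mean the two tails overlap by at least one count
        assert res.p_similarity + res.p_difference >= 1 + 1 / 200

    def test_small_b_rejected(self, niche_pair):
        ga, gb, _ = niche_pair
        with pytest.raises(ValueError, match="B"):
            nl.similarity_test(ga, gb, B=50)

    def test_unknown_strategy_rejected(self, niche_pair):
        ga, gb, _ = niche_pair
        with pytest.raises(ValueError, match="strategy"):
            nl.similarity_test(ga, gb, B=99, strategy="teleport")

    def test_resample_requires_background(self, niche_pair):
        ga, gb, _ = niche_pair
        with pytest.raises(ValueError, match="background"):
            nl.similarity_test(ga, gb, B=99, strategy="resample")


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(nl.adjust_pvalues([0.03]), [0.03])

    def test_holm_hand_example(self):
        np.testing.assert_allclose(nl.adjust_pvalues([0.01, 0.02, 0.03], "holm"),
                                   [0.03, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(nl.adjust_pvalues([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1, size=20)
        adj = nl.adjust_pvalues(p, "holm")
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            nl.adjust_pvalues([0.5], "mystery")

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            nl.adjust_pvalues([0.0, 0.5])


class TestClassifyPair:
    @pytest.mark.parametrize("p_sim,expected", [
        ((0.01, 0.01), "similar_both"),
        ((0.01, 0.20), "similar_one"),
        ((0.20, 0.90), "non_similar"),
    ])
    def test_similarity_categories(self, p_sim, expected):
        sim, _ = nl.classify_pair(p_sim, (0.5, 0.5))
        assert sim == expected

    def test_climate_legacy_pattern(self):
        # neither similar nor different in any direction
        sim, dif = nl.classify_pair((0.2, 0.9), (0.3, 0.8))
        assert (sim, dif) == ("non_similar", "not_different")

    def test_dagger_symbols(self):
        assert dagger("similar_both") == "‡"
        assert dagger("similar_one") == "†"
        assert dagger("non_similar") == "–"
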