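"""Descriptor panels, distribution binning, KL divergence, recovery, t-SNE."""

import math

import numpy as np
import pytest
from scipy.special import rel_entr
from sklearn.metrics import silhouette_score

from npforge.corpusprep import enumerate_smiles
from npforge.evaluate import (
    PANEL10,
    PANEL27,
    compute_descriptors,
    density_grid,
    embed_2d,
    kl_divergence,
    make_distribution,
    recovery_rate,
)


class TestComputeDescriptors:
    def test_ethanol_hand_counts(self):
        d = compute_descriptors("CCO")
        assert d["NumHDonors"] == 1
        assert d["NumHAcceptors"] == 1
        assert d["NumHeteroatoms"] == 1
        assert d["NumAromaticRings"] == 0
        # C2H6O: 2*4 + 6*1 + 6 = 20 valence electrons
        assert d["NumValenceElectrons"] == 20

    def test_benzene(self):
        d = compute_descriptors("c1ccccc1")
        assert d["NumAromaticRings"] == 1
        assert d["NumRotatableBonds"] == 0
        assert d["NumHeteroatoms"] == 0

    def test_methane_tpsa_zero(self):
        d = compute_descriptors("C")
        assert d["TPSA"] == 0.0

    def test_panels_have_documented_names(self):
        assert set(compute_descriptors("CCO", "panel10")) == set(PANEL10)
        assert set(compute_descriptors("CCO", "panel27")) == set(PANEL27)

    def test_writing_invariance(self):
        ref = compute_descriptors("c1ccccc1O")
        for alt in enumerate_smiles("c1ccccc1O", 5, seed=2):
            alt_d = compute_descriptors(alt)
            for k, v in ref.items():
                assert alt_d[k] == pytest.approx(v, rel=1e-9), k


class TestMakeDistribution:
    def test_identical_lists_give_equal_distributions(self):
        pair = make_distribution([0.1, 0.25, 1.4], [0.1, 0.25, 1.4])
        assert np.allclose(pair.p, pair.q)

    def test_values_in_same_bin_collapse(self):
        pair = make_distribution([0.04, 0.06], [0.04], bin_width=0.1)
        assert pair.p[0] == 1.0 and pair.q[0] == 1.0

    def test_categorical(self):
        pair = make_distribution(list("AAAB"), list("AB"), categorical=True)
        assert pair.support == ("A", "B")
        assert np.allclose(pair.p, [0.75, 0.25])

    def test_none_label_is_first_class(self):
        pair = make_distribution(["alkaloid", "none"], ["none"], categorical=True)
        assert "none" in pair.support

    def test_normalization(self):
        pair = make_distribution([0.0, 5.3, -2.1], [1.0, 1.0], bin_width=0.1)
        assert pair.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert pair.q.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_distribution([], [1.0])


class TestKlDivergence:
    def test_identical_distributions_zero(self):
        pair = make_distribution([0.1, 0.2, 0.3] * 5, [0.1, 0.2, 0.3] * 5)
        assert kl_divergence(pair) == pytest.approx(0.0, abs=1e-15)

    def test_two_term_hand_sum(self):
        # P=(0.5,0.5), Q=(0.25,0.75): 0.5 ln2 + 0.5 ln(2/3)
        pair = make_distribution([0.05, 0.15], [0.05, 0.15, 0.15, 0.15])
        expected = 0.5 * math.log(2) + 0.5 * math.log(2 / 3)
        assert kl_divergence(pair) == pytest.approx(expected, abs=1e-12)

    def test_asymmetric(self):
        fwd = make_distribution([0.05, 0.15], [0.05, 0.15, 0.15, 0.15])
        rev = make_distribution([0.05, 0.15, 0.15, 0.15], [0.05, 0.15])
        assert kl_divergence(fwd) != pytest.approx(kl_divergence(rev))

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            pair = make_distribution(
                rng.choice(6, 200, p=p) * 0.1 + 0.05,
                rng.choice(6, 200, p=q) * 0.1 + 0.05)
            if np.any(pair.q[pair.p > 0] == 0):
                continue
            direct = float(rel_entr(pair.p[pair.p > 0], pair.q[pair.p > 0]).sum())
            assert kl_divergence(pair) == pytest.approx(direct, abs=1e-12)

    def test_zero_q_bins_smoothed_to_finite_value(self):
        pair = make_distribution([0.05, 0.15], [0.05])
        d = kl_divergence(pair)
        assert math.isfinite(d)
        assert d >= 0


class TestRecoveryRate:
    def test_superset_recovers_all(self):
        assert recovery_rate({"a", "b", "c"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert recovery_rate({"x"}, {"a", "b"}) == 0.0

    def test_planted_overlap(self):
        heldout = {f"m{i}" for i in range(100)}
        generated = {f"m{i}" for i in range(37)} | {f"g{i}" for i in range(500)}
        assert recovery_rate(generated, heldout) == pytest.approx(0.37)

    def test_empty_heldout_rejected(self):
        with pytest.raises(ValueError):
            recovery_rate({"a"}, set())


class TestEmbedding:
    @pytest.fixture(scope="class")
    def two_population_matrix(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, (120, 10))
        b = rng.normal(8, 1, (120, 10))  # ≥5 pooled SDs away
        return np.vstack([a, b]), np.array([0] * 120 + [1] * 120)

    def test_deterministic_for_fixed_seed(self, two_population_matrix):
        X, _ = two_population_matrix
        e1 = embed_2d(X, random_state=7)
        e2 = embed_2d(X, random_state=7)
        assert np.array_equal(e1.coordinates, e2.coordinates)

    def test_row_count_preserved(self, two_population_matrix):
        X, _ = two_population_matrix
        assert embed_2d(X).coordinates.shape == (X.shape[0], 2)

    def test_separated_populations_stay_separated(self, two_population_matrix):
        X, labels = two_population_matrix
        emb = embed_2d(X, random_state=7)
        assert silhouette_score(emb.coordinates, labels) > 0

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 10))
        X[:, 4] = 1.0
        with pytest.warns(UserWarning):
            emb = embed_2d(X, random_state=7)
        assert 4 not in emb.params["columns_kept"]

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            embed_2d(np.random.default_rng(0).normal(size=(10, 10)))

    def test_density_grid_conserves_counts(self, two_population_matrix):
        X, _ = two_population_matrix
        emb = embed_2d(X, random_state=7)
        grid = density_grid(emb, bins=50)
        assert grid.shape == (50, 50)
        assert grid.sum() == X.shape[0]
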