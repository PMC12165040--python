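"""Blood-panel autoencoder, latent clustering and risk assignment."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from omicsformer.blood_risk import (
    BloodRiskConfig,
    RiskModel,
    assign_risk,
    build_risk_model,
    cluster_latent,
    fit_blood_autoencoder,
    order_risk_levels,
)
from omicsformer.dataio import OmicsMatrix
from omicsformer.model import Affine
from omicsformer.preprocess import ScalingStats
from omicsformer.synthetic import PANEL_FEATURES, generate_blood_panel


class TestAutoencoder:
    def test_loss_decreases(self, small_panel):
        panel, _ = small_panel
        B = (panel.values - panel.values.mean(0)) / panel.values.std(0, ddof=1)
        _, _, traj = fit_blood_autoencoder(B, BloodRiskConfig(seed=0, epochs=100))
        assert traj[-1] < traj[0]

    def test_zero_learning_rate_keeps_parameters(self, small_panel):
        panel, _ = small_panel
        B = (panel.values - panel.values.mean(0)) / panel.values.std(0, ddof=1)
        cfg = BloodRiskConfig(seed=0, epochs=5, learning_rate=0.0)
        block, decoder, traj = fit_blood_autoencoder(B, cfg)
        cfg2 = BloodRiskConfig(seed=0, epochs=1, learning_rate=0.0)
        block2, _, _ = fit_blood_autoencoder(B, cfg2)
        np.testing.assert_array_equal(block.W_Q, block2.W_Q)
        assert np.ptp(traj) == 0.0

    def test_low_rank_panel_recovered(self):
        # noiseless rank-2 panel with latent width 2: near-exact recovery
        rng = np.random.default_rng(8)
        basis = rng.normal(size=(2, 25))
        B = rng.normal(size=(80, 2)) @ basis
        B = (B - B.mean(0)) / B.std(0, ddof=1)
        cfg = BloodRiskConfig(seed=1, latent_dim=2, epochs=3000, learning_rate=3e-3)
        block, decoder, traj = fit_blood_autoencoder(B, cfg)
        rel_err = np.sqrt(traj[-1] / np.sum(B**2))
        assert rel_err < 0.05

    def test_missing_values_rejected(self):
        B = np.ones((4, 3))
        B[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            fit_blood_autoencoder(B, BloodRiskConfig())


class TestClusterLatent:
    def test_k1_single_label(self):
        H = np.random.default_rng(0).normal(size=(10, 3))
        assert set(cluster_latent(H, 1, seed=0)) == {1}

    def test_separated_blobs_fully_recovered(self):
        rng = np.random.default_rng(1)
        H = np.concatenate(
            [rng.normal(c, 0.05, size=(20, 3)) for c in (0.0, 5.0, 10.0)]
        )
        truth = np.repeat([0, 1, 2], 20)
        labels = cluster_latent(H, 3, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_duplicated_rows_co_cluster(self):
        rng = np.random.default_rng(2)
        H = rng.normal(size=(12, 4))
        doubled = np.concatenate([H, H])
        labels = cluster_latent(doubled, 3, seed=0)
        np.testing.assert_array_equal(labels[:12], labels[12:])

    def test_fewer_samples_than_k_raises(self):
        with pytest.raises(ValueError, match="at least"):
            cluster_latent(np.zeros((2, 3)), 5, seed=0)


class TestOrderRiskLevels:
    def test_decoded_magnitudes_order_levels(self):
        # centroids decoding to panel means -1, 0, +1 -> levels 1, 2, 3
        decoder = Affine(np.ones((1, 4)), np.zeros(4))
        centroids = np.array([[0.0], [-1.0], [1.0]])
        np.testing.assert_array_equal(
            order_risk_levels(centroids, decoder), [2, 1, 3]
        )

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(3)
        decoder = Affine(rng.normal(size=(2, 5)), rng.normal(size=5))
        centroids = rng.normal(size=(3, 2))
        order = order_risk_levels(centroids, decoder)
        perm = np.array([2, 0, 1])
        order_perm = order_risk_levels(centroids[perm], decoder)
        np.testing.assert_array_equal(order_perm, order[perm])

    def test_k2_levels_low_high(self):
        decoder = Affine(np.ones((1, 3)), np.zeros(3))
        assert sorted(order_risk_levels(np.array([[2.0], [-2.0]]), decoder)) == [1, 2]

    def test_exact_tie_breaks_by_cluster_index(self):
        decoder = Affine(np.zeros((1, 3)), np.zeros(3))
        np.testing.assert_array_equal(
            order_risk_levels(np.array([[1.0], [2.0]]), decoder), [1, 2]
        )


class TestBuildRiskModel:
    def test_planted_sizes_recovered_under_strong_separation(self, small_panel, risk_model):
        panel, truth = small_panel
        sizes = np.bincount(risk_model.cluster_labels, minlength=4)[1:]
        assert sorted(sizes.tolist()) == sorted(np.bincount(truth).tolist())
        assert adjusted_rand_score(truth, risk_model.cluster_labels) == 1.0

    def test_risk_order_follows_planted_magnitude(self, small_panel, risk_model):
        panel, truth = small_panel
        # group 0 has the smallest panel values, group 2 the largest
        level_of_group = {}
        for g in np.unique(truth):
            clusters = risk_model.cluster_labels[truth == g]
            level_of_group[g] = int(
                np.bincount([risk_model.risk_order[c - 1] for c in clusters]).argmax()
            )
        assert level_of_group[0] < level_of_group[1] < level_of_group[2]

    def test_training_samples_nearest_own_centroid(self, small_panel, risk_model):
        panel, _ = small_panel
        assignments = assign_risk(panel, risk_model)
        own = [
            a.risk_level == risk_model.risk_order[risk_model.cluster_labels[i] - 1]
            for i, a in enumerate(assignments)
        ]
        assert np.mean(own) >= 0.95

    def test_determinism(self, small_panel):
        panel, _ = small_panel
        cfg = BloodRiskConfig(seed=5, epochs=150)
        m1 = build_risk_model(panel, cfg)
        m2 = build_risk_model(panel, cfg)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)
        np.testing.assert_array_equal(m1.cluster_labels, m2.cluster_labels)


class TestAssignRisk:
    def test_distances_and_level_consistency(self, small_panel, risk_model):
        panel, _ = small_panel
        for a in assign_risk(panel, risk_model):
            assert np.all(a.distances >= 0)
            chosen = np.flatnonzero(risk_model.risk_order == a.risk_level)[0]
            assert a.distances[chosen] <= a.distances.min() + 1e-12

    def test_missing_fields_imputed_with_warning(self, small_panel, risk_model):
        panel, _ = small_panel
        rec = panel.values[:1].copy()
        rec[0, 3] = np.nan
        records = OmicsMatrix(rec, ["r0"], list(PANEL_FEATURES), "blood_panel")
        with pytest.warns(UserWarning, match="imputed"):
            out = assign_risk(records, risk_model)
        assert out[0].risk_level in range(1, risk_model.k + 1)

    def test_all_missing_record_raises(self, risk_model):
        rec = np.full((1, 25), np.nan)
        records = OmicsMatrix(rec, ["r0"], list(PANEL_FEATURES), "blood_panel")
        with pytest.raises(ValueError, match="no observed"):
            assign_risk(records, risk_model)

    def test_equidistant_tie_assigns_lower_risk_level(self, risk_model, monkeypatch):
        # force both centroids equidistant from every record
        model = RiskModel(
            block=risk_model.block,
            decoder=risk_model.decoder,
            stats=risk_model.stats,
            medians=risk_model.medians,
            centroids=np.array([[1.0] + [0.0] * 7, [-1.0] + [0.0] * 7]),
            risk_order=np.array([2, 1]),
            k=2,
            feature_ids=risk_model.feature_ids,
            reference=risk_model.reference,
        )
        monkeypatch.setattr(
            RiskModel, "encode", lambda self, X: np.zeros((X.shape[0], 8))
        )
        records = OmicsMatrix(
            risk_model.medians.reshape(1, -1), ["r0"], list(PANEL_FEATURES), "bp"
        )
        assert assign_risk(records, model)[0].risk_level == 1

    def test_one_dimensional_distance_example(self, risk_model, monkeypatch):
        # latent centroids at 0 and 10, record at 3 -> nearer centroid 0
        model = RiskModel(
            block=risk_model.block,
            decoder=risk_model.decoder,
            stats=risk_model.stats,
            medians=risk_model.medians,
            centroids=np.array([[0.0] * 8, [10.0] + [0.0] * 7]),
            risk_order=np.array([1, 2]),
            k=2,
            feature_ids=risk_model.feature_ids,
        )
        monkeypatch.setattr(
            RiskModel,
            "encode",
            lambda self, X: np.array([[3.0] + [0.0] * 7]),
        )
        records = OmicsMatrix(
            risk_model.medians.reshape(1, -1), ["r0"], list(PANEL_FEATURES), "bp"
        )
        a = assign_risk(records, model)[0]
        assert a.risk_level == 1
        assert a.distances[0] == pytest.approx(3.0)
        assert a.distances[1] == pytest.approx(7.0)


def test_recovery_ari_over_seeds():
    """Separation of 6 within-group sds: near-perfect partition recovery."""
    aris = []
    for seed in range(3):
        panel, truth = generate_blood_panel(
            n=90, group_sizes=(45, 23, 22), separation=6.0, seed=seed
        )
        model = build_risk_model(panel, BloodRiskConfig(seed=seed, epochs=150))
        aris.append(adjusted_rand_score(truth, model.cluster_labels))
    assert np.mean(aris) >= 0.9
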