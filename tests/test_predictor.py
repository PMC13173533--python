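"""Attention-predictor contracts: bounds, symmetry, loss algebra, training."""

import numpy as np
import pytest

import syncomdesign as scd
from syncomdesign.autodiff import Tensor
from syncomdesign.predictor import (
    CommunitySample,
    GATPredictor,
    PredictorConfig,
    cv_metrics,
    loocv,
    loss,
)


def tiny_config(input_dim=6, seed=0, **kw):
    defaults = dict(
        input_dim=input_dim,
        gat_layers=3,
        heads_per_layer=2,
        layer_dims=(4, 4, 4),
        mlp_dims=(4, 4, 3),
        dropout=0.0,
        learning_rate=0.05,
        seed=seed,
    )
    defaults.update(kw)
    return PredictorConfig(**defaults)


def random_sample(n_nodes, input_dim, seed, label=None):
    rng = np.random.default_rng(seed)
    feats = rng.normal(size=(n_nodes, input_dim))
    adj = np.eye(n_nodes)
    for i in range(n_nodes - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1.0
    return CommunitySample(
        members=tuple(f"s{i}" for i in range(n_nodes)),
        nodes=tuple(f"s{i}" for i in range(n_nodes)),
        features=feats,
        adj=adj,
        label=label,
    )


@pytest.fixture(scope="module")
def planted_dataset():
    """Small panel with a strong planted genotype->phenotype signal."""
    cfg = scd.GeneratorConfig(
        n_strains=16, n_enzymes=12, n_metabolites=6, signal_strength=6.0, seed=21
    )
    profiles, pmap = scd.generate_profiles(cfg)
    mg = scd.build_graph(profiles, pmap)
    enc = scd.SplineEncoder().fit(profiles.to_numpy())
    emb = scd.node2vec_embed(
        mg,
        scd.Node2VecParams(
            dimensions=8, walk_length=15, walks_per_node=3, context=3, epochs=1, seed=21
        ),
    )
    fmap = scd.build_feature_map(mg, enc, emb)
    planted = scd.PlantedModel.from_pathway_map(pmap, list(profiles.columns), 6.0, seed=22)
    labels = scd.generate_labels(profiles, planted, noise_sd=0.01, seed=23)
    ds = scd.build_dataset(mg, fmap, labels)
    input_dim = enc.output_dim + 8
    return ds, input_dim


class TestBuildModel:
    def test_default_config_structure(self):
        cfg = PredictorConfig()
        model = scd.build_model(cfg)
        assert cfg.gat_layers == 3 and cfg.heads_per_layer == 8
        assert cfg.mlp_dims[-1] == 3
        # one W/a_src/a_dst per head per layer
        for li in range(3):
            for h in range(8):
                assert f"gat{li}_W{h}" in model.params

    def test_seeded_initialization_reproducible(self):
        m1 = GATPredictor(tiny_config(seed=9))
        m2 = GATPredictor(tiny_config(seed=9))
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k].data, m2.params[k].data)

    def test_inconsistent_dims_rejected(self):
        with pytest.raises(ValueError):
            PredictorConfig(layer_dims=(16, 16), gat_layers=3)
        with pytest.raises(ValueError):
            PredictorConfig(layer_dims=(16, 16, 8), mlp_dims=(9, 3))
        with pytest.raises(ValueError):
            tiny_config(dropout=1.0)


class TestPredict:
    def test_output_in_unit_cube(self):
        model = GATPredictor(tiny_config())
        for seed in range(5):
            y = scd.predict(model, random_sample(4, 6, seed))
            assert y.shape == (3,)
            assert np.all(y >= 0) and np.all(y <= 1)

    def test_zeroed_head_gives_half(self):
        model = GATPredictor(tiny_config())
        last = len(model.config.mlp_dims) - 2
        model.params[f"mlp{last}_W"].data[:] = 0.0
        model.params[f"mlp{last}_b"].data[:] = 0.0
        y = scd.predict(model, random_sample(4, 6, 0))
        np.testing.assert_allclose(y, [0.5, 0.5, 0.5])

    def test_node_order_permutation_invariance(self):
        model = GATPredictor(tiny_config())
        s = random_sample(5, 6, 3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(5)
        s_perm = CommunitySample(
            members=s.members,
            nodes=tuple(s.nodes[i] for i in perm),
            features=s.features[perm],
            adj=s.adj[np.ix_(perm, perm)],
            label=None,
        )
        np.testing.assert_allclose(
            scd.predict(model, s), scd.predict(model, s_perm), atol=1e-10
        )

    def test_wrong_feature_dim_rejected(self):
        model = GATPredictor(tiny_config(input_dim=6))
        with pytest.raises(ValueError):
            scd.predict(model, random_sample(4, 7, 0))


class TestLoss:
    def test_perfect_prediction_zero_weights_gives_zero(self):
        pred = Tensor(np.array([[0.2, 0.4, 0.6]]))
        target = np.array([[0.2, 0.4, 0.6]])
        assert loss(pred, target, lambda1=0.0, lambda2=0.0).item() == 0.0

    def test_mse_closed_form(self):
        pred = Tensor(np.array([[0.3, 0.3, 0.3]]))
        target = np.array([[0.2, 0.2, 0.2]])
        assert loss(pred, target, lambda1=0.0, lambda2=0.0).item() == pytest.approx(0.01)

    def test_stability_penalty_strictly_increases_loss(self):
        pred = Tensor(np.array([[0.5, 0.5, 0.5]]))
        target = np.array([[0.5, 0.5, 0.5]])
        aux = Tensor(np.array([[0.1, 0.9, 0.5]]))
        base = loss(pred, target, lambda1=0.0, lambda2=0.0, aux_preds=aux).item()
        with_pen = loss(pred, target, lambda1=0.0, lambda2=0.01, aux_preds=aux).item()
        assert with_pen > base

    def test_lambda_zero_recovers_plain_mse(self):
        model = GATPredictor(tiny_config())
        pred = Tensor(np.array([[0.9, 0.1, 0.5]]))
        target = np.array([[0.8, 0.3, 0.5]])
        plain = float(((pred.data - target) ** 2).mean())
        assert loss(pred, target, model=model, lambda1=0.0, lambda2=0.0).item() == pytest.approx(plain)
        assert loss(pred, target, model=model).item() > plain  # default lambdas add penalty

    def test_nan_rejected(self):
        with pytest.raises(FloatingPointError):
            loss(Tensor(np.array([[np.nan, 0, 0]])), np.zeros((1, 3)))


class TestTrain:
    def test_loss_decreases_on_planted_signal(self, planted_dataset):
        ds, input_dim = planted_dataset
        model = GATPredictor(tiny_config(input_dim=input_dim, layer_dims=(8, 8, 4), mlp_dims=(4, 4, 3)))
        hist = scd.train(model, ds, epochs=60)
        assert hist["loss_trace"][-1] < hist["loss_trace"][0]

    def test_zero_learning_rate_leaves_parameters_unchanged(self, planted_dataset):
        ds, input_dim = planted_dataset
        cfg = tiny_config(input_dim=input_dim, layer_dims=(8, 8, 4), mlp_dims=(4, 4, 3), learning_rate=0.0)
        model = GATPredictor(cfg)
        before = {k: p.data.copy() for k, p in model.params.items()}
        scd.train(model, ds, epochs=5)
        for k, p in model.params.items():
            np.testing.assert_array_equal(before[k], p.data)

    def test_empty_dataset_rejected(self):
        model = GATPredictor(tiny_config())
        with pytest.raises(ValueError):
            scd.train(model, [], epochs=1)

    def test_early_stopping_on_validation_plateau(self, planted_dataset):
        ds, input_dim = planted_dataset
        cfg = tiny_config(
            input_dim=input_dim, layer_dims=(8, 8, 4), mlp_dims=(4, 4, 3),
            learning_rate=0.0, batch_norm=False,
        )
        model = GATPredictor(cfg)
        hist = scd.train(model, ds, epochs=200, val_fraction=0.25, patience=10)
        # lr = 0 cannot improve validation loss, so training stops early
        assert hist["stopped_epoch"] <= 12


class TestLOOCV:
    def test_requires_three_samples(self, planted_dataset):
        ds, input_dim = planted_dataset
        with pytest.raises(ValueError):
            loocv(ds[:2], tiny_config(input_dim=input_dim))

    def test_constant_labels_flagged_with_zero_r2(self):
        y = np.full((4, 3), 0.5)
        pred = np.random.default_rng(0).uniform(size=(4, 3))
        m = cv_metrics(y, pred)
        assert m.degenerate and m.r2 == 0.0

    def test_mean_predictor_scores_near_zero_r2(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(size=(50, 3))
        pred = np.full_like(y, y.mean())
        m = cv_metrics(y, pred)
        assert abs(m.r2) < 0.05

    def test_recovers_planted_signal_on_small_panel(self, planted_dataset):
        ds, input_dim = planted_dataset
        cfg = tiny_config(
            input_dim=input_dim,
            layer_dims=(8, 8, 4),
            mlp_dims=(4, 4, 3),
            dropout=0.1,
            learning_rate=0.01,
        )
        m = loocv(ds, cfg, epochs=120, seed=0)
        assert m.spearman_rho > 0.4  # 16-strain panel: signal clearly detected
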