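"""Stacked ensemble and the alternative fusion strategies."""

import numpy as np
import pytest

from melmp.errors import MelmpError
from melmp.evalstats import weighted_metrics
from melmp.fusion import (
    VIEW_ORDER,
    DirectFusionModel,
    FusionConfig,
    StackedModel,
    concat_views,
    fit_stacked,
    fuse_direct,
    fuse_multimodal_autoencoder,
    make_meta_features,
    phi,
    predict_stacked,
)
from melmp.learners import SubModelSpec, TrainedSubModel

from conftest import make_toy_dataset

CHEAP_GRID = {"grid": {"n_estimators": [30], "max_depth": [None]}}


def forest_specs(seed=0):
    """All-forest specs: fast and deterministic for fusion-level tests."""
    return {
        view: SubModelSpec(
            view=view, family="random-forest", hyperparams=CHEAP_GRID, seed=seed + i
        )
        for i, view in enumerate(VIEW_ORDER)
    }


class _FixedSubModel(TrainedSubModel):
    """Sub-model emitting a fixed probability; for meta-layer arithmetic."""

    def __init__(self, view, value, n_features=1):
        super().__init__(
            spec=SubModelSpec(view=view, family="random-forest"),
            estimator=None,
            n_features=n_features,
        )
        self._value = value

    def predict_proba(self, X):
        X = np.atleast_2d(X)
        return np.full(X.shape[0], self._value)


def fixed_model(weights, intercept, value=0.9):
    return StackedModel(
        submodels={v: _FixedSubModel(v, value) for v in VIEW_ORDER},
        weights=np.asarray(weights, float),
        intercept=intercept,
    )


class TestMetaFeatures:
    def test_shape_and_range(self):
        data = make_toy_dataset(n_per_class=20)
        meta = make_meta_features(data, forest_specs(), folds=4)
        assert meta.shape == (40, 4)
        assert np.all((0 <= meta) & (meta <= 1))

    def test_label_echo_views_give_label_columns(self):
        """When every view's single feature is the label itself, out-of-fold
        sub-model probabilities reproduce the labels."""
        labels = np.repeat([0, 1], 20)
        col = labels[:, None].astype(float)
        data = make_toy_dataset(n_per_class=20)
        echo = type(data)(
            ids=data.ids,
            views={v: col for v in VIEW_ORDER},
            labels=labels,
        )
        meta = make_meta_features(echo, forest_specs(), folds=4)
        np.testing.assert_allclose(meta, np.tile(col, (1, 4)), atol=0.05)

    def test_permuted_labels_give_uncorrelated_meta_columns(self):
        rng = np.random.default_rng(5)
        data = make_toy_dataset(n_per_class=100, separation=2.0, seed=5)
        permuted = type(data)(
            ids=data.ids,
            views=data.views,
            labels=rng.permutation(data.labels),
        )
        meta = make_meta_features(permuted, forest_specs(), folds=5)
        for col in meta.T:
            r = np.corrcoef(col, permuted.labels)[0, 1]
            assert abs(r) < 0.3

    def test_single_class_fold_impossible_raises(self):
        data = make_toy_dataset(n_per_class=2)
        with pytest.raises(MelmpError, match="per class"):
            make_meta_features(data, forest_specs(), folds=4)


class TestFitStacked:
    def test_meta_weights_length_and_intercept(self):
        data = make_toy_dataset(n_per_class=10)
        model = fit_stacked(data, forest_specs(), folds=3)
        assert model.weights.shape == (4,)
        assert isinstance(model.intercept, float)

    def test_constant_meta_features_fall_back_to_prior(self, monkeypatch):
        import melmp.fusion as fusion_mod

        monkeypatch.setattr(
            fusion_mod,
            "train_submodel",
            lambda data, spec: _FixedSubModel(spec.view, 0.5, n_features=3),
        )
        data = make_toy_dataset(n_per_class=10)
        constant = type(data)(
            ids=data.ids,
            views={v: np.ones((20, 3)) for v in VIEW_ORDER},
            labels=data.labels,
        )
        with pytest.warns(UserWarning, match="intercept-only"):
            model = fit_stacked(constant, forest_specs(), folds=3)
        assert not model.weights.any()
        proba = model.predict_proba({v: np.ones((2, 3)) for v in VIEW_ORDER})
        np.testing.assert_allclose(proba, 0.5, atol=1e-9)  # balanced prior

    def test_stacked_tracks_informative_view_among_noise(self):
        """One informative view + three pure-noise views: the fused F-score
        stays within 0.05 of the informative sub-model's F-score."""
        rng = np.random.default_rng(17)
        n = 100
        labels = np.repeat([0, 1], n)
        views = {v: rng.normal(size=(2 * n, 10)) for v in VIEW_ORDER}
        views["PSSM"] = rng.normal(size=(2 * n, 10))
        views["PSSM"][labels == 1, :4] += 2.5
        data = make_toy_dataset(2)
        data = type(data)(
            ids=[f"q{i}" for i in range(2 * n)], views=views, labels=labels
        )
        tr = np.arange(0, 2 * n, 2)
        te = np.arange(1, 2 * n, 2)
        model = fit_stacked(data.subset(tr), forest_specs(), folds=5)
        feats = {v: m[te] for v, m in views.items()}
        f_stacked = weighted_metrics(labels[te], model.predict(feats))[2]
        f_info = weighted_metrics(
            labels[te],
            (model.submodels["PSSM"].predict_proba(feats["PSSM"]) >= 0.5).astype(int),
        )[2]
        assert f_stacked >= f_info - 0.05

    def test_identical_views_match_single_view_model(self):
        """All four views identical (and sub-models identically seeded):
        stacking adds nothing but costs nothing (within 0.02 F of the
        single-view sub-model)."""
        rng = np.random.default_rng(23)
        n = 80
        labels = np.repeat([0, 1], n)
        base = rng.normal(size=(2 * n, 8))
        base[labels == 1, :3] += 1.2
        data = make_toy_dataset(2)
        data = type(data)(
            ids=[f"q{i}" for i in range(2 * n)],
            views={v: base for v in VIEW_ORDER},
            labels=labels,
        )
        specs = {
            view: SubModelSpec(
                view=view, family="random-forest", hyperparams=CHEAP_GRID, seed=23
            )
            for view in VIEW_ORDER
        }
        tr = np.arange(0, 2 * n, 2)
        te = np.arange(1, 2 * n, 2)
        model = fit_stacked(data.subset(tr), specs, folds=5)
        feats = {v: base[te] for v in VIEW_ORDER}
        f_stacked = weighted_metrics(labels[te], model.predict(feats))[2]
        f_single = weighted_metrics(
            labels[te],
            (model.submodels["Seq"].predict_proba(base[te]) >= 0.5).astype(int),
        )[2]
        assert abs(f_stacked - f_single) <= 0.02

    def test_honest_scheme_stays_at_chance_on_permuted_labels(self):
        """Out-of-fold meta training does not manufacture signal: a stacked
        model fit on permuted labels scores at chance on held-out rows."""
        rng = np.random.default_rng(31)
        data = make_toy_dataset(n_per_class=60, separation=0.0, seed=31)
        permuted = type(data)(
            ids=data.ids, views=data.views, labels=rng.permutation(data.labels)
        )
        tr = np.arange(0, 120, 2)
        te = np.arange(1, 120, 2)
        model = fit_stacked(permuted.subset(tr), forest_specs(), folds=5)
        feats = {v: m[te] for v, m in permuted.views.items()}
        acc = (model.predict(feats) == permuted.labels[te]).mean()
        assert abs(acc - 0.5) < 0.2


class TestPredictStacked:
    def test_zero_weights_give_half(self):
        model = fixed_model(np.zeros(4), 0.0)
        proba, label = predict_stacked(
            model, {v: np.zeros((3, 1)) for v in VIEW_ORDER}
        )
        np.testing.assert_allclose(proba, 0.5)
        np.testing.assert_array_equal(label, 1)  # 0.5 >= threshold

    def test_unanimous_high_submodels_with_positive_weights(self):
        model = fixed_model(np.ones(4), 0.0, value=1.0)
        proba, _ = predict_stacked(model, {v: np.zeros((1, 1)) for v in VIEW_ORDER})
        assert proba[0] > 0.5

    def test_hand_set_weights_closed_form(self):
        model = fixed_model(np.ones(4), 0.0, value=0.9)
        proba, _ = predict_stacked(model, {v: np.zeros((1, 1)) for v in VIEW_ORDER})
        assert proba[0] == pytest.approx(1.0 / (1.0 + np.exp(-3.6)), abs=1e-4)
        assert proba[0] == pytest.approx(0.9734, abs=1e-4)

    def test_missing_view_raises(self):
        model = fixed_model(np.ones(4), 0.0)
        with pytest.raises(MelmpError, match="missing views"):
            model.predict_proba({"Seq": np.zeros((1, 1))})

    def test_phi_monotone_in_positive_weight_inputs(self):
        w = np.array([0.5, 1.0, 2.0, 0.1])
        x = np.full(4, 0.3)
        for i in range(4):
            bumped = x.copy()
            bumped[i] += 0.2
            assert phi(bumped @ w) > phi(x @ w)


class TestDirectFusion:
    def test_joint_vector_length_is_sum_of_views(self):
        data = make_toy_dataset(n_per_class=5)
        joint = concat_views(data.views)
        assert joint.shape[1] == sum(m.shape[1] for m in data.views.values())

    def test_realistic_widths_sum(self):
        # view widths of the full encoders with P=553 retained properties
        assert 400 + 400 + 2 * 553 + 584 == 2490

    def test_forest_variant_end_to_end(self):
        data = make_toy_dataset(n_per_class=15, seed=2)
        model = fuse_direct(data, FusionConfig(strategy="direct-concat"))
        proba = model.predict_proba(data.views)
        assert proba.shape == (30,)
        assert (model.predict(data.views) == data.labels).mean() > 0.9

    def test_autoencoder_compression_variant(self):
        data = make_toy_dataset(n_per_class=20, seed=3)
        cfg = FusionConfig(
            strategy="direct-concat-ae", joint_widths=(16, 8, 16), ae_max_iter=30
        )
        model = fuse_direct(data, cfg)
        assert model.encoder is not None
        assert model.predict_proba(data.views).shape == (40,)


class TestMultimodalAE:
    def test_embeddings_concatenate_to_four_bottlenecks(self):
        data = make_toy_dataset(
            n_per_class=20, dims={v: 24 for v in VIEW_ORDER}, seed=4
        )
        cfg = FusionConfig(
            widths={v: (16, 8, 16) for v in VIEW_ORDER}, ae_max_iter=20
        )
        model = fuse_multimodal_autoencoder(data, cfg)
        assert model.embed(data.views).shape == (40, 32)

    def test_default_widths_give_512_dim_joint_embedding(self):
        cfg = FusionConfig()
        assert sum(w[len(w) // 2] for w in cfg.widths.values()) == 512
        assert cfg.widths["AA"] == (512, 128, 512)

    def test_same_seed_identical_predictions(self):
        data = make_toy_dataset(
            n_per_class=15, dims={v: 20 for v in VIEW_ORDER}, seed=6
        )
        cfg = FusionConfig(
            widths={v: (12, 6, 12) for v in VIEW_ORDER}, ae_max_iter=15, seed=8
        )
        p1 = fuse_multimodal_autoencoder(data, cfg).predict_proba(data.views)
        p2 = fuse_multimodal_autoencoder(data, cfg).predict_proba(data.views)
        np.testing.assert_array_equal(p1, p2)
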