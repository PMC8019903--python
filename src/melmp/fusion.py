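"""Fusion of the four feature views.

The primary strategy is a stacked ensemble: the four per-view sub-models
form the first layer, and a logistic meta-learner integrates their
positive-class probabilities,

    phi(z) = 1 / (1 + exp(-z)),    z = w0 + sum_i w_i x_i,

where x_i is the output of sub-model i. Meta-training inputs are produced
out-of-fold (inner stratified k-fold, default 5) so the meta-learner never
sees a sub-model's prediction on a row that sub-model trained on.

Two comparison strategies are also provided: direct concatenation of the
four views (optionally compressed by one autoencoder) ahead of a single
classifier, and a multimodal autoencoder that embeds each view to 128
dimensions before concatenation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import MelmpError
from .learners import (
    AutoencoderSpec,
    Encoder,
    LabeledDataset,
    SubModelSpec,
    TrainedSubModel,
    default_specs,
    fit_autoencoder,
    train_submodel,
)

logger = logging.getLogger(__name__)

VIEW_ORDER = ("Seq", "PSSM", "AA", "SS")

#: Printed per-view autoencoder widths of the multimodal baseline.
MULTIMODAL_WIDTHS = {
    "Seq": (256, 128, 256),
    "PSSM": (256, 128, 256),
    "AA": (512, 128, 512),
    "SS": (256, 128, 256),
}


def phi(z: np.ndarray | float) -> np.ndarray | float:
    """Standard logistic 1/(1+exp(-z))."""
    return expit(z)


@dataclass
class StackedModel:
    """Four trained sub-models plus logistic meta weights."""

    submodels: dict[str, TrainedSubModel]
    weights: np.ndarray  # length 4, VIEW_ORDER
    intercept: float
    meta_kind: str = "probability"  # or "label"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != len(self.submodels):
            raise MelmpError("one meta weight per sub-model required")

    def meta_inputs(self, features: dict[str, np.ndarray]) -> np.ndarray:
        missing = [v for v in VIEW_ORDER if v not in features]
        if missing:
            raise MelmpError(f"missing views for stacked prediction: {missing}")
        cols = []
        for view in VIEW_ORDER:
            p = self.submodels[view].predict_proba(features[view])
            if self.meta_kind == "label":
                p = (p >= self.threshold).astype(float)
            cols.append(p)
        return np.column_stack(cols)

    def predict_proba(self, features: dict[str, np.ndarray]) -> np.ndarray:
        x = self.meta_inputs(features)
        return phi(self.intercept + x @ self.weights)

    def predict(self, features: dict[str, np.ndarray]) -> np.ndarray:
        return (self.predict_proba(features) >= self.threshold).astype(int)


def make_meta_features(
    data: LabeledDataset,
    specs: dict[str, SubModelSpec] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold sub-model probabilities, columns in VIEW_ORDER.

    Each row's meta features come from sub-models trained with that row
    held out (stratified inner folds).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    specs = specs or default_specs(seed)
    n = len(data)
    counts = np.bincount(data.labels)
    if counts.min() < folds:
        raise MelmpError(
            f"need at least {folds} examples per class to stratify {folds} folds"
        )
    meta = np.empty((n, len(VIEW_ORDER)))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr_idx, te_idx in skf.split(np.zeros(n), data.labels):
        train = data.subset(tr_idx)
        for v, view in enumerate(VIEW_ORDER):
            model = train_submodel(train, specs[view])
            meta[te_idx, v] = model.predict_proba(data.views[view][te_idx])
    return meta


def fit_stacked(
    data: LabeledDataset,
    specs: dict[str, SubModelSpec] | None = None,
    folds: int = 5,
    seed: int = 0,
    meta_kind: str = "probability",
) -> StackedModel:
    """Fit the stacked ensemble.

    The logistic meta-learner is trained on out-of-fold meta features; the
    four sub-models are then refit on all training rows. If every meta
    column is constant (degenerate sub-models) the meta-learner falls back
    to an intercept-only model at the class prior.
    """
    specs = specs or default_specs(seed)
    meta = make_meta_features(data, specs, folds=folds, seed=seed)
    if meta_kind == "label":
        meta = (meta >= 0.5).astype(float)

    submodels = {view: train_submodel(data, specs[view]) for view in VIEW_ORDER}

    constant = np.all(meta == meta[0:1, :], axis=0)
    if constant.all():
        warnings.warn(
            "all meta-feature columns are constant; falling back to an "
            "intercept-only meta-learner at the class prior",
            stacklevel=2,
        )
        prior = float(np.clip(data.labels.mean(), 1e-6, 1 - 1e-6))
        return StackedModel(
            submodels=submodels,
            weights=np.zeros(len(VIEW_ORDER)),
            intercept=float(np.log(prior / (1 - prior))),
            meta_kind=meta_kind,
        )
    if constant.any():
        warnings.warn(
            f"constant meta-feature columns: "
            f"{[VIEW_ORDER[i] for i in np.where(constant)[0]]}",
            stacklevel=2,
        )
    lr = LogisticRegression(max_iter=1000, random_state=seed)
    lr.fit(meta, data.labels)
    return StackedModel(
        submodels=submodels,
        weights=lr.coef_.ravel(),
        intercept=float(lr.intercept_[0]),
        meta_kind=meta_kind,
    )


def predict_stacked(
    model: StackedModel, features: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Probability and 0/1 label for each row (threshold 0.5 by default)."""
    proba = model.predict_proba(features)
    return proba, (proba >= model.threshold).astype(int)


# ---------------------------------------------------------------------------
# comparison strategies


@dataclass
class FusionConfig:
    """Configuration of the non-stacked fusion baselines."""

    strategy: str = "stacked"  # stacked | direct-concat | direct-concat-ae | multimodal-ae
    classifier: str = "forest"  # logistic | forest | svm
    widths: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(MULTIMODAL_WIDTHS)
    )
    joint_widths: tuple[int, ...] = (256, 128, 256)
    seed: int = 0
    ae_max_iter: int = 60


def _make_classifier(kind: str, seed: int):
    if kind == "logistic":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if kind == "forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if kind == "svm":
        return SVC(probability=True, random_state=seed)
    raise MelmpError(f"unknown downstream classifier {kind!r}")


def concat_views(views: dict[str, np.ndarray]) -> np.ndarray:
    """Joint vector in the fixed order Seq, PSSM, AA, SS."""
    missing = [v for v in VIEW_ORDER if v not in views]
    if missing:
        raise MelmpError(f"missing views for concatenation: {missing}")
    return np.concatenate([views[v] for v in VIEW_ORDER], axis=1)


@dataclass
class DirectFusionModel:
    """A classifier over the concatenated (optionally compressed) views."""

    classifier: object
    encoder: Encoder | None
    n_features: int

    def _transform(self, views: dict[str, np.ndarray]) -> np.ndarray:
        joint = concat_views(views)
        if joint.shape[1] != self.n_features:
            raise MelmpError(
                f"expected joint width {self.n_features}, got {joint.shape[1]}"
            )
        return self.encoder(joint) if self.encoder is not None else joint

    def predict_proba(self, views: dict[str, np.ndarray]) -> np.ndarray:
        return self.classifier.predict_proba(self._transform(views))[:, 1]

    def predict(self, views: dict[str, np.ndarray]) -> np.ndarray:
        return (self.predict_proba(views) >= 0.5).astype(int)


def fuse_direct(
    data: LabeledDataset, config: FusionConfig = FusionConfig()
) -> DirectFusionModel:
    """Direct-combination baseline: one classifier on the joint vector.

    With ``strategy='direct-concat-ae'`` the joint vector is first
    compressed by a single autoencoder and the classifier consumes the
    bottleneck embedding.
    """
    joint = concat_views(data.views)
    encoder = None
    X = joint
    if config.strategy == "direct-concat-ae":
        encoder = fit_autoencoder(
            joint,
            AutoencoderSpec(
                hidden=config.joint_widths,
                max_iter=config.ae_max_iter,
                seed=config.seed,
            ),
        )
        X = encoder(joint)
    clf = _make_classifier(config.classifier, config.seed)
    clf.fit(X, data.labels)
    return DirectFusionModel(classifier=clf, encoder=encoder, n_features=joint.shape[1])


@dataclass
class MultimodalAEModel:
    """Per-view autoencoder embeddings concatenated before classification."""

    encoders: dict[str, Encoder]
    classifier: object

    def embed(self, views: dict[str, np.ndarray]) -> np.ndarray:
        return np.concatenate(
            [self.encoders[v](views[v]) for v in VIEW_ORDER], axis=1
        )

    def predict_proba(self, views: dict[str, np.ndarray]) -> np.ndarray:
        return self.classifier.predict_proba(self.embed(views))[:, 1]

    def predict(self, views: dict[str, np.ndarray]) -> np.ndarray:
        return (self.predict_proba(views) >= 0.5).astype(int)


def fuse_multimodal_autoencoder(
    data: LabeledDataset, config: FusionConfig = FusionConfig()
) -> MultimodalAEModel:
    """Multimodal baseline: one autoencoder per view, embeddings concatenated."""
    encoders = {}
    for view in VIEW_ORDER:
        encoders[view] = fit_autoencoder(
            data.views[view],
            AutoencoderSpec(
                hidden=config.widths[view],
                max_iter=config.ae_max_iter,
                seed=config.seed,
            ),
        )
    emb = np.concatenate([encoders[v](data.views[v]) for v in VIEW_ORDER], axis=1)
    clf = _make_classifier(config.classifier, config.seed)
    clf.fit(emb, data.labels)
    return MultimodalAEModel(encoders=encoders, classifier=clf)
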