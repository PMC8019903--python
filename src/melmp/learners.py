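"""Per-view sub-model classifiers with a uniform train/predict contract.

Each feature view has a default model family, the winner of the original
per-view model selection:

=====  ==========================  ============================
view   family                      implementation
=====  ==========================  ============================
Seq    recurrent-bidirectional     NumPy BiLSTM (:mod:`melmp._bilstm`)
PSSM   random-forest               sklearn RandomForestClassifier + grid search
AA     multilayer-perceptron       sklearn MLPClassifier (standardised inputs)
SS     autoencoder-forest          sklearn MLPRegressor encoder -> RandomForest
=====  ==========================  ============================

All trained sub-models expose positive-class probabilities; the stacking
layer consumes those probabilities (hard labels available via config).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from ._bilstm import BiLSTMClassifier
from .errors import MelmpError

FAMILIES = (
    "recurrent-bidirectional",
    "random-forest",
    "multilayer-perceptron",
    "autoencoder-forest",
)

#: Per-view winning family.
DEFAULT_FAMILY = {
    "Seq": "recurrent-bidirectional",
    "PSSM": "random-forest",
    "AA": "multilayer-perceptron",
    "SS": "autoencoder-forest",
}

#: Declared grid for the forest hyperparameter search.
DEFAULT_FOREST_GRID = {"n_estimators": [100], "max_depth": [None, 10]}


@dataclass
class LabeledDataset:
    """Aligned per-view feature matrices with binary labels (1 = MP)."""

    ids: list[str]
    views: dict[str, np.ndarray]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise MelmpError("duplicate ids in dataset")
        if self.labels.shape[0] != n:
            raise MelmpError("labels and ids disagree in length")
        for view, mat in self.views.items():
            self.views[view] = np.asarray(mat, dtype=float)
            if self.views[view].shape[0] != n:
                raise MelmpError(f"view {view}: row count != number of ids")

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            ids=[self.ids[i] for i in idx],
            views={v: m[idx] for v, m in self.views.items()},
            labels=self.labels[idx],
        )

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class SubModelSpec:
    """Which family models a view, plus its hyperparameters and seed."""

    view: str
    family: str | None = None
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def resolved_family(self) -> str:
        fam = self.family or DEFAULT_FAMILY.get(self.view)
        if fam not in FAMILIES:
            raise MelmpError(f"unknown model family {fam!r}")
        return fam


@dataclass(frozen=True)
class AutoencoderSpec:
    """Symmetric encoder/decoder widths around a bottleneck embedding."""

    hidden: tuple[int, ...] = (256, 128, 256)
    max_iter: int = 60
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden) % 2 != 1:
            raise MelmpError("autoencoder widths must have an odd length (symmetric)")
        mid = len(self.hidden) // 2
        if self.hidden[:mid] != self.hidden[: mid - len(self.hidden) : -1]:
            raise MelmpError(f"autoencoder widths {self.hidden} are not symmetric")

    @property
    def embedding_width(self) -> int:
        return self.hidden[len(self.hidden) // 2]


class Encoder:
    """Maps inputs to the bottleneck activations of a trained autoencoder."""

    def __init__(self, scaler: StandardScaler, net: MLPRegressor, depth: int) -> None:
        self._scaler = scaler
        self._net = net
        self._depth = depth  # number of layers up to and including the bottleneck
        self.loss_curve_ = list(net.loss_curve_)

    @property
    def embedding_width(self) -> int:
        return self._net.coefs_[self._depth - 1].shape[1]

    def __call__(self, X: np.ndarray) -> np.ndarray:
        a = self._scaler.transform(np.asarray(X, dtype=float))
        for layer in range(self._depth):
            a = a @ self._net.coefs_[layer] + self._net.intercepts_[layer]
            a = np.maximum(a, 0.0)  # relu hidden activations
        return a

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Decode back to (standardised) input space; for loss diagnostics."""
        a = self._scaler.transform(np.asarray(X, dtype=float))
        n_layers = len(self._net.coefs_)
        for layer in range(n_layers):
            a = a @ self._net.coefs_[layer] + self._net.intercepts_[layer]
            if layer < n_layers - 1:
                a = np.maximum(a, 0.0)
        return a


def fit_autoencoder(X: np.ndarray, spec: AutoencoderSpec = AutoencoderSpec()) -> Encoder:
    """Train a symmetric autoencoder and return its encoder half.

    Inputs are standardised; the network reconstructs the standardised
    input through relu hidden layers and an identity output.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if spec.embedding_width >= d:
        raise MelmpError(
            f"embedding width {spec.embedding_width} must be smaller than "
            f"input width {d}"
        )
    if n < spec.embedding_width:
        raise MelmpError(
            f"need at least {spec.embedding_width} examples, got {n}"
        )
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    net = MLPRegressor(
        hidden_layer_sizes=spec.hidden,
        activation="relu",
        solver="adam",
        batch_size=min(spec.batch_size, n),
        max_iter=spec.max_iter,
        random_state=spec.seed,
        tol=1e-5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at capped epochs
        net.fit(Xs, Xs)
    return Encoder(scaler, net, depth=len(spec.hidden) // 2 + 1)


def reshape_for_recurrent(vec: np.ndarray, width: int = 1) -> np.ndarray:
    """Reshape flat feature rows into (steps, width) sequences.

    Accepts a single vector or a matrix of rows; the feature length must be
    divisible by ``width``.
    """
    vec = np.asarray(vec, dtype=float)
    single = vec.ndim == 1
    mat = vec[None, :] if single else vec
    n, d = mat.shape
    if width <= 0 or d % width != 0:
        raise ValueError(f"feature length {d} is not divisible by step width {width}")
    out = mat.reshape(n, d // width, width)
    return out[0] if single else out


@dataclass
class TrainedSubModel:
    """A fitted per-view classifier exposing positive-class probabilities.

    A model constructed with ``estimator=None`` is the defined constant
    fallback and predicts 0.5 everywhere.
    """

    spec: SubModelSpec
    estimator: object | None
    n_features: int
    encoder: Encoder | None = None
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise MelmpError(
                f"view {self.spec.view}: expected feature length "
                f"{self.n_features}, got {X.shape[1]}"
            )
        if self.estimator is None:
            return np.full(X.shape[0], 0.5)
        fam = self.spec.resolved_family()
        if fam == "recurrent-bidirectional":
            width = self.spec.hyperparams.get("step_width", 8)
            return self.estimator.predict_proba(reshape_for_recurrent(X, width))
        if fam == "autoencoder-forest":
            X = self.encoder(X)
        return self.estimator.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def _fit_forest(X, y, hp, seed) -> object:
    grid = hp.get("grid", DEFAULT_FOREST_GRID)
    base = RandomForestClassifier(random_state=seed, n_jobs=1)
    n_min = int(np.bincount(y).min())
    cv = max(2, min(3, n_min))
    if n_min < 2 or sum(len(v) for v in grid.values()) <= len(grid):
        # degenerate grid or too few examples per class for inner validation
        base.set_params(**{k: v[0] for k, v in grid.items()})
        return base.fit(X, y)
    search = GridSearchCV(base, grid, cv=cv, n_jobs=1)
    search.fit(X, y)
    return search.best_estimator_


def train_submodel(data: LabeledDataset, spec: SubModelSpec) -> TrainedSubModel:
    """Fit the sub-model of ``spec.view`` on the dataset.

    Deterministic under a fixed ``spec.seed``. Raises on single-class data
    or a missing view.
    """
    if spec.view not in data.views:
        raise MelmpError(f"view {spec.view!r} not present in dataset")
    X = data.views[spec.view]
    y = data.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise MelmpError("training requires examples from both classes")
    if counts.min() < 2:
        raise MelmpError("training requires at least 2 examples per class")

    fam = spec.resolved_family()
    hp = spec.hyperparams
    encoder = None
    if fam == "random-forest":
        est = _fit_forest(X, y, hp, spec.seed)
    elif fam == "multilayer-perceptron":
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=hp.get("hidden", (64,)),
                        max_iter=hp.get("max_iter", 200),
                        early_stopping=len(y) >= 50,
                        n_iter_no_change=10,
                        random_state=spec.seed,
                    ),
                ),
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
    elif fam == "recurrent-bidirectional":
        width = hp.get("step_width", 8)
        est = BiLSTMClassifier(
            hidden=hp.get("hidden", 16),
            epochs=hp.get("epochs", 60),
            lr=hp.get("lr", 0.01),
            seed=spec.seed,
        )
        est.fit(reshape_for_recurrent(X, width), y.astype(float))
    elif fam == "autoencoder-forest":
        ae_spec = hp.get(
            "autoencoder",
            AutoencoderSpec(
                hidden=tuple(hp.get("ae_hidden", (256, 128, 256))),
                max_iter=hp.get("ae_max_iter", 60),
                seed=spec.seed,
            ),
        )
        encoder = fit_autoencoder(X, ae_spec)
        emb = encoder(X)
        est = RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100),
            random_state=spec.seed,
            n_jobs=1,
        ).fit(emb, y)
    else:  # pragma: no cover - guarded by resolved_family
        raise MelmpError(f"unknown family {fam!r}")

    return TrainedSubModel(
        spec=spec,
        estimator=est,
        n_features=X.shape[1],
        encoder=encoder,
        metadata={"seed": spec.seed, "family": fam, "n_train": len(y)},
    )


def default_specs(seed: int = 0, overrides: dict | None = None) -> dict[str, SubModelSpec]:
    """Default sub-model specs for the four views, one seed stream."""
    overrides = overrides or {}
    specs = {}
    for i, view in enumerate(("Seq", "PSSM", "AA", "SS")):
        hp = dict(overrides.get(view, {}))
        specs[view] = SubModelSpec(view=view, hyperparams=hp, seed=seed + i)
    return specs
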