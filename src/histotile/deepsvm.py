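"""Multilayer RBF-SVM ensemble ("DeepSVM") trained layer-wise.

Every unit is a soft-margin kernel SVM with the RBF kernel
K(x, y) = exp(-||x - y||^2 / c).  A model is an ordered list of hidden
layers, each holding one one-vs-rest unit per class, plus a final
one-vs-rest output layer.  A hidden layer maps a representation to the
vector of its units' decision scores (optionally concatenated with its
input — a pass-through skip that prevents representation collapse when the
class count is small); the true labels supervise every layer.  Depths are
grown greedily and scored on a validation set; the depth with the best
validation accuracy is returned, so the flat one-vs-rest SVM (depth 1,
no hidden layers) is always among the candidates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .backbone import FeatureMatrix


@dataclass(frozen=True)
class RbfKernelParams:
    """Width parameter c of K(x, y) = exp(-||x - y||^2 / c)."""

    c: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("RBF width c must be positive")


def rbf_kernel(x: np.ndarray, y: np.ndarray, params: RbfKernelParams) -> float:
    """exp(-||x - y||^2 / c) for two vectors of equal length."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"incompatible shapes {x.shape} and {y.shape}")
    return float(np.exp(-np.sum((x - y) ** 2) / params.c))


def rbf_gram(x: np.ndarray, y: np.ndarray, params: RbfKernelParams) -> np.ndarray:
    """Kernel matrix K[i, j] = K(x_i, y_j)."""
    d2 = cdist(np.atleast_2d(x), np.atleast_2d(y), metric="sqeuclidean")
    return np.exp(-d2 / params.c)


@dataclass
class SvmUnit:
    """One trained binary RBF-SVM in dual form."""

    support_vectors: np.ndarray      # m x d
    dual_coefs: np.ndarray           # alpha_j * y_j, length m
    bias: float
    kernel: RbfKernelParams
    C: float
    positive_class: str
    train_accuracy: float | None = None

    def __post_init__(self) -> None:
        self.support_vectors = np.atleast_2d(np.asarray(self.support_vectors, float))
        self.dual_coefs = np.asarray(self.dual_coefs, dtype=float)
        if len(self.dual_coefs) != len(self.support_vectors):
            raise ValueError("one dual coefficient per support vector required")
        if np.abs(self.dual_coefs).max() > self.C * (1 + 1e-8):
            raise ValueError("|alpha_j| must not exceed the box constraint C")


def decision_scores(unit: SvmUnit, x: np.ndarray) -> np.ndarray:
    """Decision values sum_j alpha_j y_j K(x, x_j) + b for each row of x."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != unit.support_vectors.shape[1]:
        raise ValueError(
            f"input dimension {x.shape[1]} does not match unit dimension "
            f"{unit.support_vectors.shape[1]}"
        )
    return rbf_gram(x, unit.support_vectors, unit.kernel) @ unit.dual_coefs + unit.bias


def svm_decision(unit: SvmUnit, x: np.ndarray) -> tuple[float, int]:
    """Decision score and hard label for one sample; sgn(0) = +1."""
    score = float(decision_scores(unit, np.asarray(x, dtype=float)[None, :])[0])
    return score, (1 if score >= 0 else -1)


def train_svm_unit(
    x: np.ndarray, binary_targets: np.ndarray, C: float,
    kernel: RbfKernelParams, positive_class: str = "+1",
) -> SvmUnit:
    """Fit one soft-margin RBF-SVM (dual solve) on +/-1 targets."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(binary_targets, dtype=int)
    if set(np.unique(t)) != {-1, 1}:
        raise ValueError("binary targets must contain both +1 and -1")
    clf = SVC(C=C, kernel="rbf", gamma=1.0 / kernel.c)
    clf.fit(x, t)
    unit = SvmUnit(
        support_vectors=clf.support_vectors_,
        dual_coefs=clf.dual_coef_[0],
        bias=float(clf.intercept_[0]),
        kernel=kernel,
        C=C,
        positive_class=positive_class,
        train_accuracy=float(clf.score(x, t)),
    )
    return unit


@dataclass(frozen=True)
class EnsembleConfig:
    C: float = 10.0
    kernel_width: float | None = None   # None: width = current feature count
    pass_through: bool = True
    bagging: bool = False
    max_layers: int = 3
    patience: int = 2
    seed: int = 0


@dataclass
class DeepSvmModel:
    hidden_layers: list[list[SvmUnit]]
    output_layer: list[SvmUnit]
    class_names: list[str]
    pass_through: bool
    val_accuracy_per_depth: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.output_layer) != len(self.class_names):
            raise ValueError("output layer needs exactly one unit per class")
        if any(len(layer) == 0 for layer in self.hidden_layers):
            raise ValueError("hidden layers must be nonempty")

    @property
    def depth(self) -> int:
        """Total layer count (hidden layers + the output layer)."""
        return len(self.hidden_layers) + 1


def layer_transform(
    layer: list[SvmUnit], x: np.ndarray, pass_through: bool = False
) -> np.ndarray:
    """Per-unit decision scores as the next-layer representation."""
    if not layer:
        raise ValueError("a layer must hold at least one SVM unit")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    scores = np.column_stack([decision_scores(u, x) for u in layer])
    return np.column_stack([x, scores]) if pass_through else scores


def _fit_ovr_layer(
    x: np.ndarray, labels: np.ndarray, class_names: list[str],
    config: EnsembleConfig, rng: np.random.Generator, bagging: bool,
) -> list[SvmUnit]:
    width = config.kernel_width if config.kernel_width is not None else float(x.shape[1])
    kernel = RbfKernelParams(c=width)
    units = []
    for cls in class_names:
        t = np.where(labels == cls, 1, -1)
        if bagging:
            while True:
                idx = rng.integers(0, len(x), size=len(x))
                if len(set(t[idx])) == 2:
                    break
            units.append(train_svm_unit(x[idx], t[idx], config.C, kernel, cls))
        else:
            units.append(train_svm_unit(x, t, config.C, kernel, cls))
    return units


def _ovr_predict(layer: list[SvmUnit], x: np.ndarray,
                 class_names: list[str]) -> np.ndarray:
    scores = np.column_stack([decision_scores(u, x) for u in layer])
    return np.asarray(class_names, dtype=object)[scores.argmax(axis=1)]


def train_deepsvm(
    train: FeatureMatrix,
    val: FeatureMatrix,
    max_layers: int = 3,
    config: EnsembleConfig = EnsembleConfig(),
) -> DeepSvmModel:
    """Greedy layer-wise construction, early-stopped on validation accuracy.

    Depth 1 is the output layer alone (a flat one-vs-rest multi-class SVM
    on the raw features); each further depth inserts one hidden layer of
    one-vs-rest units (on a seeded bootstrap resample of rows per unit when
    bagging is on) and refits the output layer on the transformed
    representation.  Construction stops after ``config.patience``
    consecutive depths without improvement, and the model is truncated at
    the best-validation depth, which therefore attains the maximum of
    ``val_accuracy_per_depth``.
    """
    if max_layers < 1:
        raise ValueError("max_layers must be >= 1")
    class_names = sorted({str(c) for c in train.labels})
    if len(class_names) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if len(val.labels) == 0:
        raise ValueError("validation split is empty")
    rng = np.random.default_rng(config.seed)
    x_tr = np.asarray(train.values, dtype=float)
    x_va = np.asarray(val.values, dtype=float)
    y_tr = np.asarray([str(c) for c in train.labels], dtype=object)
    y_va = np.asarray([str(c) for c in val.labels], dtype=object)

    hidden: list[list[SvmUnit]] = []
    val_acc_per_depth: list[float] = []
    best: tuple[float, int, list[list[SvmUnit]], list[SvmUnit]] | None = None
    bad = 0
    for depth in range(1, max_layers + 1):
        if depth > 1:
            layer = _fit_ovr_layer(x_tr, y_tr, class_names, config, rng,
                                   config.bagging)
            hidden.append(layer)
            x_tr = layer_transform(layer, x_tr, config.pass_through)
            x_va = layer_transform(layer, x_va, config.pass_through)
        output = _fit_ovr_layer(x_tr, y_tr, class_names, config, rng, bagging=False)
        acc = float(np.mean(_ovr_predict(output, x_va, class_names) == y_va))
        val_acc_per_depth.append(acc)
        if best is None or acc > best[0]:
            best = (acc, depth, [list(l) for l in hidden], output)
            bad = 0
        else:
            bad += 1
            if bad >= config.patience:
                break
    _, best_depth, best_hidden, best_output = best
    return DeepSvmModel(
        hidden_layers=best_hidden,
        output_layer=best_output,
        class_names=class_names,
        pass_through=config.pass_through,
        val_accuracy_per_depth=val_acc_per_depth,
    )


def predict(model: DeepSvmModel, x: np.ndarray) -> np.ndarray:
    """Class labels after propagating through all layers; ties break by
    class order (argmax takes the first maximum)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    for layer in model.hidden_layers:
        x = layer_transform(layer, x, model.pass_through)
    return _ovr_predict(model.output_layer, x, model.class_names)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_deepsvm(model: DeepSvmModel, path: str | Path) -> None:
    """Serialize all layers into one .npz plus a JSON sidecar."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    meta: dict = {"class_names": model.class_names,
                  "pass_through": model.pass_through,
                  "val_accuracy_per_depth": model.val_accuracy_per_depth,
                  "layers": []}

    def pack(prefix: str, unit: SvmUnit) -> dict:
        arrays[f"{prefix}/sv"] = unit.support_vectors
        arrays[f"{prefix}/dual"] = unit.dual_coefs
        return {"bias": unit.bias, "c": unit.kernel.c, "C": unit.C,
                "positive_class": unit.positive_class}

    for li, layer in enumerate(model.hidden_layers + [model.output_layer]):
        meta["layers"].append(
            [pack(f"layer{li}/unit{ui}", u) for ui, u in enumerate(layer)]
        )
    np.savez(path, **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_deepsvm(path: str | Path) -> DeepSvmModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    layers: list[list[SvmUnit]] = []
    with np.load(npz_path) as data:
        for li, layer_meta in enumerate(meta["layers"]):
            layer = []
            for ui, um in enumerate(layer_meta):
                layer.append(SvmUnit(
                    support_vectors=data[f"layer{li}/unit{ui}/sv"],
                    dual_coefs=data[f"layer{li}/unit{ui}/dual"],
                    bias=um["bias"], kernel=RbfKernelParams(c=um["c"]),
                    C=um["C"], positive_class=um["positive_class"],
                ))
            layers.append(layer)
    return DeepSvmModel(
        hidden_layers=layers[:-1], output_layer=layers[-1],
        class_names=meta["class_names"], pass_through=meta["pass_through"],
        val_accuracy_per_depth=meta["val_accuracy_per_depth"],
    )
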