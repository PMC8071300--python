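"""Two-layer terrain recognizer and its leave-one-out evaluation harness.

Layer 1 operates in the (pc1, pc2) plane and separates the stair modes
from everything else: level walking, ramp ascent and ramp descent share
one merged class (1), stair ascent is class 2, stair descent class 3.
Strides routed to the merged class go to layer 2, which separates level
walking (1), ramp ascent (2) and ramp descent (3) in the (pc1, pc3)
plane.  Each layer is a three-component Gaussian mixture fit by EM on
z-scored features, with a component-to-class map established by majority
vote of the training points' posterior assignments.

Reported accuracies follow the two-stage structure: the layer-1 accuracy
scores stair-vs-rest routing over all strides; the layer-2 accuracy is
conditioned on strides whose true mode is level/ramp and which layer 1
routed correctly, so routing errors count against layer 1 only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import (
    FeatureScaler,
    apply_scaler,
    filter_feature_outliers,
    fit_scaler,
)
from .gmm_em import (
    GmmModel,
    classify,
    e_step,
    fit_gmm,
    init_from_labels,
    init_random,
)
from .imu_core import (
    ConfusionMatrix,
    DataError,
    FeatureVector,
    LabelError,
    LmrError,
    Terrain,
)

__all__ = [
    "LmrConfig",
    "LmrModel",
    "EvaluationReport",
    "CoverageError",
    "AmbiguousMapError",
    "UnresolvableStrideError",
    "fit_lmr",
    "predict_lmr",
    "confusion_matrix",
    "accuracy",
    "loocv",
    "COLLAPSE_LAYER1",
    "LAYER2_CLASS_TO_TERRAIN",
]

#: terrain -> layer-1 class (level/ramp merged)
COLLAPSE_LAYER1 = {1: 1, 2: 2, 3: 3, 4: 1, 5: 1}

#: terrain -> layer-2 class, defined for level/ramp terrains only
TERRAIN_TO_LAYER2_CLASS = {1: 1, 4: 2, 5: 3}

#: layer-2 class -> terrain label
LAYER2_CLASS_TO_TERRAIN = {1: 1, 2: 4, 3: 5}


class CoverageError(LmrError):
    """A terrain class required for training is absent."""


class AmbiguousMapError(LmrError):
    """Component-to-class majority vote tied; re-initialize the mixture."""


class UnresolvableStrideError(LmrError):
    """A stride routed to the level/ramp layer has no pc3 value."""


@dataclass
class LmrConfig:
    """Training-time knobs of the two-layer recognizer.

    outlier_factor: scaled-MAD multiple for the per-class feature filter.
    gmm_tol / gmm_max_iter / ridge: EM stopping and regularization.
    init: "labels" (class-statistics initialization) or "random"
        (label-blind k-point seeding; components are still mapped to
        classes by majority vote afterwards).
    """

    outlier_factor: float = 2.0
    gmm_tol: float = 1e-6
    gmm_max_iter: int = 200
    ridge: float = 1e-6
    init: str = "labels"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.init not in ("labels", "random"):
            raise DataError(f"unknown init scheme {self.init!r}")


@dataclass
class LmrModel:
    """Fitted two-layer recognizer: two mixtures, maps and scalers."""

    layer1: GmmModel
    map1: dict[int, int]
    scaler1: FeatureScaler
    layer2: GmmModel
    map2: dict[int, int]
    scaler2: FeatureScaler

    def __post_init__(self) -> None:
        for name, m in (("map1", self.map1), ("map2", self.map2)):
            if sorted(m.values()) != [1, 2, 3]:
                raise DataError(f"{name} is not a bijection onto classes 1-3")


@dataclass
class EvaluationReport:
    """LOOCV outcome: per-layer confusion matrices and accuracies."""

    cm_layer1: ConfusionMatrix
    cm_layer2: ConfusionMatrix
    accuracy_layer1: float
    accuracy_layer2: float
    n_folds: int
    skipped_folds: list[int] = field(default_factory=list)
    unresolved_folds: list[int] = field(default_factory=list)
    fold_predictions: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy_layer1_percent": self.accuracy_layer1,
            "accuracy_layer2_percent": self.accuracy_layer2,
            "n_folds": self.n_folds,
            "skipped_folds": self.skipped_folds,
            "unresolved_folds": self.unresolved_folds,
            "confusion_layer1": self.cm_layer1.to_dict(),
            "confusion_layer2": self.cm_layer2.to_dict(),
            "fold_predictions": self.fold_predictions,
        }


def _fit_layer(
    X: np.ndarray,
    y_class: np.ndarray,
    cfg: LmrConfig,
    rng: np.random.Generator,
) -> tuple[GmmModel, dict[int, int], FeatureScaler]:
    scaler = fit_scaler(X)
    Z = apply_scaler(scaler, X)
    if cfg.init == "labels":
        init = init_from_labels(Z, y_class, ridge=cfg.ridge)
    else:
        init = init_random(Z, K=3, rng=rng, ridge=cfg.ridge)
    model, _ = fit_gmm(
        Z, K=3, init=init, tol=cfg.gmm_tol,
        max_iter=cfg.gmm_max_iter, ridge=cfg.ridge,
    )
    # Map components to classes by majority vote of training assignments.
    assigned = e_step(Z, model).gamma.argmax(axis=1)
    comp_map: dict[int, int] = {}
    for k in range(model.K):
        members = y_class[assigned == k]
        if len(members) == 0:
            raise AmbiguousMapError(
                f"component {k} captured no training points; re-initialize"
            )
        classes, counts = np.unique(members, return_counts=True)
        top = counts == counts.max()
        if top.sum() > 1:
            raise AmbiguousMapError(
                f"component {k} majority vote tied between classes "
                f"{classes[top].tolist()}; re-initialize"
            )
        comp_map[k] = int(classes[np.argmax(counts)])
    if sorted(comp_map.values()) != [1, 2, 3]:
        raise AmbiguousMapError(
            f"component-to-class map {comp_map} is not a bijection; "
            "re-initialize"
        )
    return model, comp_map, scaler


def fit_lmr(
    features: Sequence[FeatureVector], cfg: LmrConfig | None = None
) -> LmrModel:
    """Train both layers on labeled stride features.

    Training applies the per-class feature-outlier filter first, then fits
    layer 1 on (pc1, pc2) of all strides with terrain labels collapsed to
    {merged, SA, SD}, and layer 2 on (pc1, pc3) of the true level/ramp
    strides that carry a pc3 value.  Scalers are fit per layer on the
    respective training subsets only.
    """
    cfg = cfg or LmrConfig()
    present = {int(f.label) for f in features}
    missing = set(COLLAPSE_LAYER1) - present
    if missing:
        raise CoverageError(
            f"terrains {sorted(missing)} absent from training data"
        )
    rng = np.random.default_rng(cfg.seed)
    filtered = filter_feature_outliers(features, factor=cfg.outlier_factor)

    X1 = np.array([[f.pc1, f.pc2] for f in filtered])
    y1 = np.array([COLLAPSE_LAYER1[int(f.label)] for f in filtered])
    gmm1, map1, scaler1 = _fit_layer(X1, y1, cfg, rng)

    lr = [f for f in filtered if int(f.label) in TERRAIN_TO_LAYER2_CLASS and f.has_pc3]
    if len({int(f.label) for f in lr}) < 3:
        raise CoverageError(
            "layer 2 needs pc3-bearing strides from LW, RA and RD"
        )
    X2 = np.array([[f.pc1, f.pc3] for f in lr])
    y2 = np.array([TERRAIN_TO_LAYER2_CLASS[int(f.label)] for f in lr])
    gmm2, map2, scaler2 = _fit_layer(X2, y2, cfg, rng)

    return LmrModel(
        layer1=gmm1, map1=map1, scaler1=scaler1,
        layer2=gmm2, map2=map2, scaler2=scaler2,
    )


def _predict_detail(model: LmrModel, fv: FeatureVector) -> tuple[int, int, bool]:
    """(terrain label, layer-1 class, used_layer2)."""
    z1 = apply_scaler(model.scaler1, np.array([fv.pc1, fv.pc2]))
    k1, _ = classify(z1, model.layer1)
    class1 = model.map1[k1]
    if class1 == 2:
        return int(Terrain.SA), class1, False
    if class1 == 3:
        return int(Terrain.SD), class1, False
    if not fv.has_pc3:
        raise UnresolvableStrideError(
            f"stride {fv.trial_id}/{fv.stride_index} routed to the "
            "level/ramp layer but has no pc3"
        )
    z2 = apply_scaler(model.scaler2, np.array([fv.pc1, fv.pc3]))
    k2, _ = classify(z2, model.layer2)
    return LAYER2_CLASS_TO_TERRAIN[model.map2[k2]], class1, True


def predict_lmr(model: LmrModel, feature: FeatureVector) -> int:
    """Predict the terrain label (1-5) of one stride.

    Stair predictions come straight from layer 1; only merged-class
    strides consult layer 2.
    """
    label, _, _ = _predict_detail(model, feature)
    return label


def confusion_matrix(
    actual: Sequence[int], predicted: Sequence[int], classes: Sequence[int]
) -> ConfusionMatrix:
    """Count grid indexed (actual, predicted) over the given class order."""
    actual = [int(a) for a in actual]
    predicted = [int(p) for p in predicted]
    if len(actual) != len(predicted):
        raise DataError("actual and predicted must have equal length")
    index = {int(c): i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for a, p in zip(actual, predicted):
        if a not in index or p not in index:
            raise LabelError(f"label outside class set {list(classes)}: {a, p}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_labels=list(classes))


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent of correctly classified samples: trace / total * 100."""
    if cm.total == 0:
        raise DataError("cannot compute accuracy of an empty matrix")
    return float(np.trace(cm.counts) / cm.total * 100.0)


def loocv(
    features: Sequence[FeatureVector], cfg: LmrConfig | None = None
) -> EvaluationReport:
    """Leave-one-out cross-validation: N folds, one held-out stride each.

    Every fold refits the outlier filter, the scalers and both mixtures on
    the remaining N-1 strides (no information leaks from the held-out
    stride), then predicts the held-out stride.  A fold whose training
    remainder lacks a terrain is skipped with a warning and recorded.
    """
    cfg = cfg or LmrConfig()
    features = list(features)
    n = len(features)
    if n < 10:
        raise DataError(f"LOOCV needs at least 10 strides, got {n}")
    actual1, pred1 = [], []
    actual2, pred2 = [], []
    skipped, unresolved, fold_log = [], [], []
    for i in range(n):
        train = features[:i] + features[i + 1 :]
        test = features[i]
        try:
            model = fit_lmr(train, cfg)
        except CoverageError as exc:
            warnings.warn(f"fold {i} skipped: {exc}", stacklevel=2)
            skipped.append(i)
            continue
        true_terrain = int(test.label)
        true_class1 = COLLAPSE_LAYER1[true_terrain]
        try:
            label, class1, used_layer2 = _predict_detail(model, test)
        except UnresolvableStrideError:
            # Routed to the level/ramp layer without pc3: scored as a
            # layer-2 miss (if eligible) but not representable in the CM.
            z1 = apply_scaler(model.scaler1, np.array([test.pc1, test.pc2]))
            class1 = model.map1[classify(z1, model.layer1)[0]]
            actual1.append(true_class1)
            pred1.append(class1)
            unresolved.append(i)
            fold_log.append(
                {"fold": i, "actual": true_terrain, "predicted": None,
                 "layer1_class": class1}
            )
            continue
        actual1.append(true_class1)
        pred1.append(class1)
        if true_class1 == 1 and class1 == 1:
            actual2.append(true_terrain)
            pred2.append(label)
        fold_log.append(
            {"fold": i, "actual": true_terrain, "predicted": label,
             "layer1_class": class1}
        )
    cm1 = confusion_matrix(actual1, pred1, classes=[1, 2, 3])
    cm2 = confusion_matrix(actual2, pred2, classes=[1, 4, 5])
    return EvaluationReport(
        cm_layer1=cm1,
        cm_layer2=cm2,
        accuracy_layer1=accuracy(cm1),
        accuracy_layer2=accuracy(cm2) if cm2.total else float("nan"),
        n_folds=n,
        skipped_folds=skipped,
        unresolved_folds=unresolved,
        fold_predictions=fold_log,
    )
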