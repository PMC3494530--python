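"""Freeze the training-derived pipeline; apply it unchanged to validation data.

The frozen bundle is self-contained: normalization target, baseline window,
peak-cluster definitions, per-cluster zero-substitution constants, the
empirical-Bayes hyperparameters and the fitted classifier with its selected
features.  Applying it to an independent cohort therefore uses no
validation-derived quantity anywhere — per-spectrum normalization
coefficients are computed against the frozen training target, intensities
are read out at the frozen cluster windows (no new peak detection), and
non-positive values are imputed with the frozen training constants.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classify import DLDAModel, metrics, predict
from .diffexpr import EBayesParams
from .io import SpecError
from .peaks import PeakCluster, extract_intensity_matrix
from .preprocess import PreprocessParams, subtract_baseline, tic_normalize


@dataclass
class FrozenPipeline:
    surface: str
    specimen: str
    norm_range: tuple
    baseline_window: float
    norm_target: float
    clusters: list                     # list[PeakCluster]
    substitute_values: dict            # cluster id -> frozen half-min constant
    ebayes: EBayesParams | None
    classifier: dict                   # serialized model (see _serialize_model)
    selected_features: list            # cluster ids used by the classifier
    k_star: int
    cost_star: float | None

    @property
    def fingerprint(self) -> str:
        return hashlib.sha256(
            _canonical_json(self).encode("utf-8")).hexdigest()


def _canonical_json(frozen: FrozenPipeline) -> str:
    payload = {
        "surface": frozen.surface,
        "specimen": frozen.specimen,
        "norm_range": list(frozen.norm_range),
        "baseline_window": frozen.baseline_window,
        "norm_target": frozen.norm_target,
        "clusters": [{"id": c.id, "center_mz": c.center_mz,
                      "window": list(c.window), "support": c.support}
                     for c in frozen.clusters],
        "substitute_values": dict(sorted(frozen.substitute_values.items())),
        "ebayes": None if frozen.ebayes is None else
        {"d0": frozen.ebayes.d0, "s0_sq": frozen.ebayes.s0_sq},
        "classifier": frozen.classifier,
        "selected_features": list(frozen.selected_features),
        "k_star": frozen.k_star,
        "cost_star": frozen.cost_star,
    }
    return json.dumps(payload, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _serialize_model(model) -> dict:
    if isinstance(model, DLDAModel):
        return {"kind": "dlda",
                "classes": [str(c) for c in model.classes],
                "means": model.means.tolist(),
                "pooled_var": model.pooled_var.tolist()}
    # linear SVM: store the decision hyperplane(s); binary only
    if hasattr(model, "coef_"):
        classes = [str(c) for c in model.classes_]
        if len(classes) != 2:
            raise SpecError("frozen SVM supports binary classification only")
        return {"kind": "linear_svm", "classes": classes,
                "coef": model.coef_.tolist(),
                "intercept": model.intercept_.tolist()}
    raise SpecError(f"cannot freeze model of type {type(model).__name__}")


def _predict_serialized(classifier: dict, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if classifier["kind"] == "dlda":
        model = DLDAModel(classes=np.asarray(classifier["classes"]),
                          means=np.asarray(classifier["means"]),
                          pooled_var=np.asarray(classifier["pooled_var"]))
        return predict(model, X)
    if classifier["kind"] == "linear_svm":
        w = np.asarray(classifier["coef"])[0]
        b = float(np.asarray(classifier["intercept"])[0])
        score = X @ w + b
        classes = classifier["classes"]
        return np.where(score > 0, classes[1], classes[0])
    raise SpecError(f"unknown classifier kind {classifier['kind']!r}")


def freeze(surface: str, specimen: str, params: PreprocessParams,
           norm_target: float, clusters: list, substitute_values: dict,
           model, selected_features: list, k_star: int,
           cost_star: float | None = None,
           ebayes: EBayesParams | None = None) -> FrozenPipeline:
    """Bundle all training-derived artifacts into a FrozenPipeline."""
    missing = []
    if norm_target is None or not norm_target > 0:
        missing.append("norm_target")
    if not clusters:
        missing.append("clusters")
    if not selected_features:
        missing.append("selected_features")
    if missing:
        raise SpecError(f"cannot freeze: missing component(s) {missing}")
    known = {c.id for c in clusters}
    unknown = [f for f in selected_features if f not in known]
    if unknown:
        raise SpecError(f"selected features not among clusters: {unknown}")
    return FrozenPipeline(
        surface=surface, specimen=specimen,
        norm_range=tuple(params.norm_range),
        baseline_window=params.baseline_window,
        norm_target=float(norm_target),
        clusters=list(clusters),
        substitute_values=dict(substitute_values),
        ebayes=ebayes,
        classifier=_serialize_model(model),
        selected_features=list(selected_features),
        k_star=int(k_star),
        cost_star=None if cost_star is None else float(cost_star))


def save_frozen(frozen: FrozenPipeline, path) -> None:
    Path(path).write_text(_canonical_json(frozen))


def load_frozen(path) -> FrozenPipeline:
    data = json.loads(Path(path).read_text())
    return FrozenPipeline(
        surface=data["surface"], specimen=data["specimen"],
        norm_range=tuple(data["norm_range"]),
        baseline_window=data["baseline_window"],
        norm_target=data["norm_target"],
        clusters=[PeakCluster(id=c["id"], center_mz=c["center_mz"],
                              window=tuple(c["window"]), support=c["support"])
                  for c in data["clusters"]],
        substitute_values=data["substitute_values"],
        ebayes=None if data["ebayes"] is None else
        EBayesParams(d0=data["ebayes"]["d0"], s0_sq=data["ebayes"]["s0_sq"]),
        classifier=data["classifier"],
        selected_features=data["selected_features"],
        k_star=data["k_star"], cost_star=data["cost_star"])


def apply_frozen(frozen: FrozenPipeline, spectra: list,
                 positive_class: str = "cancer"):
    """Preprocess, extract and classify an independent cohort, frozen-only.

    Returns (IntensityMatrix, predictions array, metrics dict or None).
    Metrics are computed when the validation spectra carry known labels.
    The frozen bundle is never mutated.
    """
    spectra = [s for s in spectra if s.surface == frozen.surface]
    if not spectra:
        raise SpecError(f"no spectra on frozen surface {frozen.surface!r}")
    corrected = [subtract_baseline(s, frozen.baseline_window)[0] for s in spectra]
    norm = tic_normalize(corrected, frozen.norm_range,
                         norm_target=frozen.norm_target)
    usable = [s for s in norm.spectra if s.key not in set(norm.failed)]
    matrix, _ = extract_intensity_matrix(
        usable, frozen.clusters, substitute_values=frozen.substitute_values)
    cols = [matrix.cluster_ids.index(f) for f in frozen.selected_features]
    X = matrix.values.to_numpy()[:, cols]
    preds = _predict_serialized(frozen.classifier, X)
    labels = matrix.samples["class_label"].to_numpy()
    result = None
    if set(labels) != {"unknown"}:
        result = metrics(labels, preds, positive_class=positive_class)
    return matrix, preds, result
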