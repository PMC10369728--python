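"""Linear-SVM scorer for ACP vs non-ACP peptides.

Two model configurations mirror the screening design: model 1 contrasts
experimentally-validated-ACP-like peptides with random peptides, model 2
contrasts them with antimicrobial peptides lacking anticancer activity.
Features are the composition blocks (20 aa, 400 dipeptide, or both),
standardised with training statistics; the real-valued decision value is
the "ACP/non-ACP score" and the default decision threshold is 0, ties
labelled ACP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import LinearSVC

from .composition_features import N_FEATURES, composition_vector

__all__ = [
    "SvmModel",
    "Prediction",
    "EvaluationReport",
    "train",
    "predict_score",
    "evaluate",
    "cv_accuracy",
]

MODEL_KINDS = ("ACP_VS_RANDOM", "ACP_VS_AMP")
FEATURE_BLOCKS = {"AA": slice(0, 20), "DIPEPTIDE": slice(20, 420),
                  "BOTH": slice(0, 420)}
POSITIVE_LABEL = "ACP"


@dataclass
class SvmModel:
    model_kind: str
    feature_block: str
    weights: np.ndarray  # one weight per kept feature
    bias: float
    scale_mean: np.ndarray  # per-feature training mean (block width)
    scale_sd: np.ndarray  # per-feature training sd; kept iff > 0
    kept: np.ndarray  # bool mask over the block
    decision_threshold: float = 0.0
    version: str = "1"

    def decision_value(self, features: np.ndarray) -> float:
        x = np.asarray(features, dtype=float)
        if x.shape[-1] == N_FEATURES:
            x = x[..., FEATURE_BLOCKS[self.feature_block]]
        z = (x[..., self.kept] - self.scale_mean[self.kept]) / self.scale_sd[self.kept]
        return z @ self.weights + self.bias

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "format": "pepmine-svm", "version": self.version,
            "model_kind": self.model_kind, "feature_block": self.feature_block,
            "weights": self.weights.tolist(), "bias": self.bias,
            "scale_mean": self.scale_mean.tolist(),
            "scale_sd": self.scale_sd.tolist(),
            "kept": self.kept.astype(int).tolist(),
            "decision_threshold": self.decision_threshold,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SvmModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        if doc.get("format") != "pepmine-svm":
            raise ValueError("not a pepmine SVM model document")
        return cls(
            model_kind=doc["model_kind"], feature_block=doc["feature_block"],
            weights=np.asarray(doc["weights"], dtype=float), bias=float(doc["bias"]),
            scale_mean=np.asarray(doc["scale_mean"], dtype=float),
            scale_sd=np.asarray(doc["scale_sd"], dtype=float),
            kept=np.asarray(doc["kept"], dtype=bool),
            decision_threshold=float(doc["decision_threshold"]),
            version=str(doc["version"]),
        )


@dataclass(frozen=True)
class Prediction:
    score: float
    label: str  # ACP or NON_ACP


@dataclass(frozen=True)
class EvaluationReport:
    sensitivity: float  # percentages
    specificity: float
    accuracy: float
    confusion: dict[str, int] = field(default_factory=dict)


def _binarise(labels) -> np.ndarray:
    y = np.asarray([1 if l == POSITIVE_LABEL or l == 1 else 0 for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def train(features, labels, model_kind: str = "ACP_VS_RANDOM",
          feature_block: str = "BOTH", C: float = 1.0, seed: int = 0) -> SvmModel:
    """Fit a standardised linear soft-margin SVM; deterministic given seed."""
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    if feature_block not in FEATURE_BLOCKS:
        raise ValueError(f"feature_block must be one of {sorted(FEATURE_BLOCKS)}")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] == N_FEATURES:
        X = X[:, FEATURE_BLOCKS[feature_block]]
    y = _binarise(labels)
    if np.min(np.bincount(y)) < 1 or X.shape[0] < 4:
        raise ValueError("need at least 2 samples per class")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    kept = sd > 0
    Z = (X[:, kept] - mean[kept]) / sd[kept]
    clf = LinearSVC(C=C, random_state=seed, max_iter=50000, tol=1e-6)
    clf.fit(Z, y)
    return SvmModel(
        model_kind=model_kind, feature_block=feature_block,
        weights=clf.coef_[0].copy(), bias=float(clf.intercept_[0]),
        scale_mean=mean, scale_sd=sd, kept=kept,
    )


def predict_score(model: SvmModel, peptide) -> Prediction:
    """Decision value + thresholded label for a peptide or feature vector."""
    if isinstance(peptide, str):
        features = composition_vector(peptide)
    else:
        features = np.asarray(peptide, dtype=float)
    score = float(model.decision_value(features))
    label = POSITIVE_LABEL if score >= model.decision_threshold else "NON_ACP"
    return Prediction(score=score, label=label)


def evaluate(model: SvmModel, features, labels) -> EvaluationReport:
    """Sensitivity/specificity/accuracy (percent) on a labelled test set."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = _binarise(labels)
    scores = model.decision_value(X)
    pred = (scores >= model.decision_threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    return EvaluationReport(
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        accuracy=100.0 * (tp + tn) / len(y),
        confusion={"TP": tp, "FN": fn, "TN": tn, "FP": fp},
    )


def cv_accuracy(features, labels, n_splits: int = 5, C: float = 1.0,
                seed: int = 0, feature_block: str = "BOTH") -> float:
    """Stratified k-fold cross-validated accuracy (percent)."""
    from sklearn.model_selection import StratifiedKFold

    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = _binarise(labels)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs = []
    for tr_idx, te_idx in skf.split(X, y):
        model = train(X[tr_idx], y[tr_idx], feature_block=feature_block,
                      C=C, seed=seed)
        rep = evaluate(model, X[te_idx], y[te_idx])
        accs.append(rep.accuracy)
    return float(np.mean(accs))
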