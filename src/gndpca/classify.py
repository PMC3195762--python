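"""Normal/abnormal discrimination from core-tensor features.

Each volume's core tensor (its feature under the fitted multilinear model)
is compared with the mean training feature by Euclidean distance after
flattening (ED).  The decision boundary is the largest distance observed
among the training samples (LDT): a test sample is called abnormal iff its
ED exceeds the LDT.  Geometrically this is a sphere around the training-mean
feature; training samples are self-consistent (ED <= LDT) by construction,
and a sample exactly on the boundary is classed normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DistanceClassifier", "Prediction", "feature_distance", "build_classifier", "predict"]


@dataclass
class DistanceClassifier:
    """Mean training feature plus the largest-distance-of-training threshold."""

    center: np.ndarray
    ldt: float
    training_distances: list[float]


@dataclass
class Prediction:
    label: str           # "normal" | "abnormal"
    ed: float
    ldt: float
    ed_minus_ldt: float


def feature_distance(b: np.ndarray, center: np.ndarray) -> float:
    """Euclidean distance between flattened core tensors."""
    b = np.asarray(b, dtype=float)
    center = np.asarray(center, dtype=float)
    if b.shape != center.shape:
        raise ValueError(f"feature shapes differ: {b.shape} vs {center.shape}")
    return float(np.linalg.norm((b - center).ravel()))


def build_classifier(train_features) -> DistanceClassifier:
    """Center = entrywise mean of training features; LDT = max training ED."""
    feats = [np.asarray(f, dtype=float) for f in train_features]
    if len(feats) == 0:
        raise ValueError("need at least one training feature")
    shape = feats[0].shape
    if any(f.shape != shape for f in feats):
        raise ValueError("all training features must share one shape")
    center = np.mean(np.stack(feats), axis=0)
    dists = [feature_distance(f, center) for f in feats]
    return DistanceClassifier(center=center, ldt=float(max(dists)), training_distances=dists)


def predict(c: DistanceClassifier, b: np.ndarray) -> Prediction:
    """Abnormal iff ED > LDT (boundary inclusive to normal)."""
    ed = feature_distance(b, c.center)
    label = "abnormal" if ed > c.ldt else "normal"
    return Prediction(label=label, ed=ed, ldt=c.ldt, ed_minus_ldt=ed - c.ldt)
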