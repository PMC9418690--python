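"""Exemplar shape classification, pQMS signatures and Z-score hit calling.

The screen workflow: train one-vs-rest linear classifiers on exemplar cells,
assign every segmented cell to a shape class (or leave it unclassified),
summarise each well as a population-level quantitative morphological
signature (pQMS: the percentage of cells in each class), normalise each
shape percentage per plate to Z-scores, and call a reagent a hit when at
least two replicates exceed |Z| = 1.5 in a consistent direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .imaging import FEATURE_NAMES


class TrainingError(ValueError):
    """Raised when the exemplar set cannot train a classifier."""


class NormalizationError(ValueError):
    """Raised when plate values cannot be standardised."""


UNCLASSIFIED = "unclassified"


@dataclass
class ShapeClassifier:
    """One-vs-rest ridge linear discriminants on standardised features."""

    class_names: List[str]
    weights: np.ndarray  # (n_classes, 28)
    biases: np.ndarray  # (n_classes,)
    feature_means: np.ndarray
    feature_sds: np.ndarray
    decision_margin: float = 0.0
    training_accuracy: float = float("nan")

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)
        n_feat = len(FEATURE_NAMES)
        if self.weights.shape != (len(self.class_names), n_feat):
            raise ValueError("weights must be (n_classes, 28)")
        if np.any(self.feature_sds <= 0):
            raise ValueError("feature_sds must be positive")
        if self.decision_margin < 0:
            raise ValueError("decision_margin must be >= 0")

    def scores(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.feature_means) / self.feature_sds
        return Xs @ self.weights.T + self.biases

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        payload = {
            "class_names": self.class_names,
            "weights": self.weights.tolist(),
            "biases": self.biases.tolist(),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "decision_margin": self.decision_margin,
            "training_accuracy": self.training_accuracy,
            "feature_names": list(FEATURE_NAMES),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "ShapeClassifier":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        if payload.get("feature_names") != list(FEATURE_NAMES):
            raise ValueError("classifier was trained with a different feature set")
        return cls(
            class_names=payload["class_names"],
            weights=np.asarray(payload["weights"]),
            biases=np.asarray(payload["biases"]),
            feature_means=np.asarray(payload["feature_means"]),
            feature_sds=np.asarray(payload["feature_sds"]),
            decision_margin=payload["decision_margin"],
            training_accuracy=payload["training_accuracy"],
        )


@dataclass
class PQMS:
    """Population-level quantitative morphological signature."""

    population_id: str
    percentages: Dict[str, float]
    unclassified_pct: float
    n_cells: int

    def __post_init__(self) -> None:
        total = sum(self.percentages.values()) + self.unclassified_pct
        if self.n_cells > 0 and abs(total - 100.0) > 1e-6:
            raise ValueError(f"percentages must sum to 100, got {total}")


@dataclass
class ScreenResult:
    """Replicate-aware hit call for one reagent/library/shape."""

    reagent: str
    library: str
    shape: str
    replicate_zscores: List[float]
    direction: str  # enhancer / suppressor / none
    hit: bool


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {X.shape[1]}")
    return X


def train_classifiers(
    features,
    labels: Sequence[str],
    decision_margin: float = 0.0,
    min_exemplars_per_class: int = 10,
    alpha: float = 1.0,
) -> ShapeClassifier:
    """Fit one-vs-rest ridge discriminants (targets +/-1) on exemplars.

    Deterministic given the exemplar set (closed-form ridge solution);
    training accuracy on the exemplars is stored on the classifier.
    """
    X = _as_matrix(features)
    labels = list(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("labels and features must align")
    class_names = sorted(set(labels))
    if len(class_names) < 2:
        raise TrainingError("need at least 2 classes")
    counts = {c: labels.count(c) for c in class_names}
    small = {c: n for c, n in counts.items() if n < min_exemplars_per_class}
    if small:
        raise TrainingError(
            f"classes with fewer than {min_exemplars_per_class} exemplars: {small}"
        )
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    Xs = (X - means) / sds
    W = np.zeros((len(class_names), X.shape[1]))
    b = np.zeros(len(class_names))
    y = np.asarray(labels)
    for i, c in enumerate(class_names):
        target = np.where(y == c, 1.0, -1.0)
        model = Ridge(alpha=alpha).fit(Xs, target)
        W[i] = model.coef_
        b[i] = model.intercept_
    clf = ShapeClassifier(
        class_names=class_names,
        weights=W,
        biases=b,
        feature_means=means,
        feature_sds=sds,
        decision_margin=decision_margin,
    )
    scores = clf.scores(X)
    pred = np.array(class_names)[scores.argmax(axis=1)]
    clf.training_accuracy = float((pred == y).mean())
    return clf


def classify(features, clf: ShapeClassifier) -> List[str]:
    """Assign each cell to its top-scoring class, or leave it unclassified.

    A cell is assigned when the top score exceeds the runner-up by at least
    ``decision_margin`` and is positive; otherwise it is unclassified.
    """
    X = _as_matrix(features)
    scores = clf.scores(X)
    order = np.argsort(scores, axis=1)
    top = order[:, -1]
    top_score = scores[np.arange(len(X)), top]
    runner = scores[np.arange(len(X)), order[:, -2]]
    out = []
    for i in range(len(X)):
        if top_score[i] > 0 and top_score[i] - runner[i] >= clf.decision_margin and (
            top_score[i] != runner[i]
        ):
            out.append(clf.class_names[top[i]])
        else:
            out.append(UNCLASSIFIED)
    return out


def compute_pqms(
    assignments: Sequence[str],
    population_id: str,
    class_names: Optional[Sequence[str]] = None,
) -> PQMS:
    """Percentage of cells per class (plus the unclassified fraction)."""
    assignments = list(assignments)
    n = len(assignments)
    if n < 1:
        raise ValueError("need at least one cell")
    if class_names is None:
        class_names = sorted({a for a in assignments if a != UNCLASSIFIED})
    pct = {c: 100.0 * assignments.count(c) / n for c in class_names}
    uncl = 100.0 * assignments.count(UNCLASSIFIED) / n
    return PQMS(population_id, pct, uncl, n)


def plate_normalize(values) -> np.ndarray:
    """Z-scores of per-well values against the whole plate (sample sd)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise NormalizationError("need at least 3 wells")
    sd = x.std(ddof=1)
    if sd == 0:
        raise NormalizationError("zero variance across the plate")
    return (x - x.mean()) / sd


def normalize_screen(
    pqms_table: pd.DataFrame,
    shape_columns: Sequence[str],
    include_controls: bool = True,
) -> pd.DataFrame:
    """Per-plate Z-scores of each shape percentage.

    ``pqms_table`` needs columns plate, well, reagent, library, replicate,
    is_control plus one percentage column per shape.  With
    ``include_controls`` off, the plate mean/sd are computed from library
    wells only (controls still receive Z-scores on that scale).
    """
    out = pqms_table.copy()
    for shape in shape_columns:
        zcol = f"z_{shape}"
        out[zcol] = np.nan
        for plate, grp in pqms_table.groupby("plate"):
            ref = grp if include_controls else grp[~grp["is_control"]]
            vals = ref[shape].to_numpy(dtype=float)
            if vals.size < 3:
                raise NormalizationError(f"plate {plate}: need at least 3 wells")
            sd = vals.std(ddof=1)
            if sd == 0:
                raise NormalizationError(f"plate {plate}: zero variance in {shape}")
            out.loc[grp.index, zcol] = (grp[shape] - vals.mean()) / sd
    return out


def call_hits(
    ztable: pd.DataFrame,
    shape_columns: Sequence[str],
    threshold: float = 1.5,
    min_replicates: int = 2,
) -> List[ScreenResult]:
    """Replicate-supported hit calls per reagent and shape.

    A reagent is an enhancer (suppressor) of a shape when at least
    ``min_replicates`` replicate wells have Z >= threshold (<= -threshold);
    conflicting directions that each fall short of ``min_replicates`` do
    not make a hit.  Control wells are excluded.
    """
    results: List[ScreenResult] = []
    lib_col = "library" if "library" in ztable.columns else None
    data = ztable[~ztable.get("is_control", False)] if "is_control" in ztable else ztable
    group_cols = ["reagent"] + ([lib_col] if lib_col else [])
    for key, grp in data.groupby(group_cols, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        reagent = key[0]
        library = key[1] if lib_col else ""
        for shape in shape_columns:
            z = grp[f"z_{shape}"].to_numpy(dtype=float)
            n_up = int((z >= threshold).sum())
            n_dn = int((z <= -threshold).sum())
            if n_up >= min_replicates:
                direction, hit = "enhancer", True
            elif n_dn >= min_replicates:
                direction, hit = "suppressor", True
            else:
                direction, hit = "none", False
            results.append(
                ScreenResult(
                    reagent=reagent,
                    library=library,
                    shape=shape,
                    replicate_zscores=[float(v) for v in z],
                    direction=direction,
                    hit=hit,
                )
            )
    return results


def hit_reagents(results: Iterable[ScreenResult]) -> set:
    return {r.reagent for r in results if r.hit}


def intersect_libraries(
    results_a: Iterable[ScreenResult], results_b: Iterable[ScreenResult]
) -> List[str]:
    """Reagents that are a hit (any shape) in both libraries."""
    return sorted(hit_reagents(results_a) & hit_reagents(results_b))
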