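"""ROI-based class comparison and whole-slide classification.

Labeled regions of interest (ROIs) supply class-tagged peak-area rows; peaks
are filtered by ROC AUC (> 0.75 by default), candidate classifiers are
trained on the standardized areas, the model with the highest
cross-validated recognition capability (per-class percent correct) is
selected, and every retained pixel of a slide is assigned a class — or
UNCLASSIFIED when the top-class confidence falls below the rejection
threshold.  Picked peaks are annotated against a protein-mass table at a
+/- 1 Da tolerance.

Two classifier kinds are provided:

* ``snn`` — a single-hidden-layer feed-forward network (hidden size
  2 x n_peaks, logistic activations, full-batch L-BFGS training, seeded) on
  standardized peak areas;
* ``quick`` — a weighted nearest-centroid rule whose per-peak weights are
  proportional to the between-/within-class variance ratio (normalized to
  sum 1), mirroring fast univariate-weighted classifiers used with
  profile-spectrum software.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .imsproc import IMSDataset, PeakMatrix, PeakWindow, integrate_endpoint

__all__ = [
    "ROI",
    "ROCResult",
    "TrainedModel",
    "SegmentationMap",
    "UNCLASSIFIED",
    "extract_roi_matrix",
    "roc_auc",
    "select_discriminative",
    "train_model",
    "recognition_capability",
    "select_best_model",
    "classify_map",
    "annotate_peaks",
    "load_protein_table",
]

UNCLASSIFIED = "UNCLASSIFIED"
_CONF_EPS = 1e-9  # posterior clipped below 1 so threshold=1.0 rejects everything


@dataclass
class ROI:
    """A labeled set of pixel coordinates."""

    label: str
    pixels: set[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("ROI label must be nonempty")
        if not self.pixels:
            raise ValueError("ROI has no pixels")


@dataclass
class ROCResult:
    peak_label: str
    auc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC out of [0, 1]")


def extract_roi_matrix(
    ds: IMSDataset, rois: Sequence[ROI], windows: Sequence[PeakWindow]
) -> PeakMatrix:
    """Peak matrix restricted to ROI pixels, rows labeled by ROI class.

    ROIs must be pairwise disjoint and lie within the slide grid; pixels
    excluded upstream (e.g. null spectra) are silently absent from the rows.
    """
    seen: set[tuple[int, int]] = set()
    nx, ny = ds.grid_shape
    for roi in rois:
        if seen & roi.pixels:
            raise ValueError("ROIs overlap")
        for x, y in roi.pixels:
            if not (0 <= x < nx and 0 <= y < ny):
                raise ValueError(f"ROI pixel {(x, y)} outside grid {ds.grid_shape}")
        seen |= roi.pixels
    rows, classes, index = [], [], []
    for roi in rois:
        for xy in sorted(roi.pixels):
            if xy not in ds.pixels:
                continue  # excluded upstream
            s = ds.pixels[xy]
            rows.append([integrate_endpoint(s, w) for w in windows])
            classes.append(roi.label)
            index.append(xy)
    df = pd.DataFrame(rows, index=index, columns=[w.label for w in windows])
    return PeakMatrix(df, pd.Series(classes, index=index))


def roc_auc(
    values: Sequence[float],
    labels: Sequence[object],
    positive: object | None = None,
    peak_label: str = "",
) -> ROCResult:
    """ROC AUC of one peak: (concordant pairs + 0.5 x ties) / (n1 x n0).

    The positive class defaults to the class with the higher mean value.
    The AUC is reported as computed — never flipped to max(AUC, 1 - AUC).
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    classes = np.unique(lab)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    if positive is None:
        means = {c: v[lab == c].mean() for c in classes}
        positive = max(classes, key=lambda c: means[c])
    y = (lab == positive).astype(int)
    return ROCResult(peak_label, float(roc_auc_score(y, v)))


def select_discriminative(
    rocs: Sequence[ROCResult], threshold: float = 0.75
) -> list[str]:
    """Peak labels with AUC strictly above the threshold."""
    return [r.peak_label for r in rocs if r.auc > threshold]


@dataclass
class TrainedModel:
    """A fitted classifier over a fixed peak-window feature set."""

    kind: str                              # "snn" | "quick"
    peak_labels: list[str]
    classes: list[str]
    weights: np.ndarray                    # per-peak importance, sums to 1
    confidence_threshold: float = 0.5
    seed: int = 0
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None
    _mlp: MLPClassifier | None = field(default=None, repr=False)
    centroids: np.ndarray | None = None    # (n_classes, n_peaks), standardized

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_scale

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = self._standardize(np.asarray(X, dtype=float))
        if self.kind == "snn":
            return self._mlp.predict_proba(Z)
        d2 = ((Z[:, None, :] - self.centroids[None, :, :]) ** 2 * self.weights).sum(
            axis=2
        )
        logits = -d2
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)
        return np.asarray(self.classes)[p.argmax(axis=1)]

    def to_json(self, path: str | Path) -> None:
        """Serialize to a versioned plain-text JSON file."""
        obj = {
            "format": "ploidyims-model-1",
            "kind": self.kind,
            "peak_labels": self.peak_labels,
            "classes": self.classes,
            "weights": self.weights.tolist(),
            "confidence_threshold": self.confidence_threshold,
            "seed": self.seed,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
        }
        if self.kind == "quick":
            obj["centroids"] = self.centroids.tolist()
        else:
            obj["mlp"] = {
                "coefs": [c.tolist() for c in self._mlp.coefs_],
                "intercepts": [b.tolist() for b in self._mlp.intercepts_],
            }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        obj = json.loads(Path(path).read_text())
        if obj.get("format") != "ploidyims-model-1":
            raise ValueError("unrecognized model format")
        model = cls(
            kind=obj["kind"],
            peak_labels=obj["peak_labels"],
            classes=obj["classes"],
            weights=np.asarray(obj["weights"]),
            confidence_threshold=obj["confidence_threshold"],
            seed=obj["seed"],
            scaler_mean=np.asarray(obj["scaler_mean"]),
            scaler_scale=np.asarray(obj["scaler_scale"]),
        )
        if model.kind == "quick":
            model.centroids = np.asarray(obj["centroids"])
        else:
            import warnings

            mlp = _make_mlp(len(model.peak_labels), model.seed)
            mlp.set_params(max_iter=1)
            # one-step fit on dummy rows builds sklearn internals
            # (label binarizer, output activation); weights are then restored
            Xd = np.tile(np.eye(len(model.classes), len(model.peak_labels)), (2, 1))
            yd = np.tile(model.classes, 2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mlp.fit(Xd, yd)
            mlp.set_params(max_iter=2000)
            mlp.coefs_ = [np.asarray(c) for c in obj["mlp"]["coefs"]]
            mlp.intercepts_ = [np.asarray(b) for b in obj["mlp"]["intercepts"]]
            model._mlp = mlp
        return model


def _make_mlp(n_features: int, seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(2 * n_features,),
        activation="logistic",
        solver="lbfgs",
        max_iter=2000,
        tol=1e-6,
        random_state=seed,
    )


def _fisher_weights(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature between/within class variance ratio, normalized to sum 1."""
    classes = np.unique(y)
    overall = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        between += Xc.shape[0] * (Xc.mean(axis=0) - overall) ** 2
        within += ((Xc - Xc.mean(axis=0)) ** 2).sum(axis=0)
    # a zero within-class variance means perfect separation on that feature;
    # floor it relative to the between-class spread to keep ratios finite
    floor = 1e-12 * np.maximum(between, 1.0)
    w = between / np.maximum(within, floor)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate classes: no between-class variance")
    return w / total


def train_model(
    matrix: PeakMatrix,
    kind: str = "snn",
    seed: int = 0,
    confidence_threshold: float = 0.5,
) -> TrainedModel:
    """Fit one classifier kind on a labeled peak matrix.

    Requires >= 2 classes with >= 5 rows each.  Training is deterministic
    given the seed.  The stored per-peak weights are the normalized
    between/within variance ratios (quick) or normalized mean absolute
    first-layer weights (snn).
    """
    X, y = matrix.to_arrays()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 5:
        raise ValueError("need at least 5 rows per class")
    if np.all(X.std(axis=0) == 0):
        raise ValueError("degenerate data: zero variance in all features")
    scaler = StandardScaler().fit(X)
    scaler.scale_ = np.where(scaler.scale_ <= 0, 1.0, scaler.scale_)
    Z = (X - scaler.mean_) / scaler.scale_
    model = TrainedModel(
        kind=kind,
        peak_labels=matrix.labels,
        classes=[str(c) for c in classes],
        weights=np.ones(X.shape[1]) / X.shape[1],
        confidence_threshold=confidence_threshold,
        seed=seed,
        scaler_mean=scaler.mean_,
        scaler_scale=scaler.scale_,
    )
    if kind == "snn":
        mlp = _make_mlp(X.shape[1], seed)
        mlp.fit(Z, y.astype(str))
        model._mlp = mlp
        model.classes = [str(c) for c in mlp.classes_]
        w = np.abs(mlp.coefs_[0]).mean(axis=1)
        model.weights = w / w.sum()
    elif kind == "quick":
        model.weights = _fisher_weights(Z, y)
        model.centroids = np.vstack(
            [Z[y == c].mean(axis=0) for c in classes]
        )
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    return model


def recognition_capability(
    model: TrainedModel,
    matrix: PeakMatrix,
    folds: int = 5,
    seed: int | None = None,
) -> dict[str, float]:
    """Stratified cross-validated per-class percent correct, plus 'overall'.

    The model argument supplies the classifier kind and hyperparameters; a
    fresh instance is retrained on each training fold.  'overall' is the
    unweighted mean of the per-class rates.
    """
    X, y = matrix.to_arrays()
    y = y.astype(str)
    classes, counts = np.unique(y, return_counts=True)
    if set(model.classes) - set(classes):
        raise ValueError("labeled matrix does not cover all model classes")
    if folds > counts.min():
        raise ValueError(f"folds={folds} exceeds smallest class size {counts.min()}")
    skf = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=model.seed if seed is None else seed
    )
    classes = [str(c) for c in classes]
    correct = {c: 0 for c in classes}
    total = {c: 0 for c in classes}
    for train_idx, test_idx in skf.split(X, y):
        sub = PeakMatrix(
            matrix.values.iloc[train_idx],
            matrix.row_class.iloc[train_idx],
        )
        fold_model = train_model(
            sub, model.kind, model.seed, model.confidence_threshold
        )
        pred = fold_model.predict(X[test_idx])
        for yt, yp in zip(y[test_idx], pred):
            total[yt] += 1
            correct[yt] += int(yt == yp)
    out = {c: 100.0 * correct[c] / total[c] for c in classes}
    out["overall"] = float(np.mean([out[c] for c in classes]))
    return out


def apparent_recognition(model: TrainedModel, matrix: PeakMatrix) -> dict[str, float]:
    """Per-class percent correct of a fixed model on a labeled matrix."""
    X, y = matrix.to_arrays()
    y = y.astype(str)
    pred = model.predict(X)
    out = {}
    for c in np.unique(y):
        sel = y == c
        out[str(c)] = 100.0 * float(np.mean(pred[sel] == c))
    out["overall"] = float(np.mean([v for k, v in out.items() if k != "overall"]))
    return out


def select_best_model(
    candidates: Sequence[TrainedModel], matrix: PeakMatrix, folds: int = 5
) -> TrainedModel:
    """Candidate with the highest overall recognition capability; ties -> snn."""
    if not candidates:
        raise ValueError("no candidate models")
    scored = []
    for m in candidates:
        rc = recognition_capability(m, matrix, folds=folds)
        scored.append((rc["overall"], 1 if m.kind == "snn" else 0, m))
    scored.sort(key=lambda t: (t[0], t[1]), reverse=True)
    return scored[0][2]


@dataclass
class SegmentationMap:
    """Per-pixel class assignment with confidence; UNCLASSIFIED on rejection."""

    assignments: dict[tuple[int, int], str]
    confidence: dict[tuple[int, int], float]
    classes: list[str]

    def as_dataframe(self) -> pd.DataFrame:
        rows = [
            {"x": x, "y": y, "class": c, "confidence": self.confidence[(x, y)]}
            for (x, y), c in sorted(self.assignments.items())
        ]
        return pd.DataFrame(rows)


def classify_map(
    model: TrainedModel,
    ds: IMSDataset,
    windows: Sequence[PeakWindow],
) -> SegmentationMap:
    """Classify every grid pixel of a preprocessed slide.

    Retained pixels get the argmax class when the top posterior reaches the
    model's confidence threshold, otherwise UNCLASSIFIED; pixels excluded
    upstream are UNCLASSIFIED with confidence 0.
    """
    labels = [w.label for w in windows]
    if labels != model.peak_labels:
        raise ValueError("window labels do not match the model's feature set")
    assignments: dict[tuple[int, int], str] = {}
    confidence: dict[tuple[int, int], float] = {}
    keys = sorted(ds.pixels)
    if keys:
        X = np.array(
            [[integrate_endpoint(ds.pixels[k], w) for w in windows] for k in keys]
        )
        proba = model.predict_proba(X)
        conf = np.minimum(proba.max(axis=1), 1.0 - _CONF_EPS)
        pred = np.asarray(model.classes)[proba.argmax(axis=1)]
        for k, c, p in zip(keys, pred, conf):
            if p < model.confidence_threshold:
                assignments[k] = UNCLASSIFIED
            else:
                assignments[k] = str(c)
            confidence[k] = float(p)
    for k in ds.excluded:
        assignments[k] = UNCLASSIFIED
        confidence[k] = 0.0
    return SegmentationMap(assignments, confidence, list(model.classes))


# ---------------------------------------------------------------------------
# peak annotation


def load_protein_table(path: str | Path | None = None) -> list[tuple[str, str, float]]:
    """Protein-mass lookup rows (name, accession, mass in Da).

    Defaults to the bundled fixture of single-hit identifications from the
    study's peak tables (thymosin beta-4 at 4,761.42 and 4,977.49 Da;
    14-3-3 sigma at 3,376.60 Da).
    """
    if path is None:
        ref = resources.files("ploidyims.fixtures") / "protein_masses.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    rows = []
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        rows.append((row["name"], row["accession"], float(row["mass_da"])))
    return rows


def annotate_peaks(
    peaks: Sequence[tuple[str, float]],
    protein_table: Sequence[tuple[str, str, float]],
    tol: float = 1.0,
) -> dict[str, list[tuple[str, str, float, float]]]:
    """Match peaks to proteins within +/- tol Da.

    For each (label, m/z) peak, returns every protein whose mass lies within
    ``tol`` of the peak, sorted by |delta mass|; empty lists are allowed.
    """
    out: dict[str, list[tuple[str, str, float, float]]] = {}
    for label, mz in peaks:
        if mz <= 0:
            raise ValueError("peak masses must be positive")
        hits = []
        for name, acc, mass in protein_table:
            dm = abs(mz - mass)
            if dm <= tol:
                hits.append((name, acc, mass, dm))
        hits.sort(key=lambda h: h[3])
        out[label] = hits
    return out
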