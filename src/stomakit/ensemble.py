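"""Nine-classifier ensemble producing per-pixel stoma-probability maps.

The training set pairs circular-FFT/PCA feature vectors of disks centered
on annotated stomata (label 1) with background disks sampled away from
any annotation (label 0).  Nine learner kinds — a single-hidden-layer
perceptron, linear discriminant analysis, a small 1-D convolutional net
over the score sequence, logistic regressions without penalty and with
ridge/lasso penalties, partial least squares regression, forward-stepwise
linear regression selected by BIC, and a decision tree — each fit the
same feature set and each emit a probability map over the image: the
probability, per pixel, that a disk centered there contains a stoma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .features import DiskSpec, PCABasis, features_at_points, grid_features, project
from .synthetic import AnnotationSet

logger = logging.getLogger(__name__)

__all__ = [
    "LEARNER_KINDS",
    "TrainingSet",
    "build_training_set",
    "train_learner",
    "predict_map",
]

LEARNER_KINDS = (
    "ann",
    "lda",
    "cnn1d",
    "glm",
    "glm_ridge",
    "glm_lasso",
    "plsr",
    "stepwise",
    "tree",
)


@dataclass
class TrainingSet:
    """PCA-score rows with binary labels and per-row provenance."""

    X: np.ndarray
    y: np.ndarray
    provenance: list[tuple[str, float, float]]
    seed: int

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if not (len(self.X) == len(self.y) == len(self.provenance)):
            raise ValueError("features, labels and provenance must align")


def build_training_set(
    images: dict[str, np.ndarray],
    annotations: dict[str, AnnotationSet],
    negatives_per_positive: int = 3,
    min_neg_distance_px: float | None = None,
    spec: DiskSpec = DiskSpec(),
    basis: PCABasis | None = None,
    seed: int = 0,
    encoding: str = "weighted",
) -> TrainingSet:
    """Assemble labeled disks: one positive per usable annotation, plus
    uniformly sampled background disks at least ``min_neg_distance_px``
    from every annotation (default: the disk radius).

    Annotations whose disk does not fit in the image are skipped with a
    warning.  When ``basis`` is None the raw flattened features are
    returned (useful for fitting the basis itself).
    """
    if min_neg_distance_px is None:
        min_neg_distance_px = float(spec.radius_px)
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    labels: list[int] = []
    provenance: list[tuple[str, float, float]] = []
    r = spec.radius_px
    for image_id in sorted(images):
        image = images[image_id]
        ann = annotations.get(image_id)
        pts = ann.points if ann is not None else np.empty((0, 2))
        h, w = image.shape
        usable = []
        for x, y in pts:
            ix, iy = int(round(x)), int(round(y))
            if r <= ix <= w - r and r <= iy <= h - r:
                usable.append((ix, iy))
            else:
                logger.warning(
                    "annotation (%s, %s) in %s too close to border; skipped", x, y, image_id
                )
        n_neg = len(usable) * negatives_per_positive
        negs: list[tuple[int, int]] = []
        attempts = 0
        max_attempts = max(200 * (n_neg + 1), 1000)
        while len(negs) < n_neg and attempts < max_attempts:
            attempts += 1
            nx = int(rng.integers(r, w - r + 1))
            ny = int(rng.integers(r, h - r + 1))
            if len(pts) == 0 or np.hypot(pts[:, 0] - nx, pts[:, 1] - ny).min() >= min_neg_distance_px:
                negs.append((nx, ny))
        if len(negs) < n_neg:
            raise ValueError(
                f"could not sample {n_neg} background disks in {image_id} at "
                f"min distance {min_neg_distance_px}px"
            )
        centers = np.array(usable + negs, dtype=float).reshape(-1, 2)
        if len(centers) == 0:
            continue
        feats = features_at_points(image, centers, spec, encoding=encoding)
        rows.append(feats)
        labels.extend([1] * len(usable) + [0] * len(negs))
        provenance.extend((image_id, float(c[0]), float(c[1])) for c in centers)
    if not rows:
        raise ValueError("no usable annotations: empty training set")
    X = np.vstack(rows)
    if basis is not None:
        X = project(X, basis)
    return TrainingSet(X=X, y=np.array(labels), provenance=provenance, seed=seed)


# ---------------------------------------------------------------------------
# Learners


class _ClipRegressorProba:
    """Adapt a regressor fitted on 0/1 labels to the predict_proba contract."""

    def __init__(self, model):
        self.model = model

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        p = np.asarray(self.model.predict(X), dtype=float).ravel()
        return np.clip(p, 0.0, 1.0)


class _ClassifierProba:
    def __init__(self, model):
        self.model = model

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        proba = self.model.predict_proba(X)
        idx = list(self.model.classes_).index(1)
        return proba[:, idx]


class StepwiseBIC:
    """Forward-stepwise linear probability model selected by BIC.

    Scans candidate columns (capped at ``max_scan`` for tractability),
    adding the regressor that most lowers the Gaussian BIC until no
    addition improves it or ``max_features`` is reached.
    """

    def __init__(self, max_features: int = 15, max_scan: int = 40):
        self.max_features = max_features
        self.max_scan = max_scan

    @staticmethod
    def _bic(y: np.ndarray, resid: np.ndarray, k: int) -> float:
        n = len(y)
        rss = float(resid @ resid)
        rss = max(rss, 1e-12)
        return n * np.log(rss / n) + k * np.log(n)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "StepwiseBIC":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        scan = min(p, self.max_scan)
        selected: list[int] = []
        ones = np.ones((n, 1))
        best_bic = self._bic(y, y - y.mean(), k=1)
        coef = np.array([y.mean()])
        while len(selected) < min(self.max_features, scan):
            best_j, best_trial = None, None
            for j in range(scan):
                if j in selected:
                    continue
                cols = np.hstack([ones, X[:, selected + [j]]])
                beta, *_ = np.linalg.lstsq(cols, y, rcond=None)
                bic = self._bic(y, y - cols @ beta, k=cols.shape[1] + 1)
                if bic < best_bic - 1e-10:
                    best_bic, best_j, best_trial = bic, j, beta
            if best_j is None:
                break
            selected.append(best_j)
            coef = best_trial
        self.selected_ = selected
        self.coef_ = coef
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        cols = np.hstack([np.ones((len(X), 1)), X[:, self.selected_]])
        return cols @ self.coef_


class Conv1DNet:
    """Small 1-D convolutional classifier over the score sequence.

    conv(kernel 5, ``n_filters`` channels) → ReLU → global average pool →
    logistic readout, trained by mini-batch Adam on the log-loss.  Written
    in numpy; deterministic given ``seed``.
    """

    def __init__(
        self,
        n_filters: int = 8,
        kernel: int = 5,
        epochs: int = 60,
        batch: int = 64,
        lr: float = 0.01,
        seed: int = 0,
    ):
        self.n_filters = n_filters
        self.kernel = kernel
        self.epochs = epochs
        self.batch = batch
        self.lr = lr
        self.seed = seed

    def _forward(self, X: np.ndarray):
        # X: (n, L); conv valid-mode via stacked shifted views
        n, L = X.shape
        k = self.kernel
        Lo = L - k + 1
        windows = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)  # (n, Lo, k)
        z = windows @ self.W.T + self.b  # (n, Lo, F)
        a = np.maximum(z, 0.0)
        pooled = a.mean(axis=1)  # (n, F)
        logit = pooled @ self.v + self.c
        p = 1.0 / (1.0 + np.exp(-logit))
        return windows, z, a, pooled, p

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Conv1DNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, L = X.shape
        if L < self.kernel:
            self.kernel = max(1, L)
        rng = np.random.default_rng(self.seed)
        k, F = self.kernel, self.n_filters
        self.W = rng.normal(0, 1.0 / np.sqrt(k), size=(F, k))
        self.b = np.zeros(F)
        self.v = rng.normal(0, 1.0 / np.sqrt(F), size=F)
        self.c = 0.0
        params = ["W", "b", "v", "c"]
        m = {p: np.zeros_like(np.asarray(getattr(self, p), dtype=float)) for p in params}
        u = {p: np.zeros_like(np.asarray(getattr(self, p), dtype=float)) for p in params}
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch):
                idx = order[start : start + self.batch]
                Xb, yb = X[idx], y[idx]
                windows, z, a, pooled, p = self._forward(Xb)
                nb, Lo = z.shape[0], z.shape[1]
                dlogit = (p - yb) / nb  # (nb,)
                gv = pooled.T @ dlogit
                gc = dlogit.sum()
                dpooled = np.outer(dlogit, self.v)  # (nb, F)
                da = np.repeat(dpooled[:, None, :], Lo, axis=1) / Lo
                dz = da * (z > 0)
                gW = np.einsum("nlf,nlk->fk", dz, windows)
                gb = dz.sum(axis=(0, 1))
                grads = {"W": gW, "b": gb, "v": gv, "c": gc}
                t += 1
                for pname in params:
                    g = grads[pname]
                    m[pname] = b1 * m[pname] + (1 - b1) * g
                    u[pname] = b2 * u[pname] + (1 - b2) * np.square(g)
                    mhat = m[pname] / (1 - b1**t)
                    uhat = u[pname] / (1 - b2**t)
                    val = np.asarray(getattr(self, pname), dtype=float)
                    val = val - self.lr * mhat / (np.sqrt(uhat) + eps)
                    setattr(self, pname, val if val.ndim else float(val))
        return self

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._forward(X)[-1]


def _make_learner(kind: str, seed: int):
    if kind == "ann":
        return _ClassifierProba(
            MLPClassifier(hidden_layer_sizes=(32,), max_iter=400, random_state=seed)
        )
    if kind == "lda":
        return _ClassifierProba(LinearDiscriminantAnalysis())
    if kind == "cnn1d":
        return Conv1DNet(seed=seed)
    if kind == "glm":
        return _ClassifierProba(LogisticRegression(penalty=None, max_iter=2000))
    if kind == "glm_ridge":
        return _ClassifierProba(
            LogisticRegressionCV(Cs=7, penalty="l2", cv=3, max_iter=2000, random_state=seed)
        )
    if kind == "glm_lasso":
        return _ClassifierProba(
            LogisticRegressionCV(
                Cs=7, penalty="l1", solver="liblinear", cv=3, max_iter=2000, random_state=seed
            )
        )
    if kind == "plsr":
        return _ClipRegressorProba(PLSRegression(n_components=5))
    if kind == "stepwise":
        return _ClipRegressorProba(StepwiseBIC())
    if kind == "tree":
        return _ClassifierProba(
            DecisionTreeClassifier(min_samples_leaf=5, random_state=seed)
        )
    raise ValueError(f"unknown learner kind {kind!r}; expected one of {LEARNER_KINDS}")


@dataclass
class FittedLearner:
    kind: str
    model: object

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        p = self.model.predict_proba_pos(np.asarray(X, dtype=float))
        return np.clip(p, 0.0, 1.0)


def train_learner(kind: str, training: TrainingSet) -> FittedLearner:
    """Fit one learner kind on a training set; both classes must be present."""
    classes = set(np.unique(training.y))
    if classes != {0, 1}:
        raise ValueError(f"training set must contain both classes, got labels {classes}")
    learner = _make_learner(kind, training.seed)
    inner = learner.model if hasattr(learner, "model") else learner
    if kind == "plsr":
        n_comp = min(5, training.X.shape[1], len(training.X) - 1)
        inner.set_params(n_components=n_comp)
    if kind in ("plsr", "stepwise"):
        inner.fit(training.X, training.y.astype(float))
    else:
        inner.fit(training.X, training.y)
    return FittedLearner(kind=kind, model=learner if kind != "cnn1d" else inner)


def _upsample_grid(
    probs: np.ndarray, gx: np.ndarray, gy: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Bilinear upsampling of grid probabilities to full resolution; the
    border band where no disk fits stays 0."""
    h, w = shape
    out = np.zeros((h, w), dtype=np.float32)
    interp = RegularGridInterpolator(
        (gy.astype(float), gx.astype(float)),
        np.asarray(probs, dtype=float),
        method="linear",
        bounds_error=False,
        fill_value=0.0,
    )
    yy = np.arange(gy[0], gy[-1] + 1)
    xx = np.arange(gx[0], gx[-1] + 1)
    pts_y, pts_x = np.meshgrid(yy, xx, indexing="ij")
    vals = interp(np.stack([pts_y.ravel(), pts_x.ravel()], axis=1).astype(float))
    out[gy[0] : gy[-1] + 1, gx[0] : gx[-1] + 1] = vals.reshape(len(yy), len(xx))
    return np.clip(out, 0.0, 1.0)


def predict_maps(
    models: dict[str, FittedLearner],
    image: np.ndarray,
    spec: DiskSpec = DiskSpec(),
    basis: PCABasis | None = None,
    stride_px: int = 2,
    encoding: str = "weighted",
) -> dict[str, np.ndarray]:
    """Probability maps for several learners sharing one feature pass.

    Features are computed once on the stride-spaced grid of valid disk
    centers, projected once, then every learner scores the same matrix;
    each map is bilinearly upsampled to full resolution with a zero
    border band.
    """
    gx, gy, feats = grid_features(image, spec, stride_px, encoding=encoding)
    ny, nx = feats.shape[:2]
    X = feats.reshape(ny * nx, -1)
    if basis is not None:
        # single-precision projection: the feature pass is float32 anyway
        X = (X - basis.mean.astype(np.float32)) @ basis.components.astype(np.float32)
    out = {}
    for name, model in models.items():
        probs = model.predict_proba_pos(X).reshape(ny, nx)
        out[name] = _upsample_grid(probs, gx, gy, image.shape)
    return out


def predict_map(
    model: FittedLearner,
    image: np.ndarray,
    spec: DiskSpec = DiskSpec(),
    basis: PCABasis | None = None,
    stride_px: int = 2,
    encoding: str = "weighted",
) -> np.ndarray:
    """Per-pixel stoma-probability map for one image (single learner)."""
    return predict_maps({"m": model}, image, spec, basis, stride_px, encoding)["m"]
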