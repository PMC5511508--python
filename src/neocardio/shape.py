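"""Statistical shape modelling of 4-chamber ventricular contours.

Pipeline: arc-length resampling for point correspondence, generalized
Procrustes alignment (translation + rotation; scale retained by default so
overall size emerges as the first principal mode), a point-distribution
model (PCA of the aligned coordinates), per-mode two-sample tests, and a
linear discriminant over a selected subset of modes.  Mode 1 -- size -- is
excluded from discrimination; nested subsets {2}, {2,3}, ... are scored by
leave-one-out cross-validated AUC and the smallest subset within tolerance
of the maximum is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from sklearn.base import BaseEstimator, TransformerMixin

from .contours import ContourSet, resample_polyline

__all__ = [
    "AlignedShapeSet",
    "ProcrustesAligner",
    "PointDistributionModel",
    "ShapeLDA",
    "resample_contour",
    "generalized_procrustes",
    "fit_pdm",
    "project",
    "reconstruct",
    "per_mode_group_test",
    "train_lda",
    "loo_auc",
    "select_mode_subset",
    "mann_whitney_auc",
    "kabsch_rotation_2d",
    "centroid_size",
]


# ---------------------------------------------------------------------------
# correspondence
# ---------------------------------------------------------------------------

def resample_contour(contour: ContourSet, n_points: int) -> ContourSet:
    """Resample to n_points equally spaced in arc length, corner to corner.

    Landmarks are preserved: corners at indices 0 and n-1; the apex landmark
    is moved to the resampled point nearest the original apex.
    """
    if n_points < 20:
        raise ValueError("n_points must be >= 20")
    pts = resample_polyline(contour.points, n_points)
    apex_old = contour.points[contour.landmarks["apex"]]
    apex_new = int(np.argmin(np.linalg.norm(pts - apex_old, axis=1)))
    return ContourSet(pts, contour.border,
                      {"corner_a": 0, "apex": apex_new, "corner_b": n_points - 1})


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def centroid_size(shape: np.ndarray) -> float:
    """Root-sum-of-squares distance of points from their centroid."""
    c = shape - shape.mean(axis=0)
    return float(np.sqrt(np.sum(c ** 2)))


def kabsch_rotation_2d(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (det = +1) aligning centred source to target."""
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


@dataclass
class AlignedShapeSet:
    """Shapes after correspondence and alignment: (n_shapes, n_points, 2)."""

    shapes: np.ndarray
    rotations: np.ndarray
    translations: np.ndarray
    scale_retained: bool
    scales: np.ndarray | None = None
    n_iter: int = 0

    @property
    def mean_shape(self) -> np.ndarray:
        return self.shapes.mean(axis=0)


class ProcrustesAligner(TransformerMixin, BaseEstimator):
    """Generalized Procrustes alignment (translation + rotation, optionally
    scale) of equal-point-count 2D shapes.

    Iterates rotation of every shape to the evolving mean until the mean
    changes by less than tol (Frobenius norm) or max_iter is reached.
    Reflections are never applied.
    """

    def __init__(self, retain_scale: bool = True, tol: float = 1e-8,
                 max_iter: int = 100):
        self.retain_scale = retain_scale
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, shapes):
        shapes = np.asarray(shapes, dtype=float)
        if shapes.ndim != 3 or shapes.shape[2] != 2:
            raise ValueError("shapes must be (n_shapes, n_points, 2)")
        if shapes.shape[0] < 2:
            raise ValueError("need at least 2 shapes")
        n = shapes.shape[0]
        translations = shapes.mean(axis=1)
        centred = shapes - translations[:, None, :]
        scales = np.array([centroid_size(s) for s in centred])
        if np.any(scales == 0):
            raise ValueError("degenerate shape with zero centroid size")
        work = centred.copy()
        if not self.retain_scale:
            work = work / scales[:, None, None]
        rotations = np.tile(np.eye(2), (n, 1, 1))
        mean = work[0].copy()
        converged = False
        for it in range(1, self.max_iter + 1):
            for i in range(n):
                r = kabsch_rotation_2d(work[i], mean)
                work[i] = work[i] @ r
                rotations[i] = rotations[i] @ r
            new_mean = work.mean(axis=0)
            if not self.retain_scale:
                new_mean /= centroid_size(new_mean)
            delta = float(np.linalg.norm(new_mean - mean))
            mean = new_mean
            if delta < self.tol:
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"Procrustes did not converge in {self.max_iter} iterations "
                f"(last mean change {delta:.3e})")
        self.aligned_ = AlignedShapeSet(
            shapes=work, rotations=rotations, translations=translations,
            scale_retained=self.retain_scale,
            scales=None if self.retain_scale else scales, n_iter=it)
        self.mean_shape_ = mean
        return self

    def transform(self, shapes):
        """Align new shapes to the fitted mean (translation + rotation)."""
        shapes = np.asarray(shapes, dtype=float)
        single = shapes.ndim == 2
        if single:
            shapes = shapes[None]
        out = np.empty_like(shapes)
        for i, s in enumerate(shapes):
            c = s - s.mean(axis=0)
            if not self.retain_scale:
                c = c / centroid_size(c)
            out[i] = c @ kabsch_rotation_2d(c, self.mean_shape_)
        return out[0] if single else out


# ---------------------------------------------------------------------------
# point distribution model
# ---------------------------------------------------------------------------

class PointDistributionModel(TransformerMixin, BaseEstimator):
    """PCA of aligned shape coordinates (a point-distribution model).

    Fitted attributes: mean_shape_ (n_points, 2), modes_ (n_modes, 2*n_points)
    orthonormal rows sorted by decreasing eigenvalue, eigenvalues_
    (variances per mode).  Mode signs are oriented so the loading of each
    mode on overall scale is positive (mode 1 then reads as "bigger").
    """

    def __init__(self, n_modes: int | None = None):
        self.n_modes = n_modes

    def fit(self, shapes, y=None):
        if isinstance(shapes, AlignedShapeSet):
            shapes = shapes.shapes
        shapes = np.asarray(shapes, dtype=float)
        if shapes.ndim != 3 or shapes.shape[0] < 3:
            raise ValueError("need an (n_shapes >= 3, n_points, 2) array")
        n, p, _ = shapes.shape
        flat = shapes.reshape(n, -1)
        self.mean_shape_ = flat.mean(axis=0).reshape(p, 2)
        x = flat - flat.mean(axis=0)
        cov = x.T @ x / (n - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.maximum(evals[order], 0.0)
        evecs = evecs[:, order]
        k = self.n_modes or min(n - 1, flat.shape[1])
        evals, evecs = evals[:k], evecs[:, :k]
        # orient each mode so its scale loading is positive: adding the mode
        # should increase centroid size of the mean shape
        centred = (self.mean_shape_ - self.mean_shape_.mean(axis=0)).reshape(-1)
        for j in range(evecs.shape[1]):
            if float(centred @ evecs[:, j]) < 0:
                evecs[:, j] = -evecs[:, j]
        self.modes_ = evecs.T
        self.eigenvalues_ = evals
        self.total_variance_ = float(np.trace(cov))
        return self

    # -- projection / reconstruction ----------------------------------
    def transform(self, shapes, standardized: bool = False):
        """Mode scores of aligned shapes; raw by default, in SD units when
        standardized=True."""
        single = (np.asarray(shapes).ndim == 2)
        arr = np.asarray(shapes, dtype=float)
        if single:
            arr = arr[None]
        if arr.shape[1:] != self.mean_shape_.shape:
            raise ValueError("point-count mismatch with the fitted model")
        flat = arr.reshape(arr.shape[0], -1) - self.mean_shape_.reshape(-1)
        scores = flat @ self.modes_.T
        if standardized:
            with np.errstate(divide="ignore", invalid="ignore"):
                scores = np.where(self.eigenvalues_ > 0,
                                  scores / np.sqrt(self.eigenvalues_), 0.0)
        return scores[0] if single else scores

    def inverse_transform(self, scores):
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        k = scores.shape[1]
        flat = self.mean_shape_.reshape(-1) + scores @ self.modes_[:k]
        out = flat.reshape(len(scores), *self.mean_shape_.shape)
        return out[0] if out.shape[0] == 1 else out

    def reconstruct(self, standardized_scores, sd_multiple: float = 1.0):
        """Shape at mean + sum_k s_k * sd_multiple * sqrt(lambda_k) * mode_k."""
        s = np.asarray(standardized_scores, dtype=float)
        if s.ndim != 1 or len(s) > len(self.eigenvalues_):
            raise ValueError("scores must be a vector within retained modes")
        raw = s * sd_multiple * np.sqrt(self.eigenvalues_[: len(s)])
        return self.inverse_transform(raw)

    def explained_variance_ratio_(self):
        return self.eigenvalues_ / self.total_variance_


# ---------------------------------------------------------------------------
# group testing and discrimination
# ---------------------------------------------------------------------------

def per_mode_group_test(scores: np.ndarray, labels) -> np.ndarray:
    """Two-sample (Welch) t-test per mode column; returns p-values."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a = scores[labels == groups[0]]
    b = scores[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 shapes")
    pvals = np.empty(scores.shape[1])
    for j in range(scores.shape[1]):
        if np.var(a[:, j]) == 0 and np.var(b[:, j]) == 0:
            raise ValueError(f"zero variance in mode {j + 1}")
        pvals[j] = stats.ttest_ind(a[:, j], b[:, j], equal_var=False).pvalue
    return pvals


def mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic with averaged ties."""
    all_scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_scores)
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


class ShapeLDA(BaseEstimator):
    """Fisher linear discriminant over a subset of PDM mode scores.

    w = (Sigma_pooled + eps*I)^-1 (mu_pos - mu_neg), eps = reg*trace/dim;
    the threshold sits at the midpoint of the projected group means and the
    sign is oriented so the positive class scores higher on average.

    Fitted attributes: coef_, threshold_, auc_ (resubstitution),
    mode_subset_, classes_ (negative, positive).
    """

    def __init__(self, mode_subset=None, reg: float = 1e-6,
                 positive_class=None):
        self.mode_subset = mode_subset
        self.reg = reg
        self.positive_class = positive_class

    def _columns(self, scores):
        if self.mode_subset is None:
            return np.asarray(scores, dtype=float)
        idx = np.asarray(self.mode_subset, dtype=int) - 1  # 1-based mode ids
        return np.asarray(scores, dtype=float)[:, idx]

    def fit(self, scores, labels):
        labels = np.asarray(labels)
        classes = np.unique(labels)
        if len(classes) != 2:
            raise ValueError("ShapeLDA requires exactly two classes")
        pos = self.positive_class if self.positive_class is not None else classes[-1]
        neg = classes[classes != pos][0]
        x = self._columns(scores)
        if x.shape[1] < 1:
            raise ValueError("mode subset must contain at least one mode")
        xp, xn = x[labels == pos], x[labels == neg]
        if len(xp) == 0 or len(xn) == 0:
            raise ValueError("a class is absent from the labels")
        mp, mn = xp.mean(axis=0), xn.mean(axis=0)
        sp = np.cov(xp, rowvar=False, ddof=1) if len(xp) > 1 else np.zeros((x.shape[1],) * 2)
        sn = np.cov(xn, rowvar=False, ddof=1) if len(xn) > 1 else np.zeros((x.shape[1],) * 2)
        sp, sn = np.atleast_2d(sp), np.atleast_2d(sn)
        pooled = ((len(xp) - 1) * sp + (len(xn) - 1) * sn) / max(len(x) - 2, 1)
        eps = self.reg * np.trace(pooled) / pooled.shape[0]
        w = np.linalg.solve(pooled + eps * np.eye(pooled.shape[0]), mp - mn)
        self.coef_ = w
        self.classes_ = (neg, pos)
        self.threshold_ = float(0.5 * (mp + mn) @ w)
        self.auc_ = mann_whitney_auc(xp @ w, xn @ w)
        return self

    def decision_function(self, scores):
        return self._columns(scores) @ self.coef_ - self.threshold_

    def predict(self, scores):
        neg, pos = self.classes_
        return np.where(self.decision_function(scores) > 0, pos, neg)


def loo_auc(scores, labels, mode_subset, reg: float = 1e-6,
            positive_class=None) -> float:
    """Leave-one-out cross-validated AUC of the mode-subset LDA."""
    labels = np.asarray(labels)
    n = len(labels)
    held = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        lda = ShapeLDA(mode_subset=mode_subset, reg=reg,
                       positive_class=positive_class)
        lda.fit(np.asarray(scores)[mask], labels[mask])
        held[i] = lda.decision_function(np.asarray(scores)[i: i + 1])[0]
    pos = positive_class if positive_class is not None else np.unique(labels)[-1]
    return mann_whitney_auc(held[labels == pos], held[labels != pos])


def select_mode_subset(scores, labels, max_mode: int, tol: float = 0.005,
                       reg: float = 1e-6, positive_class=None):
    """Evaluate nested subsets {2}, {2,3}, ..., {2..max_mode} by LOO AUC.

    Mode 1 (size) is excluded.  Returns (best_subset, curve) where curve is
    a list of (subset, loo_auc); the best subset is the smallest one whose
    LOO AUC is within tol of the maximum.
    """
    if max_mode < 2 or max_mode > np.asarray(scores).shape[1]:
        raise ValueError("max_mode must lie in [2, n_modes]")
    curve = []
    for top in range(2, max_mode + 1):
        subset = tuple(range(2, top + 1))
        curve.append((subset, loo_auc(scores, labels, subset, reg=reg,
                                      positive_class=positive_class)))
    best_auc = max(a for _, a in curve)
    for subset, a in curve:
        if a >= best_auc - tol:
            return subset, curve
    return curve[-1][0], curve  # unreachable


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def generalized_procrustes(shapes, retain_scale: bool = True,
                           tol: float = 1e-8,
                           max_iter: int = 100) -> AlignedShapeSet:
    return ProcrustesAligner(retain_scale=retain_scale, tol=tol,
                             max_iter=max_iter).fit(shapes).aligned_


def fit_pdm(aligned) -> PointDistributionModel:
    return PointDistributionModel().fit(aligned)


def project(model: PointDistributionModel, shape, standardized: bool = False):
    return model.transform(shape, standardized=standardized)


def reconstruct(model: PointDistributionModel, standardized_scores,
                sd_multiple: float = 1.0):
    return model.reconstruct(standardized_scores, sd_multiple=sd_multiple)


def train_lda(scores, labels, mode_subset, reg: float = 1e-6,
              positive_class=None) -> ShapeLDA:
    return ShapeLDA(mode_subset=mode_subset, reg=reg,
                    positive_class=positive_class).fit(scores, labels)
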