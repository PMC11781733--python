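"""Gower distances, PCoA / UMAP ordination, LDA and the jackknifed pipelines.

The ordination classifiers follow the canonical-analysis-of-principal-
coordinates recipe: compute Gower dissimilarities on the standardized feature
matrix, reduce with principal coordinate analysis (or, alternatively, UMAP on
the same distances), then run linear discriminant analysis on the retained
coordinates.  Reported accuracy comes from an exhaustive leave-one-out
jackknife; the number of PCoA axes is chosen to maximize that jackknifed
accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import silhouette_score

from .errors import ComputationError, ValidationError
from .matrix import FeatureMatrix
from .metrics import ConfusionMatrix, confusion

log = logging.getLogger(__name__)

_SYM_TOL = 1e-12


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    metric_tag: str = "gower"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix must be square over ids")
        if np.any(np.abs(v - v.T) > _SYM_TOL):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be 0")
        if np.any(v < 0):
            raise ValidationError("distances must be non-negative")
        if self.metric_tag == "gower" and np.any(v > 1 + _SYM_TOL):
            raise ValidationError("gower distances must lie in [0, 1]")
        self.values = v


def _gower_ranges(X: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanmax(X, axis=0) - np.nanmin(X, axis=0)


def gower_distance(m: FeatureMatrix) -> DistanceMatrix:
    """Mean range-normalized absolute difference over jointly observed columns.

    Zero-range (and all-missing) columns are skipped; a pair of rows with no
    jointly observed informative column is an error.
    """
    if m.n_rows < 2:
        raise ValidationError("need at least 2 rows")
    X = m.values
    ranges = _gower_ranges(X)
    usable = np.isfinite(ranges) & (ranges > 0)
    if not usable.any():
        raise ComputationError("no column with positive range")
    Xu = X[:, usable]
    ru = ranges[usable]
    obs = ~np.isnan(Xu)
    diff = np.abs(Xu[:, None, :] - Xu[None, :, :]) / ru  # (n, n, p)
    both = obs[:, None, :] & obs[None, :, :]
    counts = both.sum(axis=2)
    if np.any(counts == 0):
        i, j = map(int, np.argwhere(counts == 0)[0])
        raise ComputationError(
            f"rows {m.row_ids[i]!r} and {m.row_ids[j]!r} share no observed column")
    d = np.where(both, diff, 0.0).sum(axis=2) / counts
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry against float noise
    return DistanceMatrix(list(m.row_ids), np.clip(d, 0.0, 1.0), "gower")


@dataclass
class OrdinationResult:
    ids: list[str]
    coordinates: np.ndarray  # n x m, axes scaled by sqrt(eigenvalue) for PCoA
    eigenvalues: np.ndarray  # descending, retained positive axes (empty for UMAP)
    percent_of_total: np.ndarray  # per-axis % of the positive-eigenvalue sum
    method: str
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))


def pcoa(d: DistanceMatrix, m_axes: int | None = None) -> OrdinationResult:
    """Classical principal coordinate analysis (metric MDS).

    The squared-distance matrix is double-centered (-1/2 J D^2 J) and
    eigendecomposed; axes with positive eigenvalues are retained (up to
    ``m_axes``) and scaled by the square root of their eigenvalue.  Negative
    eigenvalues are reported as diagnostics and excluded from the percent
    denominators; no Cailliez/Lingoes correction is applied.
    """
    D2 = d.values ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12
    pos = eigval > tol
    if not pos.any():
        raise ComputationError("all PCoA eigenvalues are non-positive")
    lam = eigval[pos]
    vec = eigvec[:, pos]
    if m_axes is not None:
        lam, vec = lam[:m_axes], vec[:, :m_axes]
    coords = vec * np.sqrt(lam)
    pct = lam / eigval[eigval > tol].sum() * 100.0
    return OrdinationResult(list(d.ids), coords, lam, pct, "pcoa",
                            negative_eigenvalues=eigval[eigval < -tol])


def pcoa_project(train_d2: np.ndarray, result: OrdinationResult,
                 d_new: np.ndarray) -> np.ndarray:
    """Place a new sample into an existing PCoA space (Gower add-a-point).

    ``train_d2`` is the squared training distance matrix and ``d_new`` the
    distances from the new sample to every training sample.
    """
    delta2 = np.asarray(d_new, dtype=float) ** 2
    row_means = train_d2.mean(axis=1)
    f = -0.5 * (delta2 - row_means - delta2.mean() + train_d2.mean())
    lam = result.eigenvalues
    return (result.coordinates.T @ f) / lam  # = Lambda^{-1/2} V^T f


@dataclass
class LDAModel:
    estimator: LinearDiscriminantAnalysis
    class_labels: list
    canonical_axes: np.ndarray  # feature -> canonical space map
    class_centroids: np.ndarray  # classes x canonical axes
    ellipse_specs: dict = field(default_factory=dict)


def lda_fit(coords: np.ndarray, labels: Sequence,
            *, allow_singleton_class: bool = False) -> LDAModel:
    """Fit a multi-class LDA with equal class priors on ordination coordinates.

    ``allow_singleton_class`` relaxes the two-samples-per-class requirement;
    the jackknife uses it for folds that leave a class with one member.
    """
    coords = np.asarray(coords, dtype=float)
    labels = list(labels)
    classes = sorted(set(labels), key=str)
    if len(classes) < 2:
        raise ValidationError("LDA needs at least 2 classes")
    n, p = coords.shape
    counts = {c: labels.count(c) for c in classes}
    if min(counts.values()) < (1 if allow_singleton_class else 2):
        raise ValidationError("every class needs at least 2 samples")
    if p >= n:
        raise ValidationError("coordinate count must be below sample count")
    if p > n - len(classes) and not allow_singleton_class:
        # strict nonsingularity condition; folds rely on the svd solver's
        # tolerance instead
        raise ComputationError(
            "within-class scatter is singular; use fewer ordination axes")
    est = LinearDiscriminantAnalysis(solver="svd",
                                     priors=np.full(len(classes), 1 / len(classes)))
    y = np.array([str(c) for c in labels])
    est.fit(coords, y)
    canonical = est.scalings_[:, :len(classes) - 1]
    transformed = est.transform(coords)
    centroids = np.vstack([transformed[y == str(c)].mean(axis=0) for c in classes])
    ellipses = {}
    scale = float(np.sqrt(chi2.ppf(0.95, df=2)))
    for c in classes:
        pts = transformed[y == str(c)][:, :2]
        cov = np.cov(pts.T) if pts.shape[0] > 1 and pts.shape[1] == 2 else np.eye(2)
        ellipses[c] = {"center": pts.mean(axis=0), "cov": cov, "radius_scale": scale}
    return LDAModel(est, classes, canonical, centroids, ellipses)


def lda_predict(model: LDAModel, coords: np.ndarray) -> list:
    """Nearest class centroid in canonical space (equal priors)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    transformed = model.estimator.transform(coords)
    d2 = ((transformed[:, None, :] - model.class_centroids[None]) ** 2).sum(axis=2)
    by_str = {str(c): c for c in model.class_labels}
    return [by_str[str(model.class_labels[i])] for i in d2.argmin(axis=1)]


@dataclass
class JackknifeResult:
    ids: list[str]
    predictions: list
    confusion: ConfusionMatrix
    accuracy_unadjusted: float
    accuracy_jackknifed: float
    m_axes_used: int | None = None
    umap_params: dict | None = None


def _reduce(dm: DistanceMatrix, reducer: str, m_axes: int | None,
            umap_params: Mapping | None, seed: int | None) -> np.ndarray:
    if reducer == "pcoa":
        return pcoa(dm, m_axes).coordinates
    if reducer == "umap":
        params = dict(umap_params or {})
        if seed is not None:
            params.setdefault("seed", seed)
        return umap_embed(dm, **params).coordinates
    raise ValidationError(f"unknown reducer {reducer!r}")


def jackknife_pipeline(
    features: FeatureMatrix,
    labels: Sequence,
    reducer: str = "pcoa",
    *,
    m_axes: int | None = None,
    umap_params: Mapping | None = None,
    mode: str = "fast",
    seed: int | None = None,
) -> JackknifeResult:
    """Exhaustive leave-one-out classification through Gower + reduction + LDA.

    ``fast`` (default) reduces once on all samples and refits only the LDA per
    fold.  ``strict`` recomputes Gower and PCoA on the n-1 training samples
    each fold and places the held-out sample by out-of-sample projection;
    it is defined for the PCoA reducer only.
    """
    labels = list(labels)
    n = len(labels)
    k = len(set(labels))
    if n < k + 2:
        raise ValidationError("need at least k+2 samples for the jackknife")
    if mode not in ("fast", "strict"):
        raise ValidationError(f"unknown mode {mode!r}")
    if mode == "strict" and reducer != "pcoa":
        raise ValidationError("strict mode is defined for the pcoa reducer only")
    if m_axes is not None and m_axes >= n - 1:
        raise ValidationError("reducer axes must be below the fold size")

    dm = gower_distance(features)
    preds: list = []
    if mode == "fast":
        coords = _reduce(dm, reducer, m_axes, umap_params, seed)
        model_all = lda_fit(coords, labels, allow_singleton_class=True)
        unadj = [a == b for a, b in zip(lda_predict(model_all, coords), labels)]
        for i in range(n):
            mask = np.arange(n) != i
            model = lda_fit(coords[mask], [l for j, l in enumerate(labels) if j != i],
                            allow_singleton_class=True)
            preds.append(lda_predict(model, coords[i:i + 1])[0])
    else:
        full = pcoa(dm, m_axes)
        model_all = lda_fit(full.coordinates, labels, allow_singleton_class=True)
        unadj = [a == b for a, b in
                 zip(lda_predict(model_all, full.coordinates), labels)]
        for i in range(n):
            keep = [j for j in range(n) if j != i]
            sub = features.select_rows([features.row_ids[j] for j in keep])
            # recompute ranges and distances on the n-1 training rows
            ranges = _gower_ranges(sub.values)
            usable = np.isfinite(ranges) & (ranges > 0)
            dm_tr = gower_distance(sub)
            ord_tr = pcoa(dm_tr, m_axes)
            x_new = features.values[i, usable]
            Xtr = sub.values[:, usable]
            obs = ~np.isnan(Xtr) & ~np.isnan(x_new)
            diff = np.abs(Xtr - x_new) / ranges[usable]
            d_new = np.where(obs, diff, 0.0).sum(axis=1) / obs.sum(axis=1)
            proj = pcoa_project(dm_tr.values ** 2, ord_tr, np.clip(d_new, 0, 1))
            model = lda_fit(ord_tr.coordinates, [labels[j] for j in keep],
                            allow_singleton_class=True)
            preds.append(lda_predict(model, proj[None, :])[0])

    cm = confusion(labels, preds)
    return JackknifeResult(
        ids=list(features.row_ids), predictions=preds, confusion=cm,
        accuracy_unadjusted=float(np.mean(unadj) * 100.0),
        accuracy_jackknifed=float(np.mean([p == l for p, l in zip(preds, labels)]) * 100.0),
        m_axes_used=m_axes, umap_params=dict(umap_params) if umap_params else None)


def select_pcoa_axes(
    features: FeatureMatrix,
    labels: Sequence,
    m_range: Sequence[int] | None = None,
    *,
    mode: str = "fast",
) -> tuple[int, JackknifeResult]:
    """Exhaustive search for the axis count maximizing jackknifed accuracy.

    Ties break toward the smallest axis count.
    """
    n = len(list(labels))
    if m_range is None:
        m_range = range(2, max(min(n - 2, 10), 2) + 1)
    m_range = list(m_range)
    if not m_range:
        raise ValidationError("m_range must be non-empty")
    best: tuple[int, JackknifeResult] | None = None
    for m in m_range:
        try:
            res = jackknife_pipeline(features, labels, "pcoa", m_axes=m, mode=mode)
        except (ValidationError, ComputationError) as exc:
            log.debug("m=%d skipped: %s", m, exc)
            continue
        if best is None or res.accuracy_jackknifed > best[1].accuracy_jackknifed:
            best = (m, res)
    if best is None:
        raise ComputationError("no axis count in m_range produced a valid pipeline")
    return best


def umap_embed(
    d: DistanceMatrix,
    n_neighbors: int = 5,
    min_dist: float = 0.1,
    n_components: int = 2,
    n_iter: int = 100,
    *,
    seed: int,
) -> OrdinationResult:
    """UMAP embedding of a precomputed distance matrix (seed-deterministic)."""
    n = len(d.ids)
    if n_neighbors >= n:
        raise ValidationError("n_neighbors must be below the sample count")
    import umap  # deferred: slow import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = umap.UMAP(metric="precomputed", n_neighbors=n_neighbors,
                        min_dist=min_dist, n_components=n_components,
                        n_epochs=n_iter, random_state=seed).fit_transform(d.values)
    return OrdinationResult(list(d.ids), np.asarray(emb), np.empty(0), np.empty(0),
                            "umap")


def umap_param_search(
    d: DistanceMatrix,
    labels: Sequence,
    grid: Sequence[Mapping],
    *,
    seed: int,
) -> tuple[dict, OrdinationResult, float]:
    """Pick the grid point maximizing mean silhouette over the known classes.

    Cluster separation is scored as the label-aware mean silhouette of the
    embedding; ties go to the first grid point.
    """
    if not grid:
        raise ValidationError("parameter grid must not be empty")
    y = [str(l) for l in labels]
    best = None
    for params in grid:
        emb = umap_embed(d, seed=seed, **params)
        score = float(silhouette_score(emb.coordinates, y))
        if best is None or score > best[2]:
            best = (dict(params), emb, score)
    return best
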