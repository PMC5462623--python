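"""Geometric morphometrics: Procrustes superimposition, allometry, shape PCA.

Raw landmark configurations (specimens x landmarks x 2/3 dims) are turned
into size and shape phenotypes:

* :func:`gpa` performs generalized Procrustes analysis — each configuration
  is centred, scaled to unit centroid size and rotated (proper rotations
  only) onto an iteratively re-estimated consensus.  The pre-alignment
  centroid size of each specimen is recorded as its size phenotype.
* :func:`allometric_regression` removes allometry by multivariate least
  squares of the aligned shape coordinates on a size predictor (typically
  the braincase centroid size used as a body-size proxy), with a
  permutation test of the percentage of shape variance the predictor
  explains.
* :func:`shape_pca` decomposes the regression residuals; PC1 of the facial
  (viscerocranium) landmarks is the brachycephaly axis — strongly negative
  scores correspond to short, broad faces once signs are oriented with
  :func:`orient_pc`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LandmarkSet",
    "ProcrustesResult",
    "AllometryResult",
    "ShapePCA",
    "centroid_size",
    "gpa",
    "allometric_regression",
    "shape_pca",
    "group_pc_test",
    "orient_pc",
]


@dataclass
class LandmarkSet:
    """Named specimens x landmarks x dims with named landmark subsets.

    Parameters
    ----------
    specimen_ids
        One identifier per specimen.
    coords
        Array of shape ``(n_specimens, k_landmarks, d)`` with ``d`` 2 or 3.
    masks
        Mapping from substructure name (e.g. ``"neurocranium"``,
        ``"viscerocranium"``, ``"mandible"``) to landmark indices.
    """

    specimen_ids: list[str]
    coords: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3:
            raise ValueError("coords must be specimens x landmarks x dims")
        n, k, d = self.coords.shape
        if d not in (2, 3):
            raise ValueError(f"dims must be 2 or 3, got {d}")
        if len(self.specimen_ids) != n:
            raise ValueError("specimen_ids length does not match coords")
        for i, sid in enumerate(self.specimen_ids):
            if np.allclose(self.coords[i], self.coords[i][0]):
                raise ValueError(f"specimen {sid!r} has all-identical landmarks")
        self.masks = {m: np.asarray(idx, dtype=int) for m, idx in self.masks.items()}
        for name, idx in self.masks.items():
            if idx.size and (idx.min() < 0 or idx.max() >= k):
                raise ValueError(f"mask {name!r} indexes outside 0..{k - 1}")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @property
    def ndim(self) -> int:
        return self.coords.shape[2]

    def subset(self, mask: str | np.ndarray) -> "LandmarkSet":
        """Restrict to a named substructure (or explicit landmark indices)."""
        idx = self.masks[mask] if isinstance(mask, str) else np.asarray(mask, int)
        return LandmarkSet(list(self.specimen_ids), self.coords[:, idx, :])


@dataclass
class ProcrustesResult:
    """Output of :func:`gpa`."""

    aligned: np.ndarray  # specimens x k x d, unit centroid size, centred
    centroid_sizes: np.ndarray  # pre-alignment sizes, length units
    consensus: np.ndarray  # k x d mean shape, unit centroid size
    iterations: int
    converged: bool

    def flat(self) -> np.ndarray:
        """Aligned shapes flattened to specimens x (k*d)."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)


@dataclass
class AllometryResult:
    """Shape-on-size regression with a permutation test."""

    residuals: np.ndarray  # specimens x (k*d)
    pct_predicted: float  # % of total shape variance explained by size
    perm_p: float
    n_perm: int
    slope: np.ndarray  # (k*d,) shape change per unit predictor


@dataclass
class ShapePCA:
    loadings: np.ndarray  # (k*d) x n_components, orthonormal columns
    scores: np.ndarray  # specimens x n_components
    var_fraction: np.ndarray  # per component, sums to 1


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: root summed squared landmark deviations from the centroid.

    This is the amount of scaling removed by the Procrustes fit and serves
    as the size measure of a configuration.
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 2:
        raise ValueError("need a k x d configuration with k >= 2")
    dev = config - config.mean(axis=0)
    cs = float(np.sqrt((dev**2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all landmarks identical")
    return cs


def _best_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det=+1) minimising ||x @ R - target||_F."""
    h = x.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.ones(h.shape[0])
    corr[-1] = d
    return (u * corr) @ vt


def gpa(
    landmarks: LandmarkSet,
    mask: str | np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Generalized Procrustes superimposition.

    Each configuration is translated to the origin, scaled to unit centroid
    size, and rotated onto the current consensus by the orthogonal
    (proper-rotation) Procrustes solution; the consensus is the re-scaled
    mean of aligned configurations, iterated until it moves less than
    ``tol`` (root-mean-square over coordinates).

    Pre-alignment centroid sizes are returned untouched so they can be used
    as size phenotypes.
    """
    ls = landmarks if mask is None else landmarks.subset(mask)
    x = ls.coords
    n = x.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least two specimens")
    sizes = np.array([centroid_size(c) for c in x])
    centred = x - x.mean(axis=1, keepdims=True)
    scaled = centred / sizes[:, None, None]

    consensus = scaled[0].copy()
    aligned = scaled.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = scaled[i] @ _best_rotation(scaled[i], consensus)
        new = aligned.mean(axis=0)
        new = new - new.mean(axis=0)
        new = new / np.sqrt((new**2).sum())
        delta = np.sqrt(((new - consensus) ** 2).mean())
        consensus = new
        if delta < tol:
            converged = True
            break

    # canonical orientation: consensus principal axes onto coordinate axes,
    # so the result does not depend on the initialisation specimen
    rot = _principal_axes(consensus)
    consensus = consensus @ rot
    aligned = aligned @ rot
    return ProcrustesResult(aligned, sizes, consensus, it, converged)


def _principal_axes(shape: np.ndarray) -> np.ndarray:
    """Proper rotation aligning a shape's principal axes with the coordinate
    axes, with a deterministic sign convention."""
    w, v = np.linalg.eigh(shape.T @ shape)
    v = v[:, ::-1]  # descending variance
    d = shape @ v
    # data-driven signs for the first d-1 axes; the last is fixed by det=+1
    for j in range(v.shape[1] - 1):
        if d[np.argmax(np.abs(d[:, j])), j] < 0:
            v[:, j] *= -1
    if np.linalg.det(v) < 0:
        v[:, -1] *= -1
    return v


def allometric_regression(
    shapes: np.ndarray,
    predictor: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> AllometryResult:
    """Regress shape coordinates on a size predictor; permutation test.

    Parameters
    ----------
    shapes
        Aligned shape coordinates, specimens x (k*d) (or specimens x k x d,
        flattened internally).
    predictor
        Positive per-specimen size values (e.g. neurocranium centroid size).
    n_perm
        Permutations for the significance of ``pct_predicted``; the p-value
        is ``(1 + #{permuted >= observed}) / (n_perm + 1)``.
    seed
        Seed for the permutation stream (mandatory when ``n_perm > 0``).

    Returns
    -------
    AllometryResult
        Residuals (for :func:`shape_pca`), percentage of pooled shape
        variance explained, permutation p, and the per-coordinate slope.
    """
    y = np.asarray(shapes, dtype=float)
    if y.ndim == 3:
        y = y.reshape(y.shape[0], -1)
    x = np.asarray(predictor, dtype=float)
    n = y.shape[0]
    if x.shape != (n,):
        raise ValueError("predictor length must equal specimen count")
    if np.any(x <= 0):
        raise ValueError("predictor values must be positive")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: regression undefined")
    if n_perm > 0 and seed is None:
        raise ValueError("seed is required when n_perm > 0")

    xc = x - x.mean()
    yc = y - y.mean(axis=0)
    sxx = float(xc @ xc)
    slope = (yc.T @ xc) / sxx
    fitted = np.outer(xc, slope)
    residuals = y - fitted  # grand mean retained; PCA centres again
    ss_total = float((yc**2).sum())
    ss_expl = float((fitted**2).sum())
    pct = 100.0 * ss_expl / ss_total

    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        chunk = max(1, min(n_perm, 2_000_000 // max(n, 1)))
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            perm = np.empty((n, b))
            for j in range(b):
                perm[:, j] = rng.permutation(xc)
            # explained SS under a permuted predictor: ||Y_c' x||^2 / (x'x)
            num = (yc.T @ perm) ** 2
            ss_p = num.sum(axis=0) / (perm**2).sum(axis=0)
            count += int((100.0 * ss_p / ss_total >= pct - 1e-12).sum())
            done += b
        perm_p = (1 + count) / (n_perm + 1)
    else:
        perm_p = float("nan")
    return AllometryResult(residuals, pct, perm_p, n_perm, slope)


def shape_pca(residuals: np.ndarray) -> ShapePCA:
    """PCA of the specimen covariance of (regression-residual) shape coords.

    Components are returned with a deterministic sign convention: the
    largest-magnitude element of each loading column is positive.
    """
    y = np.asarray(residuals, dtype=float)
    if y.ndim == 3:
        y = y.reshape(y.shape[0], -1)
    n = y.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least two specimens")
    yc = y - y.mean(axis=0)
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    r = min(n - 1, y.shape[1])
    u, s, vt = u[:, :r], s[:r], vt[:r]
    loadings = vt.T
    scores = u * s
    for j in range(r):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.full(r, np.nan)
    return ShapePCA(loadings, scores, frac)


def group_pc_test(
    scores: np.ndarray, group_labels: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t test of PC scores between exactly two groups.

    Pooled-variance Student's t by default; ``welch=True`` switches to the
    unequal-variance form.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly two groups, got {uniq.size}")
    a = scores[labels == uniq[0]]
    b = scores[labels == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def orient_pc(scores: np.ndarray, reference_mask: np.ndarray) -> np.ndarray:
    """Flip PC score signs so the reference group's mean is negative.

    The polarity of a principal component is arbitrary; downstream case
    selection (e.g. brachycephalic = PC1 below a threshold) needs a fixed
    orientation.
    """
    scores = np.asarray(scores, dtype=float).copy()
    ref = np.asarray(reference_mask, dtype=bool)
    if scores.ndim == 1:
        scores = scores[:, None]
        squeeze = True
    else:
        squeeze = False
    for j in range(scores.shape[1]):
        if scores[ref, j].mean() > 0:
            scores[:, j] *= -1
    return scores[:, 0] if squeeze else scores
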