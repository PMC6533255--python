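"""The 2-D ecological strategy surface.

A PCA of the five standardized traits projects species onto PC1/PC2; PC1
captures body mass and the fast-slow life-history continuum, PC2 the
diet (invertivore-herbivore) and habitat-breadth (generalist-specialist)
gradient.  Scores are averaged across the imputation ensemble after a
fixed sign anchoring (PC1: body mass loads positively; PC2: diet loads
negatively), and occurrence-probability contours are drawn as highest-
density regions of a bivariate Gaussian KDE at the 0.5/0.95/0.99 mass
quantiles.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import linalg

from .traits import OrdinationResult, StandardizedMatrix

__all__ = ["SurfaceResult", "pca_surface", "average_over_imputations", "kde_contours"]

#: default sign anchors: (trait, axis, required sign of the loading)
SIGN_ANCHORS = {"axis1": ("mass", +1), "axis2": ("diet", -1)}


def pca_surface(z: StandardizedMatrix, sign_anchors: dict | None = None) -> OrdinationResult:
    """PCA of one completed, z-scored trait matrix.

    Eigendecomposition of the covariance of the z-matrix (its correlation
    structure); loadings are unit eigenvectors, scores the projections.
    Axis signs follow a deterministic convention so ensembles can be
    averaged: by default PC1 is oriented with a positive body-mass loading
    and PC2 with a negative diet loading; remaining axes put the largest-
    magnitude loading positive.
    """
    X = z.values
    if np.isnan(X).any():
        raise ValueError("matrix has missing cells; impute first")
    anchors = SIGN_ANCHORS if sign_anchors is None else sign_anchors
    cols = list(z.data.columns)
    n, d = X.shape
    C = np.cov(X, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(d):
        axis = f"axis{j+1}"
        if axis in anchors:
            trait, sign = anchors[axis]
            if sign * vecs[cols.index(trait), j] < 0:
                vecs[:, j] = -vecs[:, j]
        elif vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] = -vecs[:, j]
    Xc = X - X.mean(axis=0)
    scores = Xc @ vecs
    axes = [f"axis{j+1}" for j in range(d)]
    return OrdinationResult(
        eigenvalues=vals,
        axis_scores=pd.DataFrame(scores, index=z.data.index, columns=axes),
        variance_fraction=vals / vals.sum(),
        axis_loadings=pd.DataFrame(vecs, index=cols, columns=axes),
    )


@dataclasses.dataclass
class SurfaceResult:
    """Ensemble-averaged strategy surface with HDR contours."""

    scores: pd.DataFrame  # per-species mean PC1/PC2
    variance_fraction: np.ndarray  # ensemble-mean, all 5 axes
    loadings: pd.DataFrame  # ensemble-mean 5x5
    density_grid: np.ndarray | None = None
    grid_x: np.ndarray | None = None
    grid_y: np.ndarray | None = None
    contours: dict[float, list[np.ndarray]] | None = None  # quantile -> polylines
    hdr_levels: dict[float, float] | None = None


def average_over_imputations(ensemble_results: list[OrdinationResult]) -> SurfaceResult:
    """Arithmetic mean of per-dataset PCA scores, loadings and variance.

    Members must already be sign-anchored by the shared convention, which
    makes the average invariant to per-member eigenvector flips.
    """
    if not ensemble_results:
        raise ValueError("empty ensemble")
    idx = ensemble_results[0].axis_scores.index
    for r in ensemble_results[1:]:
        if not r.axis_scores.index.equals(idx):
            raise ValueError("inconsistent species sets across ensemble members")
    scores = sum(r.axis_scores for r in ensemble_results) / len(ensemble_results)
    varfrac = np.mean([r.variance_fraction for r in ensemble_results], axis=0)
    loadings = sum(r.axis_loadings for r in ensemble_results) / len(ensemble_results)
    return SurfaceResult(
        scores=scores[["axis1", "axis2"]],
        variance_fraction=varfrac,
        loadings=loadings,
    )


# ---------------------------------------------------------------------------
# KDE highest-density regions
# ---------------------------------------------------------------------------


def _normal_scale_bandwidth(X: np.ndarray) -> np.ndarray:
    """Full-covariance normal-scale bandwidth matrix H.

    H = (4/(n(d+2)))^(2/(d+4)) * Sigma-hat — the multivariate normal-
    reference rule with the full sample covariance (unconstrained
    orientation).
    """
    n, d = X.shape
    factor = (4.0 / (n * (d + 2.0))) ** (2.0 / (d + 4.0))
    return factor * np.cov(X, rowvar=False, ddof=1)


def kde_contours(
    scores: np.ndarray | pd.DataFrame,
    quantiles=(0.5, 0.95, 0.99),
    bandwidth_method: str = "normal_scale",
    gridsize: int = 256,
):
    """Bivariate Gaussian KDE with highest-density-region contours.

    For each mass quantile q the contour is the density level whose
    super-level set carries total probability q (the smallest region
    containing that mass).  Returns a SurfaceResult-style bundle:
    (grid_x, grid_y, density, levels, contours, point_density).

    The grid spans the data range padded by 3 bandwidth standard
    deviations per axis.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("scores must be n x 2")
    n = X.shape[0]
    if n < 50:
        raise ValueError("need at least 50 points for a stable KDE")
    for q in quantiles:
        if not 0.0 < q < 1.0:
            raise ValueError(f"quantile outside (0,1): {q}")
    if bandwidth_method != "normal_scale":
        raise ValueError(f"unknown bandwidth method {bandwidth_method!r}")

    H = _normal_scale_bandwidth(X)
    sd = np.sqrt(np.diag(H))
    lo = X.min(axis=0) - 3 * sd
    hi = X.max(axis=0) + 3 * sd
    gx = np.linspace(lo[0], hi[0], gridsize)
    gy = np.linspace(lo[1], hi[1], gridsize)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    grid_pts = np.column_stack([GX.ravel(), GY.ravel()])

    Hinv = linalg.inv(H)
    det = linalg.det(H)
    norm = 1.0 / (2 * np.pi * np.sqrt(det) * n)

    def density_at(P: np.ndarray) -> np.ndarray:
        out = np.zeros(len(P))
        L = linalg.cholesky(Hinv, lower=True)
        Pw = (P @ L).astype(np.float32)
        Xw = (X @ L).astype(np.float32)
        x2 = (Xw ** 2).sum(axis=1)
        # bound the pairwise-distance chunk to ~2e7 entries
        step = max(1_000, int(2e7 / max(n, 1)))
        for s in range(0, len(P), step):
            chunk = Pw[s : s + step]
            d2 = ((chunk ** 2).sum(axis=1))[:, None] + x2[None, :] - 2 * chunk @ Xw.T
            np.maximum(d2, 0.0, out=d2)
            out[s : s + step] = np.exp(-0.5 * d2).sum(axis=1, dtype=np.float64)
        return out * norm

    dens = density_at(grid_pts).reshape(gridsize, gridsize)
    cell_area = (gx[1] - gx[0]) * (gy[1] - gy[0])

    # HDR level per quantile: smallest density c with mass{f >= c} >= q
    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat) * cell_area
    levels = {}
    for q in quantiles:
        k = int(np.searchsorted(cum, q))
        k = min(k, len(flat) - 1)
        levels[q] = float(flat[k])

    from skimage import measure

    contours = {}
    for q, lvl in levels.items():
        segs = measure.find_contours(dens, lvl)
        polys = []
        for seg in segs:
            xs = np.interp(seg[:, 0], np.arange(gridsize), gx)
            ys = np.interp(seg[:, 1], np.arange(gridsize), gy)
            polys.append(np.column_stack([xs, ys]))
        contours[q] = polys

    point_dens = density_at(X)
    return gx, gy, dens, levels, contours, point_dens


def hdr_area(dens: np.ndarray, level: float, gx: np.ndarray, gy: np.ndarray) -> float:
    """Area of the region where the KDE exceeds `level`."""
    cell_area = (gx[1] - gx[0]) * (gy[1] - gy[0])
    return float((dens >= level).sum() * cell_area)


def hdr_mass_fraction(point_dens: np.ndarray, level: float) -> float:
    """Fraction of data points falling inside the HDR at `level`."""
    return float((point_dens >= level).mean())
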