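"""One-class-SVM hypervolumes in standardized trait space.

A species set's d-dimensional ecological strategy space is the region
enclosed by a one-class support vector machine (Gaussian kernel) fitted
to the standardized trait points.  The enclosed volume is measured by
uniform Monte-Carlo sampling of an expanded bounding box and reported in
SD^d units (the coordinate system of the z-scored traits).  Set
operations between two spaces classify a common uniform sample with both
boundaries.

Numerical choices: the SVM is fitted on internally re-standardized
coordinates and the kernel width defaults to gamma = 0.3 + 0.1*d, which
makes the estimator scale-equivariant (volumes scale exactly as c^d under
coordinate dilation) and keeps the soft boundary's outward smoothing bias
within a few percent for known shapes up to d=5.  Removal of points can
still *increase* the fitted volume — the boundary is re-drawn per fit —
and no correction is applied for that.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from sklearn.svm import OneClassSVM

from ._rng import substream

__all__ = ["Hypervolume", "SetOperationResult", "fit_hypervolume", "set_operations", "point_density"]

_CHUNK = 500_000
_STORED_CLOUD = 5_000


def _decision_values(svm: OneClassSVM, Z: np.ndarray) -> np.ndarray:
    """Vectorized RBF decision function (libsvm's loop is the bottleneck).

    f(z) = sum_i alpha_i exp(-gamma ||z - sv_i||^2) - rho, evaluated in
    single precision with matrix algebra; agrees with
    svm.decision_function to ~1e-7, far below the Monte-Carlo noise of
    any volume estimate.
    """
    svT = np.ascontiguousarray(svm.support_vectors_.T, dtype=np.float32)
    alpha = svm.dual_coef_[0].astype(np.float32)
    rho = np.float32(svm.intercept_[0])
    gamma = np.float32(svm._gamma)
    sv_sq = (svT ** 2).sum(axis=0)
    nsv = svT.shape[1]
    out = np.empty(len(Z))
    # one reused workspace, ~2e7 entries: repeated large alloc/free costs
    # more in page faults than the kernel arithmetic itself
    step = max(10_000, int(2e7 / max(nsv, 1)))
    G = np.empty((min(step, len(Z)), nsv), dtype=np.float32)
    for s in range(0, len(Z), step):
        chunk = Z[s : s + step].astype(np.float32)
        m = len(chunk)
        Gm = G[:m]
        np.matmul(chunk, svT, out=Gm)
        Gm *= -2.0
        Gm += ((chunk ** 2).sum(axis=1))[:, None]
        Gm += sv_sq[None, :]
        np.maximum(Gm, 0.0, out=Gm)
        Gm *= -gamma
        np.exp(Gm, out=Gm)
        out[s : s + step] = Gm @ alpha + rho
    return out


@dataclasses.dataclass
class Hypervolume:
    """Fitted boundary plus its Monte-Carlo volume estimate."""

    dimension: int
    n_points: int
    volume: float  # SD^d
    box_lo: np.ndarray
    box_hi: np.ndarray
    n_samples: int
    frac_in: float
    seed: int
    nu: float
    gamma: float
    _svm: OneClassSVM
    _center: np.ndarray
    _scale: np.ndarray
    sample_cloud: np.ndarray | None = None  # stored subsample of MC points
    cloud_labels: np.ndarray | None = None

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boundary classification ('in') for points in input coordinates."""
        z = (np.asarray(points, dtype=float) - self._center) / self._scale
        return _decision_values(self._svm, z) >= 0

    @property
    def box_volume(self) -> float:
        return float(np.prod(self.box_hi - self.box_lo))

    def to_dict(self) -> dict:
        """JSON-serializable summary (params, box, volume) for caching."""
        return {
            "dimension": self.dimension,
            "n_points": self.n_points,
            "volume": self.volume,
            "box_lo": self.box_lo.tolist(),
            "box_hi": self.box_hi.tolist(),
            "n_samples": self.n_samples,
            "frac_in": self.frac_in,
            "seed": self.seed,
            "nu": self.nu,
            "gamma": self.gamma,
            "n_support": int(len(self._svm.support_)),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclasses.dataclass
class SetOperationResult:
    intersection: float
    union: float
    unique_1: float
    unique_2: float

    @property
    def shares(self) -> dict[str, float]:
        """Fraction of the union in each disjoint component."""
        u = self.union
        if u <= 0:
            raise ValueError("empty union")
        return {
            "intersection": self.intersection / u,
            "unique_1": self.unique_1 / u,
            "unique_2": self.unique_2 / u,
        }


def fit_hypervolume(points: np.ndarray, params=None, seed: int = 0) -> Hypervolume:
    """Fit the one-class-SVM boundary and estimate the enclosed volume.

    `points` is an n x d array in standardized (SD) coordinates.  The
    sampling box is the data range expanded by `box_expansion` per side;
    volume = box volume x fraction of uniform box samples classified 'in'.
    Deterministic given (points, params, seed).
    """
    from .io import SvmParams

    params = params or SvmParams()
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be 2-D")
    n, d = X.shape
    if n < d + 2:
        raise ValueError(f"need at least d+2={d+2} points, got {n}")
    if np.isnan(X).any():
        raise ValueError("points contain missing values")
    scale = X.std(axis=0, ddof=1)
    if np.any(scale == 0):
        raise ValueError("zero-variance dimension; hypervolume undefined")
    center = X.mean(axis=0)
    Z = (X - center) / scale

    gamma = params.resolve_gamma(d)
    svm = OneClassSVM(nu=params.nu, gamma=gamma).fit(Z)

    lo = X.min(axis=0)
    hi = X.max(axis=0)
    pad = (hi - lo) * params.box_expansion
    lo, hi = lo - pad, hi + pad
    box_vol = float(np.prod(hi - lo))

    n_samples = int(min(params.samples_per_point * n, params.max_samples))
    rng = substream(seed, "hypervolume.mc")
    n_in = 0
    stored_pts, stored_lab = [], []
    remaining_store = _STORED_CLOUD
    zlo = (lo - center) / scale
    zhi = (hi - center) / scale
    for s in range(0, n_samples, _CHUNK):
        m = min(_CHUNK, n_samples - s)
        zs = rng.uniform(zlo, zhi, size=(m, d))
        inside = _decision_values(svm, zs) >= 0
        n_in += int(inside.sum())
        if remaining_store > 0:
            take = min(remaining_store, m)
            stored_pts.append(zs[:take] * scale + center)
            stored_lab.append(inside[:take])
            remaining_store -= take
    frac = n_in / n_samples
    volume = box_vol * frac
    if frac == 0:
        raise ValueError(
            "no Monte-Carlo samples classified 'in'; "
            "increase gamma or samples_per_point"
        )
    return Hypervolume(
        dimension=d,
        n_points=n,
        volume=volume,
        box_lo=lo,
        box_hi=hi,
        n_samples=n_samples,
        frac_in=frac,
        seed=seed,
        nu=params.nu,
        gamma=gamma,
        _svm=svm,
        _center=center,
        _scale=scale,
        sample_cloud=np.vstack(stored_pts),
        cloud_labels=np.concatenate(stored_lab),
    )


def set_operations(hv1: Hypervolume, hv2: Hypervolume, seed: int = 0, n_samples: int | None = None) -> SetOperationResult:
    """Intersection/union/unique volumes of two fitted hypervolumes.

    Both must live in the same standardized coordinate system and have
    equal dimension.  A common uniform sample over the union of the two
    boxes is classified by both boundaries; volumes follow from the joint
    label fractions.
    """
    if hv1.dimension != hv2.dimension:
        raise ValueError("dimension mismatch")
    d = hv1.dimension
    lo = np.minimum(hv1.box_lo, hv2.box_lo)
    hi = np.maximum(hv1.box_hi, hv2.box_hi)
    box_vol = float(np.prod(hi - lo))
    if n_samples is None:
        n_samples = min(hv1.n_samples + hv2.n_samples, 5_000_000)
    rng = substream(seed, "hypervolume.setops")
    c11 = c10 = c01 = 0
    for s in range(0, n_samples, _CHUNK):
        m = min(_CHUNK, n_samples - s)
        pts = rng.uniform(lo, hi, size=(m, d))
        in1 = hv1.contains(pts)
        in2 = hv2.contains(pts)
        c11 += int((in1 & in2).sum())
        c10 += int((in1 & ~in2).sum())
        c01 += int((~in1 & in2).sum())
    f = box_vol / n_samples
    return SetOperationResult(
        intersection=c11 * f,
        union=(c11 + c10 + c01) * f,
        unique_1=c10 * f,
        unique_2=c01 * f,
    )


def point_density(hv: Hypervolume) -> float:
    """Species per SD^d: input point count over volume."""
    if hv.volume <= 0:
        raise ValueError("zero volume")
    return hv.n_points / hv.volume
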