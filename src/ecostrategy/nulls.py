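"""Trait-space null models and occupation tests.

Four null models generate alternative trait matrices of the same shape as
the observed standardized data:

1. independent uniforms over each trait's observed range (a hypercube of
   possibilities — every combination equally likely);
2. independent normals with each trait's observed mean and sd (extreme
   values selected against, axes independent);
3. independent permutations of the observed columns (observed marginals,
   shuffled dependence);
4. multivariate normal with the observed mean vector and covariance
   (correlated axes, normal margins).

Occupation is the observed hypervolume over the mean of the null-replicate
hypervolumes; the rank-based permutation p-value is one-tailed toward
restriction (observed smaller than null).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from ._rng import subseed
from .hypervolume import Hypervolume, fit_hypervolume

logger = logging.getLogger(__name__)

__all__ = ["OccupationResult", "sample_null", "occupation_test"]


@dataclasses.dataclass
class OccupationResult:
    model_id: int
    null_volumes: np.ndarray
    mean_null_volume: float
    observed_volume: float
    occupation: float  # observed / mean-null (default convention)
    occupation_mean_of_ratios: float  # alternative convention
    p_value: float
    n_replicates: int


def _nearest_psd(C: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((C + C.T) / 2)
    vals = np.clip(vals, 0, None)
    return (vecs * vals) @ vecs.T


def sample_null(
    model_id: int, observed: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One null trait matrix of the observed shape under model `model_id`."""
    X = np.asarray(observed, dtype=float)
    if np.isnan(X).any():
        raise ValueError("observed matrix must be complete")
    n, d = X.shape
    if model_id == 1:
        return rng.uniform(X.min(axis=0), X.max(axis=0), size=(n, d))
    if model_id == 2:
        return rng.normal(X.mean(axis=0), X.std(axis=0, ddof=1), size=(n, d))
    if model_id == 3:
        out = np.empty_like(X)
        for j in range(d):
            out[:, j] = X[rng.permutation(n), j]
        return out
    if model_id == 4:
        C = np.cov(X, rowvar=False, ddof=1)
        if np.linalg.eigvalsh(C).min() < 0:
            warnings.warn("observed covariance not PSD; using nearest PSD repair")
            C = _nearest_psd(C)
        return rng.multivariate_normal(X.mean(axis=0), C, size=n, method="eigh")
    raise ValueError(f"unknown null model id {model_id}")


def occupation_test(
    observed_hv: Hypervolume,
    observed: np.ndarray,
    model_id: int,
    n_replicates: int = 999,
    svm_params=None,
    seed: int = 0,
) -> OccupationResult:
    """Occupation of model-`model_id` null strategy spaces by the observed one.

    Per replicate the null generator draws a matrix of the observed shape,
    a hypervolume is fitted with the same SVM parameters and point count,
    and its volume recorded.  occupation = V_obs / mean(V_null);
    p = (1 + #{V_null <= V_obs}) / (n_replicates + 1), one-tailed toward
    restriction.  Replicates whose fit fails are dropped (abort at >= 5%).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    base = subseed(seed, f"nulls.model{model_id}")
    streams = base.spawn(n_replicates)
    vols = []
    failures = 0
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        null = sample_null(model_id, observed, rng)
        rep_seed = int(ss.generate_state(1)[0] % (2**31))
        try:
            hv = fit_hypervolume(null, params=svm_params, seed=rep_seed)
            vols.append(hv.volume)
        except ValueError as err:
            failures += 1
            logger.warning("null replicate %d failed: %s", i, err)
    if failures >= 0.05 * n_replicates and failures > 0:
        raise RuntimeError(f"{failures}/{n_replicates} null replicates failed")
    vols = np.asarray(vols)
    v_obs = observed_hv.volume
    mean_null = float(vols.mean())
    occupation = v_obs / mean_null
    p = (1 + int((vols <= v_obs).sum())) / (len(vols) + 1)
    return OccupationResult(
        model_id=model_id,
        null_volumes=vols,
        mean_null_volume=mean_null,
        observed_volume=v_obs,
        occupation=occupation,
        occupation_mean_of_ratios=float((v_obs / vols).mean()),
        p_value=p,
        n_replicates=len(vols),
    )
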