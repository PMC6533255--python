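"""Chained-equation multiple imputation with phylogenetic eigenvectors.

Missing trait values are filled by MICE-style chained equations on the
transformed (pre-z) trait scale: each incomplete trait is regressed in
turn on the other four traits plus the first k phylogenetic eigenvectors,
and missing cells are redrawn by predictive mean matching (PMM, 5 donors).
Twenty-five independent chains give an ensemble of completed datasets that
carries the imputation uncertainty.  Mammals and birds are imputed
separately (each class has its own tree), then concatenated; z-scoring is
recomputed within each completed dataset.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from ._rng import subseed
from .io import PatristicDistances, TraitTable
from .traits import (
    ANALYSIS_COLUMNS,
    DistanceMatrix,
    StandardizedMatrix,
    TransformMetadata,
    pcoa,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloEigenvectors",
    "ImputedEnsemble",
    "phylo_eigenvectors",
    "chained_impute",
    "complete_cases",
]

PMM_DONORS = 5
RIDGE_PENALTY = 1e-5


@dataclasses.dataclass
class PhyloEigenvectors:
    """First k principal-coordinate axes of the patristic distance matrix."""

    data: pd.DataFrame  # index species_id, columns ev1..evk


@dataclasses.dataclass
class ImputedEnsemble:
    """m completed trait matrices; observed cells identical across members."""

    members: list[pd.DataFrame]  # transformed (pre-z) scale
    imputed_mask: pd.DataFrame  # True where the cell was imputed
    chain_means: pd.DataFrame  # per (member, iteration, trait) mean, diagnostics

    def __len__(self) -> int:
        return len(self.members)

    def standardized(self) -> list[StandardizedMatrix]:
        """z-score each completed dataset with its own parameters."""
        from .traits import TRANSFORMS

        out = []
        for mem in self.members:
            meta = TransformMetadata(
                transform={
                    c: TRANSFORMS[c][1] if c in TRANSFORMS else "identity"
                    for c in mem.columns
                },
                mean={c: float(mem[c].mean()) for c in mem.columns},
                sd={c: float(mem[c].std(ddof=1)) for c in mem.columns},
            )
            out.append(StandardizedMatrix(meta.standardize_transformed(mem), meta))
        return out


def phylo_eigenvectors(distances: PatristicDistances | DistanceMatrix, k: int = 10) -> PhyloEigenvectors:
    """Top-k eigenvectors of the double-centered -1/2 d^2 matrix.

    These are the principal coordinates of the tree's patristic distances
    and serve as covariates encoding relatedness.  Ties in the spectrum are
    broken by fixed eigenvalue order then a sign convention (the
    largest-magnitude element of each axis is positive), so the selection
    is deterministic even for degenerate spectra (e.g. star trees).
    """
    if isinstance(distances, PatristicDistances):
        d = DistanceMatrix(distances.labels, distances.matrix)
    else:
        d = distances
    n = len(d.labels)
    if k >= n:
        raise ValueError(f"k={k} must be < number of species on the tree ({n})")
    ord_ = pcoa(d, n_axes=k)
    frame = ord_.axis_scores.copy()
    frame.columns = [f"ev{i+1}" for i in range(frame.shape[1])]
    # pad if fewer positive axes than requested
    for i in range(frame.shape[1], k):
        frame[f"ev{i+1}"] = 0.0
    return PhyloEigenvectors(frame)


def complete_cases(table: TraitTable) -> TraitTable:
    """Species with all five focal traits observed (data-deletion approach)."""
    df = table.df
    from .io import DIET_COLUMNS, TRAIT_COLUMNS

    ok = df[TRAIT_COLUMNS].notna().all(axis=1) & df[DIET_COLUMNS].notna().all(axis=1)
    if not ok.any():
        raise ValueError("no complete cases remain")
    return table.subset(ok)


# ---------------------------------------------------------------------------
# chained PMM
# ---------------------------------------------------------------------------


def _ols_predict(X_obs, y_obs, X_all):
    """OLS fit with ridge fallback for singular designs."""
    XtX = X_obs.T @ X_obs
    Xty = X_obs.T @ y_obs
    try:
        beta = np.linalg.solve(XtX, Xty)
        if not np.all(np.isfinite(beta)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular design matrix; using ridge fallback")
        beta = np.linalg.solve(XtX + RIDGE_PENALTY * np.eye(XtX.shape[0]), Xty)
    return X_all @ beta


def _pmm_draw(pred_obs, y_obs, pred_mis, rng, k=PMM_DONORS):
    """Predictive mean matching: donor value among k nearest predictions."""
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    out = np.empty(len(pred_mis))
    pos = np.searchsorted(sorted_pred, pred_mis)
    nobs = len(pred_obs)
    for i, (p, c) in enumerate(zip(pred_mis, pos)):
        lo = max(0, c - k)
        hi = min(nobs, c + k)
        cand = order[lo:hi]
        dist = np.abs(pred_obs[cand] - p)
        donors = cand[np.argsort(dist, kind="stable")[:k]]
        out[i] = y_obs[donors[rng.integers(len(donors))]]
    return out


def chained_impute(
    matrix: pd.DataFrame,
    predictors: PhyloEigenvectors | None = None,
    m: int = 25,
    n_iter: int = 10,
    seed: int = 0,
    stream: str = "impute",
) -> ImputedEnsemble:
    """MICE with predictive mean matching on a transformed trait matrix.

    `matrix` holds the five transformed traits (columns ANALYSIS_COLUMNS or
    any numeric set), indexed by species id, with NaN for missing cells.
    Each chain initializes missing cells by resampling observed values,
    then sweeps the incomplete traits `n_iter` times, regressing each on
    the remaining traits plus the eigenvector predictors and redrawing
    missing cells by PMM with 5 donors.  Chains use independent, named
    substreams of the master seed.
    """
    cols = list(matrix.columns)
    miss = matrix.isna()
    incomplete = [c for c in cols if miss[c].any()]
    for c in cols:
        n_obs = matrix[c].notna().sum()
        if n_obs < 30 and miss[c].any():
            raise ValueError(f"trait {c} has only {n_obs} observed values (< 30)")

    ev = None
    if predictors is not None:
        ev = predictors.data.reindex(matrix.index)

    members = []
    diag_rows = []
    base = subseed(seed, stream)
    chains = base.spawn(m)
    for ci, ss in enumerate(chains):
        rng = np.random.default_rng(ss)
        cur = matrix.copy()
        for c in incomplete:
            obs = matrix[c].dropna().to_numpy()
            n_mis = int(miss[c].sum())
            cur.loc[miss[c], c] = rng.choice(obs, size=n_mis, replace=True)
        if incomplete:
            for it in range(n_iter):
                for c in incomplete:
                    _sweep_trait(cur, matrix, miss, c, ev, rng)
                    diag_rows.append(
                        {"member": ci, "iteration": it, "trait": c,
                         "mean": float(cur[c].mean())}
                    )
        members.append(cur)
    chain_means = pd.DataFrame(diag_rows)
    return ImputedEnsemble(members=members, imputed_mask=miss, chain_means=chain_means)


def _sweep_trait(cur, matrix, miss, c, ev, rng):
    others = [o for o in cur.columns if o != c]
    X = cur[others].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    mis_rows = miss[c].to_numpy()
    obs_rows = ~mis_rows
    y_obs = matrix.loc[obs_rows, c].to_numpy(dtype=float)

    if ev is not None:
        ev_ok = ev.notna().all(axis=1).to_numpy()
        Xev = np.column_stack([X, np.nan_to_num(ev.to_numpy(dtype=float))])
        fit_rows = obs_rows & ev_ok
        # species off the tree fall back to the trait-only model
        if fit_rows.sum() >= Xev.shape[1] + 2:
            pred = np.empty(len(cur))
            pred[ev_ok] = _ols_predict(Xev[fit_rows], matrix.loc[fit_rows, c].to_numpy(), Xev[ev_ok])
            if (~ev_ok).any():
                pred[~ev_ok] = _ols_predict(X[obs_rows], y_obs, X[~ev_ok])
        else:
            pred = _ols_predict(X[obs_rows], y_obs, X)
    else:
        pred = _ols_predict(X[obs_rows], y_obs, X)

    pred_obs = pred[obs_rows]
    pred_mis = pred[mis_rows]
    if len(pred_mis):
        cur.loc[mis_rows, c] = _pmm_draw(pred_obs, y_obs, pred_mis, rng)


# ---------------------------------------------------------------------------
# per-class orchestration
# ---------------------------------------------------------------------------


def impute_table(
    transformed: pd.DataFrame,
    taxon_class: pd.Series,
    eigenvectors: dict[str, PhyloEigenvectors] | None = None,
    m: int = 25,
    n_iter: int = 10,
    seed: int = 0,
) -> ImputedEnsemble:
    """Impute mammals and birds separately, then concatenate.

    `transformed` is the full pre-z trait matrix indexed by species id;
    `taxon_class` aligns to it.  `eigenvectors` maps class name to that
    class's phylogenetic eigenvectors (optional).
    """
    parts: dict[str, ImputedEnsemble] = {}
    classes = [c for c in ("mammal", "bird") if (taxon_class == c).any()]
    for cls in classes:
        sub = transformed.loc[taxon_class.values == cls]
        ev = (eigenvectors or {}).get(cls)
        parts[cls] = chained_impute(
            sub, ev, m=m, n_iter=n_iter, seed=seed, stream=f"impute.{cls}"
        )
    members = [
        pd.concat([parts[cls].members[i] for cls in classes]).reindex(transformed.index)
        for i in range(m)
    ]
    mask = pd.concat([parts[cls].imputed_mask for cls in classes]).reindex(transformed.index)
    chain_means = pd.concat(
        [parts[cls].chain_means.assign(taxon_class=cls) for cls in classes],
        ignore_index=True,
    )
    return ImputedEnsemble(members=members, imputed_mask=mask, chain_means=chain_means)
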