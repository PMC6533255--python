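"""Trait transformation: diet ordination and the standardized 5-trait matrix.

The ten compositional diet percentages are reduced to a single continuous
"diet" trait: Gower distances between species' diet compositions, then a
principal coordinates analysis (classical scaling), retaining axis 1 (a
gradient running from invertivores to herbivores).  The five analysis
traits — log10 body mass, log10 litter/clutch size, sqrt habitat breadth,
log10 generation length, and the diet axis — are z-scored to give the
unitless coordinate system ("SD" units) in which all surfaces and
hypervolumes are measured.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io import DIET_COLUMNS, TraitTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "StandardizedMatrix",
    "gower_distance",
    "pcoa",
    "diet_axis",
    "transform_standardize",
]

#: analysis column order; fixed everywhere downstream
ANALYSIS_COLUMNS = ["mass", "litter", "habitat", "generation", "diet"]

#: raw column, transform name per analysis column (diet enters pre-derived)
TRANSFORMS = {
    "mass": ("body_mass", "log10"),
    "litter": ("litter_clutch_size", "log10"),
    "habitat": ("habitat_breadth", "sqrt"),
    "generation": ("generation_length", "log10"),
    "diet": ("diet_score", "identity"),
}


@dataclasses.dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diagonal(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")


@dataclasses.dataclass
class OrdinationResult:
    """Eigen-embedding output shared by the diet PCoA and the trait PCA."""

    eigenvalues: np.ndarray  # all eigenvalues, descending (may include < 0)
    axis_scores: pd.DataFrame  # species x retained axes
    variance_fraction: np.ndarray  # per retained axis, of positive eigenvalue mass
    axis_loadings: pd.DataFrame | None = None  # variables x axes where defined


def gower_distance(diet_rows: pd.DataFrame) -> DistanceMatrix:
    """Gower distances between species' diet compositions.

    Per-variable absolute differences are normalized by that variable's
    observed range and averaged across the variables with nonzero range
    (zero-range variables carry no dissimilarity signal and are excluded
    from the average).  Distances land in [0, 1].
    """
    cols = [c for c in DIET_COLUMNS if c in diet_rows.columns]
    if len(cols) != len(DIET_COLUMNS):
        cols = list(diet_rows.columns)
    X = diet_rows[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("gower_distance requires complete diet rows")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 species")
    rng_ = X.max(axis=0) - X.min(axis=0)
    informative = rng_ > 0
    if not informative.any():
        # every variable constant <=> all rows identical: distances trivially 0
        labels = list(diet_rows.index.astype(str))
        return DistanceMatrix(labels, np.zeros((n, n)))
    Xn = X[:, informative] / rng_[informative]
    acc = np.zeros((n, n))
    for j in range(Xn.shape[1]):
        acc += np.abs(Xn[:, j][:, None] - Xn[:, j][None, :])
    acc /= informative.sum()
    np.fill_diagonal(acc, 0.0)
    labels = list(diet_rows.index.astype(str))
    return DistanceMatrix(labels, acc)


def pcoa(d: DistanceMatrix, n_axes: int) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers -1/2 d^2, eigendecomposes, and scales eigenvectors by
    the square roots of positive eigenvalues.  Negative eigenvalues (which
    Gower distances can produce) are reported but excluded from scores and
    from the variance-fraction denominator; no Cailliez/Lingoes correction
    is applied.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    D = d.values
    n = D.shape[0]
    B = -0.5 * D ** 2
    B = B - B.mean(axis=0, keepdims=True) - B.mean(axis=1, keepdims=True) + B.mean()
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-10, 1e-10 * max(abs(vals[0]), 1.0))
    pos = vals > tol
    n_pos = int(pos.sum())
    k = min(n_axes, n_pos)
    if k < n_axes:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating"
        )
    if k == 0:
        scores = np.zeros((n, n_axes))
        k = n_axes
        varfrac = np.zeros(n_axes)
    else:
        scores = vecs[:, :k] * np.sqrt(vals[:k])
        varfrac = vals[:k] / vals[pos].sum()
    # deterministic sign: largest-magnitude element of each axis positive
    for j in range(scores.shape[1]):
        col = scores[:, j]
        if np.abs(col).max() > 0 and col[np.argmax(np.abs(col))] < 0:
            scores[:, j] = -col
    frame = pd.DataFrame(
        scores, index=d.labels, columns=[f"axis{i+1}" for i in range(scores.shape[1])]
    )
    return OrdinationResult(eigenvalues=vals, axis_scores=frame, variance_fraction=varfrac)


def diet_axis(table: TraitTable, n_axes: int = 1) -> tuple[pd.Series | pd.DataFrame, pd.DataFrame, OrdinationResult]:
    """Continuous diet trait from the compositional diet data.

    Returns (scores, loadings, ordination).  Scores cover diet-complete
    species only (all-missing rows are later filled by trait imputation on
    this derived axis).  Axis 1 is oriented so the invertebrate category
    loads positively; loadings are OLS slopes of each centered category on
    the axis (reported per axis).
    """
    diet = table.df[DIET_COLUMNS]
    complete = diet.notna().all(axis=1)
    if complete.sum() < 3:
        raise ValueError("need >= 3 diet-complete species")
    rows = diet[complete].copy()
    rows.index = table.df.loc[complete, "species_id"]
    d = gower_distance(rows)
    ord_ = pcoa(d, n_axes)
    n_pos = int((ord_.eigenvalues > 1e-10).sum())
    if n_axes == 2 and n_pos < 2:
        raise ValueError("2 diet axes requested but < 2 positive eigenvalues")
    scores = ord_.axis_scores.copy()
    X = rows.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    loadings = {}
    for ax in scores.columns:
        s = scores[ax].to_numpy()
        denom = (s ** 2).sum()
        load = Xc.T @ s / denom if denom > 0 else np.zeros(X.shape[1])
        inv_idx = DIET_COLUMNS.index("diet_inv")
        if ax == "axis1" and load[inv_idx] < 0:
            scores[ax] = -scores[ax]
            load = -load
        loadings[ax] = load
    loading_df = pd.DataFrame(loadings, index=DIET_COLUMNS)
    ord_.axis_scores = scores
    ord_.axis_loadings = loading_df
    out = scores["axis1"] if n_axes == 1 else scores
    return out, loading_df, ord_


# ---------------------------------------------------------------------------
# transformation + standardization
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TransformMetadata:
    """Per-column transform name and pre-z mean/sd, enough to invert."""

    transform: dict[str, str]
    mean: dict[str, float]
    sd: dict[str, float]

    def standardize_transformed(self, transformed: pd.DataFrame) -> pd.DataFrame:
        """z-score an already-transformed frame with these stored parameters."""
        out = transformed.copy()
        for c in out.columns:
            out[c] = (out[c] - self.mean[c]) / self.sd[c]
        return out

    def inverse(self, z: pd.DataFrame) -> pd.DataFrame:
        """Back to raw trait scale (un-z then un-transform)."""
        out = {}
        for c in z.columns:
            x = z[c] * self.sd[c] + self.mean[c]
            t = self.transform[c]
            if t == "log10":
                x = 10.0 ** x
            elif t == "sqrt":
                x = x ** 2
            out[c] = x
        return pd.DataFrame(out, index=z.index)


@dataclasses.dataclass
class StandardizedMatrix:
    """Species x 5 z-scored transformed traits plus invertible metadata."""

    data: pd.DataFrame  # columns ANALYSIS_COLUMNS, index species_id
    metadata: TransformMetadata

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def transform_traits(table: TraitTable, diet_scores: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Apply the per-trait transforms (no z-scoring); missing propagates."""
    df = table.df.set_index("species_id")
    if isinstance(diet_scores, pd.DataFrame):
        diet_scores = diet_scores.iloc[:, 0]
    out = {}
    for col in ANALYSIS_COLUMNS:
        raw_col, tname = TRANSFORMS[col]
        if col == "diet":
            x = diet_scores.reindex(df.index)
        else:
            x = df[raw_col]
            bad = x.notna() & (x <= 0) if tname == "log10" else pd.Series(False, index=x.index)
            if bad.any():
                raise ValueError(
                    f"nonpositive value under log10 for trait {raw_col}: "
                    f"species {list(x.index[bad])[:5]}"
                )
            x = np.log10(x) if tname == "log10" else np.sqrt(x)
        out[col] = x
    return pd.DataFrame(out, index=df.index)


def transform_standardize(
    table: TraitTable, diet_scores: pd.Series | pd.DataFrame
) -> StandardizedMatrix:
    """Transformed, z-scored 5-trait matrix.

    z-parameters are computed from the available (non-missing) values of
    the set in hand; they are stored so that subsets (e.g. extinction
    survivors) can be standardized in the same global SD units.
    """
    transformed = transform_traits(table, diet_scores)
    meta = TransformMetadata(
        transform={c: TRANSFORMS[c][1] for c in ANALYSIS_COLUMNS},
        mean={c: float(transformed[c].mean()) for c in ANALYSIS_COLUMNS},
        sd={c: float(transformed[c].std(ddof=1)) for c in ANALYSIS_COLUMNS},
    )
    for c, s in meta.sd.items():
        if not np.isfinite(s) or s == 0:
            raise ValueError(f"trait {c} has zero or undefined variance")
    z = meta.standardize_transformed(transformed)
    return StandardizedMatrix(z, meta)
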