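"""Trait-table and phylogeny I/O plus run configuration.

The trait table is a species-level CSV holding five focal traits (body
mass, litter/clutch size, habitat breadth, generation length, diet
composition over ten categories) and an IUCN Red List category.  Missing
cells are empty or "NA"; no numeric sentinels are used.  A column
dictionary maps the compiled-database / EltonTraits header names onto the
internal schema so real exports load unmodified.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: ten diet-category columns, EltonTraits granularity, internal names
DIET_COLUMNS = [
    "diet_inv",
    "diet_vend",
    "diet_vect",
    "diet_vfish",
    "diet_vunk",
    "diet_scav",
    "diet_fruit",
    "diet_nect",
    "diet_seed",
    "diet_planto",
]

TRAIT_COLUMNS = [
    "body_mass",
    "litter_clutch_size",
    "habitat_breadth",
    "generation_length",
]

IUCN_CATEGORIES = ["CR", "EN", "VU", "NT", "LC", "DD"]

REQUIRED_COLUMNS = (
    ["species_id", "taxon_class"] + TRAIT_COLUMNS + DIET_COLUMNS + ["iucn_category"]
)

#: external header name -> internal schema name (case-insensitive match)
COLUMN_ALIASES: dict[str, str] = {
    "binomial": "species_id",
    "species": "species_id",
    "scientific_name": "species_id",
    "class": "taxon_class",
    "bodymass_value": "body_mass",
    "body_mass_g": "body_mass",
    "adult_mass_g": "body_mass",
    "litter_size": "litter_clutch_size",
    "litter_clutch": "litter_clutch_size",
    "clutch_size": "litter_clutch_size",
    "habitat_number": "habitat_breadth",
    "hab_breadth": "habitat_breadth",
    "generation_length_y": "generation_length",
    "genlength": "generation_length",
    "diet-inv": "diet_inv",
    "diet-vend": "diet_vend",
    "diet-vect": "diet_vect",
    "diet-vfish": "diet_vfish",
    "diet-vunk": "diet_vunk",
    "diet-scav": "diet_scav",
    "diet-fruit": "diet_fruit",
    "diet-nect": "diet_nect",
    "diet-seed": "diet_seed",
    "diet-planto": "diet_planto",
    "iucn": "iucn_category",
    "redlist_category": "iucn_category",
    "category": "iucn_category",
}

DIET_SUM_TOLERANCE = 0.5


class TraitTableError(ValueError):
    """Raised when a trait table violates the schema."""


@dataclasses.dataclass
class TraitTable:
    """Validated species x trait table.

    `df` is indexed 0..n-1 with the internal schema columns.  Diet rows are
    either complete (summing to 100 within tolerance) or entirely missing.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = _validate(self.df.copy())

    # -- convenience ----------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.df)

    @property
    def species_id(self) -> pd.Series:
        return self.df["species_id"]

    def missing_counts(self) -> dict[str, int]:
        """Missing cells per focal trait (diet counted as one trait)."""
        out = {c: int(self.df[c].isna().sum()) for c in TRAIT_COLUMNS}
        out["diet"] = int(self.df[DIET_COLUMNS].isna().all(axis=1).sum())
        return out

    def subset(self, mask) -> "TraitTable":
        return TraitTable(self.df.loc[mask].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, na_rep="NA")


def _normalize_headers(df: pd.DataFrame) -> pd.DataFrame:
    ren = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in COLUMN_ALIASES:
            ren[col] = COLUMN_ALIASES[key]
        elif key in REQUIRED_COLUMNS:
            ren[col] = key
    return df.rename(columns=ren)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    df = _normalize_headers(df)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TraitTableError(f"missing required columns: {missing_cols}")
    df = df[REQUIRED_COLUMNS].reset_index(drop=True)

    dup = df["species_id"][df["species_id"].duplicated()]
    if len(dup):
        raise TraitTableError(f"duplicate species_id: {sorted(set(dup))[:5]}")

    bad_class = ~df["taxon_class"].isin(["mammal", "bird"])
    if bad_class.any():
        raise TraitTableError(
            f"taxon_class must be mammal|bird, got {df.loc[bad_class, 'taxon_class'].unique()}"
        )

    cat = df["iucn_category"]
    bad_cat = cat.notna() & ~cat.isin(IUCN_CATEGORIES)
    if bad_cat.any():
        raise TraitTableError(f"unknown IUCN codes: {cat[bad_cat].unique()}")

    for c in TRAIT_COLUMNS + DIET_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="raise")
        neg = df[c] < 0
        if neg.any():
            raise TraitTableError(
                f"negative values in {c}: species "
                f"{df.loc[neg, 'species_id'].tolist()[:5]}"
            )
    nonpos = df["body_mass"] <= 0
    if nonpos.any():
        raise TraitTableError(
            f"body_mass must be > 0: {df.loc[nonpos, 'species_id'].tolist()[:5]}"
        )
    hb = df["habitat_breadth"].dropna()
    if not np.allclose(hb, np.round(hb)):
        raise TraitTableError("habitat_breadth must be integral")

    diet = df[DIET_COLUMNS]
    any_diet = diet.notna().any(axis=1)
    all_diet = diet.notna().all(axis=1)
    partial = any_diet & ~all_diet
    if partial.any():
        raise TraitTableError(
            "partially missing diet rows (must be complete or all-missing): "
            f"{df.loc[partial, 'species_id'].tolist()[:5]}"
        )
    sums = diet[all_diet].sum(axis=1)
    off = (sums - 100.0).abs() > DIET_SUM_TOLERANCE
    if off.any():
        bad = df.loc[sums.index[off], "species_id"].tolist()
        raise TraitTableError(f"diet rows not summing to 100 +/- 0.5: {bad[:5]}")
    return df


def read_trait_table(path) -> TraitTable:
    """Read and validate a trait-table CSV.

    Logs a per-trait missing-value report.  Raises :class:`TraitTableError`
    on duplicate species ids, bad diet sums (naming the species), or
    unknown IUCN codes.
    """
    df = pd.read_csv(path, na_values=["NA", ""], keep_default_na=True)
    table = TraitTable(df)
    logger.info("read %d species from %s; missing per trait: %s",
                table.n_species, path, table.missing_counts())
    return table


def write_trait_table(table: TraitTable, path) -> None:
    table.to_csv(path)


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PatristicDistances:
    """Tip labels with the symmetric patristic (branch-length) distance matrix."""

    labels: list[str]
    matrix: np.ndarray

    def restrict(self, keep: Sequence[str]) -> "PatristicDistances":
        idx = [self.labels.index(k) for k in keep]
        return PatristicDistances(list(keep), self.matrix[np.ix_(idx, idx)])


def read_tree(path, species_ids: Sequence[str] | None = None) -> PatristicDistances:
    """Parse a Newick tree into a patristic distance matrix.

    Tips are matched to `species_ids` by exact string equality; unmatched
    tips (and unmatched species) are reported via logging and the matrix is
    restricted to the intersection.  Trees must carry branch lengths.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(f"tree {path} has edges without branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    labels = [t.label for t in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = d
    result = PatristicDistances(labels, mat)
    if species_ids is not None:
        wanted = set(species_ids)
        common = [l for l in labels if l in wanted]
        if not common:
            raise ValueError("no tips in common between tree and trait table")
        extra_tips = sorted(set(labels) - wanted)
        extra_sp = sorted(wanted - set(labels))
        if extra_tips:
            logger.warning("tips absent from trait table (dropped): %s", extra_tips[:10])
        if extra_sp:
            logger.warning("species absent from tree: %s", extra_sp[:10])
        result = result.restrict(common)
    return result


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

#: 100-year extinction probabilities per IUCN category
DEFAULT_EXTINCTION_PROBABILITIES = {
    "CR": 0.999,
    "EN": 0.667,
    "VU": 0.1,
    "NT": 0.01,
    "LC": 0.0001,
}

DD_PROBABILITY_FIXED = 0.277


@dataclasses.dataclass
class SvmParams:
    """One-class-SVM hypervolume settings.

    `gamma=None` selects the dimension-aware default 0.3 + 0.1*d (0.5 at
    d=2), applied to internally standardized coordinates so volume
    estimates are scale-equivariant.
    """

    nu: float = 0.01
    gamma: float | None = None
    samples_per_point: int = 500
    max_samples: int = 5_000_000
    box_expansion: float = 0.2

    def resolve_gamma(self, d: int) -> float:
        return self.gamma if self.gamma is not None else 0.3 + 0.1 * d


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    n_replicates: int = 999
    n_imputations: int = 25
    imputation_iterations: int = 10
    extinction_probabilities: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_EXTINCTION_PROBABILITIES)
    )
    dd_mode: str = "as_LC"  # as_LC | drop | fixed_0.277
    draw_mode: str = "fixed_counts"  # fixed_counts | bernoulli
    svm_params: SvmParams = dataclasses.field(default_factory=SvmParams)
    kde_quantiles: tuple[float, ...] = (0.5, 0.95, 0.99)
    diet_axes: int = 1
    occupation_convention: str = "obs_over_mean"  # or mean_of_ratios

    def __post_init__(self) -> None:
        for k, v in self.extinction_probabilities.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"extinction probability for {k} outside [0,1]: {v}")
        for q in self.kde_quantiles:
            if not 0.0 < q < 1.0:
                raise ValueError(f"KDE quantile outside (0,1): {q}")
        if self.n_replicates < 1 or self.n_imputations < 1:
            raise ValueError("replicate/imputation counts must be >= 1")
        if self.dd_mode not in {"as_LC", "drop", "fixed_0.277"}:
            raise ValueError(f"unknown dd_mode {self.dd_mode!r}")
        if self.diet_axes not in (1, 2):
            raise ValueError("diet_axes must be 1 or 2")


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML (keys mirror the dataclass fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    svm = raw.pop("svm_params", None)
    cfg = RunConfig(**raw)
    if svm:
        cfg.svm_params = SvmParams(**svm)
    return cfg
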