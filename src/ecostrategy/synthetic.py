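"""Synthetic trait tables, missingness patterns, and phylogenies.

The generator emulates the statistical structure of the compiled
mammal/bird trait database so every downstream stage is testable without
any external download: log-normal body mass spanning several orders of
magnitude, the reported pairwise correlations among the transformed traits
(a Gaussian copula on the transformed scale gives direct control of
these), guild-structured compositional diets summing to 100, right-skewed
integer habitat breadth (1 + binomial), realistic IUCN category
frequencies with an optional monotone mass–risk coupling, and per-trait
missingness at the documented rates (body mass always complete).

What it does not emulate: phylogenetic covariance of traits (traits are
exchangeable across the simulated tree), taxonomic structure, and spatial
pattern.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .io import DIET_COLUMNS, TraitTable

__all__ = ["SynthSpec", "generate_trait_table", "inject_missingness", "generate_tree"]

#: severity order used by the mass–risk coupling (worst first)
SEVERITY_ORDER = ["CR", "EN", "VU", "NT", "LC"]

_INVERTIVORE = np.array([70, 5, 5, 2, 2, 2, 4, 2, 3, 5], dtype=float)
_HERBIVORE = np.array([5, 1, 1, 1, 1, 1, 20, 5, 20, 45], dtype=float)

#: sigmoid steepness of the guild gradient; sharp enough that the diet
#: ordination separates guilds cleanly by sign
_GUILD_STEEPNESS = 5.0

#: pairwise correlations among the transformed traits
#: (mass, litter, habitat, generation, diet), strongest-to-weakest pattern
#: as observed for real mammals/birds
DEFAULT_CORRELATIONS = np.array(
    [
        #  mass  litt   hab   gen   diet
        [1.00, -0.20, 0.08, 0.41, -0.45],
        [-0.20, 1.00, 0.05, -0.34, -0.02],
        [0.08, 0.05, 1.00, -0.05, 0.15],
        [0.41, -0.34, -0.05, 1.00, 0.06],
        [-0.45, -0.02, 0.15, 0.06, 1.00],
    ]
)

DEFAULT_IUCN_FREQUENCIES = {
    "LC": 0.708,
    "NT": 0.084,
    "VU": 0.081,
    "EN": 0.056,
    "CR": 0.025,
    "DD": 0.046,
}

DEFAULT_MISSINGNESS = {
    "litter_clutch_size": 0.42,
    "habitat_breadth": 0.10,
    "diet": 0.08,
    "generation_length": 0.002,
}


@dataclasses.dataclass
class SynthSpec:
    """Study conditions for the synthetic trait table."""

    n_species: int = 2000
    class_mix: float = 0.338  # fraction mammal
    log10_mass: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {"mammal": (1.90, 1.00), "bird": (1.82, 0.60)}
    )
    litter_log10: tuple[float, float] = (0.35, 0.30)
    generation_log10: tuple[float, float] = (0.62, 0.25)
    habitat_binomial: tuple[int, float] = (12, 0.19)  # breadth = 1 + Binom(n, p)
    diet_concentration: float = 25.0
    target_correlations: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_CORRELATIONS.copy()
    )
    iucn_frequencies: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_IUCN_FREQUENCIES)
    )
    missingness_rates: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    missingness_mechanism: str = "MCAR"  # or "MAR"
    mar_driver: str = "body_mass"
    mar_slope: float = 1.0
    risk_trait_coupling: float | None = None  # logistic strength on z(log mass)

    def __post_init__(self) -> None:
        freq = sum(self.iucn_frequencies.values())
        if abs(freq - 1.0) > 1e-9:
            raise ValueError(f"iucn_frequencies must sum to 1, got {freq}")
        C = np.asarray(self.target_correlations, dtype=float)
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError(
                "correlation matrix not positive semidefinite; "
                "repair with the nearest PSD matrix before use"
            )
        for k, r in self.missingness_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness rate for {k} outside [0,1]")


def generate_trait_table(
    spec: SynthSpec, seed: int, return_truth: bool = False
) -> TraitTable | tuple[TraitTable, pd.DataFrame]:
    """Draw a complete synthetic trait table.

    Continuous traits come from a Gaussian copula with `target_correlations`
    on the transformed scale, then back-transform.  Diet compositions are
    Dirichlet draws whose mean interpolates between an invertivore and a
    herbivore guild profile along the latent diet axis (guild identity is
    returned with `return_truth` for validation).
    """
    rng = substream(seed, "synth.traits")
    n = spec.n_species
    C = np.asarray(spec.target_correlations, dtype=float)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(5))
    Z = rng.standard_normal((n, 5)) @ L.T  # mass, litter, habitat, generation, diet

    is_mammal = rng.random(n) < spec.class_mix
    taxon = np.where(is_mammal, "mammal", "bird")
    mass = np.empty(n)
    for cls, flag in (("mammal", is_mammal), ("bird", ~is_mammal)):
        mu, sd = spec.log10_mass[cls]
        mass[flag] = 10.0 ** (mu + sd * Z[flag, 0])

    lmu, lsd = spec.litter_log10
    litter = np.maximum(10.0 ** (lmu + lsd * Z[:, 1]), 1.0)
    gmu, gsd = spec.generation_log10
    generation = 10.0 ** (gmu + gsd * Z[:, 3])

    # discrete habitat margin via the copula's normal CDF (1 + binomial)
    from scipy import stats

    nb, pb = spec.habitat_binomial
    u = stats.norm.cdf(Z[:, 2])
    habitat = 1 + stats.binom.ppf(u, nb, pb).astype(int)

    # diet: latent gradient -> interpolated guild profile -> Dirichlet draw
    w = 1.0 / (1.0 + np.exp(-_GUILD_STEEPNESS * Z[:, 4]))  # weight on the invertivore guild
    prof_inv = _INVERTIVORE / _INVERTIVORE.sum()
    prof_herb = _HERBIVORE / _HERBIVORE.sum()
    mean_prof = w[:, None] * prof_inv + (1 - w[:, None]) * prof_herb
    alpha = spec.diet_concentration * mean_prof
    comp = rng.gamma(alpha)
    comp = comp / comp.sum(axis=1, keepdims=True) * 100.0

    iucn = _draw_iucn(spec, Z[:, 0], rng)

    df = pd.DataFrame(
        {
            "species_id": [f"sp{i:05d}" for i in range(n)],
            "taxon_class": taxon,
            "body_mass": mass,
            "litter_clutch_size": litter,
            "habitat_breadth": habitat,
            "generation_length": generation,
            **{c: comp[:, j] for j, c in enumerate(DIET_COLUMNS)},
            "iucn_category": iucn,
        }
    )
    table = TraitTable(df)
    if return_truth:
        truth = pd.DataFrame(
            {
                "species_id": df["species_id"],
                "guild": np.where(w > 0.5, "invertivore", "herbivore"),
                "diet_latent": Z[:, 4],
            }
        )
        return table, truth
    return table


def _draw_iucn(spec: SynthSpec, z_mass: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(z_mass)
    cats = list(spec.iucn_frequencies)
    probs = np.array([spec.iucn_frequencies[c] for c in cats])
    if spec.risk_trait_coupling is None:
        return rng.choice(cats, size=n, p=probs / probs.sum())
    # monotone coupling: rank species by beta*z_mass + noise, hand the worst
    # categories to the highest-ranked (largest-bodied) species.  DD is
    # assigned at random first (data deficiency is not a severity grade).
    out = np.empty(n, dtype=object)
    dd_frac = spec.iucn_frequencies.get("DD", 0.0)
    n_dd = int(round(dd_frac * n))
    idx = rng.permutation(n)
    dd_idx, rest = idx[:n_dd], idx[n_dd:]
    out[dd_idx] = "DD"
    beta = spec.risk_trait_coupling
    score = beta * z_mass[rest] + rng.standard_normal(len(rest))
    order = rest[np.argsort(-score)]
    weights = np.array([spec.iucn_frequencies[c] for c in SEVERITY_ORDER])
    counts = np.floor(weights / weights.sum() * len(rest)).astype(int)
    counts[-1] += len(rest) - counts.sum()  # remainder to LC
    start = 0
    for cat, cnt in zip(SEVERITY_ORDER, counts):
        out[order[start : start + cnt]] = cat
        start += cnt
    return out


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------


def inject_missingness(
    table: TraitTable, spec: SynthSpec, seed: int
) -> tuple[TraitTable, pd.DataFrame]:
    """Erase trait cells at the spec's per-trait rates; keep a truth mask.

    Body mass is never erased (complete coverage in the real database).
    Diet is erased row-wise (all ten categories together).  Under "MAR" the
    erasure probability follows a logistic in the z-scored log driver
    trait, with the intercept solved so the marginal rate is preserved.
    Returns (table-with-missing, truth frame of erased values).
    """
    rates = dict(spec.missingness_rates)
    if rates.get("body_mass", 0.0) != 0.0:
        raise ValueError("body mass is always complete; cannot erase it")
    for k, r in rates.items():
        if r >= 1.0:
            raise ValueError(f"missingness rate 1.0 for {k}: trait would be unestimable")
    rng = substream(seed, "synth.missingness")
    df = table.df.copy()
    n = len(df)
    driver = None
    if spec.missingness_mechanism == "MAR":
        raw = df[spec.mar_driver].to_numpy(dtype=float)
        ld = np.log10(raw) if (raw > 0).all() else raw
        driver = (ld - ld.mean()) / ld.std()

    truth_cols: dict[str, pd.Series] = {}
    for trait, rate in rates.items():
        if rate == 0.0:
            continue
        mask = _draw_mask(n, rate, driver, spec.mar_slope, rng)
        if trait == "diet":
            truth_cols.update({c: df[c].where(mask) for c in DIET_COLUMNS})
            df.loc[mask, DIET_COLUMNS] = np.nan
        else:
            truth_cols[trait] = df[trait].where(mask)
            df.loc[mask, trait] = np.nan
    truth = pd.DataFrame(truth_cols, index=df.index)
    truth.insert(0, "species_id", df["species_id"])
    return TraitTable(df), truth


def _draw_mask(
    n: int,
    rate: float,
    driver: np.ndarray | None,
    slope: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if driver is None:
        return rng.random(n) < rate
    # solve the logistic intercept so mean probability == rate
    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = (lo + hi) / 2
        p = 1.0 / (1.0 + np.exp(-(mid + slope * driver)))
        if p.mean() > rate:
            hi = mid
        else:
            lo = mid
    p = 1.0 / (1.0 + np.exp(-((lo + hi) / 2 + slope * driver)))
    return rng.random(n) < p


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def generate_tree(
    n_tips: int, seed: int, labels: Sequence[str] | None = None, model: str = "pure-birth"
) -> str:
    """Ultrametric pure-birth (Yule) tree as a Newick string.

    Lineages split at unit rate; after the n-th tip appears every pending
    branch is extended to the present, so all root-to-tip path lengths are
    equal by construction.
    """
    if model != "pure-birth":
        raise ValueError(f"unknown tree model {model!r}")
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if labels is None:
        labels = [f"sp{i:05d}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")
    return _yule_newick(n_tips, labels, substream(seed, "synth.tree"))


def _yule_newick(n_tips: int, labels: Sequence[str], rng2: np.random.Generator) -> str:
    """Node-based Yule simulation (used by generate_tree)."""

    class _N:
        __slots__ = ("children", "born", "label")

        def __init__(self, born):
            self.children = []
            self.born = born
            self.label = None

    t = 0.0
    root = _N(0.0)
    a, b = _N(0.0), _N(0.0)
    root.children = [a, b]
    tips = [a, b]
    while len(tips) < n_tips:
        t += rng2.exponential(1.0 / len(tips))
        i = int(rng2.integers(len(tips)))
        node = tips.pop(i)
        c1, c2 = _N(t), _N(t)
        node.children = [c1, c2]
        tips.extend([c1, c2])
    t += rng2.exponential(1.0 / len(tips))
    for lab, node in zip(labels, tips):
        node.label = lab

    def render(node: "_N") -> str:
        if not node.children:
            return f"{node.label}:{t - node.born:.12g}"
        inner = ",".join(render(c) for c in node.children)
        parent_born = node.born
        end = node.children[0].born
        return f"({inner}):{end - parent_born:.12g}"

    a_str = render(a)
    b_str = render(b)
    return f"({a_str},{b_str});"
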