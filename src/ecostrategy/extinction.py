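"""Probabilistic 100-year extinction scenarios.

Species are removed according to extinction probabilities attached to
their IUCN Red List categories (CR 0.999, EN 0.667, VU 0.1, NT 0.01,
LC 0.0001 over 100 years).  The projected scenario removes, within each
category, exactly round(count x probability) species chosen uniformly
(fixed-count mode, so every replicate loses the same total — the richness
control); the randomized scenario removes the same total uniformly from
the whole pool.  Per replicate the survivors' strategy-space volume is
recomputed in the *global* SD units (the z-context of the full observed
set is never re-estimated), and back-transformed trait summaries are
recorded.  Scenario ensembles are compared by a two-sample KS test on the
volume distributions, percentile effect sizes against the observed
volume, and rank-based trait-shift permutation tests.

Data Deficient species are handled by `dd_mode`: treated as LC
(default), dropped before simulation, or given the fixed predicted
probability 0.277.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import subseed
from .hypervolume import fit_hypervolume
from .io import DD_PROBABILITY_FIXED, DEFAULT_EXTINCTION_PROBABILITIES, TraitTable
from .traits import TransformMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioEnsemble",
    "ScenarioComparison",
    "expected_losses",
    "simulate_scenario",
    "scenario_ensemble",
    "compare_scenarios",
    "trait_shift_test",
    "summarize_traits",
]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def expected_losses(
    category_counts: dict[str, int], probabilities: dict[str, float]
) -> dict[str, int]:
    """Per-category expected species losses, rounded half-away-from-zero."""
    out = {}
    for cat, cnt in category_counts.items():
        if cat not in probabilities:
            raise ValueError(f"no extinction probability for category {cat!r}")
        if cnt < 0:
            raise ValueError(f"negative count for {cat}")
        out[cat] = _round_half_away(cnt * probabilities[cat])
    return out


def _effective_probabilities(dd_mode: str, probabilities=None) -> dict[str, float]:
    probs = dict(probabilities or DEFAULT_EXTINCTION_PROBABILITIES)
    if dd_mode == "as_LC":
        probs["DD"] = probs["LC"]
    elif dd_mode == "fixed_0.277":
        probs["DD"] = DD_PROBABILITY_FIXED
    elif dd_mode != "drop":
        raise ValueError(f"unknown dd_mode {dd_mode!r}")
    return probs


def apply_dd_mode(table: TraitTable, dd_mode: str) -> TraitTable:
    """Drop DD species when dd_mode='drop'; otherwise return unchanged."""
    if dd_mode == "drop":
        return table.subset(table.df["iucn_category"] != "DD")
    return table


def simulate_scenario(
    table: TraitTable,
    mode: str,
    rng: np.random.Generator,
    draw_mode: str = "fixed_counts",
    dd_mode: str = "as_LC",
    probabilities=None,
) -> TraitTable:
    """One extinction replicate; returns the surviving species.

    mode='projected' removes species category-wise by extinction
    probability; mode='randomized' removes the projected total uniformly
    at random.  With draw_mode='fixed_counts' each category loses exactly
    its rounded expectation; 'bernoulli' draws independent per-species
    fates (total then varies between replicates).
    """
    table = apply_dd_mode(table, dd_mode)
    df = table.df
    if df["iucn_category"].isna().any():
        raise ValueError("every species needs an IUCN category")
    probs = _effective_probabilities(dd_mode)
    if probabilities is not None:
        probs = {**probs, **probabilities}
    counts = df["iucn_category"].value_counts().to_dict()
    losses = expected_losses(counts, probs)

    n = len(df)
    dead = np.zeros(n, dtype=bool)
    if mode == "projected":
        if draw_mode == "fixed_counts":
            for cat, k in losses.items():
                idx = np.flatnonzero((df["iucn_category"] == cat).to_numpy())
                if k > len(idx):
                    raise ValueError(f"loss {k} exceeds count {len(idx)} for {cat}")
                if k > 0:
                    dead[rng.choice(idx, size=k, replace=False)] = True
        elif draw_mode == "bernoulli":
            p = df["iucn_category"].map(probs).to_numpy(dtype=float)
            dead = rng.random(n) < p
        else:
            raise ValueError(f"unknown draw_mode {draw_mode!r}")
    elif mode == "randomized":
        total = sum(losses.values())
        dead[rng.choice(n, size=total, replace=False)] = True
    else:
        raise ValueError(f"unknown scenario mode {mode!r}")
    return table.subset(~dead)


def summarize_traits(df: pd.DataFrame) -> dict[str, float]:
    """Back-transformed per-trait means and medians.

    Expects raw-scale columns body_mass, litter_clutch_size,
    habitat_breadth, generation_length plus the standardized diet_score.
    Log-transformed traits are summarized by the geometric mean
    (10^mean(log10)); habitat breadth by (mean sqrt)^2; diet by the
    arithmetic mean of the axis score.  Medians are raw-scale medians.
    """
    if len(df) == 0:
        raise ValueError("empty table")
    out = {}
    for col in ("body_mass", "litter_clutch_size", "generation_length"):
        x = df[col].to_numpy(dtype=float)
        out[f"{col}_mean"] = float(10.0 ** np.mean(np.log10(x)))
        out[f"{col}_median"] = float(np.median(x))
    hb = df["habitat_breadth"].to_numpy(dtype=float)
    out["habitat_breadth_mean"] = float(np.mean(np.sqrt(hb)) ** 2)
    out["habitat_breadth_median"] = float(np.median(hb))
    ds = df["diet_score"].to_numpy(dtype=float)
    out["diet_score_mean"] = float(np.mean(ds))
    out["diet_score_median"] = float(np.median(ds))
    return out


@dataclasses.dataclass
class ScenarioEnsemble:
    scenario: str
    volumes: np.ndarray
    survivor_counts: np.ndarray
    trait_summaries: pd.DataFrame  # one row per replicate
    n_replicates: int
    seed: int
    survivor_hashes: list[int] = dataclasses.field(default_factory=list)


def scenario_ensemble(
    table: TraitTable,
    completed: pd.DataFrame,
    z_context: TransformMetadata,
    n_replicates: int,
    mode: str,
    svm_params=None,
    draw_mode: str = "fixed_counts",
    dd_mode: str = "as_LC",
    probabilities=None,
    seed: int = 0,
) -> ScenarioEnsemble:
    """Replicate an extinction scenario and recompute volumes.

    `completed` is the imputation-completed transformed (pre-z) trait
    matrix indexed by species_id (columns ANALYSIS_COLUMNS); `z_context`
    holds the full observed set's z-parameters so survivor volumes stay in
    the same SD^5 units.  Per-replicate trait summaries are computed on
    the back-transformed scale.
    """
    table = apply_dd_mode(table, dd_mode)
    base = subseed(seed, f"extinction.{mode}")
    streams = base.spawn(n_replicates)
    vols, counts, rows, hashes = [], [], [], []
    failures = 0
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        survivors = simulate_scenario(
            table, mode, rng, draw_mode=draw_mode, dd_mode=dd_mode,
            probabilities=probabilities,
        )
        ids = survivors.df["species_id"]
        sub = completed.loc[ids]
        z = z_context.standardize_transformed(sub)
        rep_seed = int(ss.generate_state(1)[0] % (2**31))
        try:
            hv = fit_hypervolume(z.to_numpy(), params=svm_params, seed=rep_seed)
        except ValueError as err:
            failures += 1
            logger.warning("scenario replicate %d failed: %s", i, err)
            continue
        vols.append(hv.volume)
        counts.append(len(ids))
        hashes.append(hash(tuple(ids)))
        raw = z_context.inverse(z)
        raw = raw.rename(
            columns={
                "mass": "body_mass",
                "litter": "litter_clutch_size",
                "habitat": "habitat_breadth",
                "generation": "generation_length",
                "diet": "diet_score",
            }
        )
        rows.append(summarize_traits(raw))
    if failures >= 0.05 * n_replicates and failures > 0:
        raise RuntimeError(f"{failures}/{n_replicates} scenario replicates failed")
    return ScenarioEnsemble(
        scenario=mode,
        volumes=np.asarray(vols),
        survivor_counts=np.asarray(counts),
        trait_summaries=pd.DataFrame(rows),
        n_replicates=len(vols),
        seed=seed,
        survivor_hashes=hashes,
    )


@dataclasses.dataclass
class ScenarioComparison:
    ks_statistic: float
    ks_pvalue: float
    effect_size_a: float  # observed - mean volume of ensemble a
    effect_size_a_ci: tuple[float, float]
    effect_size_b: float
    effect_size_b_ci: tuple[float, float]


def compare_scenarios(
    ens_a: ScenarioEnsemble, ens_b: ScenarioEnsemble, observed_volume: float
) -> ScenarioComparison:
    """Two-sample KS test on volumes plus percentile effect sizes.

    Effect sizes are observed_volume minus per-replicate volume, reported
    as the mean with the 2.5/97.5 percentile interval, per ensemble.
    """
    if min(ens_a.n_replicates, ens_b.n_replicates) < 5:
        raise ValueError("need at least 5 replicates per ensemble")
    ks = stats.ks_2samp(ens_a.volumes, ens_b.volumes, method="asymp")

    def effect(vols):
        diff = observed_volume - vols
        lo, hi = np.percentile(diff, [2.5, 97.5])
        return float(diff.mean()), (float(lo), float(hi))

    ea, cia = effect(ens_a.volumes)
    eb, cib = effect(ens_b.volumes)
    return ScenarioComparison(
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        effect_size_a=ea,
        effect_size_a_ci=cia,
        effect_size_b=eb,
        effect_size_b_ci=cib,
    )


def trait_shift_test(
    observed_summary: dict[str, float],
    ensemble: ScenarioEnsemble,
    trait: str,
    statistic: str = "mean",
) -> dict:
    """Rank-based permutation test of a trait-distribution shift.

    Direction is set by the sign of (observed - mean replicate summary);
    p = (1 + #{replicates on the observed side}) / (n + 1), one-tailed.
    Reports the replicate min-max alongside.
    """
    key = f"{trait}_{statistic}"
    obs = observed_summary[key]
    reps = ensemble.trait_summaries[key].to_numpy(dtype=float)
    if np.ptp(reps) == 0:
        raise ValueError(f"replicate summaries for {key} are constant; p undefined")
    mean_rep = float(reps.mean())
    if mean_rep < obs:
        direction = "decrease"
        n_side = int((reps >= obs).sum())
    else:
        direction = "increase"
        n_side = int((reps <= obs).sum())
    p = (1 + n_side) / (len(reps) + 1)
    return {
        "trait": trait,
        "statistic": statistic,
        "observed": obs,
        "replicate_mean": mean_rep,
        "replicate_min": float(reps.min()),
        "replicate_max": float(reps.max()),
        "direction": direction,
        "p_value": p,
    }


def median_mass_reduction(
    observed_summary: dict[str, float], ensemble: ScenarioEnsemble
) -> dict[str, float]:
    """Percent reduction in median body mass, with replicate min-max."""
    obs = observed_summary["body_mass_median"]
    reps = ensemble.trait_summaries["body_mass_median"].to_numpy(dtype=float)
    red = 100.0 * (1.0 - reps / obs)
    return {
        "percent_mean": float(red.mean()),
        "percent_min": float(red.min()),
        "percent_max": float(red.max()),
    }
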