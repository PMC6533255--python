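"""Model-object interface to the full analysis pipeline.

`StrategySpaceModel` is built from a trait table (optionally with
per-class phylogenies); `fit()` runs diet ordination, imputation, the
PCA strategy surface with KDE contours, and the 5-D hypervolumes, and
returns a `StrategySpaceResults` carrying the estimates.  Null-model
occupation tests and extinction forecasts hang off the results object.
Every stochastic stage consumes a named substream of the master seed, so
the whole run is a pure function of (inputs, seed) and changing one
stage's replicate count does not perturb another stage's draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .extinction import (
    ScenarioComparison,
    ScenarioEnsemble,
    apply_dd_mode,
    compare_scenarios,
    median_mass_reduction,
    scenario_ensemble,
    summarize_traits,
    trait_shift_test,
)
from .hypervolume import Hypervolume, SetOperationResult, fit_hypervolume, point_density, set_operations
from .impute import ImputedEnsemble, impute_table, phylo_eigenvectors
from .io import PatristicDistances, RunConfig, TraitTable
from .nulls import OccupationResult, occupation_test
from .surface import SurfaceResult, average_over_imputations, kde_contours, pca_surface
from .traits import ANALYSIS_COLUMNS, TransformMetadata, diet_axis, transform_traits

logger = logging.getLogger(__name__)

__all__ = ["StrategySpaceModel", "StrategySpaceResults", "run_pipeline"]


class StrategySpaceModel:
    """Ecological strategy surface + space model for a trait table.

    Parameters
    ----------
    table : TraitTable
        Validated species x trait table.
    trees : dict, optional
        Map of taxon class ('mammal'/'bird') to patristic distances, used
        for the phylogenetic-eigenvector imputation predictors.
    config : RunConfig, optional
        Replicate counts, SVM parameters, extinction probabilities etc.
    """

    def __init__(
        self,
        table: TraitTable,
        trees: dict[str, PatristicDistances] | None = None,
        config: RunConfig | None = None,
    ):
        self.table = table
        self.trees = trees or {}
        self.config = config or RunConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "StrategySpaceModel":
        return cls(TraitTable(df), **kwargs)

    def fit(self, seed: int | None = None) -> "StrategySpaceResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        table = apply_dd_mode(self.table, cfg.dd_mode)

        # 1. diet axis from the compositional data
        diet_scores, diet_loadings, diet_ord = diet_axis(table, n_axes=cfg.diet_axes)
        logger.info("diet axis 1 explains %.1f%% of diet variation",
                    100 * diet_ord.variance_fraction[0])

        # 2. transformed (pre-z) matrix; missing cells remain
        transformed = transform_traits(table, diet_scores)

        # 3. imputation (skipped when complete)
        eig = {
            cls_: phylo_eigenvectors(pdm, k=10) for cls_, pdm in self.trees.items()
        }
        taxon = pd.Series(
            table.df["taxon_class"].to_numpy(), index=transformed.index
        )
        if transformed.isna().any().any():
            ensemble = impute_table(
                transformed, taxon, eig or None,
                m=cfg.n_imputations, n_iter=cfg.imputation_iterations, seed=seed,
            )
        else:
            ensemble = ImputedEnsemble(
                members=[transformed.copy() for _ in range(cfg.n_imputations)],
                imputed_mask=transformed.isna(),
                chain_means=pd.DataFrame(),
            )

        # 4. strategy surface: PCA per imputed dataset, average scores
        std_members = ensemble.standardized()
        pca_members = [pca_surface(z) for z in std_members]
        surface = average_over_imputations(pca_members)
        gx, gy, dens, levels, contours, pdens = kde_contours(
            surface.scores.to_numpy(), quantiles=cfg.kde_quantiles
        )
        surface.density_grid, surface.grid_x, surface.grid_y = dens, gx, gy
        surface.contours, surface.hdr_levels = contours, levels

        # 5. hypervolumes from one randomly selected imputed dataset,
        #    z-scored once on the full set (the global SD^5 context)
        rng = substream(seed, "pipeline.pick_imputation")
        pick = int(rng.integers(len(ensemble.members)))
        completed = ensemble.members[pick]
        from .traits import TRANSFORMS

        z_context = TransformMetadata(
            transform={c: TRANSFORMS[c][1] for c in ANALYSIS_COLUMNS},
            mean={c: float(completed[c].mean()) for c in ANALYSIS_COLUMNS},
            sd={c: float(completed[c].std(ddof=1)) for c in ANALYSIS_COLUMNS},
        )
        zfull = z_context.standardize_transformed(completed)
        hv_seed = int(substream(seed, "pipeline.hv").integers(2**31))
        hv_all = fit_hypervolume(zfull.to_numpy(), params=cfg.svm_params, seed=hv_seed)

        hv_class: dict[str, Hypervolume] = {}
        for cls_ in ("mammal", "bird"):
            mask = (taxon == cls_).to_numpy()
            if mask.sum() >= 7:
                s = int(substream(seed, f"pipeline.hv.{cls_}").integers(2**31))
                hv_class[cls_] = fit_hypervolume(
                    zfull.to_numpy()[mask], params=cfg.svm_params, seed=s
                )

        return StrategySpaceResults(
            model=self,
            table=table,
            seed=seed,
            diet_loadings=diet_loadings,
            diet_variance_fraction=float(diet_ord.variance_fraction[0]),
            ensemble=ensemble,
            surface=surface,
            z_context=z_context,
            completed=completed,
            zmatrix=zfull,
            hypervolume=hv_all,
            class_hypervolumes=hv_class,
            selected_imputation=pick,
        )


@dataclasses.dataclass
class StrategySpaceResults:
    """Fitted surface, hypervolumes and downstream analyses."""

    model: StrategySpaceModel
    table: TraitTable
    seed: int
    diet_loadings: pd.DataFrame
    diet_variance_fraction: float
    ensemble: ImputedEnsemble
    surface: SurfaceResult
    z_context: TransformMetadata
    completed: pd.DataFrame  # selected imputed dataset, pre-z scale
    zmatrix: pd.DataFrame
    hypervolume: Hypervolume
    class_hypervolumes: dict[str, Hypervolume]
    selected_imputation: int

    # -- derived ---------------------------------------------------------
    def class_overlap(self) -> SetOperationResult | None:
        """Mammal/bird strategy-space intersection, union, unique parts."""
        if set(self.class_hypervolumes) != {"mammal", "bird"}:
            return None
        s = int(substream(self.seed, "pipeline.setops").integers(2**31))
        return set_operations(
            self.class_hypervolumes["mammal"], self.class_hypervolumes["bird"], seed=s
        )

    def occupation(self, model_id: int, n_replicates: int | None = None) -> OccupationResult:
        cfg = self.model.config
        n = n_replicates or cfg.n_replicates
        return occupation_test(
            self.hypervolume,
            self.zmatrix.to_numpy(),
            model_id,
            n_replicates=n,
            svm_params=cfg.svm_params,
            seed=self.seed,
        )

    def observed_trait_summary(self) -> dict[str, float]:
        raw = self.z_context.inverse(
            self.z_context.standardize_transformed(self.completed)
        ).rename(
            columns={
                "mass": "body_mass",
                "litter": "litter_clutch_size",
                "habitat": "habitat_breadth",
                "generation": "generation_length",
                "diet": "diet_score",
            }
        )
        # diet summaries are on the z scale; replace with the z-scored axis
        raw["diet_score"] = self.zmatrix["diet"].to_numpy()
        return summarize_traits(raw)

    def forecast(
        self, n_replicates: int | None = None, modes=("projected", "randomized")
    ) -> dict[str, ScenarioEnsemble]:
        cfg = self.model.config
        n = n_replicates or cfg.n_replicates
        out = {}
        for mode in modes:
            out[mode] = scenario_ensemble(
                self.table,
                self.completed,
                self.z_context,
                n_replicates=n,
                mode=mode,
                svm_params=cfg.svm_params,
                draw_mode=cfg.draw_mode,
                dd_mode=cfg.dd_mode,
                probabilities=dict(cfg.extinction_probabilities),
                seed=self.seed,
            )
        return out

    def compare(self, ensembles: dict[str, ScenarioEnsemble]) -> ScenarioComparison:
        return compare_scenarios(
            ensembles["randomized"], ensembles["projected"], self.hypervolume.volume
        )

    def trait_shifts(self, ensemble: ScenarioEnsemble) -> pd.DataFrame:
        obs = self.observed_trait_summary()
        rows = [
            trait_shift_test(obs, ensemble, trait)
            for trait in (
                "body_mass",
                "generation_length",
                "litter_clutch_size",
                "habitat_breadth",
                "diet_score",
            )
        ]
        return pd.DataFrame(rows)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        sf = self.surface
        lines = [
            "Ecological strategy space model",
            "===============================",
            f"species: {self.table.n_species} "
            f"({(self.table.df['taxon_class'] == 'mammal').sum()} mammal, "
            f"{(self.table.df['taxon_class'] == 'bird').sum()} bird)",
            f"imputations: {len(self.ensemble)} (hypervolumes use member "
            f"{self.selected_imputation})",
            f"diet axis 1 variance fraction: {self.diet_variance_fraction:.3f}",
            "",
            "PC variance fractions: "
            + ", ".join(f"{v:.3f}" for v in sf.variance_fraction),
            f"PC1+PC2 explain {100 * sf.variance_fraction[:2].sum():.1f}% of trait variation",
            "loadings (traits x PCs):",
            sf.loadings.round(3).to_string(),
            "",
            f"5-D strategy space volume: {self.hypervolume.volume:.1f} SD^5 "
            f"({point_density(self.hypervolume):.2f} species/SD^5)",
        ]
        for cls_, hv in self.class_hypervolumes.items():
            lines.append(
                f"  {cls_}: volume {hv.volume:.1f} SD^5, "
                f"density {point_density(hv):.2f} species/SD^5"
            )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write the machine-readable result bundle (CSVs + JSON summary)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.surface.scores.to_csv(outdir / "surface_scores.csv")
        self.surface.loadings.to_csv(outdir / "pca_loadings.csv")
        self.diet_loadings.to_csv(outdir / "diet_loadings.csv")
        if self.surface.contours:
            rows = []
            for q, polys in self.surface.contours.items():
                for pi, poly in enumerate(polys):
                    for vi, (x, y) in enumerate(poly):
                        rows.append((q, pi, vi, x, y))
            pd.DataFrame(
                rows, columns=["quantile", "polyline", "vertex", "x", "y"]
            ).to_csv(outdir / "surface_contours.csv", index=False)
        summary = {
            "seed": self.seed,
            "n_species": self.table.n_species,
            "variance_fraction": self.surface.variance_fraction.tolist(),
            "diet_variance_fraction": self.diet_variance_fraction,
            "volume_sd5": self.hypervolume.volume,
            "class_volumes": {k: v.volume for k, v in self.class_hypervolumes.items()},
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)


def run_pipeline(
    config: RunConfig,
    table: TraitTable,
    trees: dict[str, PatristicDistances] | None = None,
    outdir=None,
    null_models=(1, 2, 3, 4),
    run_extinction: bool = True,
) -> dict:
    """End-to-end pipeline: surface, hypervolumes, nulls, extinction.

    Deterministic given (config.seed, inputs).  Returns the report bundle
    as a dict of tables/objects; writes CSV/JSON when `outdir` is given.
    """
    model = StrategySpaceModel(table, trees=trees, config=config)
    res = model.fit()
    report: dict = {"results": res}

    occ_rows = []
    for mid in null_models:
        occ = res.occupation(mid)
        occ_rows.append(
            {
                "model_id": mid,
                "occupation": occ.occupation,
                "occupation_mean_of_ratios": occ.occupation_mean_of_ratios,
                "mean_null_volume": occ.mean_null_volume,
                "observed_volume": occ.observed_volume,
                "p_value": occ.p_value,
            }
        )
    report["occupation"] = pd.DataFrame(occ_rows)

    if run_extinction:
        ens = res.forecast()
        report["scenarios"] = ens
        report["comparison"] = res.compare(ens)
        report["trait_shifts"] = res.trait_shifts(ens["projected"])
        report["median_mass_reduction"] = median_mass_reduction(
            res.observed_trait_summary(), ens["projected"]
        )

    if outdir is not None:
        outdir = Path(outdir)
        res.save(outdir)
        if occ_rows:
            report["occupation"].to_csv(outdir / "occupation.csv", index=False)
        if run_extinction:
            vols = pd.concat(
                [
                    pd.DataFrame(
                        {"scenario": name, "replicate": np.arange(e.n_replicates),
                         "volume": e.volumes}
                    )
                    for name, e in ens.items()
                ]
            )
            vols.to_csv(outdir / "scenario_volumes.csv", index=False)
            report["trait_shifts"].to_csv(outdir / "trait_shifts.csv", index=False)
            comp = report["comparison"]
            with open(outdir / "comparison.json", "w") as fh:
                json.dump(dataclasses.asdict(comp), fh, indent=2)
    return report
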