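# ecostrategy

Trait-based analysis of mammal and bird **ecological strategies**: the
package builds the 2-D ecological strategy *surface* and the 5-D
strategy *space* of a species pool from five traits — body mass (g),
litter/clutch size, habitat breadth, generation length (years), and
diet — tests how much of the space permitted by null models of trait
variation is actually occupied, and forecasts how the space contracts
under probabilistic 100-year extinction scenarios compared with random
species loss.  It is written for macroecologists and conservation
scientists working with species × trait tables (e.g. EltonTraits-style
diet compositions plus IUCN Red List categories), and it ships a
synthetic-data generator so the entire pipeline is testable without any
data download.

## The model

Diet enters as a continuous axis: Gower distances between the ten-part
compositional diet records, ordinated by principal coordinates (PCoA);
axis 1 runs from invertivores (+) to herbivores (−).  The five traits
are transformed (log₁₀ mass, log₁₀ litter/clutch, √habitat breadth,
log₁₀ generation length, diet axis) and z-scored, so every analysis
lives in unitless SD coordinates.

- **Surface**: PCA of the z-matrix; species scores on PC1/PC2 (averaged
  over an ensemble of *m* = 25 chained-equation imputations with
  phylogenetic-eigenvector predictors), with occurrence-probability
  contours at the 0.5/0.95/0.99 highest-density regions of a bivariate
  Gaussian KDE.
- **Space**: a one-class SVM (Gaussian kernel) encloses the 5-D point
  cloud; the volume *V* (in SD⁵) is estimated by uniform Monte-Carlo
  sampling of an expanded bounding box.  Occupation of null model *k* is
  *V*obs / mean(*V*null) over replicated null fits, with the rank-based
  permutation p-value *p* = (1 + #{*V*null ≤ *V*obs}) / (*n* + 1).
- **Forecast**: species go extinct with IUCN-category probabilities
  (CR 0.999, EN 0.667, VU 0.1, NT 0.01, LC 0.0001 per century); a
  randomized scenario removes the same number of species at random.
  Replicated scenario volumes are compared by a two-sample KS test,
  effect sizes against the observed volume, and rank-based tests of
  back-transformed trait shifts (geometric-mean body mass, etc.).

See `docs/methods.md` for estimator details, defaults and limitations.

## Worked example

```python
from ecostrategy import RunConfig, StrategySpaceModel, SvmParams, SynthSpec, \
    generate_trait_table, inject_missingness

spec = SynthSpec(n_species=2000, risk_trait_coupling=1.5)
table, _ = inject_missingness(generate_trait_table(spec, seed=1), spec, seed=1)

cfg = RunConfig(seed=1, n_imputations=5, n_replicates=99)
cfg.svm_params = SvmParams(samples_per_point=100)
res = StrategySpaceModel(table, config=cfg).fit()
print(res.summary())

occ = res.occupation(1)          # null model 1: independent uniforms
ens = res.forecast()             # projected vs randomized extinction
comp = res.compare(ens)
print(f"occupation={occ.occupation:.2f} p={occ.p_value:.3f}  KS D={comp.ks_statistic:.2f}")
```

which prints (abridged):

```
Ecological strategy space model
===============================
species: 2000 (699 mammal, 1301 bird)
imputations: 5 (hypervolumes use member 0)
diet axis 1 variance fraction: 0.447

PC variance fractions: 0.345, 0.238, 0.201, 0.140, 0.076
PC1+PC2 explain 58.2% of trait variation
...
5-D strategy space volume: 423.5 SD^5 (4.72 species/SD^5)
  mammal: volume 320.1 SD^5, density 2.18 species/SD^5
  bird: volume 289.9 SD^5, density 4.49 species/SD^5
occupation=0.10 p=0.010  KS D=0.82
```

Reading the output: PC1+PC2 carry about half of the trait variance (PC1
is the mass/fast–slow axis, PC2 the diet/habitat-breadth axis); the
observed 5-D cloud occupies only a small fraction of the uniform
null's hypercube (occupation ≪ 1, p at the permutation floor); and
because extinction risk is coupled to body mass in these synthetic
conditions, the projected scenario contracts the strategy space more
than the randomized control (KS D well above 0), shifting the surviving
pool toward smaller-bodied species.

The same pipeline is scriptable from the shell:

```sh
ecostrategy synth --n-species 2000 --seed 1 --out traits.csv
ecostrategy run traits.csv --seed 1 --replicates 99 --out results/
```

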