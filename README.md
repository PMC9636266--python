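# fcsweep

**Threshold sensitivity of EEG functional-connectivity graph analysis.**

Graph analyses of M/EEG functional connectivity almost always begin by
thresholding a dense synchronization matrix — deleting "weak" edges below a
proportional (quantile) cutoff — before computing network measures. The
cutoff is arbitrary, and the choice can change not just the values of the
network measures but the *conclusions* of a group comparison. `fcsweep` is a
pipeline for quantifying exactly that sensitivity:

* estimate five spectral synchronization measures per channel pair —
  **wPLI** `|E[Im S_xy]| / E[|Im S_xy|]`, **ImCoh**
  `Im(E[S_xy] / √(E[S_xx]·E[S_yy]))`, **coherence**
  `|E[S_xy]| / √(E[S_xx]·E[S_yy])`, **ciPLV**
  `Im(PLV) / √(1 − Re(PLV)²)` and **PPC**, the unbiased pairwise phase
  consistency — from Hann-windowed per-epoch cross-spectra in a frequency
  band (default alpha, 8–13 Hz);
* sweep proportional quantile thresholds **q = 0.01 … 0.99** over each
  subject's own edge-weight distribution, removing edges strictly below the
  q-quantile, then pruning isolated nodes and keeping the largest component;
* compute four global graph measures at every level: characteristic path
  length (**median** hop count over node pairs), binary clustering
  coefficient, mean participation coefficient `1 − Σ_m (k_im/k_i)²` against
  a modularity partition, and the small-world index
  `σ = (C/⟨C_rand⟩) / (L/⟨L_rand⟩)` with degree-preserving rewired nulls;
* build cohort-level **edge-probability graphs** (per edge, the fraction of
  subjects whose pruned network contains it) across all thresholds, and
  **orthogonal-MST** networks selected by maximizing global efficiency minus
  wiring cost `J(m) = GE(m) − cost(m)`, compared against the proportional
  threshold of matched density;
* run the statistical layer: metric-vs-threshold OLS, subject-wise Spearman
  correlations between thresholds, and permutation t-tests with Cohen's *d*
  per threshold for two-group designs.

Because real resting-state EEG cohorts are rarely shareable, the package
includes a first-class synthetic-cohort generator: band-limited oscillators
with fixed-phase-lag coupling between designated channel pairs, chained
driver modules whose synchronization decays with within-module distance,
per-subject coupling variability, and planted two-group effects — so every
downstream behavior can be exercised against known ground truth.

## Worked example

```python
from fcsweep import (
    CohortSpec, modular_oscillator_spec, generate_cohort, band_connectivity,
    run_sweep, add_metrics, fit_density_regression, extract_orthogonal_msts,
)

# a small synthetic cohort: 16 channels, 2 planted modules, 6 subjects/group
base = modular_oscillator_spec(n_channels=16, n_modules=2, seed=0)
cohort = CohortSpec(n_subjects_per_group=6, seed=0)
recordings = generate_cohort(cohort, base, epoch_length=512)

# alpha-band wPLI connectivity, one matrix per subject
matrices = [band_connectivity(rec, "wpli") for rec in recordings]

# proportional-threshold sweep q = 0.01 ... 0.99 with the four graph measures
sweep = run_sweep(matrices)
add_metrics(sweep, master_seed=0)
df = sweep.to_frame()

for metric in ("cpl", "clustering", "participation", "swi"):
    fit = fit_density_regression(df, metric, x="q")
    print(f"{metric:>14}: slope vs q = {fit.slope:+.3f}  adj R^2 = {fit.adj_r_squared:.2f}")

res = extract_orthogonal_msts(matrices[0])
print(f"\nOMST: {res.selected_m} trees selected, union density "
      f"{res.density:.3f}, J(selected) = {res.gce_trace[res.selected_m - 1][3]:.3f}")
```

Output:

```
           cpl: slope vs q = +1.273  adj R^2 = 0.42
    clustering: slope vs q = -0.705  adj R^2 = 0.75
 participation: slope vs q = -0.560  adj R^2 = 0.67
           swi: slope vs q = +1.171  adj R^2 = 0.20

OMST: 1 trees selected, union density 0.125, J(selected) = 0.456
```

The slopes say what the sweep is for: as the threshold level q rises
(density falls), path length grows while clustering and participation fall —
a large fraction of each measure's variance is explained by the analyst's
threshold choice alone, before any physiology enters. The OMST line shows
the data-driven alternative: for this subject the efficiency/cost trade-off
peaks after one orthogonal tree, a union network of 12.5% density.

## Command line

The same stages are available as subcommands over delimited-text artifacts:

```
fcsweep all --config demo.yaml --seed 1 --out results/
fcsweep simulate | connectivity | sweep | omst | edgeprob | stats ...
```

Every run writes a `manifest.json` with the resolved configuration, package
version and master seed; identical config + seed reproduces all CSV outputs
byte for byte.

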