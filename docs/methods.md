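# Methods

## Synthetic recordings and cohorts

Each channel carries a phase trajectory `φ(t)` obtained by integrating an
instantaneous frequency that performs a reflected random walk inside the
carrier band (default 8–13 Hz, step SD `freq_drift_sd` = 0.05 Hz per sample
at 256 Hz, i.e. ≈ 1.1 Hz of wander over a 2-s epoch). The signal is
`cos φ(t)` plus white measurement noise of SD `noise_sd` (default 1.0,
equal to the oscillation's RMS ≈ 0.71 — a low-ish but realistic SNR for a
narrow-band component).

For a coupled pair `(i, j)` with lag θ and strength `s ∈ [0, 1]`:

```
φ_j(t) = φ_i(t) + θ + (1 − s) · η(t)
```

where η is an independent Ornstein–Uhlenbeck phase jitter with stationary SD
`phase_noise_sd` (default π rad) and correlation time `phase_noise_tau`
(default 0.5 s). The two limits are analytic: at `s = 1` the phase
difference is exactly θ at every sample, so wPLI = ciPLV = PPC =
coherence = 1 and |ImCoh| = sin θ at the carrier frequency; at `s = 0` the
residual phase concentration is `exp(−π²/2) ≈ 7·10⁻³`, i.e. chance-level
synchronization. In between, tracking fidelity grows smoothly as
`exp(−((1 − s)·phase_noise_sd)²/2)`, so a coupling-strength difference
between groups translates into a graded synchronization difference rather
than a step.

The default cohort layout (`modular_oscillator_spec`) consists of chained
driver modules: a driver channel whose phase propagates hop by hop along a
chain of followers, each hop adding a distinct non-zero lag (spread over
(π/6, 5π/6)) and fresh jitter. Synchronization therefore decays with
within-module distance, emulating the spatially graded connectivity of
sensor recordings; the strongest edges of a subject are the chain links, the
second tier the distance-2 edges, and so on. Uniform all-to-all modules were
deliberately avoided: they make the top percentile of edges a union of
cliques, which no measured cohort shows. Remaining channels are independent
background oscillators. Cohorts draw per-subject coupling strengths around
the group mean (SD `subject_variability_sd` = 0.1, clipped to [0, 1]); a
`GroupEffect` shifts group B's mean strengths or adds extra coupled pairs.

What the generator does **not** emulate: 1/f background spectra, broadband
artifacts, volume-conduction mixing across all channels, 2-D scalp geometry,
or realistic forward models. Tests passing on these cohorts demonstrate that
the pipeline's behavior under threshold variation is as designed, not that
any particular empirical EEG result will replicate.

## Spectral estimation

Cross-spectra are Hann-windowed FFTs of fixed-length, non-overlapping epochs
(trailing partial epoch discarded; default epoch 512 samples = 2 s at
256 Hz, giving 0.5-Hz resolution; at least 2 epochs required). No epoch
length for connectivity estimation is standard in the literature, so it is a
free configuration parameter. Per-bin measure values are averaged over bins
whose center lies in the band (inclusive), then rectified into a
non-negative edge strength: |ImCoh|, |ciPLV|, PPC clipped at zero (wPLI and
coherence are already non-negative). Rectification is configurable
(`abs`/`clip`/`raw`) because quantile thresholding and spanning trees need
an unsigned strength ordering, and whether signed measures should be folded
or clipped is a genuine analytic choice. The wPLI and ciPLV guards
(denominator → 0, |Re PLV| → 1) return 0, with the wPLI guard scale-aware so
that machine-precision imaginary residue of an exactly real cross-spectrum
does not masquerade as lag.

## Thresholding

The threshold at level q is the q-quantile (linear interpolation between
order statistics — a nearest-rank rule is available via the
`interpolation` argument) of the subject's own off-diagonal upper-triangle
weights; the diagonal is structurally zero and is excluded. Edges strictly
below the threshold are eliminated, so ties at the threshold survive and an
all-equal matrix is never emptied. Isolated nodes are then removed and
recorded; if the remainder is disconnected, only the largest component
survives, ties broken toward the component containing the lexicographically
smallest label (determinism). Densities are reported against the original
node count so they remain comparable across subjects: with all-distinct
weights the surviving-edge fraction equals `1 − q` to one-edge rounding
(q = 0.55 keeps 45% of edges, q = 0.01 keeps 99%).

## Graph measures

* **Characteristic path length**: the *median* unweighted hop count over all
  unordered node pairs (mean behind a flag). Requires a connected graph —
  pruning must precede.
* **Clustering**: mean binary per-node clustering; degree < 2 contributes 0.
  A weighted variant is behind a flag.
* **Participation**: `1 − Σ_m (k_im/k_i)²` per node, averaged. The module
  partition defaults to weight-aware greedy modularity maximization on the
  pruned graph: using the synchronization weights lets near-complete
  low-threshold graphs still resolve the planted modular structure (binary
  modularity on a 99%-dense graph returns one module and a constant
  participation of 0, which would be an artifact of the partition method,
  not of the network).
* **Small-world index**: `σ = (C/⟨C_rand⟩)/(L/⟨L_rand⟩)` with C and L as
  above, against `n_random_refs` = 20 degree-preserving double-edge-swap
  references (10 swap attempts per edge; disconnected rewires resampled, up
  to 50 retries). The rewiring runs through igraph's C implementation,
  seeded per (subject, measure, q) from the master seed; the reference-side
  clustering and median-path statistics are definitionally identical to the
  package's own operations (tested). Conventions: a graph with zero
  clustering gets σ = 0 (it cannot be small-world); a degree sequence that
  admits no rewiring (complete graph) is its own null, σ = 1; a clustered
  graph whose entire null ensemble has zero clustering yields NaN rather
  than ∞. σ is the classic ratio form; a lattice-referenced index is a
  possible extension point but is not implemented.

## Orthogonal MSTs

Spanning trees are extracted on the distance transform `d = 1/w`
(`1 − w` behind a flag), so each minimum-distance tree is the
maximum-synchronization tree; Kruskal with lexicographic tie-breaking makes
extraction deterministic. After the m-th tree is moved from the residual to
the union, `cost(m)` = union weight / total weight and `GE(m)` = weighted
global efficiency of the union (mean over pairs of `1/d_ij`, Dijkstra on the
inverse-weight distances) normalized by the full graph's efficiency, so that
`J(m) = GE(m) − cost(m)` is dimensionless and GE ∈ (0, 1]. The union at
argmax J is the selected network. J is not guaranteed unimodal, so
extraction continues 3 rounds past the running maximum (bounded lookahead,
`patience`) and stops early if the residual disconnects. The matched
proportional threshold for comparison is the grid level whose pre-pruning
density is nearest the OMST union's density (≈ `1 − density` for
all-distinct weights).

## Edge-probability graphs

Per edge and threshold level, the fraction of subjects whose *pruned*
network contains the edge — a removed node's incident edges count as absent,
because the probability graph describes the networks actually analyzed.
Probabilities for one measure are min–max scaled jointly across all its
threshold levels (per measure and node-label set; pooling across label sets
is off by default); a degenerate all-equal field scales to 0 by convention.
The per-edge monotonicity report exists precisely because probability is
*not* guaranteed monotone in q once component pruning acts.

## Statistics

Metric-vs-threshold regressions are pooled OLS over subjects and levels.
The regressor is selectable: the threshold level `q` (the knob actually
swept, and the scale on which the canonical sign pattern — CPL positive,
clustering/participation negative — is stated) or the realized `density`,
where all signs flip. Cross-threshold similarity is the subject-wise
Spearman ρ between metric vectors at every pair of levels (midranks for
ties; constant vectors recorded as missing).

The two-sample permutation test uses the Welch t statistic. All
`C(n_a+n_b, n_a)` label splits are enumerated exactly when there are at most
20,000; otherwise 10,000 Monte-Carlo permutations are drawn (seeded) and the
observed labelling is counted among them, giving the standard
`(hits + 1)/(B + 1)` estimate. Cohen's d uses the pooled SD. Group-effect
profiles run the test at every threshold level with per-level derived seeds
and flag contiguous significant runs, splitting a run when the sign of d
flips so direction reversals across thresholds are visible. Significance is
two-sided α = 0.05 with no multiple-testing correction by default — a
deliberate, documented limitation of per-threshold profiling (a
Benjamini–Hochberg switch is available).

## Problem sizes and numerical choices

Default study-scale runs use 20 subjects × 32 channels (sweep
phenomenology) and 24 subjects × 16 channels (group-effect profiles), 120 s
of signal per subject (60 two-second epochs), the full 99-level grid, 20
small-world references, and 999–10,000 permutations; these sizes were chosen
so that the planted effects sit comfortably above estimation noise while a
complete analysis stays in the minutes range on a single CPU. Matrix
symmetry is enforced to 1e-9 on ingest; the diagonal is always zeroed;
all-zero matrices are rejected as having no weight distribution.

## Known limitations

* The sigma small-world index *rises* with the threshold level on these
  synthetic cohorts (pruning reveals the planted modular/lattice structure,
  which is more clustered than its degree-preserving nulls) before
  collapsing to 0 when graphs fragment. Empirical sensor-space cohorts have
  been reported with σ falling across the sweep, which requires the
  top-percentile edge structure to be *less* clustered than its rewired
  nulls (hub-dominated tails). The generator does not encode such hub
  dominance, and no attempt was made to force it.
* Participation depends on the (unstated-in-the-field) community detection
  step; greedy modularity is a stand-in and is exposed so callers can pass
  their own partition.
* No directed/Granger measures, no time-resolved connectivity, no
  absolute-value or windowed thresholding, no permutation-based edge
  selection.
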