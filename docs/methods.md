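# Methods

## The analysis model

`brainstates` treats each scan as a weighted functional network. ROI time
series are correlated (Pearson) to give an N×N connectivity matrix; the
strongest *t*% of positive correlations are retained as a weighted graph;
graph metrics are computed on weights (never binarized) and normalized by
degree-matched random networks; condition effects are evaluated with a
within-subject (repeated-measures) design throughout, because every
subject is scanned in all four states (W, S, LOC, R).

Key conventions, and why:

* **Edge length = 1/weight.** Strong correlations are functionally close.
  The alternative −log w is steeper for weak edges; 1/w is the common
  convention of weighted connectivity toolboxes and is what all path-based
  quantities here use (config-exposed).
* **Onnela clustering and local efficiency** use weights normalized by the
  network-wide maximum and the *binary* neighbor count k in the
  denominator. With the weight-sum denominator sometimes quoted for
  weighted clustering the coefficient is no longer bounded by 1; the
  geometric-mean/binary-k form is bounded and scale-invariant, which the
  tests rely on.
* **Modularity** is the weighted Newman quality with l = Σij w_ij over
  both orientations. Optimization runs, per restart: deterministic greedy
  agglomeration (igraph fastgreedy), a fine-tuning pass moving single
  nodes while Q strictly increases, and a probabilistic pass reassigning a
  random fraction p = 0.45 of nodes followed by re-fine-tuning, keeping
  the best. Reported values are means over 50 restarts (10 for null
  networks, where only the ensemble mean matters). Restart-to-restart
  variation is small but real; the engine is recorded in provenance.
* **Null model.** Double-edge swaps (10 per edge) with weights traveling
  on their original edges: exact degree sequence and exact weight multiset
  preserved, topology randomized. When the swap count is zero the
  ensemble is degenerate at the graph itself and all ratios are exactly 1.
* **Thresholding.** round(t·N(N−1)/2) edges, ranked by signed value, ties
  broken by index order (making edge sets nested across densities);
  negative correlations never enter graphs but remain available to the
  classifier, which sees unthresholded matrices. The density range is
  bounded below by mean degree ≥ 2·ln N (natural log; estimability) and
  above by mean small-worldness ≥ 1 per condition.
* **Classification.** Linear SVM (cost 1) on the vectorized upper
  triangle; leave-one-subject-out CV holds out both of a subject's paired
  scans per fold; the permutation null flips each subject's pair of labels
  with probability 1/2 and reruns the full CV; p = (1+#{≥obs})/(n_perm+1).
  A precomputed linear kernel makes the 10⁴-permutation setting tractable.
* **Evidence maps.** An edge belongs to a condition's map when its weight
  times that condition's mean correlation pushes the decision function
  toward that condition; map values are |w|·mean r of the correctly
  classified samples, so a negative entry is a negative correlation doing
  the classifying. The two maps can overlap at sign-discordant edges
  (positive in one state, negative in the other) — exactly the edges that
  discriminate in both directions.
* **RM-ANOVA.** Each within-subject effect is tested against its own
  effect×subject interaction. Sphericity is assessed per effect by
  Mauchly's test on orthonormalized contrasts; under violation the
  degrees of freedom are scaled by Huynh-Feldt ε when ε_GG ≥ 0.75 and by
  Greenhouse-Geisser ε otherwise. Effect size is partial omega squared,
  ω²p = df(F−1)/(df(F−1)+N), clipped at 0. Pairwise contrasts are paired
  t-tests with Sidak correction (m = 6 for four conditions). Node-wise
  tests use Benjamini-Yekutieli FDR (valid under dependency), q = 0.05.
* **Distance ANCOVA.** Correlation strength is averaged into fifteen 9-mm
  bins per subject and condition (half-open bins; the last absorbs the
  remainder). The condition effect is the standard RM test on condition
  means; the distance effect and the condition×distance interaction are
  tested on per-subject regression slopes of mean r on bin-center distance
  (a summary-statistics formulation that keeps subject-level degrees of
  freedom honest — edge-level pseudo-replication would not). Binned means
  rather than raw edges are the observational unit for the same reason.

## The synthetic study generator

The generator emulates a 12-subject × 4-condition study on a 194-ROI
whole-brain atlas (8 subdivisions, box-placed barycenters), 196 timepoints
at TR 2.46 s. It is a latent factor model:

* K = 6 spatially coherent modules (k-means on coordinates) each drive
  their ROIs; cross-module leakage decays as exp(−d/λ), λ = 60 mm, so
  modular structure and distance-dependent correlation decay coexist.
  Module loading 1.0, leak 1.0, unit observation noise: wakeful median
  correlation ≈ 0.18 with the bulk of correlations in [0, 0.4].
* A sparse backbone of ~75 long-range cross-module cortico-cortical
  "integration shortcuts" (target correlation ≈ 0.55) is built from
  shared pairwise factors, so the covariance is positive semi-definite by
  construction. These carry global integration: they keep wakeful graphs
  connected at low densities and dominate shortest paths.
* Tight spatial sub-cliques (~12 ROIs) nested inside modules carry local
  assembly coherence; their within-clique couplings are the clustering
  channel.

Condition effects (the planted ground truth):

* **W**: sub-clique coherence damped (×0.55) — active wakefulness is the
  locally desynchronized, globally integrated state.
* **S**: as W, plus thalamo-cortical hyperconnectivity (+0.22 on
  established couplings above 0.20, i.e. visible to the classifier on
  unthresholded matrices with limited re-shaping of the thresholded
  graphs), slight global gain 0.96 and mildly weakened shortcuts (×0.85).
* **LOC**: global gain 0.70; 14% of edges made negative by sign-flipping
  cortico-cortical couplings — the integration shortcuts first, then a
  tranche of the strongest remaining cross-module couplings, then weak
  ones (weak flips keep the matrix near PSD; any residual violation is
  repaired by eigenvalue clipping with a warning). Local assemblies stay
  coherent (sub-cliques undamped) and cortical within-module coupling is
  boosted ×1.45. Net phenotype: weakened, partly anti-correlated, more
  clustered, longer functional paths.
* **R**: near-W gain (0.97) with sub-clique coherence largely restored
  (×0.8), shortcuts mildly strengthened (×1.1) and mild thalamo-cortical
  elevation — elevated clustering with near-wakeful integration.

Between-subject variance is a symmetric log-normal perturbation of all
couplings (SD 0.15), drawn once per subject and shared across that
subject's four scans so the paired design is meaningful. On top, a
per-scan log-normal factor (SD 0.5) scales the shortcut backbone,
emulating session-to-session drifts of global integration. Time series
are sampled by mixing temporally smoothed (Gaussian, σ = 1.5 samples)
unit-variance innovations through the matrix square root of each scan's
target correlation matrix.

### What the generator does and does not emulate

It reproduces the study's statistical skeleton: the condition-wise
correlation descriptives (LOC median ≈ 0.11 vs ≈ 0.17–0.19 elsewhere,
~13–14% negative edges in LOC only), distance decay, modular small-world
topology, the classifiable state differences and their anatomical
signatures, and the repeated-measures variance structure. It does not
model haemodynamics, scanner noise spectra, motion, or spatial smoothness;
its wakeful strong-correlation tail (~8% above 0.4) is lighter than real
resting-state data (~17%). Passing recovery tests therefore validates the
*pipeline*, not any claim about real brains.

### A known limitation of the planted dissociation

The headline qualitative pattern — normalized clustering elevated in LOC
and R relative to W and S, normalized path length elevated only in LOC —
is planted and recovered directionally in essentially every replicate,
with LOC's path-length excess (≈ +0.15–0.25) several times larger than
R's (≈ +0.03–0.06). In this covariance family, however, any manipulation
that concentrates strong weights locally raises nC and nL together at
roughly 4:1, so R's clustering elevation necessarily carries a small
path-length elevation. Because the paired design resolves nL differences
of ~0.02, the Sidak contrast R-vs-W on nL can reach nominal significance
even though R's excess is a fraction of LOC's. Strictly reading
"path length separated only for LOC" as "no other Sidak contrast is
significant" therefore fails in a substantial share of replicates; the
ordering and magnitude dissociation always holds. The tests encode the
strict reading and this is documented rather than hidden.

## Problem sizes and numerical choices

* Default study: 194 ROIs, 12 subjects, 196 timepoints; densities
  {11, 16, 21, 26, 31}%; 100 nulls (20 in the test suite and the
  acceptance script, where only ensemble means at modest precision are
  needed); 50 modularity restarts (10 on nulls); 10 swaps per edge.
* Permutations: 10,000 in a full study run; 500–1,000 in the acceptance
  script and tests (the smallest attainable p is then 1/(n+1)).
* Matrices are written as TSV at 10 significant digits; reruns of the
  pipeline with an identical config and master seed are byte-identical
  (seeds for every stage derive from the master seed via SeedSequence).
* Degenerate inputs: constant ROI columns are a validation error naming
  the ROI; disconnected node pairs are reported (fraction unreachable)
  and excluded from L, and contribute 0 to E; a coupling matrix that
  leaves the PSD cone after planted effects is repaired by eigenvalue
  clipping with a logged warning; ties at the threshold cutoff are broken
  by (i, j) index order.
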