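# brainstates

State-dependent functional brain-network analysis for within-subject,
multi-condition resting-state studies: from ROI time series to weighted
connectivity graphs, null-normalized graph-theoretic metrics, linear-SVM
state classification with edge-level importance maps, and repeated-measures
statistics. The package targets the four-state anesthesia design —
wakefulness (W), propofol sedation (S), loss of consciousness (LOC) and
recovery (R) — and ships a synthetic study generator with planted, fully
known condition effects so that every stage of the pipeline can be
validated end to end without any imaging data.

## What it computes

Given per-subject, per-condition ROI time series (T timepoints × N ROIs)
and an ROI atlas (names, anatomical subdivisions, barycenter coordinates):

1. **Connectivity.** Optional temporal cleaning (trim, quadratic detrend,
   nuisance regression, zero-phase band-pass), then the Pearson correlation
   matrix per scan, plus descriptive statistics (median r, negative-edge
   fraction, distance-binned correlation profiles, two-sample KS tests).
2. **Graphs.** Proportional thresholding: the strongest *t*% of positive
   edges are retained with their weights, at densities bounded below by
   mean degree ≥ 2 ln N and above by mean small-worldness σ ≥ 1.
3. **Weighted metrics.** Characteristic path length `L` (shortest paths on
   lengths 1/w), global efficiency `E`, Onnela clustering `C` (geometric-
   mean triangles on max-normalized weights), nodal strength `s_i`, local
   efficiency, and weighted Newman modularity
   `Q = (1/l) Σ_ij [w_ij − s_i s_j / l] δ(c_i, c_j)` optimized by greedy
   agglomeration plus fine-tuning and probabilistic-tuning restarts.
4. **Null normalization.** Each metric is divided by its mean over 100
   degree-matched random networks (double-edge swaps, weights traveling
   with their edges), giving nC, nL, nE, nQ and small-worldness σ = nC/nL.
5. **Classification.** Pairwise linear SVM on unthresholded, vectorized
   correlation matrices; leave-one-subject-out cross-validation (both of a
   subject's paired scans held out per fold); significance by paired label
   permutation; hyperplane weights mapped back to edges as per-condition
   evidence maps; the top 1% of classifying edges counted by anatomical
   kind (class pair × correlation sign) and compared by chi-square.
6. **Statistics.** Two-way repeated-measures ANOVA (condition × density)
   with Mauchly's test and Huynh-Feldt/Greenhouse-Geisser corrections,
   partial omega-squared effect sizes, Sidak pairwise contrasts,
   per-density one-way follow-ups, Benjamini-Yekutieli node-wise FDR, and
   a repeated-measures ANCOVA of distance-binned correlation strength.

## Worked example

```python
from brainstates import (make_atlas, make_ground_truth, simulate_study,
                         correlation_matrix, proportional_threshold,
                         normalize_metrics, loocv_classify)

atlas = make_atlas(194, seed=7)
truth = make_ground_truth(atlas, seed=7)
study, truth = simulate_study(atlas, truth, n_subjects=12,
                              n_timepoints=196, seed=7)

m = correlation_matrix(study.panel("sub01", "W"))
graph = proportional_threshold(m, density=0.21)
norm = normalize_metrics(graph, n_null=20, seed=7, include_modularity=False)
print(f"nC={norm.nC:.2f} nL={norm.nL:.2f} sigma={norm.sigma:.2f}")

mats = {k: correlation_matrix(p) for k, p in study.panels.items()}
ga = [mats[(s, "S")] for s in study.subjects]
gb = [mats[(s, "LOC")] for s in study.subjects]
res = loocv_classify(ga, gb, comparison="S vs LOC")
print(f"accuracy={res.accuracy:.1f}%")
```

prints

```
nC=1.45 nL=1.21 sigma=1.20
accuracy=100.0%
```

the wakeful graph is small-world (clustering 1.45× its degree-matched
nulls at 21% density against a 1.21× path-length excess, σ > 1), and the
planted sedation-vs-unconsciousness effect — thalamo-cortical
hyperconnectivity in S against globally weakened, partly anti-correlated
cortico-cortical coupling in LOC — is linearly separable across subjects.

A full study run (all stages, report bundle, run manifest) is one call or
one command:

```sh
brainstates run-all --config config.yaml --seed 7 --outdir out/
```

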