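# Methods

## Scoring model

A labeling of a localization table is scored as a posterior (up to a
table-wide constant) under a generative model with three parts.

**Background.** Each localization is background with prior probability
`p_b` (default 0.5) and then uniform on the ROI: per-point contribution
`log(p_b/A)` with A the ROI area in nm². `p_b` is a fixed prior parameter,
not estimated; labelings that assign more points to clusters pay
`log(1−p_b)` per clustered point instead.

**Partition prior.** Clustered points are partitioned under a
Chinese-restaurant process with concentration `alpha` (default 20):
`K log α + Σ_k log Γ(n_k) + log Γ(α) − log Γ(α+n_c)`. Larger `alpha`
tolerates more clusters; with the defaults the prior is mild compared with
the likelihood terms at benchmark sizes (~1000 clustered points).

**Cluster marginal likelihood.** Cluster k is an isotropic 2-D Gaussian
with unknown center µ (uniform over the ROI, density 1/A) and unknown
spread σ. Localization i contributes per-axis variance `v_i = σ² + sd_i²`,
so better-localized points constrain the cluster more. Integrating µ over
the whole plane is closed-form per axis:

```
(2π)^{−(n_k−1)/2} (Π_i v_i)^{−1/2} (Σ_i 1/v_i)^{−1/2}
exp(−½ [Σ_i x_i²/v_i − (Σ_i x_i/v_i)² / Σ_i 1/v_i])
```

and σ is marginalized over a discrete grid with uniform weights (default:
20 log-spaced values between 5 and 300 nm, mirroring the radius search
range). Extending the µ-integral over the plane instead of the ROI ignores
a boundary effect of order (cluster size / ROI size); for 50-nm clusters
on a 3-µm field this is negligible. A singleton cluster has marginal
exactly 1/A — allowed, and penalized only through the prior terms. The
implementation is validated against direct 2-D quadrature of the integral
(relative tolerance 1e-6) in the test suite.

Why this works as a parameter selector: for the benchmark data a uniform
blob of background modeled as one huge "cluster" scores ≈ −21.5 per point
(σ capped at 300 nm) versus −16.7 as background, while a true 50-nm
cluster scores ≈ −11.7 per point as a cluster — so the optimum labeling
keeps the background diffuse and the real clusters tight, and the grid
point that produces that labeling wins.

## Proposal generation

All clusterers use the exact Euclidean fixed-radius neighbor graph (k-d
tree, no approximations; verified against brute force). Localization
precision deliberately does not influence proposal generation — it enters
only the score. Determinism rules: ToMATo processes points in decreasing
density with ties broken by lower row index, the same rule ordering
"highest-density neighbor" and peak comparisons; DBSCAN border points join
the cluster of their lowest-index core neighbor; cluster ids are
renumbered 1..K by first appearance. ToMATo's threshold shares the grid's
integer second parameter, read in density (neighbor-count) units: peaks
with persistence < T merge, surviving peaks with density < T are
background.

The engine evaluates the grid grouped by radius (one neighbor graph per
radius); identical thresholded point sets at one radius are computed once.
Scores are pure float64 with a fixed summation order, so sequential and
parallel runs (process pool over radius groups, reassembled in grid order)
are bit-identical — parallelism is an implementation convenience with a
correctness contract, not a numerical approximation. Ties in the best
score resolve to smaller r, then smaller T.

## Synthetic data

**Ground-truth generator.** Cluster centers are rejection-sampled uniform
positions with pairwise separation ≥ 100 nm (up to 10⁶ attempts, then a
placement error); each cluster gets exactly `locs_per_cluster`
localizations at center + N(0, 50² I), background is exactly
`round(f/(1−f)·n_clustered)` uniform points, and every row receives a
localization error N(0, sd_i² I) with sd_i ~ gamma(shape 5, rate
0.166667 nm⁻¹) (mean 30 nm). The observed per-axis cluster spread is
therefore √(50² + sd_i²) ≈ 60 nm, which is what makes the ground-truth
convex-hull area come out at ≈ 0.061 µm² for 100-point clusters; without
the localization error the same hulls measure only ≈ 0.043 µm². With the
defaults the background density is exactly 1000/9 ≈ 111 µm⁻².

**Blinking emulator.** Molecules are placed in 40 disjoint 50-nm discs
(Poisson(49) molecules each, uniform in the disc; discs ≥ 500 nm from
every border) plus a Poisson uniform background (346 µm⁻² by default) on
the remaining area. Each molecule runs a two-state on/off Markov chain
across frames with per-frame switch probabilities `1 − exp(−k·Δt)`
(k_on = 0.01 s⁻¹, k_off = 10 s⁻¹, Δt = 10 ms), started from the discrete
chain's stationary distribution; every on-frame emits one localization at
the molecule position plus Gaussian error with its own gamma-drawn
precision. This emulates the key artifact — bursts of several
localizations per fluorophore activation — directly at localization
level; it does not model camera images, PSF shape, detection failures,
overlapping-emitter fitting artifacts, drift, or diffusion. Passing tests
on these data therefore demonstrate robustness to blinking multiplicity
and background, not to image-formation artifacts.

One consequence of the image-free emulation deserves emphasis: separate
activation bursts of the same molecule (which dT = 1 grouping rightly does
not merge) land within a few nanometres of each other, because nothing
blurs them between acquisitions. At long acquisitions (tens of thousands
of frames, several bursts per molecule) every background molecule thereby
becomes a small, perfectly tight localization stack that any sound
cluster model will detect; quantitative cluster counts from the emulator
are therefore only meaningful at acquisition lengths where molecules
produce ≈ 1 burst on average (the 5,000-frame setting used throughout),
and even there small Poisson clumps of grouped background inflate the
detected count above the number of designed clusters by roughly 25%.

**Grouping.** Localizations are chained chronologically: a detection at
frame f joins an existing chain when the chain's last member is within
`dX` (default 96 nm, one camera pixel) and at a frame in [f−dT−1, f−1]
(≤ dT intervening dark frames, default dT = 1); each chain accepts one
detection per frame, competing chains resolve to the earliest-started one,
and a chain collapses to its precision-weighted mean with combined
precision `(Σ sd_i⁻²)^{−1/2}` at the chain's first frame. Grouping is
idempotent when merged events are separated by more than the gates; on
very dense data with interleaved bursts a second pass can merge a few
additional pairs (~6% observed at 49 molecules per 50-nm disc) because
merged chains are re-represented at their first frame and mean position.
Row count never increases.

## Statistics

Cluster area is the 2-D convex hull of the cluster's localizations
(µm²); clusters with fewer than three non-collinear points have zero area
and are excluded from area/density summaries while still counting toward
the cluster number. Percent clustered is 100·n_c/n. Relative density is
(n_c / Σ hull areas) / (n_background / (ROI area − Σ hull areas)),
reported as missing when no cluster has positive hull area or there is no
background. Batch summaries report mean ± sd (population convention,
ddof = 0) per metric and pool per-cluster areas for ECDFs
(right-continuous, rank/n). Group comparison uses the Kruskal–Wallis H
test with tie correction and the chi-square approximation.

## Problem sizes and tolerances

The repeated-benchmark checks in the test suite and `scripts/acceptance.py`
use 10 simulated datasets through the full 6000-proposal grid per
clusterer (≈ 6 s per method and dataset), 50 datasets for the
ground-truth area statistic, and three replicate 5000-frame blinking
acquisitions for the grouping pipeline — sizes chosen so the whole suite
completes in a few minutes while keeping the standard errors of the
benchmark means (≈ 0.2 clusters, ≈ 0.002 µm²) well below the assertion
bands. Test bands on the
benchmark means are ±1.5–2 clusters and ±0.015–0.02 µm² (about one
between-dataset/between-cluster standard deviation of the benchmark
distributions).

## Known limitations

* The Ripley's-K-based proposals threshold raw neighbor counts; an
  equivalence experiment showed that thresholding the normalized local
  L(r) instead selects the same labelings under the Bayesian score, so
  the choice is immaterial here — but this variant produces less
  dispersed results (count sd ≈ 0.7, mean detected area ≈ 0.05–0.06 µm²)
  than some published Ripley-based implementations.
* `p_b` is fixed, not inferred; grossly wrong values bias the
  background/cluster trade-off.
* The σ grid caps cluster spread at 300 nm; clusters much larger than
  that are scored poorly and will be left as background.
* Scores across different tables (or different `BayesParams`) are not
  comparable; no normalizing constant is computed.
* No 3-D, dual-color, or Voronoï-tessellation support.
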