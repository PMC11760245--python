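# Methods

`cellalign` registers two modalities of the same histology specimen — in the
motivating use case a hematoxylin-and-eosin (H&E) restain or serial section
against multiplexed immunofluorescence (MxIF) of a tissue-microarray (TMA)
core — using only the cell centroids produced by upstream segmentation. No
image pixels are read. This note records the model, the tunable parameters,
the numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## Transformation model

A TMA core moves between scans essentially rigidly, so the alignment model is
a 4-degree-of-freedom similarity transform

    M = | S·cosθ  −S·sinθ  dx |
        | S·sinθ   S·cosθ  dy |
        |   0        0      1 |

with rotation θ (radians, counter-clockwise in the image frame: origin
top-left, y downward), isotropic scale S > 0 and translation (dx, dy) in μm.
Deformable registration is deliberately out of scope: at core scale the
rigid model is adequate and far more robust to the heavy content differences
between stains.

Both point clouds are converted from pixels to micrometers at ingestion
(multiplying by the scanner pixel size, e.g. 0.325 μm/px for MxIF and
0.212 μm/px for H&E). After that conversion the physical scale between the
modalities is unity, so the pipeline clamps S = 1 and estimates only θ, dx,
dy. Landmark-derived ground-truth fits leave S free as a check that the
data really are in consistent physical units.

## Coarse alignment: rigid Coherent Point Drift

The moving cloud (H&E) is treated as the centroids of an isotropic Gaussian
mixture; the fixed cloud (MxIF) as samples from it, plus a uniform component
of weight `w` absorbing cells present in only one modality. EM alternates
soft correspondence with closed-form similarity updates (rotation from the
SVD of the posterior-weighted cross-covariance, determinant-corrected so a
reflection can never be returned; translation from weighted centroids; a
variance update). The negative log-likelihood is evaluated every iteration
and is non-increasing along each run — the test suite asserts this with
1e−9 relative slack on every synthetic alignment.

Parameters (defaults; `cpd` section of the config):

- `w = 0.1` — expected unmatched-cell fraction. The result is insensitive
  to moderate misspecification because unmatched cells carry little
  posterior mass once σ² has annealed.
- `tolerance = 1e−6` relative objective change, `max_iterations = 150`.
- σ² is initialised to the pooled mean squared distance between the clouds
  (the cited method's convention), and floored at 1e−10 μm²; hitting the
  floor means the clouds coincide to machine precision and the run stops
  with a warning flag.
- `orientation_restarts = True`: EM is local and cores may be arbitrarily
  rotated, so the fit is probed from 0°/90°/180°/270° for
  `probe_iterations = 40` iterations each. The correct basin separates
  decisively within a few tens of iterations (its objective falls by
  percents while wrong basins plateau), so only candidates within 0.5% of
  the best probe objective are run to convergence and the lowest final
  objective wins. This is a pure wall-clock optimisation; with the margin
  rule, ambiguous cases degenerate gracefully to four full runs.
- `supercell_cap = 20,000`: larger inputs are first reduced by proximity
  clustering ("super-cells", below) before CPD, mirroring the whole-slide
  workaround.

### Super-cell reduction

Single-linkage clustering of centroids at a linkage distance (default 15 μm
when triggered by the cap), iterated to a fixed point: if merged pseudo-cell
centroids themselves fall within the linkage distance they merge again, so
re-reduction is a no-op. Each pseudo-cell sits at the mean of its original
member centroids, carries the mean of the numeric features and a
`member_count`. One-pass single linkage is *not* idempotent in general —
two cluster centroids can land closer than the threshold — which is why the
fixed-point form was chosen.

## Refinement: windowed graph matching

CPD aligns densities, not cells. The refinement stage builds explicit
one-to-one cell correspondences:

1. **Window sampling.** Per-cell density by Gaussian KDE (bandwidth 25 μm,
   half the source window — smooth at window scale), min-max normalised;
   window centers are drawn without replacement from cells with normalised
   density ≥ 0.5 (dense subregions carry the architecture; sparse ones
   mostly segmentation noise). If no cell passes, the top decile is used.
   Default `n_windows = 32`: the precision of the final fit is limited by
   the pooled pair count, and at TMA densities 32 windows of 50 μm give a
   few hundred putative pairs.
2. **Subgraphs.** The source subgraph takes the cells in a 50 μm square
   window; the window center is mapped through the CPD transform and the
   target subgraph takes a 150 μm window there — wider, to tolerate residual
   coarse-alignment error. Edges join cells closer than 15 μm.
   `max_nodes_per_window = 300` is an honest cap: at TMA densities a 150 μm
   window holds ~130–200 cells, and a low cap silently deletes true
   counterparts (measured as a hard precision ceiling).
3. **Affinity.** Candidate assignments are scored in a Lawler-form
   association matrix: node affinity is a Gaussian kernel
   (`node_feature_scale = 1.0`) on per-graph standardised morphology
   features (perimeter, solidity), multiplied by a Gaussian spatial prior
   (`spatial_scale = 15` μm) on the distance between the CPD-mapped source
   cell and the target cell; assignments beyond 3 spatial scales are gated
   out entirely. Edge affinity is a Gaussian kernel
   (`edge_length_scale = 5` μm) on edge-length differences, modulated by the
   geometric mean of the endpoint node affinities. The spatial terms are
   essential, not cosmetic: morphology plus edge lengths alone cannot
   identify a 50 μm pattern inside a 9×-area window — edge lengths are
   translation-invariant, so a coherently shifted wrong embedding can
   outscore the true one. The coarse alignment that placed the window is
   exactly the prior that makes the assignment identifiable, and the gate
   also keeps the association matrix sparse.
4. **Solving.** Reweighted random walks on the association graph (power
   iteration interleaved with exponential inflation, β = 30, and Sinkhorn
   reweighting; jump probability α = 0.2; tolerance 1e−6, cap 300). For
   rectangular problems the Sinkhorn step normalises rows to sum 1 and only
   caps column sums at 1 — full column normalisation is infeasible when the
   sides differ and washes out the signal. The walk restarts from several
   initial distributions and inflation strengths (a dense grid plus one-hot
   seeds when the association space has ≤ 36 entries, where restarts are
   nearly free; two restarts at production sizes), and the converged iterate
   whose Hungarian discretisation maximises the quadratic objective is
   returned. On enumerable problems (≤ 6 nodes) drawn like the windows the
   pipeline actually builds, the solver matches exhaustive search; on
   featureless adversarial instances it remains a heuristic, as all
   polynomial graph-matching solvers do.
5. **Discretisation and pooling.** Hungarian assignment per window
   (surplus nodes stay unmatched), matches below `min_affinity = 0.2`
   discarded, pairs pooled across windows with one-to-one enforcement on
   both sides (highest affinity wins).
6. **Filtering.** Locality Preserving Matching: for each putative pair the
   cost counts how many of its K = 8 nearest neighbours among the pairs (by
   source position) are not also among its K nearest by target position.
   Correct matches under a similarity preserve neighbourhoods exactly;
   mismatches land in foreign neighbourhoods. Two passes: permissive
   (cost ≤ λ₁ = 6) over all pairs, then strict (cost ≤ λ₂ = 4) with
   neighbourhoods recomputed among survivors.
7. **Final fit.** A similarity fit (S clamped to 1) over the kept pairs,
   made robust by two rounds of residual trimming at 3× the MAD-based scale
   (floored at 0.5 μm so noise-free data are never trimmed): mismatches that
   slip through LPM sit at cell-spacing offsets, an order of magnitude above
   centroid noise, and separate cleanly in residual space.

### Guarded adoption

The refined transform replaces the CPD transform only when the matched-cell
evidence supports it: the kept pairs are split into two deterministic folds,
each fold's transform is fitted on the complement, and the pooled held-out
residual median must beat the CPD transform's residual median by more than
one standard error of the median. The rationale: when the coarse alignment
is already at the information limit — which is exactly what happens under
unbiased centroid noise, where the density-based EM estimator uses every
cell — a re-fit on a few hundred matched pairs is a strictly noisier
estimator, and replacing a good transform with a noisier one would violate
the design goal that refinement never worsens the alignment. When the
coarse alignment is biased (the situation refinement exists for), the
improvement is large, unambiguous, and adopted. With too few pairs to
cross-validate (< 8) the refined fit is adopted outright.

## Evaluation metrics

Against landmark pairs annotated in both modalities (or generated with known
truth), with the ground-truth transform fitted from the landmarks (S free):

- **ΔD** (μm): mean distance between each target landmark and the
  estimated-transform-mapped source landmark.
- **ΔT** (μm): |T′ − T| of the translation magnitudes T = √(dx² + dy²).
- **Δθ** (degrees): absolute rotation difference, wrapped to [0°, 180°].

## Synthetic TMA-core generator

The generator emulates one core seen by two modalities: a 400 μm-radius disc
of cell centroids, half background (uniform in the disc) and half in six
Gaussian hotspots (SD 40 μm) — the density contrast that drives KDE window
sampling. Morphology features (area: lognormal, median 35 μm²; perimeter
tracking √area with a lognormal shape factor; solidity: Beta(18, 2);
intensity: lognormal) are drawn once per base cell and shared by both sides,
so cross-modal concordance is high by construction for surviving one-to-one
cells. The target side is the source mapped through a known similarity
(default θ = 5°, t = (20, −10) μm), then each side independently receives
centroid jitter (default SD 1 μm), per-cell dropout (default 20%),
over-segmentation splits (2%; two children at ±2 μm along a random axis) and
under-segmentation merges (2%; a cell absorbs its nearest neighbour), plus
multiplicative lognormal feature noise (5%). Landmarks are eight base cells
that survived unperturbed on both sides, chosen by greedy farthest-point
selection, stored at their pre-jitter positions — so the returned
ground-truth transform maps them exactly.

Two presets bracket the real-world conditions: `restained_like` (same
physical cells in both modalities: 5% dropout, 0.5 μm jitter, 5% feature
noise) and `serial_like` (adjacent 5 μm cut: 40% dropout, 2 μm jitter, 60%
feature noise, 5% splits/merges).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatially correlated tissue damage (dropout here
is i.i.d.), systematic inter-modality segmentation bias (jitter is zero-mean
and isotropic), anisotropic section deformation, and staining-dependent
feature shifts beyond multiplicative noise. One consequence is worth
stating plainly: under these unbiased perturbations CPD alone is already
nearly information-optimal (median landmark ΔD ≈ 0.2 μm at the default
conditions), so on this benchmark the guarded refinement usually ties CPD
rather than beating it; its value shows when the coarse alignment is
biased, which the guard test exercises directly by offsetting it.

## Concordance statistics

After alignment, each source cell pairs with its nearest target cell within
10 μm (about one cell diameter). Targets claimed by exactly one source with
a mutually-nearest claim are class N=1; unclaimed sources are N=0; multiple
or ambiguous claims are N>1. Pearson correlation of a feature is computed
over N=1 pairs only. Regional maps use an axis-aligned grid: raw counts for
density, and for composition the per-region similarity 1 − |p_source −
p_target| of tumor proportions (labels supplied by upstream classifiers),
masking regions with fewer than `min_cells = 5` cells on either side. The
absolute-difference similarity is a package choice; only the region-by-region
comparison itself is externally prescribed.

## Problem sizes used in the shipped benchmarks

The test suite and `scripts/acceptance.py` run on cores of 600–1,000 cells,
20 seeded replicates for the degraded-recovery, filter and concordance
statistics, and 50 enumerable graph pairs for the solver-optimality check.
These sizes put every statistic well inside its asymptotic regime for the
effects being measured while keeping the full suite in the minutes range on
one CPU.

## Known limitations

- Rigid-only: no local deformation model; whole-slide images are handled
  only through super-cell reduction of the CPD stage.
- The matcher needs the morphology features it is configured with
  (perimeter, solidity by default) present in both tables; if they are
  missing, the pipeline falls back to the CPD transform with a warning.
- RRWM is a heuristic on large windows; optimality is only guaranteed where
  exhaustive enumeration is feasible.
- The LPM thresholds are tuned for ~100+ pooled pairs; with fewer than
  K + 2 pairs the filter keeps everything (with a warning).
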