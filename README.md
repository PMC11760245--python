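# cellalign

Cell-anchored rigid registration of multimodal histopathology images from
segmentation centroids alone.

## The problem

Pairing multiplexed immunofluorescence (MxIF) with an H&E stain of the same
tissue — either the identical restained section or an adjacent serial cut —
requires the two images to share a coordinate frame at *cell* resolution.
Pixel-based registration struggles here: whole-slide files are huge, the
stains look nothing alike, and tissue-microarray (TMA) slides contain
hundreds of cores that each need their own alignment. `cellalign` sidesteps
the pixels entirely: it consumes the per-cell measurement tables that
segmentation pipelines (e.g. QuPath exports) already produce, and aligns the
two modalities' cell-centroid point clouds.

It is intended for image-analysis scientists who have per-core cell tables
for both modalities and want a transform, explicit cell-to-cell
correspondences, and quantitative quality metrics — without touching the
underlying images.

## Method at a glance

The alignment model is a 4-DOF similarity transform

    M = [[S·cosθ, −S·sinθ, dx],
         [S·sinθ,  S·cosθ, dy],
         [0,       0,      1 ]]

with centroids converted to micrometers first so the physical scale is S = 1
and only θ, dx, dy are estimated. The pipeline is:

1. **Coherent Point Drift (CPD)** — rigid EM point-set registration: the
   moving (H&E) cloud is a Gaussian mixture, the fixed (MxIF) cloud its
   data, with a uniform outlier component for unmatched cells. Coarse
   orientation restarts (0°/90°/180°/270°) make arbitrary core rotations
   safe.
2. **Graph matching** — windows sampled in dense subregions (Gaussian-KDE
   ranked, 50 μm source / 150 μm target windows, 15 μm proximity edges) are
   matched cell-to-cell with a Reweighted Random Walks (RRWM) solver on a
   node/edge affinity matrix (morphology + edge lengths + a spatial prior
   from the CPD mapping), discretised by the Hungarian algorithm.
3. **Locality Preserving Matching (LPM)** — putative pairs whose spatial
   neighbourhoods disagree between the two frames are removed; the
   survivors yield the final robust similarity fit, adopted only when
   held-out matched-pair residuals show it improves on CPD.
4. **Evaluation** — against annotated landmark pairs: ΔD (mean mapped
   landmark distance, μm), ΔT (translation-magnitude difference, μm) and
   Δθ (rotation difference, degrees).

A synthetic TMA-core generator (known transform, centroid jitter, dropout,
over/under-segmentation) makes the whole stack testable with no data
downloads, and a concordance module computes the downstream cross-modal
statistics (nearest-cell N=0/1/>1 triage, per-feature Pearson r, regional
density and tumor-composition maps).

## Worked example

Simulate a core pair with a known transform (θ = 5°, t = (20, −10) μm,
degraded by jitter, dropout and segmentation errors), align it, and evaluate
against the landmarks:

```bash
cellalign simulate --out-dir core --seed 3 --n-cells 1000
cellalign align --source core/source_cells.tsv --target core/target_cells.tsv \
                --landmarks core/landmarks.tsv --out-dir out --seed 3
cellalign evaluate --transform out/transform.json \
                   --landmarks core/landmarks.tsv --out metrics.json
```

which prints:

```
simulated core pair: 790 source cells, 810 target cells, 8 landmarks -> core
aligned 790 -> 810 cells: theta=4.9820 deg, t=(19.883, -9.841) um, 102/103 pairs kept
landmark evaluation: dD=0.113 um, dT=0.176 um, dtheta=0.0180 deg
dD=0.113 um, dT=0.176 um, dtheta=0.0180 deg (8 landmarks)
```

Reading the output: the recovered transform (4.98°, (19.9, −9.8) μm) is the
generating one to within centroid noise; 102 of 103 putative cell pairs
survived the locality filter; and the landmark metrics say the mapped source
landmarks land 0.113 μm from their targets on average, with rotation off by
0.018°. On real data the same `align` call takes QuPath-style measurement
exports (`--source-pixel-size 0.212 --target-pixel-size 0.325` for H&E/MxIF)
and writes the transform JSON, the match table TSV and a full report JSON.

The library surface mirrors the CLI: `cellalign.align()`,
`cellalign.cpd_align()`, `cellalign.match_cells()`,
`cellalign.evaluate_alignment()`, `cellalign.generate_core_pair()`, and the
concordance functions; see `docs/methods.md` for the model, parameters and
design rationale.

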