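# Methods

`myobarcode` quantifies whole-body fast-myofiber turnover in growing
zebrafish from multicolor (Brainbow-style) lineage-barcoded imaging. This
note documents the generative model behind the synthetic-data module, the
measurement operators, their parameters and defaults, the numerical choices
made where the design was open, and the limits of what the synthetic tests
demonstrate.

## Population model

Each animal carries `n_myotomes` myotomes (default 34, the zebrafish trunk
count), each holding a set of fast myofibers with a centroid in a
120 × 160 µm cross-section, a dorsal/ventral compartment, and a medial-edge
flag. Between observation times (days post-fertilization, dpf) four
processes act:

- **Elimination.** Each fiber dies per interval with probability
  `1 − (1 − h)^Δt`, where `h` is the per-day hazard. The default hazard is
  calibrated per rearing condition so that a 14-dpf cohort reaches the
  observed 28-dpf endpoints: ~99% cumulative elimination under fast growth
  (FG, 1 fish/200 ml) and ~55% under slow growth (SG, 1 fish/20 ml),
  i.e. `h = 1 − (1 − endpoint)^(1/14)` ≈ 0.28/day (FG) and 0.055/day (SG).
- **Medial-edge spatial bias.** Dissolution events favor the medial edge of
  each compartment (53% dorsal, 68% ventral). The per-fiber death
  probability is scaled linearly by `2·bias` (medial) or `2·(1 − bias)`
  (lateral), which makes P(medial | death) equal the bias exactly in a
  half-medial population over one interval. With `p_die = 1` every fiber
  dies regardless of the factor. Because newborn fibers inherit the parent's
  flag, the medial share of the population drifts slightly over many
  intervals; bias-recovery checks therefore use a single interval.
- **Replacement.** Each elimination draws a replacement count from a
  categorical distribution over {0, 1, 2, 3, 4, ≥5} with default mass
  (0.11, 0.29, 0.21, 0.18, 0.13, 0.08). The first five entries follow the
  observed event catalog (no birth 11%, one to four births 29/21/18/13%);
  those percentages sum to 92%, and the residual 8% is assigned to the ≥5
  category, exposed as a configurable parameter because the observed
  catalog does not label it explicitly. Newborns are placed inside the dead
  fiber's footprint.
- **Hyperplasia.** Independent growth-front additions arrive as
  Poisson(`hyperplasia_rate`·Δt) new fibers per myotome per day (default
  4.5, sized so a ~34-myotome larva roughly matches the observed 1942 →
  4988 per-animal increase from 6 to 14 dpf).

**Hypertrophy / nuclear domain.** Surviving fibers accrete myonuclei
(Poisson, 0.6 nuclei/day) and volume follows the nuclear-domain law
`V = s·N · (1 + cv·ε)`, ε standard normal, with default cv = 0.1. The slope
table stores the condition- and age-dependent unit volumes: 1.9 vs 1.0
× 10³ µm³/nucleus (FG vs SG) at 10 dpf and 3.2 vs 1.5 × 10³ µm³/nucleus at
14 dpf; intermediate ages use the nearest tabulated age. After
`hypertrophy_cap_day` volumes and nucleus counts freeze.

**Deformation and puncta.** A fiber destined to die is flagged deformed for
one observation step before death (configurable, 1–2 steps). Deformed fibers
carry autophagic puncta with probability 0.80 and normal fibers with 0.001,
matching the observed 33/41 and 3/2728 rates.

**Color barcodes.** Tagging happens at induction (the first observation)
only: each tagged fiber draws `cassette_copies` (default 10) independent
categorical recombination outcomes over three fluorophores (default
uniform); its color is the per-fluorophore copy fraction, fixed for life.
Fibers born later carry the default unlabeled state — this is what lets the
tracker call eliminations of the tagged cohort even when replacements
occupy the same footprint.

**Randomness.** One root seed is split by `numpy.random.SeedSequence` into
child streams consumed in a fixed order (population, colors, rendering,
qPCR), so identical configs give bit-identical outputs.

## Rendering

A myotome cross-section is tiled by an area-weighted (power-diagram),
Lloyd-relaxed Voronoi partition: pixels go to `argmin(‖p − s_i‖² − w_i)`,
weights are nudged toward target area shares (proportional to fiber volume,
i.e. constant fiber length per myotome per time point) with step 0.5, and
seeds move to cell centroids; 100 iterations bring per-cell areas within a
few percent of target, and any starved cell is rescued with its nearest
pixel so the label map always contains every fiber. Channels: membrane
(label boundaries at the configured thickness), three fluorophore channels
filled with copy fractions, and a nuclear channel of isotropic Gaussian
blobs (FWHM 7 µm default). Noise, when enabled, is Poisson shot noise scaled
by gain plus additive Gaussian read noise — the standard confocal
approximation. The label map is voxel-identical to the noiseless tiling.
Physical coordinates use the voxel-center convention: µm = index × voxel
size.

## Measurement operators

- **Preprocess:** Gaussian blur, σ = 2 px default; σ = 0 is an exact copy.
- **Cross-section:** bilinear resampling along an arbitrary plane
  (axis-aligned planes reproduce slices exactly).
- **Fiber segmentation:** watershed on the blurred membrane channel seeded
  by connected components of the sub-Otsu interior (raster-order labels,
  deterministic). External label masks (e.g. Cellpose output) pass through
  unchanged.
- **Nucleus detection:** scale-normalized Laplacian of Gaussian at
  σ = diameter/(2√2) for a 7.0 µm diameter. The quality score is the peak
  response divided by the robust noise of the response map (1.4826 × MAD);
  detections below quality 3.0 are discarded and non-maximum suppression
  keeps one peak per diameter. The quality gate is defined this way because
  the original acquisition software's "quality" has no public formula; the
  MAD-normalized response plays the same SNR-gate role and is testable.
- **Nucleus assignment:** each centroid goes to the label of its containing
  voxel; counts are conserved by construction.
- **Volume:** voxel count above the fiber surface threshold (240 after
  linear 8-bit rescale) × voxel volume. The 0.9/0.2 µm surface thicknesses
  are carried in config for provenance only — at these voxel sizes a
  marching-surface volume differs negligibly and costs far more.
- **Labeled-area fraction:** Otsu threshold on the max-projected color
  channels within a compartment mask; constant images return 0 with a
  warning.

## Color-barcode analysis

Fluorophore proportions are treated as **linear** RGB primaries (confocal
intensities are linear; no gamma), mapped through the standard sRGB primary
matrix to XYZ and then to CIELAB. The D65 white point is taken as the image
of (1,1,1) under the matrix so the neutral axis lands exactly on a = b = 0.
Color difference is CIE76 (Euclidean in Lab) by default with CIEDE2000
available for sensitivity analysis; the distinct-hue count comes from
agglomerative clustering of the pairwise ΔE matrix cut at 37.4. Complete
linkage is the default because it guarantees the "any two colors within a
hue differ by ≤ 37.4" reading of the threshold; single linkage is offered.
Barcodes are canonicalized by sorted Lab order before linkage and clusters
renumbered by smallest member, so the partition is invariant to input
order.

## Tracking

Fibers at consecutive time points are matched by minimizing
`w_color·min(ΔE/ΔE_sat, 1) + w_space·min(‖Δx‖/d_max, 1)` (defaults 0.5/0.5,
ΔE_sat = 100, d_max = 30 µm) with the Hungarian algorithm; pairs costing
more than `max_cost` = 0.6 dissolve into unmatched sets. Unmatched-left
fibers are eliminated, unmatched-right open newborn tracks. Dissolution
events pair each elimination with newborns of the following
`event_window` = 1 interval whose centroids fall inside the parent's
circular footprint dilated by 5 µm; a birth inside several footprints goes
to the nearest parent centroid (ties to the lower track id), so replacement
sets are disjoint. The medial-edge zone is operationalized as the fiber's
stored flag; in image-derived data it corresponds to centroids within about
two fiber diameters of the medial boundary.

Tracking accuracy claims apply to the **tagged cohort**: because fibers born
after induction are unlabeled, a replacement cannot impersonate its parent,
and fate calls on simulated 12-h frame series are ≥ 98% correct. When all
fibers are equally visible (membrane-only imaging) and turnover is high, an
in-situ replacement with a coincidentally similar color can absorb its
parent's identity; resolving that requires the color barcode, exactly as in
the original experimental design.

## qPCR model and ΔΔCt

The recombined-cassette transcript share of the whole-animal pool maps to
`Ct_target = base − log₂(share) (+ noise)`; the reference gene has constant
per-cell abundance, so elimination shrinks the numerator while whole-animal
growth dilutes it. Samples follow biological quadruplicate × technical
triplicate. Analysis averages technical replicates within each biological
replicate, forms ΔCt = Ct_target − Ct_ref, ΔΔCt against the control group's
mean, and fold change 2^−ΔΔCt with amplification efficiency fixed at 2.0
(no standard-curve correction). Fold changes are invariant to any constant
Ct offset.

Weekly transcript reduction uses the linear convention by default — total
percent reduction divided by elapsed weeks (98% over 4 weeks ≈ 25
points/week) — with an exponential-decay variant available but non-default.
Report rounding: percentages to the nearest integer, except values below 1%
which keep one decimal.

## Problem sizes and determinism in the shipped checks

The test suite and the acceptance script generate everything at run time:
myotomes of 5–60 fibers on a 120 × 160 px grid, cohorts of 300–2400 fibers,
500+ dissolution events for distribution recovery, 2057 barcodes for the
50-hue palette check, and 12 single-myotome animals (328 tagged fibers) for
the full-elimination pipeline run. These sizes were chosen as the smallest
that leave the statistical checks well-powered (multinomial/binomial 99%
intervals, 5% slope tolerance). All randomness flows from explicit seeds.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the pipeline assumes:
nuclear-domain scaling with condition-dependent slopes, hazard-driven
elimination with footprint-coupled replacement, induction-restricted color
tagging, and dilution-coupled qPCR decay. It does not emulate optical
sectioning artifacts, chromatic aberration, fiber shape anisotropy,
registration error between re-mounted animals (frames are aligned up to
small jitter), spectral bleed-through, or segmentation failure modes of
densely packed real tissue. Passing tests therefore validate the
correctness of the measurement and tracking logic under the stated model,
not the performance of the classical segmenter on real stitched volumes —
for real data the external-mask import path exists precisely so that a
dedicated segmenter can be used upstream.

## Known limitations

- The watershed segmenter assumes closed, bright membranes; broken
  membranes merge fibers (use the external-mask import).
- Nucleus detection undercounts when nuclei sit closer than one diameter
  (non-maximum suppression); counts on crowded fibers are conservative.
- The power-diagram renderer is O(pixels × fibers) per iteration; very
  large scenes should reduce `lloyd_iterations` or raster size.
- `elimination_fraction` assumes the cohort is observable at the cohort
  time; fibers that appear and die entirely between observations are
  invisible to any tracker and are not generated by the simulator.
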