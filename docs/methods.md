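# Methods

This note documents the models implemented in `spheroquant`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical choices
that affect results.

## Dose-response and fold resistance

Viability as a function of drug concentration is modelled with the
conventional three-parameter inhibition curve,

    V(c) = bottom + (top − bottom) / (1 + c / IC50),

i.e. a four-parameter logistic with the Hill slope fixed at 1.  Fitting is
least squares in log-dose space with the IC50 parameterized as log(IC50);
this keeps the problem well conditioned across the five orders of magnitude
a dilution series spans.  Initialization: top = max response, bottom = min
response, log(IC50) = the log-dose whose response is nearest the half-range.
Technical replicates are averaged before fitting; each experimental
replicate is fitted independently and the replicate IC50s summarized as
mean ± SEM — matching how plate experiments are replicated in practice.
A response range below 1e−6 is treated as flat and flagged non-convergent
(no IC50 is reported); a fitted IC50 outside the tested dose range is
flagged extrapolated.  Fold resistance is the plain ratio of two IC50s.

MTT normalization: net absorbance per well is A560 − A690 minus the mean
blank net; viability is net divided by the mean untreated net *of the same
experimental replicate*.  Untreated wells must have positive mean net
absorbance, otherwise normalization is refused.  Cytotoxicity (red-object
area) is divided by matched viability and then by the untreated value of
the same quantity; wells with non-positive viability are excluded with a
warning rather than producing infinite death scores.

## Logistic growth and doubling time

Confluency (%) over time is fitted with K / (1 + exp(−r (t − t₀))),
bounded to K ∈ (0, 100] and r > 0.  The reported doubling time is the
exponential-phase value ln(2)/r; the logistic has no constant doubling
time, and the early-phase rate is the quantity of biological interest.
Constant or non-increasing series (Spearman ρ ≤ 0 against time) are flagged
non-convergent before any optimizer runs.  At the study's sampling (4-h
imaging over 180 h, ~1% confluency noise) the recovery bias of the doubling
time is below 2% over 100 simulation seeds.

## Chemoprotection

For a co-culture seeded at ratio w₁:w₂, the expected viability at each dose
is the ratio-weighted mean of the mono-culture viabilities,
E[V] = (w₁V₁ + w₂V₂)/(w₁ + w₂), computed from mono-culture *means* per dose
(no per-replicate pairing — wells are not paired across plates).  The
chemoprotection coefficient is C_O/E = observed/expected.  Its SEM is
propagated from the observed and expected SEMs by the first-order delta
method, var(O/E) ≈ var(O)/E² + O²·var(E)/E⁴.  Doses where the expected
viability falls below 2% of the untreated signal are reported but flagged
unstable: the ratio of two near-zero numbers is noise-dominated, and 2% is
a typical plate-reader floor.

## Radial sorting statistic

Pipeline per spheroid type (typically 20 spheroids):

1. Spheroid detection: Gaussian smoothing (σ = 2 px), global Otsu, largest
   connected component, hole fill; centroid = intensity-weighted center.
2. Background: median intensity outside a 1.5×-radius isotropic dilation of
   the mask is subtracted.  The result is deliberately *not* clipped at
   zero — symmetric residuals keep annulus means and cumulative sums
   unbiased outside the spheroid.
3. Radial profile: mean tracker intensity in concentric half-open 1-px
   annuli [r, r+1) around the centroid, out to the nearest image border.
   The profile conserves total intensity exactly (Σ mean × count equals the
   image sum over covered pixels).
4. Spheroid radius: the distance enclosing 95% of the profile's total
   intensity, by linear interpolation of the outward cumulative sum; the
   per-type radius is the mean over spheroids (a per-spheroid option
   exists).
5. Normalization: distances divided by the spheroid radius; profiles
   resampled to 100 uniform bins on [0, 1.2]; averaged across spheroids;
   then scaled so the center intensity is 1.  The shell readout is the
   normalized intensity at normalized distance 0.77, with SEM from
   per-spheroid center-normalized values.

Center estimation: `normalize_profile` defaults to the count-weighted mean
of annuli within the innermost 5% of the spheroid radius, since a
single-pixel center is noise-dominated.  The aggregate pipeline
(`sorting_analysis`) goes further and uses the interior plateau out to half
the spheroid radius: with a sparsely labeled population (hundreds of
labeled cells per spheroid) even the innermost 5% contains at most a cell
or two, so its mean carries ~30% Poisson noise, while the spheroid interior
inside the shell band is radially uniform in expectation and pooling it
brings the center error down to a few percent.  The plateau extent (0.5) is
a parameter; shrink it if the enriched band starts below half the radius.

Spheroid death: integrated PI intensity over the mask, divided by the mean
of the same quantity over untreated control wells.

## Junction enrichment

Nuclei are primary objects: smoothing, Otsu, watershed split of touching
objects seeded at distance-transform maxima (≥ 5 px apart), size filter
(≥ 20 px²).  The watershed labels are preserved through the size filter —
re-running connected components would fuse touching nuclei again.

Cell territories grow from the nuclei over the marker-positive foreground
by watershed on the distance-from-nearest-nucleus map (nearest-seed
geometry).  Foreground thresholding does not use a plain histogram split:
a junction-enriched marker is several-fold brighter at cell borders than in
the cytoplasm, and Otsu then separates junction from cytoplasm instead of
cell from background.  The threshold is instead anchored to the biology:
the cytoplasm level is the median marker intensity in a ≤ 6 px ring around
the nuclei, the background level the 2nd intensity percentile, and the
cutoff their midpoint.  This assumes some visible background in the field;
a perfectly confluent zero-background image degenerates to an (almost)
all-foreground mask, which is the correct limit.

Per cell: edge band = (cell expanded 2 px) − (cell shrunk 7 px); shrunken
cytoplasm = cell shrunk 7 px.  Expansion/shrinking are
Euclidean-distance-transform thresholds (isotropic, CellProfiler-like),
with contested expanded pixels assigned to the nearest cell.  The outward
EDT threshold carries a +0.5 px offset because outside pixel centers sit
half a pixel beyond the region boundary; with it, the discrete band area
matches the continuous annulus π((r+2)² − (r−7)²) to under 1.5% for disk
radii 20–50 px (without it the band is ~5% small).  Cells whose 7-px
erosion is empty, cells touching the image border, and cells with zero
cytoplasm mean are excluded with warnings.  The enrichment ratio is mean
edge intensity / mean cytoplasm intensity per cell, averaged over the
field; fields under 160 analyzed cells warn (the conventional minimum for
this assay).

## Collagen invasion

A sheet is an above-threshold connected component of the label channel,
outside the initial (t = 0) spheroid footprint, touching its 3-px dilated
boundary, and at least 50 px² (smaller components are debris).  Per sheet
the end distance is the maximum Euclidean distance from the spheroid center
over its pixels; the statistic is the mean of the top-3 distances divided
by the starting diameter (2 × equivalent radius of the t = 0 mask).  Ties
are broken by component area then label order, deterministically.  Fewer
than 3 sheets: the available ones are averaged and flagged.  No sheets: the
statistic falls back to 0.5 — the center-to-boundary floor, since the
spheroid boundary itself sits at half a diameter — and is flagged so it can
be filtered.

## Molecular quantification

Copy number: technical replicates are combined by arithmetic mean on the
Ct scale (conventional; averaging 2^−Ct instead would weight outlier wells
exponentially).  ΔCt = Ct_target − Ct_reference-gene, n_rel = 2^−ΔCt
(amplification efficiency fixed at 2; no efficiency correction in v1), and
n_abs = n_rel / n_rel,diploid-control × 2 — so the control is assigned
exactly 2 copies by construction.  Shifting both genes of a sample by a
common Ct offset leaves n_abs unchanged.  ΔΔCt expression and
loading-normalized densitometry follow the standard arithmetic.

## Synthetic data: what it emulates, what it does not

All generators draw from one `numpy.random.default_rng(seed)` per call and
are bit-reproducible.

- **Spheroid images** (default 384×384 px, radius 120 px, 2000 cells, 25%
  labeled): cells are placed on a 2D disk — the unlabeled population
  uniformly, the labeled one rejection-sampled with weight
  exp(strength · 1[r/R ∈ shell band]), so the accepted density is exactly
  proportional to the weight and the true edge/center intensity ratio is
  exp(strength) at read-out positions inside the band (default band
  0.7–1.0).  Cells render as isotropic Gaussians (σ = cell radius / 2,
  default 6 px / σ 3 px ≈ a 15–20 μm cell at IncuCyte magnification) over
  a constant background (5) with additive Gaussian noise (σ 1) clipped at
  zero.  Not emulated: 3D structure and projection (a real z-projected
  spheroid accumulates signal toward the center; the flat 2D disk is what
  makes the χ²-uniformity and exp(strength) oracles exact), PSF optics,
  photobleaching, Poisson shot noise, agent-based sorting dynamics.
- **Protection tables**: mono-cultures follow the three-parameter curve
  (top 1, bottom 0); the co-culture is the weight-averaged mixture with the
  sensitive arm evaluated at dose/attenuation in shielding mode.  The
  attenuation factor is a test construct standing in for drug depletion and
  limited transport — it is not a transport model, and no mechanistic claim
  is attached to it.  Replicate noise is additive Gaussian and not floored
  at zero (blank-subtracted viabilities can dip negative; flooring would
  bias deep-kill doses upward and manufacture false anti-protection).
- **Growth curves**: exact logistic plus Gaussian noise, clipped to
  [0, 100] % confluency.
- **Monolayer fields** (default 512×512 px): nuclei at seed points ≥ 28 px
  apart; the cell sheet is all pixels within 45 px of a seed, partitioned
  by nearest seed (Voronoi); the marker is `cytoplasm_level` inside cells
  plus `enrichment × cytoplasm_level` within 2 px of a cell boundary, so
  the intended edge/cytoplasm ratio is 1 + enrichment.  The measured ratio
  is lower (the 9-px analysis band is wider than the 2-px drawn band) but
  strictly increasing in the parameter, which is what the recovery tests
  assert.  Fields are deliberately not fully confluent so that
  foreground/background separation is well posed.
- **Invasion fields**: a 100-intensity disk plus radial 16-px-wide bands
  ending at the requested center distances, angles evenly spread with
  seeded jitter.
- **Ct tables**: Ct_target = Ct_reference − log₂(copies/2) plus
  per-replicate Gaussian noise (default 3 technical replicates), so the
  ΔCt chain recovers the requested copy numbers exactly at zero noise.

Because the generators realize the pipeline's *assumptions* exactly
(radially structured intensity, logistic kinetics, exponential
amplification), passing recovery tests demonstrates correctness of the
measurement code, not robustness to real-data violations of those
assumptions (uneven illumination, debris, efficiency < 2, etc.).

## Problem sizes and tolerances

Test and acceptance runs use the study-scale conditions: 20 spheroids per
sorting readout (50 for the well-mixed null), 11-point 3-fold dilution
series with 6 technical replicates, 45–46 confluency time points over
180 h, ~120-cell monolayer fields, 100 seeds for bias estimates.  Optimizer
tolerance is xtol = 1e−8; non-convergence is a flagged result, never an
exception.  The full suite runs in about a minute on one CPU.

## Known limitations

- The three-parameter model cannot represent steep or shallow Hill slopes;
  a slope parameter would be the first extension.
- Sorting analysis assumes one spheroid per image and a radially symmetric
  intensity distribution; multi-spheroid wells need cropping upstream.
- The junction foreground threshold assumes nuclei lie inside their cells'
  marker territory; markers absent from the perinuclear region would push
  the cytoplasm estimate toward background.
- qPCR quantification assumes perfect doubling per cycle; primer
  efficiencies below 2 bias copy numbers multiplicatively.
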