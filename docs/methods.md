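# Methods

This note documents the models, parameter choices and numerical decisions
behind `ichdquant`, and what the synthetic test bed does and does not show
about real phase-contrast CT data.

## Segmentation

Hyperdense voxels are separated from parenchyma by Kapur–Sahoo–Wong
maximum-entropy thresholding of a 256-bin histogram spanning [min, max] of
the VOI (256 bins is the classic implementation's convention; configurable).
For a candidate boundary after bin t, with class masses P₀ = Σ_{i≤t} p_i and
P₁ = 1 − P₀, the criterion maximises

  H₀ + H₁ = ln P₀ + ln P₁ − A₀/P₀ − A₁/P₁,  A_c = Σ_{i∈c} p_i ln p_i,

with 0·ln 0 ≡ 0, candidates with an empty class skipped, ties (within 1e-12)
broken to the lowest boundary for determinism.  The threshold is found **per
VOI**, not per scan: hyperdensity prevalence and local contrast vary strongly
between tissue locations, and a global threshold would let one dense region
set the operating point of all others.  Foreground is *strictly above* the
threshold, assigning the boundary bin to background.  The implementation is
vectorised over cumulative sums; an exhaustive per-boundary search serves as
the test oracle.

A consequence worth noting: the entropy criterion typically places the
threshold below the half-contrast level of the particle/background step, so
segmented particles dilate by a fraction of the PSF width.  With the default
phantom PSF (below) this bias stays under ~2 % of the diameter for the
smallest population.

## 3-D object counting

Components are labeled at 26-connectivity by default (the common convention
of 3-D object-counting tools; 6 and 18 available for sensitivity analysis),
then canonically relabeled in first-voxel raster order so results are
independent of traversal order.  Volume is exactly voxel count × voxel³;
sizes are reported as equivalent-sphere diameters d = 2·(3V/4π)^{1/3}.
Particles touching the VOI boundary are retained (no edge correction): a
documented bias source, mitigated in the phantom by placing whole cells
inside the volume (see below).

Plaque-like extracellular clusters (~100 µm) are excluded by a size rule,
eq. diameter > 20 µm (configurable): the largest cellular population is
~8 µm, so 20 µm separates cleanly.  A size rule was chosen over manual
curation so the exclusion is reproducible; both retained and excluded sets
are returned.  An optional despeckle filter (minimum voxel count, default
off; the end-to-end drivers use 10 voxels) suppresses single-voxel noise
detections, with the removed count logged.  The smallest genuine particles
in the default phantom occupy ≳ 30 voxels, an order of magnitude above the
despeckle cut.

## Population mixture

Equivalent-sphere diameters (µm) are modelled with a univariate K-component
Gaussian mixture fitted by EM.  Diameters, not volumes, are fitted: volumes
are heavily right-skewed and the reported population sizes are µm-scale
diameters (the alternative is a one-line change at the call site).
Initialisation is deterministic — component means at the (2k−1)/2K sample
quantiles, shared SD, uniform weights — plus 5 restarts with seeded jitter;
the best final log-likelihood wins, making the fit reproducible and
order-invariant.  A variance floor σ ≥ max(voxel/2, 1e-3 µm) prevents
collapse onto voxel-discretised sizes (important at 3 µm voxels where many
particles are 1–2 voxels).  Convergence: relative log-likelihood change
< 1e-8 or 500 iterations; the full trace is kept so tests can assert EM
monotonicity.  Model order is chosen by BIC (p = 3K − 1); K = 3 is the
default model for fine-voxel data, and BIC selection over {2, 3} is the
mechanism by which 3 µm data, where nucleoli are unresolved, report a
bimodal distribution.  Components are named by ascending mean (nucleoli <
glia < ICHD neurons); K = 2 merges nucleoli+glia and carries a `merged`
flag.  Mixtures are fitted per VOI, not pooled across animals.

## Group statistics

The study design is four groups (WT-saline, WT-LY, TG-saline, TG-LY; n = 4,
4, 3, 4 animals) × four regions (dCTX, dHIP, vCTX, vHIP).  Per region:
classical one-way ANOVA, then Tukey–Kramer all-pairs post hoc with the
unequal-n standard error SE_ij = √(MSW/2·(1/n_i + 1/n_j)) and adjusted p
from the studentized-range distribution (scipy's implementation, numerical
integration well below 1e-6 absolute error).  The unit of analysis is the
VOI, matching per-VOI quantification; this pseudo-replicates animals when
several VOIs share one animal, so an animal-mean aggregation mode
(`unit="animal"`) is provided.  No multiplicity correction is applied across
regions or elements beyond Tukey within a region.

Wilcoxon rank-sum comparisons are exact (null distribution of U) when
n₁ + n₂ ≤ 20 and the pooled data are tie-free, otherwise normal
approximation with tie and continuity corrections.  Exact two-sided
p = min(1, 2·min tail).  Note that exact small-sample p-values are discrete
and conservative by construction, so the null-uniformity calibration tests
run in the effectively continuous regime (n = 15 + 15); the exact path is
verified separately against full enumeration.

## Imaging physics

Homogeneous single-material model: refractive index n = 1 − δ + iβ,
attenuation μ = 4πβ/λ.  Forward model: exit wave √I₀·exp(−μt/2 + iφ),
φ = −2πδt/λ, propagated by the Fresnel transfer function exp(−iπλz|f|²);
the sign pair (φ, transfer function) is matched and fixed by the round-trip
test.  Paganin retrieval divides the normalised intensity spectrum by
1 + (δz/μ)k², k = 2π|f|, and inverts Beer–Lambert; at z = 0 it reduces to
exact log-inversion.  Non-periodic fields are mirror-padded to twice the
size before filtering and cropped after (wrap-around suppression); a
`pad=False` mode keeps periodic boundaries, under which pure-phase
propagation conserves energy exactly (Parseval).  A near-field guard warns
when the per-pixel Fresnel number (pixel)²/(λz) falls below 0.1 — the
retrieval model degrades outside the near field.  Default optical constants
are a soft-tissue-like δ = 5.76e-7, β = 5.76e-9 (δ/β = 100) at 20 keV;
these are assumptions, not measured values, and are configurable
everywhere.  Nonpositive values entering the retrieval logarithm are clamped
to ε with a logged count — a nonzero count signals model violation or noise.

## Synthetic phantoms

The generator emulates the statistical structure the analysis assumes, not
brain anatomy:

- **Populations**: mean diameters 8 / 4 / 2 µm (SD 1.0 / 0.6 / 0.4 µm) for
  ICHD neurons / glia / nucleoli, proportions 0.2 / 0.3 / 0.5, counts scaled
  to the VOI volume so the default planted load falls in the 1–5 % band
  reported for AD-lesion tissue loads.  Diameters are truncated at ±2.5 SD.
  Per-class number densities are not published anywhere we know of; the
  defaults reproduce the load band and size anchors only.
- **Rasterisation**: voxel-centre-in-sphere (a voxel is foreground iff its
  centre, (index+0.5)·voxel, lies within the sphere) — no partial-volume
  anti-aliasing, so an exact enumeration oracle exists for every particle.
- **Placement**: rejection sampling with a minimum surface gap of
  2·(PSF σ) + 1 voxel between particles, so the blur the generator itself
  applies cannot bridge neighbours and connected-component labeling can
  recover the planted count.  Whole spheres are placed inside the VOI
  (margin = radius + gap): edge-clipped cells are *not* emulated, which is a
  known difference from real VOIs where boundary-touching particles occur.
- **Contrast and noise**: particles ≈ +50 density units over a background of
  100 (intensity SD 5 per class), background texture SD 2 added before the
  PSF, additive Gaussian detector noise SD 5 after it (SNR ≈ 10).  PSF:
  Gaussian, σ = voxel/3 (FWHM ≈ 0.8 voxel) at every scale — the resolution
  is set by the voxel grid, as in a multiscale acquisition series.  No
  Poisson noise in v1 (photon-rich synchrotron imaging).
- **Vessels**: a few hypodense cylinders (−30 units) to ~1 % volume.
- **Resampling**: block-mean downsampling (integer block nearest to the
  ratio, documented crop), conserving integrated density — this is what
  makes the 0.3 µm → 3.0 µm bimodality experiment a controlled comparison
  on identical tissue.
- **Elemental maps**: 22 normal + 11 ICHD disk-shaped cells on 256² pixels
  at 0.5 µm; class mean densities (ng/mm²) with a 3× ICHD elevation in
  P, S, Ca, Fe by default; pixel noise SD 5 ng/mm², optional between-cell
  scatter (`between_cell_cv`, default 0 so planted means are exact).
- **Study generator**: per-VOI loads drawn lognormally around the
  group×region mean (CV 0.25 — load varies conspicuously between VOIs of
  one animal) with a configurable effect multiplier; the default emulation
  elevates TG-saline × vCTX by 2.5×.  The base design is 15 animals × 4
  regions = 60 VOI; `n_extra_dorsal=6` reproduces a 66-VOI design.
  `render=True` realises each VOI as a phantom whose expected load matches
  the draw.

Passing tests on these phantoms certify the *pipeline arithmetic* —
segmentation, counting, mixture decomposition, load computation, inference —
against known truth.  They do not certify performance on real tissue, where
contrast is structured (dendrites, layers, partial-volume edges), noise is
correlated, and cell shapes are not spheres.

## Problem sizes

Defaults were chosen so the full validation runs comfortably on one CPU:
the reference VOI is 256³ voxels at 0.3 µm (≈ 77 µm cube, ~300 particles);
end-to-end recovery statistics use medians over 20 phantom seeds; power and
calibration simulations use 100–2000 replicates.  All are configuration
parameters, and all scale up without code changes.

## Known limitations

- Spherical particles only; no branch morphology, no shape descriptors.
- No edge-clipped cells in phantoms (see placement above).
- Single-material Paganin model; no CT reconstruction, ring/cupping
  correction, or partial coherence.
- The plaque-exclusion size rule stands in for what may have been manual
  curation in comparable studies.
- Per-VOI analysis pseudo-replicates animals unless `unit="animal"` is used.
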