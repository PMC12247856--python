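# Methods

## Coordinate and unit conventions

All volumes are `(z, y, x)` arrays with per-axis physical pitch in nm
(default 300 × 65 × 65 nm: a 0.3 µm z-step and a lateral pitch plausible
for a 60× super-resolution-by-optical-reassignment configuration — the
lateral pitch is an explicit user input, since every localization cutoff is
physical). Voxel centres sit at integer multiples of the pitch (0-based).
Internally everything is nm; reported volumes/areas are µm³/µm².

## Segmentation and surfaces

A channel is Gaussian-smoothed at the configured *grain* scale (the
per-channel defaults 0.15 µm for lamin, 0.10 µm for the aggregate channel,
0.095 µm for DAPI, 0.0378 µm for human pathology are shipped in
`DEFAULT_CHANNEL_PARAMS`, as are the absolute intensity bands
929.58–6042.27, 251.685–868, 1385.42–7707.77 and the DAPI
background-subtraction level 25.5). Absolute mode keeps the closed band —
voxels saturated above the upper limit are excluded. Local-contrast mode
subtracts a grey-opening background whose box edge
(`background_box_um`, default 8 µm) must exceed the diameter of the
structures being kept; a radius tied to the grain scale is geometrically
wrong for nucleus-sized objects, because an opening at sub-object scale
returns the object itself as background. Components are labelled with
26-connectivity; objects under `min_voxels` (default 10) are dropped.

Surfaces are extracted by marching cubes at the 0.5 iso-level **in physical
coordinates** (no isotropic resampling; interpolation artefacts in area
would bias ψ). The binary object is pre-smoothed at a physical scale of
130 nm (per-axis σ = 130 nm / pitch, floored at 0.7 voxel) before meshing:
without this, the staircase from the 300 nm z-step inflates the measured
area of a 2 µm sphere enough to depress ψ by ≈ 0.03; with it the
discretisation error of ψ on analytic shapes at this sampling is ≈ 0.01
(measured by the acceptance script's error study). Volume is voxel count ×
voxel volume, replaced by the mesh-enclosed volume when the mesh is
watertight (the two agree within 5% above ~500 voxels; tested).

**Rupture detection.** Marching cubes over a padded binary mask always
produces a closed mesh, so mesh watertightness cannot detect a ruptured
envelope. Instead a lamin shell is *open* iff hole-filling adds no enclosed
cavity (the would-be interior leaks to the image border through the hole).
Open shells are capped by dilate → fill → erode with a 1 µm element — this
bridges any hole narrower than 2 µm even on a curved shell, where a plain
morphological closing fails — and the resulting nucleus is flagged
`capped`, so rupture (itself a phenotype) never silently voids the inside
test.

## Nuclear-localization calling

For every aggregate voxel inside the nuclear region, penetration depth is
measured two ways: the in-plane distance to the nearest non-nuclear voxel
in the same z-slice, and the along-z distance in the same (y, x) column
(both via anisotropic distance transforms; equivalent to brute-force
nearest-outside search, which the tests verify). The aggregate's maxima
must clear 240 nm laterally **or** 600 nm axially — each cutoff twice the
corresponding resolution limit. OR is the default combination: each axis'
cutoff is already conservative for that axis, so penetration unambiguous on
either axis suffices; AND is available in config and the pipeline records
which rule produced a bundle. Aggregates are assigned to the nucleus with
the largest mask overlap, falling back to the nearest nucleus by centroid
distance.

The exact binomial test attached to localization proportions needs a null
proportion the source analyses never state; the default is 0.5
("no preference in vs out"), configurable.

## Morphology taxonomy

Verbal class criteria are bound to measured features with named thresholds
(all in config):

| class | rule (first match wins) |
|---|---|
| VI | elongation ≥ 4, not encircling, soma overlap ≤ 0.25 |
| V | ≥ 6 disconnected intranuclear components ≤ 0.5 µm³ each, not encircling |
| II | encircles the nucleus and β₁ ≥ 2 (ring + connecting loop) |
| IV | encircles the nucleus and β₁ = 1 (plain ring) |
| III | max skeleton junction degree ≥ 3, cage coverage ≥ 0.5, fill < 0.5 |
| I | cell-body fill ≥ 0.5 and continuous into a neurite |

β₁ (independent loops) is computed exactly from the cubical complex
(χ = V − E + F − C; β₁ = β₀ + β₂ − χ), which is robust for thin tubes
where a triangulated surface picks up spurious handles. The ring test
("encircles") projects voxels in a thin slab through the nucleus centre
onto candidate planes (grid axes plus the component's principal axes) and
requires ≥ 90% azimuthal coverage with a clear centre. Cage coverage is
the fraction of a 4 × 8 solid-angle binning around the nucleus centre
touched by the aggregate. The fill-fraction conjunct on class III is this
package's addition: without it, a soma-filling class-I mass (whose skeleton
is junction-rich and whose cage coverage is ~1) would be captured by the
earlier class-III rule.

Nuclei are classified by the severity precedence
**ruptured > multi-lobed > malformed > normal** (the operational reading of
"classified as the more predominant irregularity"): ruptured from the
open-shell test; multi-lobed when the internal-distance watershed yields
≥ 2 lobes each ≥ 20% of the volume (or ≥ 2 enclosed lamin components);
malformed when ψ falls below `psi_threshold`. The threshold must be
calibrated against controls on the intensity/geometry of the data at hand:
the shipped pipeline default (0.8) is the midpoint between measured normal
(ψ ≈ 0.97+) and malformed (ψ ≈ 0.45–0.55) synthetic nuclei, while the
`classify_nucleus` signature default (0.47) is the midpoint of the
published tissue group means.

## Spot detection

Scale-matched LoG: σ = diameter/(2√3) converted per-axis to voxels. The
response is normalised so a matched Gaussian blob of unit peak amplitude
scores 1, making "quality" an intensity-scale number; the shipped default
threshold (635, nominal diameter 0.5 µm) therefore only transfers to data
on a comparable intensity scale. Local maxima above threshold are kept;
maxima closer than diameter/2 merge, higher quality winning. Spots are
assigned to nuclei by the same filled region used for localization — one
geometric authority for "inside". Counts are reported per *nucleus* (the
imaged compartment), not per cell.

## Compartments

The RNA partition uses the DAPI-derived (hole-filled) mask as the nuclear
border; everything stained outside is cytoplasmic, and bright intranuclear
foci (nucleoli) count as nuclear. The N/C ratio is nuclear/cytoplasmic
stained volume with an `inf` sentinel when nothing is cytoplasmic. Cell
volume is total segmented α-tubulin volume per field divided by the number
of nuclei.

## Statistics

* **Wilson score interval** (default) reproduces three of the four
  published proportion bounds exactly (26/30 → 70.32–94.69; 12/20 →
  38.66–78.12; 19/20 lower → 76.39). The fourth (19/20 upper, 99.74)
  matches the Newcombe continuity-corrected Wilson bound, implemented as
  `method="wilson_cc"`; near-boundary counts (≤ 2 or ≥ n−2) report both.
* **Exact binomial test**: two-sided by doubling the smaller tail, capped
  at 1; equals brute-force pmf summation (tested for all n ≤ 25).
* **Freeman–Halton Fisher test**: sums conditional probabilities of all
  fixed-margin tables no more probable than the observed (log-space
  tolerance 1e-9). 2×k tables are fully enumerated column-by-column with
  the last column forced by the margin (the published 2×6 table has
  ~1.2 M candidate states, ≈ 2 s); larger or r×c tables fall back to Monte
  Carlo over Patefield-sampled tables with a reported standard error.
* **Two-sample t**: pooled by default (matching the "unpaired t"
  convention), Welch by flag; identical constant groups return t = 0,
  p = 1, zero variance with unequal means raises.
* **Viability**: mean media-only background is subtracted and wells are
  expressed as percent of the highest background-subtracted well.
  Dose-wise comparisons fit a condition × dose ANOVA and report per-dose
  contrasts with Šidák adjustment (Bonferroni switchable) — Šidák being the
  common companion of a two-way-ANOVA workflow.

## Synthetic scenes: what they emulate, and what they do not

The generator renders ground-truth geometry (sphere/perturbed nuclei, thin
lamin shells with optional spherical-cap holes, six aggregate recipes,
puncta, an RNA partition with an exact nuclear fraction, soma/neurite cell
masks), convolves with a separable Gaussian PSF (σ_xy ≈ 51 nm from the
120 nm lateral FWHM; σ_z ≈ 127 nm from the 300 nm axial FWHM) and applies
Poisson shot noise plus Gaussian read noise — the standard fluorescence
noise model; the source imaging reports no noise statistics, so SNR is a
free parameter. Channel amplitudes are chosen so the published absolute
bands segment the synthetic channels directly (aggregate 500, lamin 2000
intensity units, etc.).

The malformed-nucleus recipe perturbs the radius with a rough angular field
(12 cosine terms, angular frequency 8, amplitude 0.6 on a 0.9× base
radius), producing measured ψ ≈ 0.45–0.55 — clearly separated from
spherical controls. Nucleus radius draws are clipped to ±1.5 sd because
field sizes are chosen for the mean radius. Truth sphericity is exactly 1
for spherical nuclei and mask-mesh-derived otherwise.

What passing synthetic tests does **not** show: real tissue has spectrally
bleeding channels, depth-dependent attenuation, deconvolution artefacts,
touching nuclei, autofluorescent debris and postmortem degradation, none of
which are modelled. Published intensity thresholds are instrument- and
preprocessing-specific (the source pipeline deconvolves first), so all
thresholds are config, not constants.

## Problem sizes used in the shipped benchmarks

Scenes are 32 × 192 × 192 voxels (9.6 × 12.5 × 12.5 µm) with one ~3 µm
nucleus unless stated. The acceptance benchmarks use 6 scenes × 18
aggregates for localization (108 truth objects), 10 replicates × 6 classes
per condition for morphology (60 scenes noiseless, 60 at SNR 5 with PSF
blur), 6 scenes of ~12 well-separated puncta for spot detection, and 200
replicate cohorts of 105 (sphericity) / 50 (puncta) nuclei per group for
effect-size recovery, with group SDs back-derived from the published 95%
CIs. The published group means themselves (ψ 0.5836/0.3550, 53BP1
66.89/29.64, N/C 0.4954/0.09499) are not desk-reproducible — they depend
on unavailable raw images — and enter only as generator settings whose
separation the pipeline must recover.

## Known limitations

- The six-class decision list is a geometric idealisation; borderline real
  aggregates (partial rings, broken cages) fall to `unclassified` rather
  than a nearest class.
- Lobe decomposition assumes lobes of comparable scale (watershed markers
  ≥ 2 µm apart); chains of > 2 lobes may undercount.
- The inside test is voxel-based (distance to the nearest outside voxel
  centre); sub-voxel penetration below one pitch is not resolved, which is
  far below the 240/600 nm cutoffs.
- Per-component quality of the human Type I/II punctate-vs-fibril
  distinction is summarised only through elongation of attached components.
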