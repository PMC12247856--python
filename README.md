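# nucmorph

Open 3D quantification of pathological protein aggregates at the nucleus.

In synucleinopathies (Parkinson's disease, Lewy Body Dementia), misfolded
α-synuclein phosphorylated at Ser129 (p-α-syn) accumulates in and around
neuronal nuclei. Whether aggregates are *inside* the nuclear compartment —
and what that does to nuclear shape, DNA integrity, and RNA export — can be
asked quantitatively from super-resolution spinning-disc stacks, but the
published analyses run through proprietary surface-rendering software.
`nucmorph` reimplements that workflow as a tested open pipeline for anyone
analysing multichannel 3D fluorescence stacks of nuclei and aggregates
(DAPI, Lamin A/C, p-α-syn, 53BP1, RNA dye, α-tubulin), together with a
synthetic scene generator so every stage is verifiable against ground truth.

## What it computes

- **Surfaces.** Channels are smoothed at a configurable grain, thresholded
  (absolute band or local contrast), labelled in 3D, and meshed by marching
  cubes in physical coordinates on the anisotropic grid (z-step 300 nm,
  lateral pitch ~65 nm). Each object gets volume *V*, area *A*, and
  sphericity ψ = π^(1/3) (6V)^(2/3) / A ∈ (0, 1].
- **Nuclear localization.** An aggregate is called nuclear only if its
  deepest voxel penetrates the lamin boundary by ≥ 240 nm in-plane or
  ≥ 600 nm axially — twice the lateral (~120 nm) and axial (~300 nm)
  resolution limits, so resolution error cannot fake a call. Ruptured
  envelopes are hole-capped for the inside test and flagged.
- **Morphology taxonomy.** Aggregates are classified into six classes
  (soma-filling/harp, basket, skein cage, ring, intranuclear puncta,
  neuritic rod) from measured topology (loops via cubical Euler
  characteristic), skeleton branching, elongation, ring/cage coverage, and
  soma fill. Nuclei are classed ruptured / multi-lobed / malformed / normal
  by severity precedence.
- **Puncta.** 53BP1 spots via scale-matched Laplacian-of-Gaussian detection
  (0.5 µm nominal diameter), counted per nucleus.
- **Compartments.** RNA nuclear/cytoplasmic volume ratio against the
  DAPI-derived border; whole-cell volume per nucleus from α-tubulin.
- **Statistics.** Wilson score intervals (plus a continuity-corrected
  variant near the boundary), exact binomial tests, the Freeman–Halton
  Fisher exact test on 2×k tables by full enumeration, pooled/Welch t
  tests, and plate-reader viability normalisation with dose-wise
  two-way-ANOVA contrasts.

## Worked example

Generate a pathology-like scene (one nucleus, six intranuclear puncta of
aggregate, nuclear 53BP1 spots, RNA dye split 33% nuclear) and analyse it:

```python
from nucmorph import RunConfig, analyze_scene
from nucmorph.synth import AggregateSpec, SceneParams, generate_scene

params = SceneParams(
    aggregates=[AggregateSpec("V", count=1, depth_nm=1000.0)],
    puncta_per_nucleus=8, puncta_min_sep_nm=1000.0,
    rna_nuclear_fraction=0.33, seed=2,
)
channels, truth = generate_scene(params)
analysis = analyze_scene(channels, RunConfig())
print(analysis.cells[["morphology_class", "nuclear_localized",
                      "sphericity", "spot_count"]])
print(analysis.compartments[["measure", "value"]])
```

prints

```
  morphology_class  nuclear_localized  sphericity  spot_count
0                V               True    0.991268           6
                       measure       value
0                 rna_nc_ratio    0.390473
1  cell_volume_per_nucleus_um3  497.713028
```

i.e. the aggregate is recognised as intranuclear punctate pathology
(class V), its deepest voxel clears both localization cutoffs, the nucleus
is still spherical (ψ ≈ 0.99, class *normal*), six 53BP1 puncta were
detected (matching this seed's Poisson draw), and the measured RNA N/C
volume ratio ≈ 0.39 against the generated nuclear fraction of 0.33/0.67 ≈ 0.49
(the DAPI-derived border is slightly tighter than the true envelope).

The same stages are scriptable from the shell:

```bash
nucmorph synth --params scene.yaml --seed 2 --out scene/
nucmorph classify --input scene/scene.tif --channels dapi,lamin,psyn,53bp1,rna,tubulin --out out/
nucmorph stats --test wilson --successes 26 --n 30
```

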