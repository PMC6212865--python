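# vesicoloc

Object-based colocalization and co-transport analysis for multi-channel
fluorescence microscopy of vesicles — with a ground-truthed synthetic image
generator so every number the package reports can be validated end to end.

## The problem

Endosomal membrane markers (EGFP-tagged Rab5a/7a/9a/11a GTPases) sit on the
*surface* of the endosome and image as rings; a lumenal cargo (e.g. an
mCherry-tagged viral envelope glycoprotein) *fills* the vesicle interior.
The two signals belong to the same organelle yet occupy disjoint pixels, so
pixel-correlation measures (Pearson, Manders) can report near-zero or even
negative association for perfectly colocalized vesicles. The right unit of
analysis is the vesicle: build a mask of filled regions of interest (ROIs)
from the marker channel, measure the cargo intensity inside each ROI, call
each vesicle cargo-positive or negative against a robust background
threshold, and report

percent positive = 100 · (# cargo-positive marker ROIs) / (# marker ROIs),

with a Wilson 95% binomial interval. For time-lapse data the package also
measures whether punctate particles (e.g. EGFP-tagged capsids) are
*co-transported* with cargo vesicles, and classes each vesicle track's
motion from its mean squared displacement, MSD(τ) ∝ τ^α: directed/active
(α ≥ 1.4), diffusive (0.7 ≤ α < 1.4) or confined (α < 0.7), with
MSD(τ) = 4Dτ giving the diffusion coefficient and MSD(τ) = v²τ² the
transport speed.

It is intended for microscopists quantifying vesicular trafficking
(virology, membrane biology) who want scripted, reproducible versions of
the usual ImageJ ROI-mask and Coloc2 workflows, plus single-particle
tracking, in one place.

## What's inside

| module | contents |
|---|---|
| `vesicoloc.simulate` | synthetic ring/lumen/punctum image and time-lapse generator with per-vesicle and per-track ground truth |
| `vesicoloc.detect` | vesicle segmentation (band-pass → Otsu → hole fill → label) and LoG punctum detection with sub-pixel localization |
| `vesicoloc.coloc` | robust background model, per-ROI yes/no cargo calls, percent-positive summary, masked Pearson/Manders |
| `vesicoloc.track` | greedy nearest-neighbor linking with gap closing, time-averaged MSD, weighted power-law motion classification, co-transport fraction |
| `vesicoloc.pipeline_io` | YAML config, TIFF/CSV I/O, provenance, the two composed analyses |
| `vesicoloc.cli` | `vesicoloc simulate / coloc / track / run-rab-coloc / run-cotransport` |

## Worked example

```python
from vesicoloc import (SimulationConfig, simulate_field, detect_vesicles,
                       estimate_background, classify_objects,
                       percent_positive, pixel_coloc)

cfg = SimulationConfig(n_vesicles=80, coloc_fraction=0.6,
                       image_height=640, image_width=640, seed=11)
stack, truth = simulate_field(cfg)

rois, label_map = detect_vesicles(stack.channel("marker"))
bg = estimate_background(stack.channel("cargo"), label_map)
calls = classify_objects(stack.channel("cargo"), rois, bg, k=3.0)
summary = percent_positive(calls)
print(f"vesicles detected: {summary.n_objects}")
print(f"cargo-positive:    {summary.n_positive} ({summary.percent_positive:.1f}%, "
      f"95% CI {summary.ci_low:.1f}-{summary.ci_high:.1f})")
print(f"true fraction:     {100*truth.realized_cargo_fraction():.1f}%")

px = pixel_coloc(stack.channel("marker"), stack.channel("cargo"), label_map,
                 threshold_mode="otsu")
print(f"pearson_r={px.pearson_r:.3f}  M1={px.manders_m1:.3f}  M2={px.manders_m2:.3f}")
```

prints

```
vesicles detected: 80
cargo-positive:    56 (70.0%, 95% CI 59.2-78.9)
true fraction:     70.0%
pearson_r=-0.427  M1=0.189  M2=0.527
```

All 80 simulated vesicles are found and the object-based statistic recovers
the true cargo-positive fraction exactly — while the masked pixel Pearson
coefficient is *negative* (−0.43), because ring and lumen anti-localize
pixel-wise. That contrast is precisely why the object-based statistic
exists.

The same analysis from the shell, reproducibly:

```sh
vesicoloc run-rab-coloc --config demo.yaml --seed 11 --outdir results/demo
```

where `demo.yaml` holds a `schema: 1` header, an output directory and a
`simulation:` block (or an `input_path:` pointing at a multi-page TIFF).
Outputs are `objects.csv` (one row per ROI with its call), `summary.csv`,
`label_map.tif` and a `provenance.json` carrying the config hash and seed;
identical (config, seed) runs are byte-identical.

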