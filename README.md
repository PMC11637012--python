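# spheroprofile

Radial intensity profiling, microregion statistics, and NADH
fluorescence-lifetime / optical redox analysis of multicellular tumor
spheroid microscopy images.

As a scaffold-free tumor spheroid grows it organises into concentric
microregions — a necrotic core, a quiescent middle zone, and a
proliferative edge — and markers such as CD80/CD206 (M1/M2 macrophages),
Ki67 (proliferation), CC3 (apoptosis), and HIF-1α/HIF-2α (hypoxia) develop
radial gradients across them. `spheroprofile` quantifies those gradients
from fluorescence or brightfield images, and maps cellular metabolism from
TCSPC fluorescence-lifetime stacks. It is written for imaging labs that
need a reproducible, scriptable replacement for by-eye spheroid triage and
ad-hoc profile extraction.

## Method

For each quality-controlled single-spheroid crop (converted to grayscale
and down-sampled to a 200 × 200 working grid), a binary mask is segmented
by Otsu threshold, the mask centroid is located, and *K* = 20 rays are cast
from the centroid to the mask boundary. Each ray is sampled at *M* = 80
points equally spaced on its normalised radius, the K × M matrix is reduced
to a mean profile X, and the profile is min–max normalised:

    normalized intensity = (X − min X) / (max X − min X)

Profiles are partitioned into microregions by size class — small spheroids
(0–200 µm): 25 % core / 50 % quiescent / 25 % edge; large spheroids
(201–400 µm): 60 % / 30 % / 10 % — and per-region values (midpoint sample
or block mean) are compared with an ordinary two-way ANOVA
(region × size class) plus Tukey's HSD, and regressed on diameter.

For metabolic imaging, each pixel's TCSPC histogram is fit with a
constrained biexponential decay

    I(t) = I0 · (A1 · e^(−t/τ1) + A2 · e^(−t/τ2)) + bg,

where τ1 is the short lifetime of free NADH and τ2 the long lifetime of
protein-bound NADH. The package reports the amplitude-weighted mean
lifetime τm = (A1 τ1 + A2 τ2)/(A1 + A2), A1/A2 maps, and — from gain- and
laser-power-normalised NADH/FAD intensity images — the pixel-wise optical
redox ratio FAD/(FAD + NADH).

A `synthetic` module generates phantoms with known ground truth for every
stage (radial marker gradients, multi-spheroid QC fields, Poisson decay
stacks, statistical cohorts), so the whole pipeline is testable without any
imaging data.

## Worked example

```python
import numpy as np
from spheroprofile import synthetic, profiling, regions

# an edge-high marker (e.g. CD80) on a 240 um spheroid, no noise
spec = synthetic.PhantomSpec(diameter_um=240, profile_shape="edge_high")
image, truth = synthetic.make_spheroid_image(spec)

record, pset = profiling.profile_spheroid(image)
print(f"diameter {record.diameter_um:.1f} um, "
      f"circularity {record.circularity:.3f}, class {record.size_class}")

partition = regions.build_partition(record.size_class, pset.M)
summary = regions.extract_regions(pset.normalized_profile, partition)
print(f"core {summary.core:.3f}  quiescent {summary.quiescent:.3f}  "
      f"edge {summary.edge:.3f}")
```

prints

```
diameter 239.8 um, circularity 0.997, class large
core 0.291  quiescent 0.747  edge 0.949
```

The measured diameter matches the phantom's 240 µm to within raster
precision, and the large-class partition (60/30/10) reads the normalised
ramp at its three representative radii (the block midpoints at normalised
radius ≈ 0.29, 0.75, 0.95) — an edge-high marker rising from core to edge.

The same workflow runs from the shell:

```sh
spheroprofile simulate image --seed 7 --out sim/
spheroprofile qc sim/phantom.tif --pixel-size 2 --out-dir crops/
spheroprofile profile crops/phantom_sph1.tif --pixel-size 2 --out profile.csv
spheroprofile run --manifest manifest.csv --out-dir results/
```

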