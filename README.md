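# mtbundle

Quantitative analysis of how a small cytoskeletal crosslinker (a
GAS2-family spectraplakin: one actin-binding CH3 domain, one
microtubule-binding GAR domain) organises microtubule bundles — from
cryo-EM helical-segment metadata, co-sedimentation densitometry, size
exclusion chromatography, and TIRF-style dynamic-instability traces.

The package is aimed at structural/cell biologists who have RELION particle
STAR files of bundled filaments and tabular assay read-outs, and want the
downstream numbers: per-filament polarity, parallel vs antiparallel pair
counts, wall-to-wall bundle spacing, binding constants, oligomeric state,
and growth/catastrophe/rescue statistics.

## What it computes

**Microtubule polarity from segment metadata.** Each helical segment carries
ZYZ Euler angles (rot, tilt, psi) relating the 3D reference to the image;
the in-plane image of the filament plus-end axis is

    u = (cos psi, sin psi),    weight = sin(tilt),

independent of rot. Per filament, segment directions are combined by a
weighted circular mean with two-orientation (axial) disambiguation; the
weighted mean resultant length R ∈ [0, 1] ("coherence") gates confidence.
Arrow overlays (minus→plus) are exported as CSV/SVG.

**Bundle geometry.** Filament axes are total-least-squares lines; two
filaments in one micrograph form a bundled pair when they overlap by ≥ 50%
and their edge gap (center-to-center distance minus the 25 nm outer
diameter) is ≤ 50 nm. Pairs are parallel if the angle between plus-end
directions is < 90°, antiparallel if > 90°; the parallel fraction gets an
exact two-sided binomial test against 0.5. Axial lattice compaction is
reported as the dimer-rise difference between a reference and an observed
lattice.

**Binding and oligomers.** Densitometry lanes reduce to pellet fractions
P/(P+S); titrations are fitted per replicate with the single-site isotherm
f([L]) = Bmax·[L]/(Kd+[L]) (quadratic ligand-depletion variant available);
SEC apparent masses come from a log10(MW)-vs-elution-volume calibration and
yield the oligomeric state as the nearest integer multiple of the monomer
mass.

**Dynamic instability.** Length-vs-time traces are segmented into
growth/pause/shrinkage by penalised optimal partitioning into line segments
(noise level estimated robustly from the trace itself), giving growth
velocity (mean ± SEM over well-measured growth phases), catastrophe
frequency per time in growth+pause, rescue frequency per time in
shrinkage, and pause durations.

**Synthetic ground truth.** Seeded generators emulate each data stream —
bundled filament pairs written as valid STAR tables, isotherm densitometry
with multiplicative noise, and a three-state continuous-time Markov chain
(growth/pause/shrinkage with reflection at zero length) — each alongside a
serialised ground-truth record, so every pipeline stage is testable against
known truth.

## Worked example

```python
import mtbundle as mb

# simulate 177 bundled pairs, 91 parallel, 5-degree angle noise
table, truth = mb.gen_bundle_star(n_pairs=177, fraction_parallel=91/177,
                                  angle_noise_deg=5.0, seed=42)
traces, pairs, summary = mb.analyze_particles(table)
print(summary.n_total, summary.n_parallel, summary.n_antiparallel)
print(round(summary.fraction_parallel, 3), round(summary.binomial_p, 3))
```

prints

```
177 91 86
0.514 0.764
```

i.e. all 177 simulated pairs are detected and classified, 91 parallel and
86 antiparallel exactly as generated; the parallel fraction 0.514 is not
distinguishable from 0.5 (exact binomial p = 0.76), the signature of a
crosslinker indifferent to bundle orientation.

```python
import numpy as np
rows, _ = mb.gen_cosed(kd_uM=0.69, cv_noise=0.05, seed=1)
fit = mb.fit_isotherm(mb.binding_series_from_rows(rows))
print(f"Kd = {fit.kd_uM:.2f} +/- {fit.kd_sd_uM:.2f} uM")
```

prints `Kd = 0.69 +/- 0.05 uM` — triplicate recovery of a 0.69 µM
dissociation constant at 5% multiplicative gel noise.

The same stages are scriptable from a shell:

```bash
mtbundle simulate bundles --n-pairs 177 --seed 42 --out sim/
mtbundle bundles --star sim/particles.star --out results/
mtbundle dynamics --csv traces.csv --out results/
```

Every run writes a `run_manifest.json` (config, input checksums, version)
sufficient to reproduce it.

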