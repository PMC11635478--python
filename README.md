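# evpscope

Single-particle analysis of multi-channel TIRF images of small
extracellular vesicles and nanoparticles (sEVPs).

Cells secrete a mixture of membrane-bounded small extracellular vesicles
(sEVs, 30–200 nm) and non-vesicular nanoparticles (NPs) of similar size.
When such particles are anchored on a functionalized coverslip and imaged
by total internal reflection fluorescence microscopy, each one appears as
a diffraction-limited spot in up to three channels: a water-soluble
membrane dye (COE) marking the lipid bilayer, CFSE marking luminal
esterase/cargo content, and PE-Cy5-labelled CD63 antibodies marking a
tetraspanin surface protein. `evpscope` turns these images into
quantitative single-particle biology for people building or using
imaging-based EV assays: it detects and measures every spot, decides
per-channel positivity, classifies each particle into one of seven
subpopulations, and converts antibody-channel intensities into molecule
copy numbers.

## The analysis in brief

1. **Preprocess** (per channel): flat-field correction by division with
   the normalized Gaussian-blurred image (σ = 30 px = 7.5 µm), then
   rolling-ball background subtraction (radius 50 px = 12.5 µm).
2. **Detect**: band-pass the image (Gaussian + Mexican-hat at a 2 px
   scale), threshold at `k_sd`·SD of the filtered image (k ∈ [3, 4],
   default 3.5, robust SD), keep connected regions ≥ 3 px. Integrated
   intensity is the background-corrected sum over the spot footprint;
   strings of merged particles are split by watershed; large bright
   circular aggregates are flagged and excluded.
3. **Colocalize**: channels are merged into a noise-normalized composite,
   detection runs once, and channel *c* is positive iff its band-pass
   response reaches `k_sd`·SD_c inside the spot. The positivity triple
   maps to one of seven labels — COE⁺ particles are vesicular
   (`sEV CFSE±CD63±`, four classes), COE⁻ particles non-vesicular
   (`NP CFSE+CD63+`, `NP CFSE+CD63-`, `NP CFSE-CD63+`).
4. **Quantify**: subpopulation (Venn) fractions with between-ROI standard
   errors; CD63 copy numbers per particle as intensity/μ₁, where μ₁ is
   the Gaussian peak fitted to the intensity histogram of isolated single
   antibodies — or, alternatively, the full copy-number distribution by
   NNLS deconvolution of the intensity histogram against
   Σₙ wₙ·N(n·μ₁, n·σ₁²); pairwise marker correlations, √intensity size
   proxies, the normalized between-subpopulation intensity variance, and
   Welch tests between sample groups.

A fully ground-truthed synthetic scene generator (Gaussian PSF, log-normal
marker intensities with a latent-copula correlation, per-fluorophore CD63
emission, illumination ramp, Poisson + read noise) makes every stage
testable without real data. See `docs/methods.md` for models, defaults
and limitations.

## Worked example

Simulate a field, analyze it, and read the subpopulation fractions:

```bash
evpscope simulate --out scene --seed 7 --density 0.02 --size 600 600
evpscope detect --config config.yaml          # points at scene/*.tif
evpscope analyze --particles out/particles.csv --out analysis
```

or in Python:

```python
from evpscope import (SceneParams, generate_scene, preprocess_field,
                      composite_detect, venn_fractions)

image, truth = generate_scene(SceneParams(
    field_size_px=(600, 600), particle_density_per_um2=0.02, seed=7))
particles = composite_detect(preprocess_field(image))
venn = venn_fractions([particles])
print(f"{len(truth.particles)} particles simulated, "
      f"{venn['n_particles']} analysed")
for label, v in venn["fractions"].items():
    print(f"{label:16s} {v['fraction']:.3f}  (n={v['count']})")
print(f"total sEV fraction {venn['sev_fraction']:.3f}")
```

```text
458 particles simulated, 435 analysed
sEV CFSE+CD63+   0.115  (n=50)
sEV CFSE+CD63-   0.126  (n=55)
sEV CFSE-CD63+   0.062  (n=27)
sEV CFSE-CD63-   0.120  (n=52)
NP CFSE+CD63+    0.083  (n=36)
NP CFSE+CD63-    0.262  (n=114)
NP CFSE-CD63+    0.232  (n=101)
total sEV fraction 0.423
```

The fractions estimate the generator's seven-way mixture
(0.10, 0.15, 0.05, 0.12, 0.08, 0.28, 0.22); the total sEV fraction is the
sum of the four COE⁺ classes (0.42 in the generator). Deviations at this
field size are dominated by binomial sampling noise (~450 particles);
the two dozen unanalysed particles sit near the field border or below
the detection floor of the default log-normal brightness.

## Layout

```
src/evpscope/
  simulate.py      synthetic TIRF scenes + calibration fields with ground truth
  preprocess.py    flat-field and rolling-ball background correction
  detect.py        band-pass filtering, thresholding, photometry, strings, aggregates
  colocalize.py    composite / matched colocalization, 7-way labels, Venn fractions
  quantify.py      calibration fit, copy numbers, correlations, capture, statistics
  suites.py        canonical synthetic benchmarks (shared by tests and acceptance)
  pipeline.py      config-driven end-to-end runs with logged provenance
  cli.py           `evpscope simulate | detect | analyze | report`
```
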