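# deepmarrow

Quantitative analysis of deep-tissue three-photon microscopy (3p.m.) of bone
marrow in intact long bones — the calibration physics, the label-free
third-harmonic-generation (THG) cell phenotyping, and the cell-motility
statistics — exercised end to end on a synthetic tibia phantom generator that
emulates the statistical structure of intravital data.

It is written for microscopists and image analysts who work with deep
multiphoton imaging: people who need to fit attenuation lengths and SNR depth
profiles from their own z-stacks, classify cells by volume and THG content,
track them, and decompose motility distributions — and who want every step of
that chain validated against ground truth before trusting it on real data.

## The science in brief

**Depth attenuation.** In tissue, laser power decays as `exp(-z / l_e)` where
`l_e` is the *effective attenuation length* (≈113 μm in cortical bone and
≈263 μm in marrow at 1650 nm). For an n-photon process with applied pulse
energy `E(z)`, the detected signal scales as `S(z) ∝ [E(z)·exp(-z/l_e)]^n`,
so the power-corrected statistic `ln[S(z)^(1/n) / E(z)]` is linear in depth
with slope `-1/l_e` — that regression is `fit_attenuation_length`. Around it
sit the pulse-train bookkeeping (`P = E·R`, pulses per pixel `= τ·R`),
exponential pulse-energy z-adaptation through two anchors, effective pulse
energy through layered tissue, fluorophore saturation depth, depth-dependent
SNR `(S̄-B̄)/σ_B` with its SNR = 1 (detection) and SNR = 3 (segmentation)
limit depths, Gaussian-profile/edge-derivative resolution estimation
(FWHM = 2√(2 ln 2)·σ), and exponential photobleaching fits.

**THG phenotyping.** Marrow plasma cells (segmented objects of 500-4189 μm³;
B cells are 65-500 μm³) split into a THG^hi subset — granular intracellular
THG from membrane-rich organelles, chiefly endoplasmic reticulum (ER), a
label-free proxy for antibody-synthesis capacity — and a THG^lo subset with
membrane-only signal. THG^hi is called by the *top-1%-of-voxels* rule: a cell
is THG^hi if it contains at least `m` voxels (default 3) above the 99th
percentile of the in-tissue THG intensity distribution. ER positivity is
gated against a detection limit defined as the highest reference-channel
count inside a signal-free control region.

**Motility.** Tracks are linked by optimal bipartite assignment with a
constant-velocity predictor, an 8 μm frame-to-frame distance cap and up to 3
bridged gap frames. Each track yields a *mean displacement rate* (net
start→end displacement / duration) and a *mean velocity* (path length /
duration). The population histogram of plasma-cell displacement rates is
decomposed into two Gaussians; the component areas give the weights of a
migratory subset (≈0.96 μm/min) and a sessile subset (≈0.21 μm/min).

**Similarity unmixing (SIMI).** With few detection channels, mixed voxels are
classified — not linearly unmixed — by assigning each above-background voxel
to the unit-sum spectral fingerprint (pure or mixed, e.g. "THG+GFP+ER") with
the highest cosine similarity; in-situ fingerprints are found by k-means on
normalized foreground vectors.

**Synthetic tibia phantoms** (`deepmarrow.phantom`) provide the ground truth:
a two-layer tissue with per-layer `l_e`, ellipsoidal cells of both volume
classes with cytoplasmic fluorophore, THG membrane shells, intracellular THG
granules co-occurring with ER signal, bright extracellular THG structures,
two-state motility (truncated-Gaussian rate mixture, fast-state weight
0.378), exponential photobleaching, and PMT noise (Poisson + Gaussian read
noise + offset). Every generator is deterministic for a given seed.

## Worked example

```python
from deepmarrow import pipeline

cortex = pipeline.attenuation_recovery(113.0, seed=7, n_seeds=5)
print(f"cortex l_e: {cortex['l_e_mean']:.1f} μm (generated with 113 μm)")

r = pipeline.thg_er_experiment(seed=7)
print(f"THG^hi plasma cells: {r['thg_hi_plasma_pct']:.1f}% "
      f"(ground truth {r['true_thg_hi_plasma_pct']:.1f}%)")
print(f"ER+ among THG^hi:    {r['er_given_thg_hi_pct']:.1f}%")

res = pipeline.motility_experiment(seed=7)
m = res.mixture
print(f"fast subset {100*m.weights[0]:.1f}% at {m.means[0]:.2f} μm/min, "
      f"slow {100*m.weights[1]:.1f}% at {m.means[1]:.2f} μm/min")
```

prints

```
cortex l_e: 114.6 μm (generated with 113 μm)
THG^hi plasma cells: 33.5% (ground truth 33.0%)
ER+ among THG^hi:    89.7%
fast subset 31.7% at 0.97 μm/min, slow 68.3% at 0.24 μm/min
```

Reading it: a depth stack generated with `l_e = 113` μm under Poisson noise is
fit back to ≈114.6 μm; a marrow phantom in which 33.0% of plasma cells truly
carry THG granules is recovered at 33.5% THG^hi with 89.7% of THG^hi cells
ER-positive; and the full segmentation → tracking → histogram-fit chain on one
176-cell time-lapse returns a 31.7% migratory subset with component means
0.97/0.24 μm/min — single-seed estimates scatter by several points, which is
why multi-seed averages are used for validation (below).

A thin CLI wraps the same functions: `deepmarrow phantom` (seeded phantom +
ground-truth JSON), `deepmarrow run --config cfg.json` (end-to-end experiment
with a reproducibility report carrying the config hash and seed), and
`deepmarrow verify` (multi-seed recovery summary).

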