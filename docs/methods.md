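# Methods

This note documents the models implemented in `deepmarrow`, the assumptions
behind them, the parameter defaults and why they were chosen, what the
synthetic phantoms do and do not emulate, and the numerical choices that a
user re-deriving results should know about. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and calibration

### Attenuation

The package treats the effective attenuation length `l_e` of a tissue as an
*operational* quantity: the depth over which laser power falls to 1/e,
jointly capturing scattering and absorption on the excitation path, with
emission-path losses folded into the same effective constant. For excitation
order `n` (2 or 3 photons) and applied pulse energy `E(z)` the expected
detected signal is

```
S(z) ∝ [E(z) · exp(-Σ_i d_i(z)/l_e,i)]^n ,
```

where `d_i(z)` is the depth traversed in layer `i`. `fit_attenuation_length`
therefore regresses `ln[S(z)^(1/n) / E(z)]` on z; the slope is `-1/l_e`.

*Why semi-log, and why the n-th root?* An exponential decay linearizes in
semi-log coordinates, and dividing the n-th root of the signal by the applied
energy removes both the nonlinearity of the excitation process and any
pulse-energy z-adaptation applied during acquisition. A raw `ln S` vs z fit
(slope `-n/l_e`) is available via `power_corrected=False`; on constant-energy
single-layer data the two agree exactly, which the tests verify. Whether one
additionally log-transforms depth is a representation choice only — the decay
law itself is exponential in z, so depth is kept linear here.

Per-plane signal is the mean of the top-decile in-mask voxels minus a
background estimate (a user-designated empty region; the slab phantoms carry
one by construction). The top-decile estimator is robust to partially filled
masks but sits ≈1.3 background-noise s.d. above the plane mean; with the slab
brightness used here (2×10⁴ counts at the surface) this inflates recovered
`l_e` by ≈1-2%, well inside the 5% validation band, and vanishes as
brightness grows. Planes with non-positive corrected signal are excluded; at
least 5 usable planes are required.

### Pulse-energy bookkeeping

Average power is exactly `E·R` (nJ × Hz → mW), pulses per pixel exactly
`τ·R`. The z-adaptation law `E(z) = E_a·exp((z-z_a)/l_adapt)` is determined
by two anchors; equal anchor energies yield the flat law (`l_adapt = ∞`).
Effective pulse energy multiplies the applied law by the per-layer
attenuation; the saturation depth (first depth where the effective energy
reaches a fluorophore's saturation energy, e.g. 4.03 nJ for tdTomato) is
found by bisection to 0.1 μm and reported as "not reached" when the profile
stays below it. Saturation energies are accepted as input constants, not
estimated. Non-monotone effective-energy profiles are refused rather than
silently searched.

### SNR

Depth-dependent SNR is `(S̄ - B̄)/σ_B` per plane, with `S̄` the mean of
in-mask voxels above the background mean and `B̄`, `σ_B` from a disjoint
background region. The depths where SNR crosses 1 (detection limit) and 3
(reliable 3D segmentation) are linearly interpolated between planes and
flagged "not reached" past the last plane. The statistic is invariant under a
constant offset and scales linearly with repetition rate at fixed dwell time
and pulse energy — both are asserted in tests.

### Resolution

Lateral/axial FWHM is estimated from 1D profiles through sub-resolution
structures, fitted by a Gaussian either directly (`gaussian_profile`) or
after a first finite difference (`edge_derivative`; the derivative of a
blurred step is the blur kernel). FWHM = 2√(2 ln 2)·σ; estimates are means
over ≥5 successfully fitted structures, with failures counted. The
diffraction-limit reference values use a Gaussian-focus approximation with
the 1/√n multiphoton narrowing (lateral `0.71·λ/(NA·√n)`, axial
`2·n_im·λ/(NA²·√n)`, water immersion `n_im = 1.33`); a vectorial focal-field
computation is deliberately out of scope, so these are reference lines, not
instrument truth.

### Photobleaching

`F(t) = F₀·exp(-k·t)` is fitted by nonlinear least squares seeded from the
log-linear solution; `k` is reported in min⁻¹ with its standard error.
Non-positive samples are excluded. On noise-free generator traces the fit
recovers the generative `k` (defaults 1.3×10⁻³ min⁻¹, the 1650 nm value; the
1100 nm value 2.4×10⁻³ is exercised in tests) to better than 1%.

## THG phenotyping

Segmentation works on a cubic-voxel resampled working copy: local-contrast
background subtraction (Gaussian-smoothed copy at 3× the 7.5 μm seed
diameter; a median filter is available but is prohibitively slow in 3D at
stack scale), Otsu threshold clamped at zero contrast, 3D connected
components, then marker-based watershed with markers at local maxima of the
smoothed distance transform spaced at least one seed diameter apart. Two
robustness details matter in time-lapse use: the distance transform is
smoothed (σ = 1 voxel) so marker placement does not flicker between frames,
and every foreground component is guaranteed a marker (watershed silently
drops unmarked components). The working-voxel target is the *coarsest* axis
spacing (normally dz), which bounds the working volume; volumes are voxel
counts × working-voxel volume, centroids are mapped back to μm.

Per-cell channel statistics and the THG^hi voxel count are read on the
*native* grid by nearest-neighbour mapping of the label volume — THG granules
occupy single native voxels and would be diluted or missed entirely on a
resampled copy.

Volume gates: B cells 65 ≤ V < 500 μm³, plasma cells 500 ≤ V ≤ 4189 μm³
(the volumes of 5 μm and 20 μm spheres); 500 μm³ belongs to the plasma class
and both outer bounds are inclusive. The THG^hi rule: threshold at the 99th
percentile of the in-tissue THG distribution (computed per stack over the
tissue mask; the field of view of a marrow stack is tissue throughout), call
a cell THG^hi if ≥ m voxels exceed it. `m = 3` by default — "presence" of
granular signal needs more than one bright voxel to be robust to noise, and
since granule-bearing cells carry ≥3 granules the call is identical for
m ∈ {1,2,3} on phantoms (tested) and only shrinks beyond that.

ER gating: the detection limit is the *maximum* reference-channel count in a
signal-free control region (in vivo: cortical bone, where no ER tracker
accumulates; in phantoms: a reserved cell-free band). A cell is
reference-positive iff its mean in-cell reference signal exceeds the limit.
Both concordance fractions (ER⁺ | THG^hi and THG^hi | ER⁺) are reported,
with empty denominators flagged rather than coerced to zero.

Cortical thickness is the per-(x,y)-column contiguous z-span of the binary
cortex mask times dz (columns with holes report the first span and are
flagged); a sphere-fitting local-thickness transform is out of scope.

## Tracking and motility decomposition

Linking is frame-to-frame optimal bipartite assignment
(`scipy.optimize.linear_sum_assignment`) with a constant-velocity position
predictor standing in for a commercial autoregressive-motion tracker. The
8 μm frame-to-frame distance cap is hard (the predictor only ranks
candidates; it cannot authorize longer jumps), and a track unmatched for
g ≤ 3 frames may reconnect within a linear budget of `8·(g+1)` μm — the
gap-closing budget of the commercial tool is undocumented, so the linear rule
is this package's documented choice. Linking is deterministic given input
order.

Mean displacement rate = net start→end displacement / duration; mean
velocity = path length / duration. This is the only reading under which
velocities of ≈3.6 μm/min coexist with displacement rates of ≈0.4 μm/min for
the same cells, and the triangle inequality (rate ≤ velocity) is asserted as
a property test.

The displacement-rate histogram is fitted by the sum of two Gaussians
(unweighted least squares on bin counts; a log-count variant is exposed for
comparison with logarithmic displays but is not used for weights, since
amplitudes fitted in log space no longer represent counts — a 150-replicate
simulation showed it biases the fast weight by >20 points). Component weights
are Gaussian areas (`a·σ`) normalized; the larger-mean component is always
reported first. Initialization is the 25th/75th-percentile split, refit from
5 jittered starts, best residual kept, seed-controlled. Two numerical guards:
component σ is floored at half the bin width (a component narrower than a bin
is unidentifiable) and capped at a third of the histogram range — a "double
Gauss-peak" decomposition presumes peak-like components, and without the cap
the fit occasionally degenerates into a narrow spike plus a flat pedestal
whose analytic area swamps the weights. All-identical rates return a flagged
single-component fallback; ≥30 cells are required.

In the end-to-end motility experiment the histogram uses 15 bins and only
tracks covering ≥15 of 21 frames enter the fit. Both are the package's own
analysis choices: Freedman-Diaconis binning at n ≈ 176 suggests ~11-15 bins,
and a simulation at the study's sample size showed ≈-0.3 point weight bias at
15 bins versus ≈-2 at 20; the ≥15-frame rule guarantees at most one fragment
per cell and ≥14 min of duration, keeping centroid endpoint noise
(≈0.5 μm/axis) below 0.1 μm/min on the rate. The library-level defaults
(20 bins, ≥5 frames) remain available. Mixing cohorts acquired at different
frame intervals underestimates fast-cell rates; `stratify_by_thg` operates on
tracks of one cohort and per-group mixture fits are only attempted at ≥30
cells.

## SIMI

Voxels above a background threshold (default: Otsu on the channel-sum image)
are normalized to unit sum. Assignment maximizes cosine similarity to the
fingerprint set — scale-free, so per-voxel intensity does not influence the
label; Euclidean-on-normalized is exposed as an option; ties break in
fingerprint list order. In-situ fingerprint identification clusters the
normalized foreground with k-means (10 restarts, seeded) and returns
centroids labelled by dominant channel or by user-supplied names ordered by
cluster size. Mixed signals (e.g. "THG+GFP+ER") are their own fingerprints:
SIMI is a classifier; per-voxel abundances and linear unmixing are
non-goals.

## The phantom generator: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analysis chain
relies on, with defaults set to the study conditions:

| quantity | default | role |
|---|---|---|
| `l_e` cortex / marrow | 113 / 263 μm | layer attenuation at 1650 nm |
| excitation order n | 3 | signal ∝ (energy at focus)³ |
| z-adaptation anchors | (50 μm, 2.76 nJ), (488 μm, 108.64 nJ) | applied-energy law |
| plasma / B volumes | uniform in 500-4189 / 65-500 μm³ | class gates |
| granule-bearing plasma fraction | 0.344 | THG^hi phenotype |
| ER concordance | 0.931 | P(ER⁺ | granule-bearing) |
| motility mixture | w_fast 0.378; 0.96±0.38 / 0.21±0.12 μm/min | two-state rates, truncated at 0 |
| photobleaching k | 1.3×10⁻³ min⁻¹ | fluorophore channels only |
| noise | Poisson + read σ 2 + offset 100 counts | PMT model |

Cells are ellipsoids (axis ratio ≤ 1.5, shortest axis along z so cells fit
the thin imaging slab) with uniform cytoplasmic fluorophore intensity, a
1-voxel THG^lo membrane shell at 20% of granule brightness, and 3-8 granules
of 0.8-1.5 μm nominal diameter — below the axial voxel size, hence rendered
as single-voxel impulses at full granule brightness in distinct interior
voxels. Cell centres are rejection-sampled so that pairwise separation is at
least 0.95× the sum of volume-equivalent radii (cells are solid bodies;
interpenetrating cells would produce merged objects no segmenter could
split), with a 12 μm floor.

About 2% of extracellular voxels carry bright THG "structure" signal at
0.4-0.9× granule brightness, standing in for vessel walls, erythrocytes and
matrix interfaces. This tail is load-bearing: the top-1%-of-voxels THG^hi
rule only isolates granular signal because the upper intensity tail of real
marrow THG is dominated by such structures; without them the 99th percentile
would fall among membrane voxels and every cell would trivially classify
THG^hi.

The motion model is per-cell constant-rate drift along a fixed random
in-plane direction plus isotropic Gaussian jitter (σ 0.15 μm/frame). The
underlying study quantifies only summary displacement statistics, not the
step process, so the generator makes the conservative choice for which the
realized net-displacement/duration of *every* (sub-)track equals the drawn
rate by construction — no persistence calibration is needed and truncated
tracks remain unbiased. Consequences to keep in mind: cells may drift into
contact (transiently merged segmentations truncate both tracks) or out of
the field of view, as in real recordings, and the phantom cannot test
estimators that distinguish directed from diffusive motion. Cell-state
switching, vascular flow fields within the cell phantom, PSF blur beyond the
bead phantoms, optical aberrations and bone remodeling are not modelled.
Passing tests therefore validate the analysis chain's statistical recovery,
not the generator's biological fidelity.

Time-lapse phantoms multiply fluorophore (never harmonic-generation)
channels by `exp(-k·t)` and keep the extracellular THG structures static.

## Problem sizes

Validation and the acceptance script run at desk scale on one CPU:

* attenuation: 25 planes (dz 5 μm cortex-like, 12 μm marrow-like), 48×96
  planes, brightness 2×10⁴ counts, 20 seeds (~seconds);
* THG/ER: 11×334×334 voxels at (3, 1.2, 1.2) μm — a 33×400×400 μm volume —
  with 176 plasma + 60 B cells, 20 seeds (~1 min);
* motility: 11×250×250 voxels at (3, 1.6, 1.6) μm, 176 plasma cells, 21
  frames at 60 s (20 min of imaging), 20 seeds (~1-2 min);
* the `run_pipeline` default config matches the motility geometry and
  completes in well under a minute.

These sizes reproduce the field-of-view and cell-count scale of the
intravital recordings while keeping a full multi-seed validation in the
minutes range; recovered values are means over seeds, so they carry
Monte-Carlo error of ~2 points (motility weight) and below 1 point
(THG/ER percentages).

## Known limitations

* The attenuation fit inherits the small positive top-decile bias described
  above; use a brighter calibration region or a larger mask to suppress it.
* The double-Gaussian weight estimate scatters by ~8-10 points per realization
  at n ≈ 150-176 cells; single-run values should never be quoted without
  replication.
* `cortical_thickness` measures straight z-spans, not sphere-fitting local
  thickness, and so underestimates thickness where the cortex is strongly
  inclined.
* SIMI assigns exactly one label per voxel; genuinely fractional mixtures are
  represented only insofar as a mixed fingerprint exists for them.
* The segmentation is a faithful re-implementation of the documented
  parameter choices (7.5 μm seed diameter, local-contrast background
  subtraction), not a bit-for-bit reproduction of any commercial tool.
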