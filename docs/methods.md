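# Methods

`capiflow` implements, end to end, the analysis chain of eigen-decomposition
(ED) OCTA capillary velocimetry: a synthetic complex M-scan generator with
known ground truth, clutter filtering and Kasai mean-frequency (MF)
estimation, angiogram-based capillary segmentation, gamma-law transit-time
fitting (MTT/CTTH), and two-region group statistics. This note records the
model, the numerical choices, and what the synthetic data do and do not
emulate.

## Signal model

At each transverse position the scanner records `n_repeats` (default 50)
complex A-lines at interval `T` (default 50 µs, i.e. a 20 kHz M-scan rate and
a 10 kHz Nyquist Doppler frequency). The per-voxel repeat series is modelled
as

```
s[k] = A_c · e^{i(2π f_d T k + φ_c)}                 (static clutter)
     + A_b · g(kT) · e^{i(2π f T k + φ_b)} · 1{vessel}   (blood)
     + n[k],   n[k] ~ CN(0, σ²)                      (shot noise)
```

* **Clutter** — one dominant static-tissue component per voxel (random
  speckle phase `φ_c`, shared bulk-motion drift `f_d`, default 0 Hz,
  amplitude `A_c = 10`). An optional second clutter component (amplitude
  `second_clutter_amplitude`, default off) exists for stress-testing the
  adaptive rank selection.
* **Blood** — inside vessel voxels a Doppler tone at `f = v / c_cal` with the
  calibration slope `c_cal` (below), amplitude `A_b = 1`, multiplied by a
  real Gaussian decay `g(t) = exp(−t²/2t_dec²)` (default `t_dec` = 5 ms).
  The envelope gives the moving-scatterer signal a finite spectral bandwidth
  without modelling scatterer geometry; being real, it leaves the lag-one
  phase — and therefore the MF — unbiased.
* **Noise** — circularly symmetric complex Gaussian, the standard
  shot-noise-limited OCT approximation (default σ = 0.1, i.e. −40 dB vs
  clutter power and −20 dB vs blood amplitude).

The repeated-B-scan (angiography) volume uses the same three classes on a
slower frame axis (default 8 frames at 2.5 ms): static tissue repeats
identically, blood is modelled as an AR(1)-decorrelating speckle process, so
frame differences carry flow contrast. Aliasing is irrelevant on this axis —
the angiogram uses decorrelation magnitude, not phase.

## Capillary network and ground truth

Vessels are straight cylinders with random position and (transversely biased)
orientation, lengths 40–120 µm. Geometry is irrelevant to per-voxel
velocimetry statistics; only the velocity and diameter marginals matter.
Diameters are a mixture: 85 % capillaries uniform in 5–10 µm and 15 % wide
surface vessels in 18–30 µm, so the population straddles the 15 µm
segmentation cutoff the way a cortical field of view does. Each segment
carries a single speed `v = L/τ` with `τ ~ gamma(α, β)` and the uniform path
length `L = 400 µm`; the defaults `α = 3.127`, `β = 0.1318 s` are the values
implied by a resting activated-cortex bed with MTT = 0.412 s and
CTTH = 0.233 s through `α = (MTT/CTTH)²`, `β = CTTH²/MTT`.

Draws implying a speed beyond the Nyquist-mapped maximum are resampled from
the truncated law (the gamma tail always has some mass there); the truncated
count is recorded in the ground truth, and `strict_nyquist=True` turns the
condition into an error instead. At the default calibration the truncated
mass is ≈0.3 %, a negligible perturbation of the transit-time law.

The geometry stream and the transit-time stream are seeded independently, so
two specs sharing a seed produce the same network layout with different
flows. The experiment driver uses this for paired conditions (below).

## Velocity ↔ frequency calibration

The measured MF is linearly proportional to RBC speed in single-file
capillary passages; the constant is a system calibration. Simulator and
estimator share a single constant, `DEFAULT_CALIBRATION_SLOPE = 1e-3
(mm/s)/Hz`, chosen so the 10 kHz Nyquist limit maps to 10 mm/s and
physiological capillary speeds (~0.3–3 mm/s) sit far from aliasing. Because
both sides share the constant, velocity recovery tests are exact round trips.

## Eigen-decomposition velocimetry

Per transverse position, the repeat-by-repeat covariance is averaged over a
small axial block (default 5 voxels; a single voxel would give a degenerate
rank-1 estimate). Eigendecomposition splits the block signal into
components; each component's MF is the Kasai estimator — the phase of the
lag-one autocorrelation of its eigenvector, `|arg Σ v[k+1]·v*[k]| / 2πT` —
which is exact for pure phase ramps anywhere in (0, Nyquist). The absolute
value is reported: flow direction is not used downstream.

Clutter separation is two-stage:

1. **Volume-wide static regression.** The covariance of the whole volume is
   eigendecomposed and the leading run of components with MF below the
   static threshold (default 100 Hz) forms a bulk-static subspace that is
   regressed out of every voxel. Rationale: with only ~5 voxels per block the
   sample clutter eigenvector tilts toward any blood tone in the block
   (finite-sample cross-covariance), leaking static power into the retained
   components; estimated over tens of thousands of voxels with independent
   speckle phases the cross terms average out and the static subspace is
   clean. Physically this is bulk tissue motion, which is global.
2. **Per-block adaptive classification.** On the residual, components are
   classified in descending-eigenvalue order: the leading run with MF below
   the threshold is clutter (rank adapts per block, 0 permitted — e.g. a
   50 Hz bulk drift is still caught); of the rest, components are retained as
   blood if they carry at least `power_floor` (default 5 %) of the
   post-clutter residual power **and** their eigenvector has lag-one phase
   coherence ≥ 0.5. The coherence gate is the load-bearing discriminator
   against noise: with ~5-sample covariances noise eigenvalues are large, but
   noise eigenvectors are phase-incoherent (coherence ~ n^−1/2 ≈ 0.14) while
   blood eigenvectors ride a coherent ramp (≈1). The power floor is defined
   on post-clutter residual power because clutter dominates total power by
   ~20 dB by construction; a total-power floor would reject all blood.

Per voxel, the MF is the Kasai estimate of the voxel's own clutter-nulled
series. Autocorrelating the filtered signal rather than averaging component
MFs keeps each voxel's tone exact even when two vessels closer than the
spectral resolution 1/(n_repeats·T) = 400 Hz share a block and their
eigencomponents mix. Nulling the static subspace removes part of a
low-Doppler tone and biases its Kasai phase; since the nulled subspace is
shared volume-wide, the measured frequency of a nulled tone is a
deterministic monotone map `m(f)`, which is inverted through a 4096-point
lookup table. A voxel enters the valid mask when the block retained blood
components and the voxel's blood-subspace power clears (a) the relative
floor against its residual power, (b) `snr_mult` (default 10) times its own
per-degree-of-freedom noise estimate, and (c) an absolute sensitivity floor
of `min_blood_fraction` (default 1e-4, −40 dB) of its unfiltered power — the
clutter-rejection limit that keeps the rule specific even at zero noise.
Blocks whose post-regression residual sits at the volume's noise floor
(below 2× the median block residual) are skipped outright; this is purely an
optimization, as nothing in them can pass the validity tests.

Velocity is `v = c_cal · MF` on valid voxels. On the standard fixtures the
estimator recovers ≥ 99 % of vessel voxels within 1 % of the true Doppler
frequency in the noise-free case, with static-voxel leakage ≈ 0 at default
thresholds.

## Angiography and segmentation

The angiogram is the mean magnitude of successive complex frame differences.
En-face projections (maximum or average) cover a stated depth slab, default
0–300 µm from the cortical surface, with optional half-open 100 µm colour
bands [0,100), [100,200), [200,300). Vessel support is thresholded by Otsu's
method on the **log** intensity histogram (angiogram intensities are
heavy-tailed; a linear-domain split lands inside the minority vessel class);
mask or threshold can be supplied instead. Per-pixel diameter is estimated in
the 2-D en-face plane (matching surface-vessel removal) by medial-axis local
thickness: each vessel pixel takes `(2r − 1)` pixels from its nearest
skeleton point, where `r` is the skeleton's Euclidean distance to background
— the −1 accounts for the EDT measuring centre-to-background-centre, half a
pixel beyond each wall. The estimate is within one 7.5 µm pixel on synthetic
cylinders from 7.5–40 µm. The capillary mask keeps vessel pixels with
diameter ≤ 15 µm.

## Transit times and the gamma law

Valid capillary speeds convert to transit times `τ = L/v` with the uniform
path length `L = 400 µm` (so 1 mm/s ↔ 0.4 s). τ values above the 99.5th
percentile are excluded from the histogram range (a handful of near-zero
velocities would otherwise stretch the support); the exclusion count is
logged. The default binning is Freedman–Diaconis on [0, q99.5]. The density
histogram is fitted by bounded nonlinear least squares with the model
`A · h(τ; α, β)`, `h` the two-parameter gamma density; the explicit amplitude
`A` makes the α, β estimates invariant to the counts-vs-density convention
(A ≈ 1 for a normalized histogram). Initialization is method-of-moments
(α₀ = mean²/var, β₀ = var/mean), bounds (10⁻³, 10³); a fit pinned at a bound
is flagged, non-convergence raises carrying the initializer. Reported:
MTT = αβ, CTTH = √α·β (hence MTT/CTTH ≡ √α identically), and R² of the curve
against the histogram at bin centers. Maximum-likelihood fitting on the raw
samples is available as an independent cross-check (`fit_gamma_mle`); the
two agree to a few percent on well-sampled data.

Histogram differentiation (stimulation − rest density per bin, after
piecewise-constant rebinning onto a common grid if needed) reports every
sign change plus a dominant switch — the bin edge where the cumulative
difference mass is extremal, i.e. the boundary between the gained-short-τ
and lost-long-τ regions.

## Group statistics

Per animal, region and condition the records carry MTV (mean of the valid
capillary speeds), MTT and CTTH (from the gamma fit). Relative changes are
`Δx = 100·(x_stim − x_rest)/x_rest`. Between regions, per-animal Δ values are
compared by a classical pooled-variance two-tailed t-test (Welch by flag);
degenerate identical groups return t = 0, p = 1 rather than dividing by
zero. Significance is annotated at 0.05 (*) and 0.01 (**). No
multiple-testing correction is applied across the three parameters, matching
the source analysis; with three tests the family-wise error is accordingly
higher.

## The synthetic experiment

`run_experiment` emulates a 12-animal, two-region (activated vs control),
two-condition (rest vs stimulation) design. Per-animal variability is
injected on (MTT, CTTH): resting values are drawn around the group means
(default std 0.05 s / 0.025 s), each animal applies the group's rest→stim
ratio with optional per-animal noise on the relative change (defaults
0.022 / 0.014, the scale of the reported per-animal spreads), and (α, β)
follow by moment inversion.

Two modelling choices matter for desk-scale recovery:

* **Paired conditions.** Both conditions of an animal image the *same*
  network: the stimulation transit times are the rest draws quantile-mapped
  from the rest gamma law to the stimulation law. This mirrors the
  experiment — the vasculature does not change, flow redistributes within
  it — and removes segment-sampling noise (≈ CTTH/√n_segments per fit,
  which would otherwise swamp few-percent effects at any affordable
  n_segments) from the within-animal change.
* **Shared segmentation mask.** The capillary mask is computed once per
  animal-region (from the resting scan) and reused for stimulation, again
  because the vasculature is unchanged; re-segmenting would randomly swap a
  few percent of capillaries in and out of the sample between conditions.

Default desk-scale geometry is 96 × 96 transverse positions × 32 depths with
200 segments per volume (a 12-animal experiment runs in minutes; the paper-
scale 200 × 100 × 40 protocol remains available and is exercised by a test
that recovers > 20,000 MF estimates from a dense bed). Each condition is
simulated as stationary; the within-scan nonstationarity of a stimulus
delivered during acquisition is not modelled. Full provenance (config,
seeds) is attached to every result object.

## What the synthetic data do not emulate

Optical beam propagation, speckle statistics of real tissue, multiple-
scattering attenuation below 300 µm, partial-volume effects at vessel
boundaries, vessel tortuosity and branching, within-scan flow dynamics, and
the physiological dependence of the MF↔velocity slope on RBC shape and
hematocrit. Passing tests therefore demonstrate the correctness and
statistical behaviour of the analysis chain under its stated signal model,
not the hardware-level performance of a real scanner.

## Known limitations

* Velocities at or above the Nyquist-mapped maximum are truncated by the
  generator and would alias in the estimator; phase unwrapping is out of
  scope.
* The gamma fit's per-animal CTTH has a few-percent sampling error at
  desk-scale segment counts; group comparisons inherit it.
* Bandwidth-frequency (temporal-heterogeneity) analysis is not implemented.
* The diameter estimator works in the en-face projection; overlapping
  vessels merge and are conservatively excluded by the cutoff.
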