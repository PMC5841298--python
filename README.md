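# capiflow

Eigen-decomposition OCTA capillary velocimetry and capillary transit-time
heterogeneity (CTTH) analysis, with a synthetic M-scan simulator for
validation.

## The problem

During functional activation the brain's blood flow rises more than its
oxygen consumption. Transit-time modelling explains part of the puzzle:
oxygen extraction depends not only on the mean transit time (MTT) of red
blood cells through the capillary bed but also on the *heterogeneity* of
those transit times (CTTH) — and activation is accompanied by capillary flow
homogenization, a CTTH reduction localized to the activated cortex.
Measuring that requires velocity estimates in thousands of individual
capillaries, which OCT angiography (OCTA) velocimetry delivers: at each
position a burst of 50 repeated A-lines (an M-scan, 50 µs apart) samples the
complex backscattered field, and statistics of that repeat series separate
moving red blood cells from the ~100×-stronger static tissue signal.

`capiflow` implements the full analysis chain as a Python library:

1. **octsim** — synthetic 4-D complex M-scan ensembles (repeat × z × x × y)
   over a capillary network with ground-truth velocities drawn from a gamma
   transit-time law, `v = L/τ`, `τ ~ Γ(α, β)`;
2. **edvel** — clutter filtering in the eigenbasis of the repeat-covariance
   matrix, per-component mean frequency (MF) by the Kasai lag-one
   autocorrelation estimator, and the linear MF → velocity map;
3. **angio** — OMAG-style frame-difference angiograms, depth-coded en-face
   projections, and medial-axis diameter estimation to remove vessels wider
   than 15 µm before capillary statistics;
4. **transit** — τ = L/v conversion (L = 400 µm), normalized histograms,
   nonlinear least-squares fit of the gamma density
   `h(τ; α, β) = τ^(α−1) e^(−τ/β) / (β^α Γ(α))`,
   with MTT = αβ, CTTH = √α·β, and rest-vs-stimulation histogram
   differentiation;
5. **groupstats** — per-animal relative changes
   Δx = 100·(x_stim − x_rest)/x_rest and two-tailed Student t-tests between
   an activated and a control region;
6. **pipeline** — the multi-animal synthetic experiment driver tying it all
   together.

See `docs/methods.md` for the signal model, estimator details and the
design decisions.

## Worked example

`examples/` contains one short script per capability. The core round trip —
simulate a volume, run the eigen filter, map MF back to velocity
(`examples/02_eigen_velocimetry.py`):

```text
865 voxels passed the blood-signal validity test (865 true vessel voxels, 0 static leaks)
median velocity error 0.34% (clutter is 10x stronger than blood)
recovered speeds 0.44-9.77 mm/s
```

Every true vessel voxel is detected, no static voxel leaks through the
filter, and the recovered speeds match the ground truth to a fraction of a
percent despite the 20 dB clutter-to-blood power ratio.

Fitting the gamma transit-time law at the resting operating point of the
activated cortex (`examples/04_transit_time_fit.py`):

```text
rest: alpha=3.133 beta=0.1324 -> MTT=0.415 s CTTH=0.234 s R^2=0.9970
(generating values: MTT=0.412 s, CTTH=0.233 s)
histogram differentiation (stim - rest) switches sign at tau = 0.324 s
```

From 20,000 transit times the fit recovers MTT and CTTH to well under a
percent with R² ≈ 0.997; the differentiation shows stimulation shifting
probability mass from long to short transit times, switching sign near
τ ≈ 0.32 s.

Between-region statistics at published effect sizes
(`examples/05_group_comparison.py`):

```text
dCTTH activated: -5.87 +- 1.03 %
dCTTH control:   -1.22 +- 1.39 %
t = -9.29, p = 4.54e-09 (**)
```

A ~5-point difference in CTTH reduction at 1.4-point spread with 12 animals
per region is overwhelmingly significant — the homogenization is local to
the activated cortex.

`examples/06_full_experiment.py` runs the complete chain (simulate →
velocimetry → segmentation → gamma fit → t-tests) over several animals and
recovers an injected −10.9 % MTT reduction to within ~1 point.

## Command line

A thin CLI wraps the library:

```sh
capiflow simulate   --config sim.yaml --out volume.h5 --seed 1
capiflow velocimetry --in volume.h5 --static-threshold 100
capiflow angio      --in volume.h5 --cutoff-um 15 --slab-um 300
capiflow transit    --in volume.h5 --l-um 400 --csv fit.csv
capiflow compare    --records records.csv --param ctth
capiflow run        --config experiment.yaml --out results/
```

All volumes travel in a single HDF5 container (ensemble, ground truth,
protocol attributes, derived results under `results/`).

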