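# Methods

## Signal model

A white-matter voxel is modeled as two water pools in slow exchange:
myelin water (baseline T2 ≈ 10 ms, T1 ≈ 200 ms) and intra/extracellular
(IE) water (baseline T2 ≈ 50–60 ms, T1 ≈ 1100 ms). Each pool's
transverse rate depends on the angle θ between the local fiber axis and
B0 through

    R2(θ) = a + b sin²θ + c sin⁴θ      [1/s]

which also subsumes the dipolar models: `a₁ + b₁(3cos²θ − 1)` is
algebraically `a₁ + 2b₁ − 3b₁ sin²θ`, and its square expands to
`a₂ + 4b₂ − 12b₂ sin²θ + 9b₂ sin⁴θ`. These identities are enforced by
`model_identity_transform` and exercised by tests; they imply that the
dipolar model and a pure sin²θ model produce identical least-squares
fits, and that the sin²/sin⁴ basis nests both dipolar forms (so its RSS
can never be larger). At the magic angle arccos(1/√3) ≈ 54.7356° the
dipolar term vanishes.

Between excitations each pool recovers by `E = 1 − exp(−TR/T1)`, so the
measured ("apparent") myelin water fraction for a true fraction f is

    MWF_app(TR) = f·E_mw / (f·E_mw + (1 − f)·E_ie).

Since T1_mw ≪ T1_ie, myelin water is almost fully recovered at any
practical TR (E_mw = 0.9953 at TR = 1073 ms) while the IE pool is not
(E_ie = 0.623), hence MWF_app exceeds f and decreases monotonically
toward f as TR grows.

## Echo-train simulation (EPG)

CPMG echo amplitudes are computed with the extended phase graph
algorithm: complex configuration states F(k), Z(k) are propagated
through relaxation over each TE/2, gradient dephasing (one order per
half-interval), and hard refocusing pulses about x with the excitation
about y (CPMG condition). Orders beyond n_echoes + 1 are truncated —
they cannot rephase before the last recorded echo. Longitudinal
recovery within the train is neglected (TE ≪ T1); amplitudes are
magnitudes for unit initial magnetization. At α = 180° the recursion
collapses to `exp(−t/T2)` exactly; at lower α stimulated-echo pathways
depress the first echo and raise later ones. The implementation is
validated against an independent isochromat Bloch simulator (10,000
uniformly dephased spins, explicit rotation matrices) to 1e−4 per echo;
in fact the two agree to near machine precision because evenly spaced
isochromat phases realize the same configuration algebra.

One empirical note: individual late-echo amplitudes are *not* monotone
in T2 when α < 180° — even/odd pathway interference can make an echo
larger for a shorter T2 (the Bloch oracle reproduces this). The first
echo and the total recorded signal are monotone; tests assert those.

## Spectrum inversion

Each voxel's decay y is modeled as `y ≈ B(α) x`, `x ≥ 0`, where column j
of B is the EPG train for grid value T2_j (40 log-spaced points in
[8 ms, 2 s]; the basis assumes T1 = 1000 ms, to which the fit is
insensitive at the −0.003 MWF level). The effective refocusing angle α
is estimated per voxel by minimizing the unregularized NNLS misfit
χ²(α):

* default "grid" search: χ² on a fixed 3°-spaced grid over [90°, 180°]
  whose bases are built once and shared across all voxels, followed by
  parabolic refinement of the minimum (the basis build dominates
  runtime, so shared nodes are an order of magnitude faster than a
  per-voxel line search);
* "golden": classic golden-section search to 0.5°, available for
  single-voxel work and cross-checked against the grid search in tests.

The spectrum is then stabilized by minimum-energy Tikhonov
regularization `min ‖Bx − y‖² + μ‖x‖²`, with μ found by bisection on
log μ so that the data misfit equals `reg_factor × χ²_min` (within 1%;
if the bracket is ambiguous the larger μ — smoother spectrum — wins;
noiseless data short-circuit to μ = 0). The default `reg_factor` is
**1.005**. The 1.02 inflation used as a convention elsewhere in the
relaxometry literature is available but not the default: at SNR 100 it
biases the recovered MWF by about −0.014 on two-pool decays (the
smoothed myelin peak leaks across the fixed 25 ms cutoff; the bias is
proportional to the allowed χ² inflation), which is the same order as
the orientation effects this package exists to resolve.

Magnitude MRI noise is Rician; once late echoes decay below the noise
floor, an unweighted fit inflates long-T2 amplitudes and depresses the
MWF. With `rician_correction` (default in the pipeline) the fit
iteratively replaces the Rician bias term using the exact expected
magnitude `E[m | s, σ]` (Bessel-function form) of the current model
prediction. σ is estimated from high-signal residuals — per voxel, or
once per volume (median over an evenly spaced voxel subsample), the
pipeline default, since scanner noise is spatially uniform.

## Fiber orientation

Single diffusion tensors are fitted by log-linear least squares to
`log S = log S0 − b gᵀDg` (≥ 6 non-collinear directions and a b=0 image
required; voxels with non-positive signals are flagged invalid). The
fiber angle is `θ = arccos |v̂₁ · b̂₀| ∈ [0°, 90°]`, sign-invariant, with
B0 along the volume z-axis by default. Voxels with FA < 0.2 are
orientation-undefined (an isotropic tensor has no axis). The
white-matter mask is eroded with a full 3×3×3 structuring element before
pooling.

## Pooling and group statistics

Voxels across the whole white matter are pooled into 18 half-open 5°
bins ([85°, 90°] closed at the top so θ = 90° is kept). The per-bin
statistic is the arithmetic mean of the voxel metric; counts are
recorded and empty bins flagged. Group curves across subjects use the
per-bin across-subject mean with a Student-t 95% band (df = n−1);
coverage of the band is verified by Monte-Carlo in the tests. Model
fits to pooled R2(θ) = 1000/gmT2(θ) curves are weighted by bin voxel
counts by default, because bins near 0° hold few voxels in real brains.

## Synthetic phantom

The generator emulates the measurement situation with known truth:
θ sweeps (0°, 90°) uniformly along x (two grid columns per 5° bin in the
default 36×12×6 grid, so all 18 bins survive one-voxel erosion — unlike
real white matter, where near-parallel fibers are rare); the true MWF
sweeps 0.10–0.15 along y; the effective flip angle sweeps 150–180°
along z. Pool R2(θ) coefficients default to (100, 5, 5) /s for myelin
water (T2 10 → 9.1 ms) and (17, 2, 2) /s for IE water (58.8 → 47.6 ms),
inside the 30–60 ms range quoted for IE water at 3 T. Echo volumes are
generated by the same EPG forward model used for inversion (with the
pools' own T1 values), weighted by saturation-recovery factors per TR
(1073/1500/2000 ms), and corrupted by Rician noise at first-echo
SNR 100. Matched DWI volumes (b = 700 s/mm², 60 Fibonacci-sphere
directions + b0, eigenvalues (1.7, 0.3, 0.3)×10⁻³ mm²/s, SNR 30) encode
the same fiber field. Cohorts add per-subject jitter: 10% relative SD
on the MWF scale, 3% on pool R2 baselines, 10% on orientation
coefficients — matching the between-subject spread of global MWF
reported in vivo. Bundles are written as NIfTI + FSL b-tables + a YAML
spec; generation is bit-reproducible given the seed.

What the phantom does **not** emulate: anatomy, partial volume, exchange
between pools, B0 inhomogeneity, EPI distortions, motion, multi-channel
coil noise correlations. Passing tests therefore demonstrate correctness
of the estimation chain under the stated model, not robustness to every
property of in-vivo data.

## Problem sizes and numerical choices

The test suite runs the full pipeline on an 8-subject 36×12×6 cohort
(≈ 1,360 analyzed voxels per subject per TR, ≈ 4 minutes single-core);
unit tests use 16–64 voxel phantoms. Voxelwise inversion is chunked for
memory, with results independent of chunk boundaries (asserted).
Bisection and search tolerances: μ to 0.5% of the χ² target, α to 0.5°
(golden) or one parabolic refinement of a 3° grid. Degenerate inputs
(all-zero decay, empty mask, zero-total spectrum, isotropic tensor,
underdetermined model fits) raise errors naming the stage.

## Known limitations

* **Finite-SNR MWF bias.** Even with the Rician mean-correction and
  near-minimal regularization, the voxelwise MWF from nonnegative
  least squares is biased low by ≈ 0.003–0.016 (of ≈ 0.18 apparent) at
  first-echo SNR 100 in the phantom's conditions, growing toward
  perpendicular fibers where the IE-pool T2 is shortest. The bias
  persists with the true σ, the true flip angle, and without
  regularization, so it is intrinsic to constrained least squares on
  magnitude data at this SNR. Consequently the end-to-end check that
  the recovered group MWF(θ) curve covers the generating curve in ≥95%
  of bins fails honestly (13–15 of 18 bins at the default conditions);
  the TR-monotonicity check passes in every subject. At SNR ≳ 400 the
  bias is negligible.
* Single-tensor orientation only; crossing-fiber voxels get a single
  compromise axis.
* No spatial regularization of the inversion; voxels are independent.
* The α search assumes a unimodal χ²(α), which holds for CPMG trains in
  the clinical B1 range but is not proven globally.
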