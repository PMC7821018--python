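# mworient

Orientation dependence of myelin water imaging (MWI) from multi-echo
spin-echo MRI.

White-matter voxels show a multi-exponential T2 decay: water trapped
between myelin bilayers relaxes fast (T2 ≈ 10 ms at 3 T) while
intra/extracellular (IE) water relaxes slowly (T2 ≈ 30–60 ms).
Inverting a 48-echo CPMG decay into a nonnegative T2 spectrum and
integrating the short-T2 peak yields the **myelin water fraction**

    MWF = ∫₈ᵐˢ²⁵ᵐˢ S(T2) dT2 / ∫₈ᵐˢ²ˢ S(T2) dT2 ,

a widely used in-vivo myelin proxy. The *apparent* MWF, however, is not
a pure tissue property: it varies systematically with the angle θ
between the local fiber direction (the principal eigenvector of the
diffusion tensor) and the main field B0, and with the sequence TR
through the different T1 values of the two pools (T1 ≈ 200 ms for
myelin water vs ≈ 1100 ms for white matter overall). `mworient` is a
library + CLI for quantifying both effects, for researchers working on
quantitative MRI of myelin:

* **epg** — extended-phase-graph simulation of CPMG echo trains with
  imperfect refocusing pulses (stimulated echoes);
* **nnls** — voxelwise T2 spectrum inversion: Tikhonov-regularized NNLS
  over an EPG basis with joint estimation of the effective refocusing
  flip angle α, optional Rician noise-floor correction
  (`T2SpectrumNNLS`, a scikit-learn-style transformer);
* **pools** — pool partitioning at the 25 ms cutoff: apparent MWF,
  per-pool geometric-mean T2/R2, cumulative spectra;
* **dti** — log-linear diffusion tensor fit, fiber-to-B0 angle maps,
  white-matter mask erosion (3×3×3);
* **pooling** — whole-white-matter pooling into 18 × 5° fiber-angle bins
  and group curves with 95% t-confidence bands;
* **models** — the three orientation models of white-matter R2(θ),

      R2(θ) = a₁ + b₁ (3cos²θ − 1)          (dipolar)
      R2(θ) = a₂ + b₂ (3cos²θ − 1)²         (squared dipolar)
      R2(θ) = a₃ + b₃ sin²θ + c₃ sin⁴θ      (susceptibility/diffusion)

  fitted as exact weighted linear least squares, their algebraic
  identities (the dipolar model equals a + 2b − 3b sin²θ; the squared
  model equals a + 4b − 12b sin²θ + 9b sin⁴θ), the magic angle
  (arccos(1/√3) ≈ 54.7°), and the TR/T1 attenuation model
  `apparent MWF = f·E_mw / (f·E_mw + (1−f)·E_ie)`, `E = 1 − exp(−TR/T1)`;
* **phantom** — a fully ground-truthed synthetic generator: co-registered
  multi-echo CPMG volumes (orientation-dependent two-pool relaxation,
  TR-dependent T1 weighting, flip-angle field, Rician noise) plus
  matched DWI with FSL-style b-tables;
* **pipeline / cli** — an end-to-end driver (`mworient`) with
  subcommands `simulate`, `fit-t2`, `orient`, `pool`, `fit-models`, `all`.

## Worked example

Simulate a 2-subject phantom cohort and run the full pipeline:

```sh
mworient all --out demo_out --subjects 2 --seed 7 --shape 18,4,4
```

prints

```
pipeline complete; global mean MWF by TR: {'1073': 0.18292393931795775,
 '1500': 0.15666049157363532, '2000': 0.14956627537776507}
```

The global white-matter apparent MWF decreases monotonically as TR grows
from 1073 ms to 2000 ms — at short TR the slow-relaxing IE pool is
attenuated by its long T1, inflating the measured myelin fraction; the
same mechanism acting on the published global means (0.079 at
TR = 1073 ms) predicts 0.060 at TR = 2000 ms, within a few percent of
the published 0.062:

```python
>>> from mworient import true_mwf_from_apparent, apparent_mwf_vs_tr, TrAttenuationParams
>>> f = true_mwf_from_apparent(0.079, 1073.0)   # underlying fraction
>>> round(f, 4)
0.051
>>> round(apparent_mwf_vs_tr(TrAttenuationParams(true_mwf=f), 2000.0), 4)
0.0602
```

`demo_out/` contains per-subject NIfTI maps (`mwf_tr1073.nii.gz`,
`alpha_deg_tr1073.nii.gz`, pool T2 maps, θ map, eroded mask), per-voxel
spectra (`spectra_tr*.npz` with the T2 grid), angle curves and
orientation-model fit tables (CSV, each stamped with the configuration
hash), and `report.json`.

The equivalent library route:

```python
from mworient import PhantomSpec, PipelineConfig, simulate_cohort
from mworient.pipeline import analyze_subject, analyze_cohort, fit_models_to_curves

cohort = simulate_cohort(PhantomSpec(), n_subjects=8, seed=42)
results = [analyze_subject(ds, PipelineConfig()) for ds in cohort]
group = analyze_cohort(results)                # 95% CI curves per TR
fits = fit_models_to_curves(group[1073.0])     # all five R2(theta) models
```

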