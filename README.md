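# decidemri

Quantitative placental diffusion–relaxation MRI in Python: a three-compartment
forward signal model jointly sensitive to diffusion weighting (b) and echo
time (TE), with

- **fast linearized fitting** (variable-projection nonnegative least squares)
  used to synthesize per-volume model targets,
- **model-driven registration (MDR)** — iterative motion correction that
  registers every acquired volume to its own synthetic target, so no
  cross-contrast registration is ever needed,
- **constrained nonlinear least-squares fitting** (Levenberg–Marquardt in
  transformed coordinates, so the box constraints hold by construction),
- **Bayesian shrinkage-prior (BSP) estimation** — a hierarchical model in
  which every ROI voxel's transformed parameters are drawn from a shared
  multivariate Gaussian, fitted by Metropolis-within-Gibbs MCMC with the
  baseline amplitude profiled out and the noise level marginalized,
- **seeded synthetic phantoms** (smooth parameter fields, Gaussian/Rician
  noise, calibrated smooth motion), so the entire pipeline is testable
  without clinical data.

## Model

```
S(b, TE) = S0 [ f e^{-b d* - TE r2fb}
              + (1-f) e^{-b d} ( v e^{-TE r2mb} + (1-v) e^{-TE r2t} ) ]
```

Five free parameters per voxel (plus S0): rapid-perfusing volume fraction
`f`, diffusivity `d` (mm²/s), pseudo-diffusivity `d*` (mm²/s), fetal-blood
T2 `t2fb` (ms, with `r2fb = 1/t2fb`), slow-perfusing volume fraction `v`.
Maternal-blood and tissue relaxation rates default to (240 ms)⁻¹ and
(46 ms)⁻¹.

Units are fixed package-wide: b in s/mm², TE in ms, diffusivities in mm²/s,
relaxation rates in ms⁻¹ (the product `b·d` mixes s- and ms-based units by
convention, exactly as the parameter values above imply).

Two modelling conventions are fixed deliberately:

- the tissue compartment carries the same `e^{-b d}` attenuation as the
  maternal-blood compartment (consistent with the linearized amplitudes
  `λ1 = S0 f`, `λ2 = S0(1-f)v`, `λ3 = S0(1-f)(1-v)`);
- the inverse amplitude map uses `S0 = λ1 + λ2 + λ3`, the unique value
  consistent with those definitions.

The optional saturation map uses a quadratic blood-relaxometry calibration
`1/T2 = A + K(1-FO2)²` with documented, overridable constants and is only
emitted when explicitly requested.

## Command line

```sh
decide simulate --spec phantom.json --snr 50 --motion --seed 3 --out phantom/
decide fit-lls  --series s.nii.gz --mask roi.nii.gz --protocol p.csv --out out/
decide fit-nls  --series s.nii.gz --mask roi.nii.gz --protocol p.csv --out out/ [--smooth-sigma 1.0] [--fo2]
decide fit-bsp  --series s.nii.gz --mask roi.nii.gz --protocol p.csv --out out/ [--n-burn 2000 --n-keep 3000]
decide mdr      --series s.nii.gz --mask roi.nii.gz --protocol p.csv --out out/ [--iterations 3] [--spacings 10,5,2.5]
decide evaluate --table subjects.csv --out trends.json
```

Volumes are NIfTI-1; protocols are CSV (`index,b_s_per_mm2,te_ms`); every
run writes a JSON provenance record (version, seed, config hash).

The default protocol (`build_protocol("decide_default")`) pairs seven
b-values (0–600 s/mm²) with ten echo times (81–300 ms): all TEs at b=0, all
b-values at TE=96 ms, plus two intermediate shells across seven TEs — 31
settings as acquired, 28 unique with `dedup=True`; extra repeats can be
declared explicitly.

## Layout

| module | contents |
| --- | --- |
| `decidemri.protocol` | acquisition protocol type, presets, CSV I/O |
| `decidemri.model` | forward model, constants, amplitude/physiology maps, FO2 calibration |
| `decidemri.linear_fit` | design matrix, NNLS fits, d grid search, target synthesis |
| `decidemri.nonlinear_fit` | constrained multi-start LM fitting (voxel/ROI/volume) |
| `decidemri.bsp_fit` | shrinkage-prior MCMC (likelihood, conjugate updates, sampler) |
| `decidemri.registration` | B-spline FFD backend, warping, field composition |
| `decidemri.mdr_pipeline` | the fit–synthesize–register loop and NRMSE |
| `decidemri.synthetic_data` | phantoms, noisy series, simulated motion |
| `decidemri.evaluation` | relative error, ROI summaries, age-trend regression |
| `decidemri.io` / `decidemri.cli` | NIfTI/CSV/JSON I/O and the `decide` CLI |
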