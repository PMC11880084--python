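# Methods

## Problem

Dynamic Rb-82 cardiac PET reconstructs the first pass of an activity bolus
into a coarse frame grid (10 s early frames by vendor default). The
cardiopulmonary transit time (CPTT) — LV-peak minus RV-peak time of the
two cavity time–activity curves — is therefore observed only after heavy
discretization, and the package treats CPTT estimation explicitly as a
discretization problem: what the estimator can resolve, when it must
impute, and how the downstream cohort statistics behave.

## Transit-time estimator

**First-pass isolation.** The window runs from curve onset (first frame
exceeding 10 % of the global maximum) to the first local minimum after the
global maximum, which cuts off recirculation. Both thresholds are exposed
(`onset_fraction`; the minimum rule is structural). A flat, all-zero or
monotone curve raises `NoPeakError` rather than returning a guess; a
maximum on the final frame is treated the same way because the first pass
was evidently not covered.

**Peak time.** The midpoint of the maximal frame inside the window. Absent
sub-frame information a frame's counts are best summarized by its
midpoint; parabolic or centroid sub-frame interpolation is deliberately
not the default (a centroid mode exists, labelled, for sensitivity
analyses). Tied maxima resolve to the earliest frame and set
`ambiguous_peak`.

**Imputation.** Raw peak-to-peak differences on uniform frames of width
*w* are multiples of *w* (a property test asserts this). A raw 0 s is
impossible — it corresponds to a true transit in (0, 5) s on 10 s frames —
and is replaced by the interval midpoint 2.5 s, with `imputed=True`. The
2.5 s constant is applied for any schedule rather than generalized to
*w*/4, keeping the clinical convention fixed; a negative raw difference
raises `PeakOrderError` (venous bolus cannot reach the LV first; almost
always swapped VOI labels).

**Normalization.** NCPTT = CPTT / RR with RR = 60/HR, using the
scan-concurrent heart rate (rest HR for rest acquisitions, stress HR for
stress). NCPTT is invariant to the SUV scale, so the body-weight SUV
convention (1 g/mL density) adopted for curve extraction cannot affect
transit estimates.

## Bolus simulator

The RV curve is a normalized gamma-variate
`A·((t−t0)/(αβ))^α · exp(α − (t−t0)/β)` — zero before onset, analytic
mode at `t0 + αβ` where the value is exactly `A`. Defaults
(`t0 = 15 s, A = 40 SUV, α = 3, β = 2.5 s`) give a bolus peaking 7.5 s
after onset with ~4.3 s width, consistent with a high-flow (30 mL/min)
infusion protocol. The LV curve is the RV curve convolved with a gamma
lung kernel parameterized by mean = `transit_delay` and sd = `dispersion`;
at `dispersion = 0` this degenerates to a pure shift, which keeps the true
CPTT well-defined as the continuous peak separation — the simulator's
ground truth. An optional recirculation tail adds
`recirculation_fraction` times a delayed (30 s), broadened (10 s) copy of
the LV first pass.

Frame values are **time-averages** (adaptive quadrature of the continuous
curve over each frame divided by its duration, absolute tolerance 1e-10);
midpoint evaluation was rejected because reconstructed frames aggregate
counts over their full duration. A fixed Gauss–Legendre rule was also
rejected: the bolus onset is a kink that fixed rules resolve only to
~1e-5, short of the 1e-6 integral-conservation tolerance the tests
enforce. Noise is additive Gaussian on the frame SUV_mean (averaging over
a ~1 cm³ VOI justifies Gaussianity), clipped at zero; per-voxel Gaussian
or scaled-Poisson noise is available only in phantom rendering, where the
central-limit averaging argument does not yet apply.

## Cohort simulator

Each patient draws CPTT and HR (rest and stress) from lower-truncated
normals (CPTT > 0 s, HR > 30 bpm). The parent parameters are
moment-matched numerically so the **truncated** distribution has exactly
the stated mean and sd — otherwise the CPTT_rest calibration target of
9.2 ± 4.2 s would drift by ~0.16 s from truncation alone. NCPTT is then
computed per patient as CPTT·HR/60, i.e. the normalization is mechanistic,
not drawn; rest and stress transits are parameterized independently
because no coupling model between them is established.

EF_Echo follows `64.41 − 0.77·NCPTT_rest + ε`, `ε ~ N(0, 8.24²)`, clipped
to [10, 80] %. The intercept places the line through the cohort means
(56.4 % at NCPTT 10.4); the residual sd is derived so the marginal EF_Echo
sd matches 9 %: `8.24 = sqrt(9² − 0.77²·4.7²)`. EF_PET mixes the
standardized EF_Echo with independent noise so that corr(EF_PET, EF_Echo)
≈ 0.4 while the EF_PET marginal stays at 51.5 ± 13.5 % — a pure additive
measurement error could match the correlation or the marginal sd, but not
both. TAPSE (22.8 ± 4.5 mm) and E/A (0.9 ± 0.5) are truncated normals;
they enter only descriptively. Missingness is applied completely at
random at fractions 6/44, 15/44 and 20/44 (EF_Echo, TAPSE, E/A).

What a green test does *not* establish: real curves carry reconstruction
artifacts, VOI placement error, decay and spill-over that the phantom does
not model, and real missingness is unlikely to be MCAR. The simulator
validates the estimator and the statistical machinery, not the clinical
measurement chain.

## Statistics

Univariate OLS (statsmodels) with t-based 95 % CIs (n − 2 df) and
two-sided p for the slope; complete-case per analysis, with drop counts
reported — per-parameter completeness differs, so each analysis uses its
own subset, and predictors being *compared* are restricted to their shared
complete-case subset. Residual diagnostics (Shapiro–Wilk normality,
Breusch–Pagan homoscedasticity) stand in for simulation-based residual
checking; for simple OLS they address the same assumptions, and they are
reported, never used to auto-reject a fit.

LOOCV-RMSE is computed by explicit leave-one-out refits; the hat-matrix
closed form `sqrt(mean((e_i/(1−h_ii))²))` is kept as an independent
cross-check and the suite asserts agreement to 1e-10. No multivariable
model selection is implemented: only the univariate fits are specified
well enough to reproduce.

## Reproducibility

A pipeline run is keyed by one master seed; each stochastic stage derives
its seed as `sha256(stage_name:seed) mod 2³¹−1`, so stages can be re-run
in isolation. Cohort CSV and result JSONs are byte-identical across runs
with identical configs (sorted-key JSON, no timestamps in data files);
fixture volumes are written as uncompressed `.nii` so byte-level
comparisons are meaningful. The manifest records the config, its SHA-256
and the derived stage seeds.

## Limitations

- Peak-to-peak on coarse frames has an irreducible ±half-frame error; the
  consistency guarantee (|estimate − truth| ≤ one frame width) is proven
  for dispersion-free boluses only. Strong lung dispersion shifts the LV
  peak relative to the kernel mean, so "true CPTT" itself becomes
  model-dependent.
- The 2.5 s imputation is a convention, not an estimate; cohorts dominated
  by fast transits inherit its bias.
- EF clipping to [10, 80] % very slightly attenuates the generating slope
  (immeasurable at the calibrated parameters; the 1000-cohort recovery
  test bounds it below Monte-Carlo error).
- DICOM ingestion, reconstruction, attenuation correction, gated EF
  computation and automatic VOI placement are out of scope; masks and
  metadata are inputs.
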