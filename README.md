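# cptt — cardiopulmonary transit time from dynamic cardiac PET

`cptt` estimates the **cardiopulmonary transit time (CPTT)** — the seconds an
injected activity bolus needs to travel from the right to the left
ventricular cavity — from dynamic Rubidium-82 cardiac PET acquisitions, and
provides everything needed to study the estimator: a first-pass bolus
simulator with known ground truth, phantom rendering, heart-rate
normalization, and the cohort-level statistics linking transit time to left
ventricular function.

It is aimed at nuclear-medicine and cardiac-imaging researchers who want a
tested, reproducible implementation of peak-to-peak transit estimation on
coarse clinical frame grids.

## The method

Dynamic Rb-82 scans are reconstructed into a vendor-default frameset
(1 s delay, 12 × 10 s, 2 × 30 s, 2 × 60 s, 1 × 120 s; 17 frames, 421 s).
From 1 cm³ VOIs in the right and left ventricular cavities, SUV_mean
time–activity curves are extracted:

```
SUV(t_k) = mean_VOI conc(t_k) [kBq/mL] × weight [kg] / dose [MBq]
```

CPTT is the **peak-to-peak** difference between the LV and RV first-pass
peaks, each taken at the midpoint of its maximal frame. On 10 s early
frames the raw difference is quantized to {0, 10, 20, …} s; a raw value of
0 s is physiologically impossible (it means a true transit somewhere in
(0, 5) s), so the interval midpoint **2.5 s is imputed** and flagged.
Normalization by the RR-interval gives

```
NCPTT = CPTT / RR,   RR = 60 / HR [s]
```

— roughly the number of cardiac cycles blood needs to cross the pulmonary
circuit. Cohort statistics cover univariate OLS of echocardiographic
ejection fraction (EF_Echo) on NCPTT_rest with 95% CI and residual
diagnostics, Pearson correlations, and a leave-one-out cross-validated
RMSE comparison of NCPTT_rest versus gated-PET EF as predictors of
EF_Echo.

The synthetic generators state a calibrated reference world: gamma-variate
first-pass curves (analytic peak at `t0 + α·β`), a gamma lung-transport
kernel with controllable true transit, and 44-patient cohorts with
CPTT_rest 9.2 ± 4.2 s, HR_rest 70.1 ± 11.5 bpm, EF_Echo 56.4 ± 9 %, a
generating slope of −0.77 % EF per NCPTT unit, and realistic echo
missingness (14/34/45 %).

## Worked example

```python
import numpy as np
from cptt import *

s = make_frame_schedule()                       # clinical 17-frame grid
p = BolusParams(transit_delay=9.2, noise_sd=0.5, seed=7)
rv_c, lv_c = simulate_first_pass(p)
rng = np.random.default_rng(7)
rv = bin_to_frames(rv_c, s, noise_sd=0.5, seed=rng, label="RV")
lv = bin_to_frames(lv_c, s, noise_sd=0.5, seed=rng, label="LV")
res = compute_cptt(rv, lv, heart_rate_bpm=70.1)
print(f"CPTT  = {res.cptt:.1f} s (raw {res.raw_cptt:.1f} s, imputed={res.imputed})")
print(f"NCPTT = {res.ncptt:.2f} cardiac cycles (RR = {res.rr_interval:.3f} s)")

df = simulate_cohort(CohortParams(seed=1))
reg = fit_univariate(df, "ef_echo_pct", "ncptt_rest")
print(f"slope = {reg.slope:.2f} (95% CI {reg.ci_low:.2f}, {reg.ci_high:.2f}), "
      f"p = {reg.p_value:.4f}, n = {reg.n_used}")
```

prints

```
CPTT  = 10.0 s (raw 10.0 s, imputed=False)
NCPTT = 11.68 cardiac cycles (RR = 0.856 s)
slope = -1.40 (95% CI -2.04, -0.76), p = 0.0001, n = 40
```

The true transit of 9.2 s is read off as 10.0 s — the nearest multiple of
the 10 s frame width, which is exactly the discretization the imputation
rule exists for. The single-cohort slope (−1.40) scatters around the
generating −0.77 with a standard error of ~0.3; averaged over many
cohorts it recovers −0.77 (see the acceptance suite).

A shell workflow is available too:

```bash
cptt fixtures --out demo --seed 2
cptt estimate --image demo/phantom.nii --rv-mask demo/rv_mask.nii \
              --lv-mask demo/lv_mask.nii --hr 70 --out demo/result.json
cptt analyze  --cohort demo/cohort.csv --out demo/report
cptt run      --seed 1 --out demo/full_run
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the CPTT value assigned by the imputation rule
when a noiseless simulated first pass (true transit 3 s) lands both
ventricular peaks in the same 10 s frame, and the mean OLS slope of
EF_Echo on NCPTT_rest across 1000 freshly simulated 44-patient cohorts.
Results are written as JSON keyed by target id.

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
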