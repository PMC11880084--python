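"""Calibration defaults for the synthetic generators and the pipeline.

The cohort constants emulate a single-centre clinical Rb-82 myocardial
perfusion cohort of 44 outpatients (mean age ~72 y): summary moments for
transit times, heart rates and ejection fractions, the observed linear
EF_Echo ~ NCPTT_rest relation, and the per-parameter completeness of the
echocardiographic records.  The bolus constants describe a sharp
first-pass bolus as delivered by a high-flow (30 mL/min) Rb-82 infusion.

These are a stated reference world, not tuning knobs: tests and the
acceptance suite treat them as fixed.
"""

from __future__ import annotations

import math

from .frames import DEFAULT_DELAY_S, DEFAULT_FRAME_SPEC  # noqa: F401  (re-exported)

# --- cohort moments (mean, sd) ------------------------------------------------
CPTT_REST_S = (9.2, 4.2)
CPTT_STRESS_S = (7.4, 3.6)
NCPTT_REST = (10.4, 4.7)        # cardiac cycles (dimensionless)
NCPTT_STRESS = (10.9, 5.4)
HR_REST_BPM = (70.1, 11.5)
HR_STRESS_BPM = (89.7, 13.8)
EF_PET_PCT = (51.5, 13.5)
EF_ECHO_PCT = (56.4, 9.0)
TAPSE_MM = (22.8, 4.5)
E_A_RATIO = (0.9, 0.5)

#: Cohort size of the reference study population.
N_PATIENTS = 44

# --- echo record completeness (missing fraction, MCAR) ------------------------
MISSING_EF_ECHO = 6 / 44        # 14 %
MISSING_TAPSE = 15 / 44         # 34 %
MISSING_E_A = 20 / 44           # 45 %

# --- EF_Echo ~ NCPTT_rest linear relation -------------------------------------
#: Slope, % EF per NCPTT unit (one extra cardiac cycle of transit).
EF_SLOPE = -0.77
#: Intercept chosen so the line passes through the cohort means.
EF_INTERCEPT = EF_ECHO_PCT[0] - EF_SLOPE * NCPTT_REST[0]          # 64.408 %
#: Residual sd so that the marginal EF_Echo sd matches the cohort table:
#: sd_resid^2 = sd_EF^2 - slope^2 * sd_NCPTT^2.
EF_RESIDUAL_SD = math.sqrt(EF_ECHO_PCT[1] ** 2 - EF_SLOPE ** 2 * NCPTT_REST[1] ** 2)  # ~8.24 %
#: Target correlation between gated-PET and echo ejection fractions.
EF_PET_ECHO_CORR = 0.4

# --- imputation / discretization ----------------------------------------------
#: Replacement for a raw peak-to-peak difference of 0 s on 10 s frames: a
#: transit in (0, 5) s discretizes to 0, an impossible value, so the
#: midpoint 2.5 s of that interval is substituted.
IMPUTED_CPTT_S = 2.5

# --- bolus kinetics -----------------------------------------------------------
#: Bolus arrival in the right ventricle, seconds after scan start.
BOLUS_T0_S = 15.0
#: Peak blood-pool SUV of the first pass.
BOLUS_AMPLITUDE_SUV = 40.0
#: Gamma-variate shape; mode at t0 + alpha*beta = t0 + 7.5 s, width
#: sqrt(alpha)*beta ~ 4.3 s -- a sharp high-flow-infusion bolus.
BOLUS_ALPHA = 3.0
BOLUS_BETA_S = 2.5

# --- acquisition metadata for phantoms ----------------------------------------
INJECTED_DOSE_MBQ = 595.0       # cohort mean injected Rb-82 activity
PATIENT_WEIGHT_KG = 81.3        # cohort mean body weight
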