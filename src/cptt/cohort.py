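"""Synthetic patient cohorts.

Draws per-patient transit times, heart rates, ejection fractions and
echocardiographic indices so that a simulated cohort reproduces the
reference study population: its summary moments, the linear
EF_Echo ~ NCPTT_rest relation, the EF_PET/EF_Echo correlation, and the
per-parameter completeness of the echo records (missing completely at
random).

Positive-valued quantities (CPTT, heart rate, TAPSE, E/A) are drawn from
lower-truncated normals whose parent parameters are moment-matched so the
*truncated* distribution has exactly the stated mean and sd.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import defaults
from .errors import ParameterError

__all__ = ["CohortParams", "simulate_cohort", "COHORT_COLUMNS"]

COHORT_COLUMNS = [
    "patient_id",
    "cptt_rest_s",
    "cptt_stress_s",
    "hr_rest_bpm",
    "hr_stress_bpm",
    "ncptt_rest",
    "ncptt_stress",
    "ef_echo_pct",
    "ef_pet_pct",
    "tapse_mm",
    "e_a_ratio",
]


@lru_cache(maxsize=64)
def _matched_truncnorm_params(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """Parent (mu, sigma) so the normal truncated at ``lower`` has the target moments."""

    def residual(theta):
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        a = (lower - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol, info, ier, msg = optimize.fsolve(
        residual, x0=[mean, np.log(sd)], full_output=True
    )
    if ier != 1:
        raise ParameterError(
            f"cannot match truncated normal to mean={mean}, sd={sd}, lower={lower}: {msg}"
        )
    return float(sol[0]), float(np.exp(sol[1]))


def _truncnorm(rng: np.random.Generator, n: int, mean: float, sd: float, lower: float) -> np.ndarray:
    if sd < 0:
        raise ParameterError(f"sd must be >= 0, got {sd}")
    if sd == 0:
        if mean < lower:
            raise ParameterError(f"degenerate draw at {mean} below lower bound {lower}")
        return np.full(n, mean)
    if lower > mean + 5 * sd:
        raise ParameterError(f"infeasible truncation: lower={lower}, mean={mean}, sd={sd}")
    mu, sigma = _matched_truncnorm_params(mean, sd, lower)
    a = (lower - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)


@dataclass(frozen=True)
class CohortParams:
    """Generating parameters of a synthetic cohort (reference-study defaults)."""

    n: int = defaults.N_PATIENTS
    cptt_rest: tuple[float, float] = defaults.CPTT_REST_S
    cptt_stress: tuple[float, float] = defaults.CPTT_STRESS_S
    hr_rest: tuple[float, float] = defaults.HR_REST_BPM
    hr_stress: tuple[float, float] = defaults.HR_STRESS_BPM
    ef_pet: tuple[float, float] = defaults.EF_PET_PCT
    tapse: tuple[float, float] = defaults.TAPSE_MM
    e_a: tuple[float, float] = defaults.E_A_RATIO
    slope: float = defaults.EF_SLOPE
    intercept: float = defaults.EF_INTERCEPT
    residual_sd: float = defaults.EF_RESIDUAL_SD
    ef_pet_corr: float = defaults.EF_PET_ECHO_CORR
    missing_ef_echo: float = defaults.MISSING_EF_ECHO
    missing_tapse: float = defaults.MISSING_TAPSE
    missing_e_a: float = defaults.MISSING_E_A
    cptt_lower: float = 0.0
    hr_lower: float = 30.0
    ef_bounds: tuple[float, float] = (10.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ParameterError(f"cohort size must be >= 3, got {self.n}")
        for name in ("cptt_rest", "cptt_stress", "hr_rest", "hr_stress", "ef_pet", "tapse", "e_a"):
            if getattr(self, name)[1] < 0:
                raise ParameterError(f"{name} sd must be >= 0")
        for name in ("missing_ef_echo", "missing_tapse", "missing_e_a"):
            if not 0 <= getattr(self, name) < 1:
                raise ParameterError(f"{name} must be in [0, 1)")
        if self.residual_sd < 0:
            raise ParameterError("residual_sd must be >= 0")
        if not -1 < self.ef_pet_corr < 1:
            raise ParameterError("ef_pet_corr must be in (-1, 1)")


def simulate_cohort(params: CohortParams = CohortParams()) -> pd.DataFrame:
    """Simulate one cohort table.

    Per patient: CPTT and heart rate at rest and stress from truncated
    normals; RR = 60/HR; NCPTT = CPTT/RR.  EF_Echo follows the linear
    model ``intercept + slope * NCPTT_rest`` plus Gaussian residuals,
    clipped to physiological bounds.  EF_PET shares a latent factor with
    EF_Echo so their correlation matches ``ef_pet_corr`` while keeping
    the stated EF_PET marginal moments.  Missing echo values are blanked
    completely at random at the stated fractions.  Bit-reproducible for
    a fixed seed.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n

    cptt_rest = _truncnorm(rng, n, *p.cptt_rest, p.cptt_lower)
    cptt_stress = _truncnorm(rng, n, *p.cptt_stress, p.cptt_lower)
    hr_rest = _truncnorm(rng, n, *p.hr_rest, p.hr_lower)
    hr_stress = _truncnorm(rng, n, *p.hr_stress, p.hr_lower)
    ncptt_rest = cptt_rest / (60.0 / hr_rest)
    ncptt_stress = cptt_stress / (60.0 / hr_stress)

    ef_echo = p.intercept + p.slope * ncptt_rest + rng.normal(0.0, p.residual_sd, n)
    ef_echo = np.clip(ef_echo, *p.ef_bounds)

    # EF_PET: match its marginal moments and corr(EF_PET, EF_Echo) by mixing
    # the standardized echo EF with independent noise
    sd_echo = ef_echo.std(ddof=1)
    z = (ef_echo - ef_echo.mean()) / sd_echo if sd_echo > 0 else np.zeros(n)
    rho = p.ef_pet_corr
    ef_pet = p.ef_pet[0] + p.ef_pet[1] * (
        rho * z + np.sqrt(1.0 - rho**2) * rng.normal(0.0, 1.0, n)
    )
    ef_pet = np.clip(ef_pet, *p.ef_bounds)

    tapse = _truncnorm(rng, n, *p.tapse, 0.0)
    e_a = _truncnorm(rng, n, *p.e_a, 0.0)

    ef_echo_out = np.where(rng.random(n) < p.missing_ef_echo, np.nan, ef_echo)
    tapse_out = np.where(rng.random(n) < p.missing_tapse, np.nan, tapse)
    e_a_out = np.where(rng.random(n) < p.missing_e_a, np.nan, e_a)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "cptt_rest_s": cptt_rest,
            "cptt_stress_s": cptt_stress,
            "hr_rest_bpm": hr_rest,
            "hr_stress_bpm": hr_stress,
            "ncptt_rest": ncptt_rest,
            "ncptt_stress": ncptt_stress,
            "ef_echo_pct": ef_echo_out,
            "ef_pet_pct": ef_pet,
            "tapse_mm": tapse_out,
            "e_a_ratio": e_a_out,
        },
        columns=COHORT_COLUMNS,
    )
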