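"""First-pass bolus kinetics simulator.

Generates continuous right- and left-ventricular blood-pool activity
curves with a *known* transit time between them, bins them into a dynamic
frame schedule, and renders 4-D phantom volumes, so that the whole
extraction -> estimation chain can be tested against ground truth.

Model
-----
The right-ventricular curve is a normalized gamma-variate

    g(t) = A * ((t - t0) / (alpha*beta))**alpha * exp(alpha - (t - t0)/beta)

for t > t0 and 0 otherwise -- the standard indicator-dilution form, chosen
because its mode is analytic (t0 + alpha*beta equals the peak, where
g = A).  The left-ventricular curve is the RV curve passed through a lung
transport kernel: a gamma density with mean ``transit_delay`` and standard
deviation ``dispersion`` (a pure time shift when dispersion = 0, which
keeps the true peak-to-peak transit exactly ``transit_delay``).  An
optional recirculation tail adds a delayed, broadened copy of the LV
first pass.

Frame values are time-averages of the continuous curve over each frame
(Gauss-Legendre quadrature), matching how reconstructed dynamic frames
aggregate counts, plus optional additive Gaussian noise on the SUV_mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate, stats

from . import defaults
from .errors import CoverageError, GeometryError, ParameterError
from .frames import DynamicPETImage, FrameSchedule, TimeActivityCurve, VOIMask

__all__ = [
    "BolusParams",
    "ContinuousCurve",
    "gamma_variate",
    "simulate_first_pass",
    "bin_to_frames",
    "render_phantom",
]

#: Internal grid step (s) for convolution-based curves.
_FINE_DT = 0.01


def gamma_variate(t, t0: float, amplitude: float, alpha: float, beta: float):
    """Normalized gamma-variate, zero before onset, peak ``amplitude`` at t0 + alpha*beta."""
    if alpha <= 0 or beta <= 0:
        raise ParameterError(f"alpha and beta must be > 0, got alpha={alpha}, beta={beta}")
    t = np.asarray(t, dtype=float)
    tau = t - t0
    out = np.zeros_like(tau)
    pos = tau > 0
    # log-space evaluation avoids overflow for large alpha
    with np.errstate(divide="ignore"):
        out[pos] = amplitude * np.exp(
            alpha * (np.log(tau[pos]) - np.log(alpha * beta)) + alpha - tau[pos] / beta
        )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BolusParams:
    """Parameters of a simulated first-pass acquisition.

    ``transit_delay`` is the true cardiopulmonary transit time (seconds):
    with ``dispersion = 0`` it is exactly the continuous LV-peak minus
    RV-peak separation.  ``dispersion`` is the sd of the gamma lung
    kernel; ``recirculation_fraction`` scales a delayed, broadened copy
    of the LV first pass arriving ``recirculation_delay`` s later.
    ``noise_sd`` is additive Gaussian noise on the binned SUV_mean.
    """

    t0: float = defaults.BOLUS_T0_S
    amplitude: float = defaults.BOLUS_AMPLITUDE_SUV
    alpha: float = defaults.BOLUS_ALPHA
    beta: float = defaults.BOLUS_BETA_S
    transit_delay: float = defaults.CPTT_REST_S[0]
    dispersion: float = 0.0
    recirculation_fraction: float = 0.0
    recirculation_delay: float = 30.0
    recirculation_width: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ParameterError("gamma-variate alpha and beta must be > 0")
        if self.amplitude <= 0:
            raise ParameterError("amplitude must be > 0")
        if self.transit_delay < 0 or self.dispersion < 0 or self.noise_sd < 0:
            raise ParameterError("transit_delay, dispersion and noise_sd must be >= 0")
        if not 0 <= self.recirculation_fraction < 1:
            raise ParameterError("recirculation_fraction must be in [0, 1)")

    @property
    def peak_time(self) -> float:
        """Analytic mode of the RV curve: t0 + alpha*beta."""
        return self.t0 + self.alpha * self.beta


class ContinuousCurve:
    """A continuous activity curve: analytic callable or dense-grid interpolant."""

    def __init__(
        self,
        fn: Callable[[np.ndarray], np.ndarray] | None = None,
        grid: np.ndarray | None = None,
        values: np.ndarray | None = None,
        support: tuple[float, float] = (-np.inf, np.inf),
    ) -> None:
        if fn is None and (grid is None or values is None):
            raise ParameterError("either fn or (grid, values) required")
        self._fn = fn
        self._grid = None if grid is None else np.asarray(grid, dtype=float)
        self._values = None if values is None else np.asarray(values, dtype=float)
        if self._grid is not None:
            support = (float(self._grid[0]), float(self._grid[-1]))
        self.support = support

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self._fn is not None:
            return self._fn(t)
        return np.interp(t, self._grid, self._values)

    def integral(self, a: float, b: float, n: int = 512) -> float:
        """Gauss-Legendre integral over [a, b]."""
        x, w = np.polynomial.legendre.leggauss(n)
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        return float(half * np.sum(w * self(mid + half * x)))


def _gamma_kernel(mean: float, sd: float) -> Callable[[np.ndarray], np.ndarray]:
    """Gamma pdf with given mean and sd (shape k = m^2/s^2, scale = s^2/m)."""
    k = (mean / sd) ** 2
    theta = sd ** 2 / mean
    frozen = stats.gamma(a=k, scale=theta)
    return frozen.pdf


def simulate_first_pass(
    params: BolusParams, grid: np.ndarray | None = None
) -> tuple[ContinuousCurve, ContinuousCurve]:
    """Continuous RV and LV first-pass curves.

    ``grid`` bounds the support of convolution-based curves; the default
    covers [0, 421] s, the span of the clinical frame schedule.  With
    ``dispersion = 0`` and no recirculation both curves are analytic and
    the LV curve is an exact time shift of the RV curve.
    """
    if grid is None:
        grid = np.linspace(0.0, 421.0, 422)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ParameterError("grid must be a strictly increasing 1-D array")

    p = params  # validated in __post_init__

    def rv_fn(t):
        return gamma_variate(t, p.t0, p.amplitude, p.alpha, p.beta)

    rv = ContinuousCurve(fn=rv_fn)

    needs_grid = p.dispersion > 0 or p.recirculation_fraction > 0
    if not needs_grid:
        d = p.transit_delay
        lv = ContinuousCurve(fn=lambda t: rv_fn(np.asarray(t, dtype=float) - d))
        return rv, lv

    t_fine = np.arange(grid[0], grid[-1] + _FINE_DT, _FINE_DT)
    rv_vals = rv_fn(t_fine)
    if p.dispersion > 0:
        # transport through the lung: convolution with the gamma kernel
        tk = np.arange(0.0, p.transit_delay + 8 * p.dispersion, _FINE_DT)
        kernel = _gamma_kernel(p.transit_delay, p.dispersion)(tk)
        lv_vals = np.convolve(rv_vals, kernel)[: t_fine.size] * _FINE_DT
    elif p.transit_delay > 0:
        lv_vals = rv_fn(t_fine - p.transit_delay)
    else:
        lv_vals = rv_vals.copy()
    if p.recirculation_fraction > 0:
        tk = np.arange(0.0, p.recirculation_delay + 8 * p.recirculation_width, _FINE_DT)
        rk = _gamma_kernel(p.recirculation_delay, p.recirculation_width)(tk)
        tail = np.convolve(lv_vals, rk)[: t_fine.size] * _FINE_DT
        lv_vals = lv_vals + p.recirculation_fraction * tail
    lv = ContinuousCurve(grid=t_fine, values=lv_vals)
    return rv, lv


def bin_to_frames(
    curve: ContinuousCurve | Callable[[np.ndarray], np.ndarray],
    schedule: FrameSchedule,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    label: str = "",
) -> TimeActivityCurve:
    """Bin a continuous curve into frame time-averages.

    value(k) = (1/duration_k) * integral of the curve over frame k, by
    adaptive quadrature per frame (the bolus onset is a kink that a fixed
    rule resolves poorly), plus optional Gaussian noise clipped at zero.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if not isinstance(curve, ContinuousCurve):
        curve = ContinuousCurve(fn=curve)
    lo, hi = curve.support
    if schedule.starts[0] < lo - 1e-9 or schedule.ends[-1] > hi + 1e-9:
        raise CoverageError(
            f"schedule span {schedule.span} extends past curve support ({lo}, {hi})"
        )
    vals = np.empty(len(schedule))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        for k, (a, dur) in enumerate(zip(schedule.starts, schedule.durations)):
            integral, _ = integrate.quad(
                curve, a, a + dur, epsabs=1e-10, epsrel=1e-10, limit=200
            )
            vals[k] = integral / dur
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    return TimeActivityCurve(
        midpoints=schedule.midpoints, values=np.clip(vals, 0.0, None), label=label
    )


def _box_mask(shape: tuple[int, int, int], box: tuple[tuple[int, int], ...]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    sl = tuple(slice(lo, hi) for lo, hi in box)
    mask[sl] = True
    return mask


def render_phantom(
    rv_tac: TimeActivityCurve,
    lv_tac: TimeActivityCurve,
    schedule: FrameSchedule,
    shape: tuple[int, int, int] = (8, 8, 8),
    voxel_size: tuple[float, float, float] = (4.0, 4.0, 4.0),
    rv_box: tuple[tuple[int, int], ...] = ((1, 3), (2, 6), (2, 6)),
    lv_box: tuple[tuple[int, int], ...] = ((5, 7), (2, 6), (2, 6)),
    injected_dose_MBq: float = defaults.INJECTED_DOSE_MBQ,
    patient_weight_kg: float = defaults.PATIENT_WEIGHT_KG,
    voxel_noise_sd: float = 0.0,
    noise_model: str = "gaussian",
    seed: int | np.random.Generator | None = None,
) -> tuple[DynamicPETImage, VOIMask, VOIMask]:
    """Render two cuboid ventricular VOIs carrying the given TACs into a 4-D volume.

    Masked voxels carry the TAC value converted from SUV back to activity
    concentration (conc = SUV * dose / weight); background is zero.
    ``voxel_noise_sd`` adds per-voxel noise: Gaussian in concentration
    units, or Poisson resampling scaled to the local mean.
    """
    if len(rv_tac) != len(schedule) or len(lv_tac) != len(schedule):
        raise GeometryError("TAC length must equal the schedule length")
    rv_mask = _box_mask(shape, rv_box)
    lv_mask = _box_mask(shape, lv_box)
    if not rv_mask.any() or not lv_mask.any():
        raise GeometryError("VOI boxes must contain at least one voxel")
    if (rv_mask & lv_mask).any():
        raise GeometryError("RV and LV VOIs overlap")

    suv_to_conc = injected_dose_MBq / patient_weight_kg
    voxels = np.zeros(shape + (len(schedule),), dtype=float)
    voxels[rv_mask, :] = rv_tac.values * suv_to_conc
    voxels[lv_mask, :] = lv_tac.values * suv_to_conc
    if voxel_noise_sd > 0 or noise_model == "poisson":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if noise_model == "gaussian":
            voxels = np.clip(voxels + rng.normal(0.0, voxel_noise_sd, voxels.shape), 0.0, None)
        elif noise_model == "poisson":
            # scaled Poisson: variance ~ voxel_noise_sd^2 at the mean level
            scale = max(voxel_noise_sd, 1e-12) ** 2
            voxels = rng.poisson(np.clip(voxels, 0.0, None) / scale) * scale
        else:
            raise ParameterError(f"unknown noise_model {noise_model!r}")

    image = DynamicPETImage(
        voxels=voxels,
        voxel_size=voxel_size,
        schedule=schedule,
        injected_dose_MBq=injected_dose_MBq,
        patient_weight_kg=patient_weight_kg,
    )
    vol = float(np.prod(voxel_size)) / 1000.0  # mm^3 -> cm^3
    return (
        image,
        VOIMask(rv_mask, nominal_volume_cm3=rv_mask.sum() * vol),
        VOIMask(lv_mask, nominal_volume_cm3=lv_mask.sum() * vol),
    )
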