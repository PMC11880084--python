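"""Peak-to-peak cardiopulmonary transit time estimation.

The transit time (CPTT) is the interval between the first-pass bolus
peak in the right-ventricular cavity and its peak in the left-ventricular
cavity, read off the two SUV_mean time-activity curves.  On coarse
clinical frames (10 s early frames) the raw peak-to-peak difference is
quantized to multiples of the frame width; a raw difference of 0 s is
physiologically impossible and is replaced by 2.5 s — the midpoint of the
(0, 5) s band that discretizes to zero.  CPTT is normalized by the
RR-interval (60 / heart rate) to give NCPTT, roughly the number of
cardiac cycles blood needs to cross the pulmonary circuit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import defaults
from .errors import NoPeakError, ParameterError, PeakOrderError
from .frames import FrameSchedule, TimeActivityCurve
from .simulate import BolusParams, bin_to_frames, simulate_first_pass

__all__ = [
    "CPTTResult",
    "PeakEstimate",
    "isolate_first_pass",
    "peak_time",
    "compute_cptt",
    "discretization_support",
]


@dataclass(frozen=True)
class CPTTResult:
    """Estimated transit time and its quality flags.

    ``imputed`` is set when the raw frame-quantized difference was 0 s and
    the 2.5 s substitute was used; ``ambiguous_peak`` when either curve had
    tied frame maxima (resolved to the earliest frame).
    ``first_pass_window`` spans from the RV first-pass onset to the LV
    recirculation cutoff, in seconds (frame midpoints).
    """

    cptt: float
    ncptt: float
    rr_interval: float
    raw_cptt: float
    imputed: bool
    ambiguous_peak: bool
    first_pass_window: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "cptt_s": self.cptt,
            "ncptt": self.ncptt,
            "rr_interval_s": self.rr_interval,
            "raw_cptt_s": self.raw_cptt,
            "imputed": self.imputed,
            "ambiguous_peak": self.ambiguous_peak,
            "first_pass_window_s": list(self.first_pass_window),
        }


class PeakEstimate(NamedTuple):
    time_s: float
    frame_index: int
    ambiguous: bool


def isolate_first_pass(tac: TimeActivityCurve, onset_fraction: float = 0.1) -> tuple[int, int]:
    """Inclusive frame-index window containing only the first-pass peak.

    The window runs from curve onset (first frame exceeding
    ``onset_fraction`` of the global maximum) to the first local minimum
    after the global maximum, which cuts off the recirculation tail.
    """
    if len(tac) < 3:
        raise NoPeakError(f"need >= 3 frames, got {len(tac)}")
    if not 0 < onset_fraction < 1:
        raise ParameterError("onset_fraction must be in (0, 1)")
    v = tac.values
    vmax = v.max()
    if vmax <= 0:
        raise NoPeakError("all-zero time-activity curve has no peak")
    d = np.diff(v)
    if np.all(d >= 0) or np.all(d <= 0):
        raise NoPeakError("monotone time-activity curve has no isolated peak")
    p = int(np.argmax(v))  # first occurrence on ties
    if p == len(v) - 1:
        raise NoPeakError("global maximum at the final frame; first pass not covered")
    onset = int(np.argmax(v > onset_fraction * vmax))
    # first local minimum strictly after the peak
    end = len(v) - 1
    for j in range(p + 1, len(v) - 1):
        if v[j] < v[j - 1] and v[j] <= v[j + 1]:
            end = j
            break
    return onset, end


def peak_time(tac: TimeActivityCurve, window: tuple[int, int], mode: str = "peak") -> PeakEstimate:
    """Bolus arrival time within a first-pass window.

    ``mode='peak'`` (default): midpoint of the frame with maximal
    SUV_mean; ties go to the earliest frame and are flagged ambiguous.
    ``mode='centroid'``: activity-weighted mean frame midpoint over the
    window — an alternative arrival definition, never flagged.
    """
    lo, hi = window
    if not 0 <= lo <= hi < len(tac):
        raise ParameterError(f"invalid window {window} for a {len(tac)}-frame curve")
    v = tac.values[lo : hi + 1]
    t = tac.midpoints[lo : hi + 1]
    if mode == "centroid":
        total = v.sum()
        if total <= 0:
            raise NoPeakError("zero total activity in window")
        return PeakEstimate(float(np.sum(t * v) / total), -1, False)
    if mode != "peak":
        raise ParameterError(f"unknown mode {mode!r}")
    k = int(np.argmax(v))
    ambiguous = bool(np.sum(v == v[k]) > 1)
    return PeakEstimate(float(t[k]), lo + k, ambiguous)


def compute_cptt(
    rv: TimeActivityCurve,
    lv: TimeActivityCurve,
    heart_rate_bpm: float,
    onset_fraction: float = 0.1,
    imputed_value: float = defaults.IMPUTED_CPTT_S,
    mode: str = "peak",
) -> CPTTResult:
    """Peak-to-peak CPTT and heart-rate-normalized NCPTT from an RV/LV curve pair.

    Raw transit = LV peak time − RV peak time.  A raw value of exactly
    0 s (both peaks in the same frame) is replaced by ``imputed_value``
    (2.5 s) and flagged; a negative raw value raises
    :class:`~cptt.errors.PeakOrderError` since the bolus cannot reach the
    left ventricle first.
    """
    if heart_rate_bpm <= 0:
        raise ParameterError(f"heart rate must be > 0, got {heart_rate_bpm}")
    if not np.array_equal(rv.midpoints, lv.midpoints):
        raise ParameterError("RV and LV curves must share the same frame schedule")
    rv_win = isolate_first_pass(rv, onset_fraction)
    lv_win = isolate_first_pass(lv, onset_fraction)
    rv_peak = peak_time(rv, rv_win, mode=mode)
    lv_peak = peak_time(lv, lv_win, mode=mode)
    raw = lv_peak.time_s - rv_peak.time_s
    if raw < -1e-9:
        raise PeakOrderError(
            f"LV peak ({lv_peak.time_s:.1f} s) precedes RV peak ({rv_peak.time_s:.1f} s); "
            "check VOI labels"
        )
    imputed = bool(abs(raw) <= 1e-9)
    cptt = imputed_value if imputed else float(raw)
    rr = 60.0 / heart_rate_bpm
    return CPTTResult(
        cptt=cptt,
        ncptt=cptt / rr,
        rr_interval=rr,
        raw_cptt=float(max(raw, 0.0)),
        imputed=imputed,
        ambiguous_peak=bool(rv_peak.ambiguous or lv_peak.ambiguous),
        first_pass_window=(float(rv.midpoints[rv_win[0]]), float(lv.midpoints[lv_win[1]])),
    )


def discretization_support(
    schedule: FrameSchedule,
    transits: np.ndarray,
    onsets: np.ndarray,
    base_params: BolusParams = BolusParams(),
    decimals: int = 6,
) -> np.ndarray:
    """Distinct raw peak-to-peak values a frame schedule can produce.

    Sweeps true transit times and bolus onsets through the noiseless,
    dispersion-free simulator, estimates the raw (un-imputed)
    peak-to-peak difference for each pair, and returns the sorted set of
    distinct values.  On uniform early frames of width w the support is a
    small set of multiples of w — the discretization the imputation rule
    exists to handle.
    """
    from dataclasses import replace

    values = set()
    for t0 in np.asarray(onsets, dtype=float):
        for d in np.asarray(transits, dtype=float):
            p = replace(
                base_params,
                t0=float(t0),
                transit_delay=float(d),
                dispersion=0.0,
                recirculation_fraction=0.0,
                noise_sd=0.0,
            )
            rv_c, lv_c = simulate_first_pass(p)
            rv = bin_to_frames(rv_c, schedule)
            lv = bin_to_frames(lv_c, schedule)
            res = compute_cptt(rv, lv, heart_rate_bpm=60.0)
            values.add(round(res.raw_cptt, decimals))
    return np.array(sorted(values))
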