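"""Figures: EF scatter plots with regression lines, TAC overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .frames import TimeActivityCurve
from .stats import fit_univariate

__all__ = ["plot_ef_scatter", "plot_tacs"]

_LABELS = {
    "ncptt_rest": "NCPTT (rest, cardiac cycles)",
    "ef_pet_pct": "EF$_{PET}$ (%)",
    "ef_echo_pct": "EF$_{Echo}$ (%)",
}


def plot_ef_scatter(cohort: pd.DataFrame, predictor: str, response: str, path) -> None:
    """Scatter of response vs predictor with the univariate OLS line."""
    res = fit_univariate(cohort, response, predictor)
    sub = cohort[[predictor, response]].dropna()
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(sub[predictor], sub[response], s=18, color="tab:blue", alpha=0.8)
    xs = sub[predictor].sort_values()
    ax.plot(xs, res.intercept + res.slope * xs, color="tab:red", lw=1.5)
    ax.set_xlabel(_LABELS.get(predictor, predictor))
    ax.set_ylabel(_LABELS.get(response, response))
    ax.set_title(f"slope={res.slope:.2f}, r={res.r:.2f}, n={res.n_used}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tacs(rv: TimeActivityCurve, lv: TimeActivityCurve, path, window=None) -> None:
    """RV (blue) and LV (orange) time-activity curves; optional peak-to-peak span."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.plot(rv.midpoints, rv.values, "o-", color="tab:blue", label=rv.label or "RV")
    ax.plot(lv.midpoints, lv.values, "o-", color="tab:orange", label=lv.label or "LV")
    if window is not None:
        ymax = max(rv.values.max(), lv.values.max())
        ax.hlines(ymax * 1.02, window[0], window[1], color="tab:red", lw=2,
                  label="peak to peak")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("SUV$_{mean}$")
    ax.set_xlim(0, min(150, rv.midpoints[-1]))
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
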