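"""End-to-end orchestration: simulate -> render -> extract -> estimate -> analyze.

A run is driven by a single :class:`RunConfig` and a master seed; every
stochastic stage derives its own seed from the master seed and the stage
name, so a stage can be re-run in isolation and still reproduce the full
run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__, defaults
from .cohort import CohortParams, simulate_cohort
from .errors import CPTTError, InsufficientDataError
from .estimation import compute_cptt
from .frames import DEFAULT_DELAY_S, DEFAULT_FRAME_SPEC, extract_tac, make_frame_schedule
from .nifti import write_dynamic_nifti, write_mask_nifti
from .simulate import BolusParams, bin_to_frames, render_phantom, simulate_first_pass
from .stats import compare_predictors, fit_univariate, pearson_r

__all__ = ["RunConfig", "stage_seed", "run_pipeline", "analyze_cohort", "make_fixtures"]

log = logging.getLogger("cptt")


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived from the master seed and the stage name (< 2^31)."""
    digest = hashlib.sha256(f"{stage}:{master_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    seed: int = 0
    frame_spec: tuple[tuple[int, float], ...] = DEFAULT_FRAME_SPEC
    delay_s: float = DEFAULT_DELAY_S
    bolus: BolusParams = field(default_factory=BolusParams)
    cohort: CohortParams = field(default_factory=CohortParams)
    heart_rate_bpm: float = defaults.HR_REST_BPM[0]
    make_figures: bool = True
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame_spec"] = [[int(c), float(w)] for c, w in self.frame_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "frame_spec" in d:
            d["frame_spec"] = tuple((int(c), float(w)) for c, w in d["frame_spec"])
        if "bolus" in d and not isinstance(d["bolus"], BolusParams):
            d["bolus"] = BolusParams(**d["bolus"])
        if "cohort" in d and not isinstance(d["cohort"], CohortParams):
            c = dict(d["cohort"])
            for key, val in c.items():
                if isinstance(val, list):
                    c[key] = tuple(val)
            d["cohort"] = CohortParams(**c)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_listify(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _listify(obj):
    """Tuples -> lists for clean YAML round-trips."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n")


@contextmanager
def _stage(name: str):
    log.info("stage %s: start", name)
    try:
        yield
    except CPTTError as exc:
        raise CPTTError(f"[stage {name}] {exc}") from exc
    log.info("stage %s: done", name)


def analyze_cohort(cohort, response: str = "ef_echo_pct") -> dict:
    """Regression, correlations and the LOOCV predictor comparison for one cohort.

    Fits ``response ~ ncptt_rest`` by OLS, reports Pearson correlations of
    the response with both NCPTT_rest and EF_PET, and compares the two as
    univariate LOOCV predictors on their shared complete-case subset.
    """
    regression = fit_univariate(cohort, response, "ncptt_rest")
    log.info(
        "regression %s ~ ncptt_rest: slope=%.3f CI=(%.3f, %.3f) p=%.4f n=%d (dropped %d)",
        response, regression.slope, regression.ci_low, regression.ci_high,
        regression.p_value, regression.n_used, regression.n_dropped,
    )
    correlations = {}
    for pred in ("ncptt_rest", "ef_pet_pct"):
        sub = cohort[[response, pred]].dropna()
        r, p = pearson_r(sub[pred], sub[response])
        correlations[pred] = {"r": r, "p_value": p, "n_used": len(sub)}
    try:
        comparison = compare_predictors(cohort, response, ["ncptt_rest", "ef_pet_pct"]).to_dict()
    except InsufficientDataError as exc:
        log.warning("predictor comparison skipped: %s", exc)
        comparison = None
    return {
        "regression": regression.to_dict(),
        "correlations": correlations,
        "comparison": comparison,
    }


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute a full run; returns the artifact paths.

    Artifacts: ``cohort.csv``, ``results.json`` (cohort statistics),
    ``phantom.nii`` + masks + sidecar, ``cptt_result.json`` (single-case
    estimate from the phantom), figures, ``run.log`` and ``manifest.json``
    (config hash, per-stage seeds, package version).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    artifacts: dict[str, str] = {}
    try:
        schedule = make_frame_schedule(config.frame_spec, config.delay_s)

        with _stage("cohort"):
            cohort_params = replace(config.cohort, seed=stage_seed(config.seed, "cohort"))
            cohort = simulate_cohort(cohort_params)
            cohort.to_csv(out / "cohort.csv", index=False)
            artifacts["cohort_csv"] = str(out / "cohort.csv")

        with _stage("analyze"):
            results = analyze_cohort(cohort)
            _write_json(results, out / "results.json")
            artifacts["results_json"] = str(out / "results.json")

        with _stage("phantom"):
            bolus = replace(config.bolus, seed=stage_seed(config.seed, "bolus"))
            rv_c, lv_c = simulate_first_pass(bolus)
            rng = np.random.default_rng(bolus.seed)
            rv = bin_to_frames(rv_c, schedule, noise_sd=bolus.noise_sd, seed=rng, label="RV")
            lv = bin_to_frames(lv_c, schedule, noise_sd=bolus.noise_sd, seed=rng, label="LV")
            image, rv_mask, lv_mask = render_phantom(rv, lv, schedule)
            write_dynamic_nifti(
                image, out / "phantom.nii",
                extra_meta={"true_transit_s": bolus.transit_delay,
                            "heart_rate_bpm": config.heart_rate_bpm},
            )
            write_mask_nifti(rv_mask, out / "rv_mask.nii", image.voxel_size)
            write_mask_nifti(lv_mask, out / "lv_mask.nii", image.voxel_size)
            artifacts["phantom_nii"] = str(out / "phantom.nii")

        with _stage("estimate"):
            rv_x = extract_tac(image, rv_mask, label="RV")
            lv_x = extract_tac(image, lv_mask, label="LV")
            result = compute_cptt(rv_x, lv_x, config.heart_rate_bpm)
            if result.imputed:
                log.info("imputation fired: raw peak-to-peak difference was 0 s")
            if result.ambiguous_peak:
                log.info("ambiguous peak: tied frame maxima resolved to the earliest frame")
            payload = result.to_dict()
            payload["true_transit_s"] = bolus.transit_delay
            _write_json(payload, out / "cptt_result.json")
            artifacts["cptt_result_json"] = str(out / "cptt_result.json")

        if config.make_figures:
            with _stage("figures"):
                from .plots import plot_ef_scatter, plot_tacs

                plot_ef_scatter(cohort, "ef_pet_pct", "ef_echo_pct", out / "fig_ef_pet.png")
                plot_ef_scatter(cohort, "ncptt_rest", "ef_echo_pct", out / "fig_ncptt.png")
                plot_tacs(rv_x, lv_x, out / "fig_tacs.png",
                          window=result.first_pass_window)
                artifacts["figures"] = str(out)

        config_dict = _listify(config.to_dict())
        manifest = {
            "version": __version__,
            "config": config_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(config_dict, sort_keys=True).encode()
            ).hexdigest(),
            "stage_seeds": {s: stage_seed(config.seed, s) for s in ("cohort", "bolus")},
        }
        _write_json(manifest, out / "manifest.json")
        artifacts["manifest_json"] = str(out / "manifest.json")
    finally:
        log.removeHandler(handler)
        handler.close()
    return artifacts


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Small deterministic test assets: an 8x8x8x17 phantom with masks and
    sidecar (ground-truth transit included), and a 44-row cohort CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schedule = make_frame_schedule()

    bolus = BolusParams(noise_sd=0.5, seed=stage_seed(seed, "fixture-bolus"))
    rv_c, lv_c = simulate_first_pass(bolus)
    rng = np.random.default_rng(bolus.seed)
    rv = bin_to_frames(rv_c, schedule, noise_sd=bolus.noise_sd, seed=rng, label="RV")
    lv = bin_to_frames(lv_c, schedule, noise_sd=bolus.noise_sd, seed=rng, label="LV")
    image, rv_mask, lv_mask = render_phantom(rv, lv, schedule)
    write_dynamic_nifti(
        image, out / "phantom.nii",
        extra_meta={"true_transit_s": bolus.transit_delay,
                    "heart_rate_bpm": defaults.HR_REST_BPM[0]},
    )
    write_mask_nifti(rv_mask, out / "rv_mask.nii", image.voxel_size)
    write_mask_nifti(lv_mask, out / "lv_mask.nii", image.voxel_size)

    cohort = simulate_cohort(replace(CohortParams(), seed=stage_seed(seed, "fixture-cohort")))
    cohort.to_csv(out / "cohort.csv", index=False)
    return {
        "phantom_nii": str(out / "phantom.nii"),
        "rv_mask_nii": str(out / "rv_mask.nii"),
        "lv_mask_nii": str(out / "lv_mask.nii"),
        "cohort_csv": str(out / "cohort.csv"),
    }
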