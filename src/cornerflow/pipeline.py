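"""End-to-end pipeline orchestration from a YAML/dict configuration.

A run is a list of stages executed in order; each stage writes its outputs
under the configured output directory and contributes to a schema-versioned
summary report.  Identical config + seeds produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as cfio
from .corner import (CornerSpec, SurfactantSeries, concus_finn_flow,
                     critical_concentration, critical_corner_angle,
                     max_rise_height)
from .errors import ConfigurationError
from .imaging import DropImage, contact_angle_from_image
from .synthetic import (gen_concentration_series, gen_corner_timelapse,
                        gen_pendant_image, gen_sessile_image)
from .tracking import flow_onset_end, track_tip_heights
from .younglaplace import DEFAULT_GRAVITY, FluidProperties, fit_pendant_profile

log = logging.getLogger("cornerflow")

REPORT_SCHEMA_VERSION = 1

_KNOWN_STAGES = {
    "simulate_pendant", "simulate_sessile", "simulate_timelapse",
    "simulate_series", "tensiometry", "contact_angle", "corner_predict",
    "track",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: Path
    stages: list = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigurationError("config must be a mapping")
        if "outdir" not in raw:
            raise ConfigurationError("config requires an 'outdir' key")
        stages = raw.get("stages", [])
        if not isinstance(stages, list):
            raise ConfigurationError("'stages' must be a list")
        base = base or Path.cwd()
        for st in stages:
            if not isinstance(st, dict) or "kind" not in st:
                raise ConfigurationError("each stage needs a 'kind' key")
            if st["kind"] not in _KNOWN_STAGES:
                raise ConfigurationError(f"unknown stage kind {st['kind']!r}")
            for key in ("input", "image", "stack", "series"):
                if key in st:
                    p = (base / st[key]).resolve() if not Path(st[key]).is_absolute() \
                        else Path(st[key])
                    if not p.exists():
                        raise ConfigurationError(f"missing input path: {p}")
                    st[key] = str(p)
        outdir = base / raw["outdir"] if not Path(raw["outdir"]).is_absolute() \
            else Path(raw["outdir"])
        return cls(outdir=outdir, stages=stages, seed=int(raw.get("seed", 0)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        return cls.from_dict(yaml.safe_load(p.read_text()), base=p.parent)


def _stage_simulate_pendant(st, cfg, outdir):
    image, truth = gen_pendant_image(
        gamma=float(st.get("gamma", 0.072)),
        density_difference=float(st.get("density_difference", 1000.0)),
        apex_radius=float(st.get("apex_radius", 1.5e-3)),
        calibration=float(st.get("calibration", 5e-6)),
        noise_sigma_px=float(st.get("noise_sigma_px", 0.0)),
        seed=int(st.get("seed", cfg.seed)))
    name = st.get("name", "pendant")
    cfio.write_grayscale_png(image.pixels, outdir / f"{name}.png")
    (outdir / f"{name}_truth.json").write_text(truth.to_json() + "\n")
    return {"artifact": f"{name}.png"}


def _stage_simulate_sessile(st, cfg, outdir):
    image, truth = gen_sessile_image(
        theta_deg=float(st.get("theta_deg", 60.0)),
        cap_base_radius=float(st.get("cap_base_radius", 1.5e-3)),
        calibration=float(st.get("calibration", 5e-6)),
        noise_sigma_px=float(st.get("noise_sigma_px", 0.0)),
        seed=int(st.get("seed", cfg.seed)))
    name = st.get("name", "sessile")
    cfio.write_grayscale_png(image.pixels, outdir / f"{name}.png")
    (outdir / f"{name}_truth.json").write_text(truth.to_json() + "\n")
    return {"artifact": f"{name}.png", "baseline_row": truth.truth["baseline_row"]}


def _stage_simulate_timelapse(st, cfg, outdir):
    stack, truth = gen_corner_timelapse(
        h_max=float(st.get("h_max", 9e-3)),
        t_start_h=float(st.get("t_start_h", 8.0)),
        t_end_h=float(st.get("t_end_h", 15.0)),
        total_hours=float(st.get("total_hours", 24.0)),
        frame_interval_min=float(st.get("frame_interval_min", 10.0)),
        noise_sigma=float(st.get("noise_sigma", 0.02)),
        seed=int(st.get("seed", cfg.seed)))
    name = st.get("name", "timelapse")
    cfio.write_stack_tiff(stack, outdir / f"{name}.tif")
    (outdir / f"{name}_truth.json").write_text(truth.to_json() + "\n")
    return {"artifact": f"{name}.tif"}


def _stage_simulate_series(st, cfg, outdir):
    import numpy as np
    concs = st.get("concentrations")
    if concs is None:
        concs = np.logspace(-5.5, -2.5, 13)
    series, truth = gen_concentration_series(
        concentrations=np.asarray(concs, dtype=float),
        noise=float(st.get("noise", 0.0)),
        seed=int(st.get("seed", cfg.seed)))
    name = st.get("name", "series")
    series.to_csv(outdir / f"{name}.csv")
    (outdir / f"{name}_truth.json").write_text(truth.to_json() + "\n")
    return {"artifact": f"{name}.csv"}


def _stage_tensiometry(st, cfg, outdir):
    from .imaging import extract_drop_edge
    if "image" in st:
        pixels = cfio.read_grayscale_image(st["image"])
        image = DropImage(pixels, calibration=float(st["calibration"]))
        profile = extract_drop_edge(image, orientation="pendant")
    else:
        profile = cfio.read_profile_csv(st["input"])
    fit = fit_pendant_profile(profile,
                              density_difference=float(st.get("density_difference", 1000.0)),
                              gravity=float(st.get("g", DEFAULT_GRAVITY)))
    name = st.get("name", "tensiometry")
    cfio.write_json(fit.to_dict(), outdir / f"{name}.json")
    return fit.to_dict()


def _stage_contact_angle(st, cfg, outdir):
    pixels = cfio.read_grayscale_image(st["image"])
    image = DropImage(pixels, calibration=float(st["calibration"]),
                      baseline_row=st.get("baseline_row"))
    meas = contact_angle_from_image(image,
                                    tangent_window=int(st.get("tangent_window", 15)))
    name = st.get("name", "contact_angle")
    cfio.write_json(meas.to_dict(), outdir / f"{name}.json")
    return meas.to_dict()


def _stage_corner_predict(st, cfg, outdir):
    alpha = float(st["alpha_deg"])
    theta = float(st["theta_deg"])
    pred = concus_finn_flow(alpha, theta,
                            tolerance_deg=float(st.get("tolerance_deg", 1.0)))
    record = pred.to_dict()
    record["critical_corner_angle_deg"] = critical_corner_angle(theta)
    if "min_gap" in st and pred.flows != "no":
        fluid = FluidProperties(
            density=float(st.get("rho", 1000.0)),
            surface_tension=float(st["gamma"]),
            contact_angle_deg=theta,
            gravity=float(st.get("g", DEFAULT_GRAVITY)))
        corner = CornerSpec(alpha_deg=alpha, min_gap=float(st["min_gap"]))
        record["h_max_m"] = max_rise_height(fluid, corner)
    if "series" in st:
        series = SurfactantSeries.from_csv(st["series"])
        bracket = critical_concentration(series, alpha)
        record["critical_concentration_bracket_M"] = (
            None if bracket is None else [bracket.c_low, bracket.c_high])
    name = st.get("name", "corner_predict")
    cfio.write_json(record, outdir / f"{name}.json")
    return record


def _stage_track(st, cfg, outdir):
    stack = cfio.read_stack(st["stack"])
    roi = st.get("roi")
    if roi is None:
        w = stack.shape[2]
        roi = (w // 2 - 4, w // 2 + 4)
    traj = track_tip_heights(
        stack, corner_roi=tuple(int(v) for v in roi),
        baseline_row=int(st["baseline_row"]),
        calibration=float(st["calibration"]),
        intensity_threshold=float(st.get("intensity_threshold", 0.5)),
        frame_interval_min=float(st.get("frame_interval_min", 2.0)))
    kin = flow_onset_end(traj,
                         movement_threshold=float(st.get("movement_threshold", 0.2e-3)))
    name = st.get("name", "track")
    cfio.write_trajectory_csv(traj, outdir / f"{name}_trajectory.csv")
    cfio.write_json(kin.to_dict(), outdir / f"{name}_kinetics.json")
    return kin.to_dict()


_DISPATCH = {
    "simulate_pendant": _stage_simulate_pendant,
    "simulate_sessile": _stage_simulate_sessile,
    "simulate_timelapse": _stage_simulate_timelapse,
    "simulate_series": _stage_simulate_series,
    "tensiometry": _stage_tensiometry,
    "contact_angle": _stage_contact_angle,
    "corner_predict": _stage_corner_predict,
    "track": _stage_track,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage in order and write a summary report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "cornerflow_version": __version__,
        "seed": config.seed,
        "stages": [],
    }
    for st in config.stages:
        kind = st["kind"]
        log.info("running stage %s", kind)
        result = _DISPATCH[kind](st, config, outdir)
        report["stages"].append({"kind": kind, "name": st.get("name", kind),
                                 "result": result})
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
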