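"""End-to-end workflow: simulate -> fit -> calibrate -> predict -> compare.

A scenario (dict, YAML or TOML) names the study conditions; the runner
writes a deterministic artifact tree:

    release.csv        simulated (or copied) release-study records
    fits.csv           per-design fit-quality table (R^2, n, log k)
    calibration.json   a, m, n_mean, R^2 and the regression inputs
    compare_<id>.json  f1/f2 for each target shape
    manifest.json      seed, config hash, package version, artifact list
    run.log            stage-by-stage log

Scenario keys (all optional):

    seed: int                      master RNG seed
    truth: {a, m, n}               generating calibration constants
    noise: {measurement_cv, mass_rsd, content_rsd}
    replicates: int                implants per design
    schedule: [days...]            sampling time points
    designs: [ids...]              subset of the built-in design series
    release_csv: path              use measured data instead of simulating
    cutoff: percent                truncation level for fits/comparisons
    targets: [{id, av_ratio, dose_mg?}, ...]   shapes to predict & compare
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__, reference
from .geometry import cylinder_av_ratio
from .kinetics import fit_all_models, pooled_exponent, summarize_designs
from .prediction import AVPowerModel, predict_fraction_profile
from .profiles import mean_profile, profiles_from_frame, read_release_csv
from .similarity import compare_profiles
from .synthetic import NoiseModel, make_design_series, simulate_release_study

__all__ = ["run_pipeline", "load_config"]

logger = logging.getLogger("relkin.pipeline")


def load_config(path: str | Path) -> dict:
    """Load a YAML (or TOML, by extension) scenario file."""
    path = Path(path)
    if path.suffix in (".toml", ".tml"):
        import tomllib

        return tomllib.loads(path.read_text(encoding="utf-8"))
    import yaml

    loaded = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(loaded, Mapping):
        raise ValueError(f"scenario file {path} does not hold a mapping")
    return dict(loaded)


def _config_hash(config: Mapping[str, Any]) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: Mapping[str, Any] | str | Path, outdir: str | Path) -> dict:
    """Run the full workflow for one scenario; returns the manifest dict."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    config = dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    seed = int(config.get("seed", 0))
    truth_cfg = config.get("truth", {})
    truth = (
        float(truth_cfg.get("a", reference.A_INTERCEPT)),
        float(truth_cfg.get("m", reference.M_EXPONENT)),
        float(truth_cfg.get("n", reference.N_MEAN)),
    )
    noise_cfg = config.get("noise", {})
    noise = NoiseModel(
        measurement_cv=float(noise_cfg.get("measurement_cv", 0.0)),
        mass_rsd=float(noise_cfg.get("mass_rsd", 0.0)),
        content_rsd=float(noise_cfg.get("content_rsd", 0.0)),
    )
    cutoff = float(config.get("cutoff", 80.0))
    replicates = int(config.get("replicates", 3))
    schedule = tuple(config.get("schedule", reference.DEFAULT_SCHEDULE))
    rng = np.random.default_rng(seed)

    artifacts: list[str] = []
    try:
        designs = make_design_series()
        if "designs" in config:
            wanted = set(config["designs"])
            designs = [d for d in designs if d.design_id in wanted]
            if not designs:
                raise ValueError(f"no known designs among {sorted(wanted)}")

        _stage("simulate")
        if "release_csv" in config:
            release_profiles = read_release_csv(config["release_csv"])
            frame = None
        else:
            frames = [
                simulate_release_study(
                    design=d, truth=truth, schedule=schedule, noise=noise,
                    replicates=replicates, seed=rng,
                )
                for d in designs
            ]
            frame = pd.concat(frames, ignore_index=True)
            frame.to_csv(outdir / "release.csv", index=False)
            artifacts.append("release.csv")
            release_profiles = profiles_from_frame(frame)

        _stage("fit")
        by_design: dict[str, list] = {}
        for p in release_profiles:
            by_design.setdefault(p.design_id, []).append(p)
        fits_by_design = {
            d: fit_all_models(mean_profile(reps), cutoff=cutoff)
            for d, reps in by_design.items()
        }
        table = summarize_designs(fits_by_design)
        table.to_csv(outdir / "fits.csv")
        artifacts.append("fits.csv")

        _stage("calibrate")
        av_by_design = {d.design_id: cylinder_av_ratio(d) for d in designs}
        rows = [d for d in table.index if d in av_by_design]
        model = AVPowerModel(
            [av_by_design[d] for d in rows],
            [table.loc[d, "log_k"] for d in rows],
            n_mean=pooled_exponent(table.loc[rows]),
        )
        calibration = model.fit()
        (outdir / "calibration.json").write_text(
            json.dumps(calibration.to_dict(), indent=2), encoding="utf-8"
        )
        artifacts.append("calibration.json")
        logger.info("calibration: a=%.6f m=%.6f n=%.6f",
                    calibration.a, calibration.m, calibration.n_mean)

        _stage("predict/compare")
        comparisons = {}
        for target in config.get("targets", []):
            tid = str(target["id"])
            av = float(target["av_ratio"])
            dose = float(target.get(
                "dose_mg",
                reference.DRUG_LOAD * reference.PRINT_LINE_DENSITY * 400.0,
            ))
            observed_frame = simulate_release_study(
                av_ratio=av, truth=truth, dose_mg=dose, schedule=schedule,
                noise=noise, replicates=replicates, seed=rng, design_id=tid,
            )
            observed = mean_profile(profiles_from_frame(observed_frame))
            predicted = predict_fraction_profile(
                calibration, av, observed.times, cap=cutoff
            )
            result = compare_profiles(predicted, observed, cutoff=cutoff)
            payload = result.to_dict() | {"av_ratio": av, "id": tid}
            name = f"compare_{tid}.json"
            (outdir / name).write_text(json.dumps(payload, indent=2),
                                       encoding="utf-8")
            artifacts.append(name)
            comparisons[tid] = payload
            logger.info("target %s: f1=%.2f f2=%.2f", tid, result.f1, result.f2)
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest = {
        "relkin_version": __version__,
        "seed": seed,
        "config_sha256": _config_hash(config),
        "calibration": {"a": calibration.a, "m": calibration.m,
                        "n_mean": calibration.n_mean,
                        "r_squared": calibration.r_squared},
        "comparisons": comparisons,
        "artifacts": sorted(artifacts),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                          encoding="utf-8")
    return manifest
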