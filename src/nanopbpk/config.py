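"""Run configuration, orchestration and manifests.

A run is described by a small YAML (or JSON) file with one block per
stage.  Unknown keys are rejected so typos fail loudly; every output is
recorded in a manifest with input paths, the seed, package version and
SHA-256 hashes, so any file on disk is attributable to the run that wrote
it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .mcis import DEFAULT_FIT_PARAMS, FittingData, fit_three_stage
from .model import DEFAULT_SOLVER_OPTS, DoseSchedule, simulate
from .parameters import PBPKParameters
from .physiology import PhysiologyTable
from .sensitivity import cv_table, nsc_table, sensitivity_frame
from .synth import StudyDesign, generate_from_model
from .validation import HoldoutData, validate_holdout

log = logging.getLogger("nanopbpk")


class ConfigError(ValueError):
    pass


_SCHEMA: dict[str, dict[str, object]] = {
    "common": {
        "seed": 0,
        "outdir": "runs",
        "physiology": None,  # CSV path or None for the packaged default
        "parameters": None,
        "solver": dict(DEFAULT_SOLVER_OPTS),
    },
    "simulate": {"doses_mg": [0.5], "t_end": 48.0, "dt": 0.1},
    "synth": {"noise_sd": 0.10, "n_animals": 3, "doses_mg": [0.1, 0.5, 2.0, 2.5, 3.5]},
    "fit": {"n_sims": 1000, "stages": 3, "dose_design": [0.1, 0.5, 2.0, 2.5, 3.5], "fit_params": list(DEFAULT_FIT_PARAMS)},
    "sensitivity": {"perturbation": 0.01, "dose_mg": 0.5, "t_end": 48.0},
    "validate": {"n_draws": 100, "z_threshold": 20.0, "dose_mg": 0.5},
    "quantify": {"plate_dir": None, "per_animal": False},
}


@dataclass
class RunConfig:
    stages: list[str]
    blocks: dict[str, dict] = field(default_factory=dict)

    def __getitem__(self, block: str) -> dict:
        return self.blocks[block]

    @property
    def seed(self) -> int:
        return self.blocks["common"]["seed"]

    @property
    def outdir(self) -> Path:
        return Path(self.blocks["common"]["outdir"])


def _validated_block(name: str, given: dict) -> dict:
    defaults = _SCHEMA[name]
    unknown = set(given) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown key(s) in [{name}]: {sorted(unknown)}")
    block = {**defaults, **given}
    for key in ("doses_mg", "dose_design"):
        if key in block and any(d < 0 for d in block[key]):
            raise ConfigError(f"[{name}] {key} must be nonnegative")
    if "dose_mg" in block and block["dose_mg"] < 0:
        raise ConfigError(f"[{name}] dose_mg must be nonnegative")
    return block


def parse_config(path) -> RunConfig:
    """Load and validate a run configuration, filling documented defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of blocks")
    stages = raw.pop("stages", [k for k in raw if k != "common"])
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown block(s): {sorted(unknown)}")
    blocks = {"common": _validated_block("common", raw.get("common", {}))}
    for name in stages:
        if name not in _SCHEMA:
            raise ConfigError(f"unknown stage {name!r}")
        blocks[name] = _validated_block(name, raw.get(name, {}))
    for required in ("physiology", "parameters"):
        p = blocks["common"][required]
        if p is not None and not Path(p).exists():
            raise ConfigError(f"common.{required} path does not exist: {p}")
    return RunConfig(stages=list(stages), blocks=blocks)


def default_config(stages=("simulate",)) -> RunConfig:
    return RunConfig(
        stages=list(stages),
        blocks={"common": dict(_SCHEMA["common"]),
                **{s: dict(_SCHEMA[s]) for s in stages}},
    )


def write_config(config: RunConfig, path) -> None:
    data = {"stages": config.stages, **config.blocks}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> tuple[int, dict]:
    """Execute the configured stages; returns (exit status, manifest)."""
    common = config["common"]
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    phys = (
        PhysiologyTable.from_csv(common["physiology"])
        if common["physiology"]
        else PhysiologyTable.default()
    )
    params = (
        PBPKParameters.from_csv(common["parameters"])
        if common["parameters"]
        else PBPKParameters.reference()
    )
    seed = common["seed"]
    manifest = {
        "version": __version__,
        "seed": seed,
        "stages": config.stages,
        "inputs": {k: common[k] for k in ("physiology", "parameters")},
        "outputs": {},
        "timings_s": {},
    }
    state: dict = {}
    try:
        for stage in config.stages:
            t0 = time.time()
            log.info("stage %s started", stage)
            _STAGE_RUNNERS[stage](config[stage], common, phys, params, outdir, seed, state)
            manifest["timings_s"][stage] = round(time.time() - t0, 3)
            log.info("stage %s finished in %.1f s", stage, manifest["timings_s"][stage])
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        log.error("stage %s failed: %s", stage, exc)
        log.removeHandler(fh)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    for p in sorted(outdir.glob("*")):
        if p.is_file() and p.name not in ("manifest.json", "run.log"):
            manifest["outputs"][p.name] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.removeHandler(fh)
    return 0, manifest


# ----------------------------------------------------------- stage runners


def _run_simulate(block, common, phys, params, outdir, seed, state):
    t_grid = np.round(np.arange(0, block["t_end"] + block["dt"] / 2, block["dt"]), 10)
    for dose in block["doses_mg"]:
        sim = simulate(params, phys, DoseSchedule.from_mg(dose), t_grid, common["solver"])
        sim.to_frame().to_csv(outdir / f"simulation_dose{dose:g}mg.csv", index=False)
        state.setdefault("simulations", {})[dose] = sim


def _run_synth(block, common, phys, params, outdir, seed, state):
    design = StudyDesign(
        doses_mg=tuple(block["doses_mg"]),
        n_animals=block["n_animals"],
        noise_sd=block["noise_sd"],
        seed=seed,
    )
    blood, biodist = generate_from_model(params, phys, design, seed=seed)
    blood.to_csv(outdir / "blood_pk.csv")
    biodist.to_csv(outdir / "biodistribution.csv")
    state["blood"], state["biodist"], state["design"] = blood, biodist, design


def _run_fit(block, common, phys, params, outdir, seed, state):
    if "blood" not in state:
        raise RuntimeError("fit requires a synth stage (or data files) before it")
    data = FittingData.from_datasets(state["blood"], state["biodist"])
    res = fit_three_stage(
        params, data, phys,
        dose_design=tuple(block["dose_design"]),
        fit_params=tuple(block["fit_params"]),
        n_sims_per_stage=block["n_sims"],
        seed=seed,
    )
    from .distributions import distributions_to_frame

    distributions_to_frame(res.final_dists).to_csv(outdir / "posterior_distributions.csv", index=False)
    res.ensemble.to_csv(outdir / "posterior_ensemble.csv")
    res.posterior_params.to_csv(outdir / "posterior_parameters.csv")
    state["mcis"] = res


def _run_sensitivity(block, common, phys, params, outdir, seed, state):
    records = nsc_table(
        params, phys,
        perturbation=block["perturbation"],
        dose_mg=block["dose_mg"],
        t_end=block["t_end"],
        solver_opts=common["solver"],
    )
    cvs = None
    if "mcis" in state:
        cvs = cv_table(state["mcis"].final_dists)
    sensitivity_frame(records, cvs).to_csv(outdir / "sensitivity.csv", index=False)


def _run_validate(block, common, phys, params, outdir, seed, state):
    if "mcis" not in state or "blood" not in state:
        raise RuntimeError("validate requires synth and fit stages before it")
    from .mcis import posterior_predict

    pred = posterior_predict(
        state["mcis"].final_dists, phys, block["dose_mg"], params,
        n=block["n_draws"], seed=seed,
    )
    holdout = HoldoutData.from_datasets(state["blood"], state["biodist"], dose_mg=block["dose_mg"])
    table, summary = validate_holdout(pred, holdout, z_threshold=block["z_threshold"])
    table.to_csv(outdir / "validation.csv", index=False)
    (outdir / "validation_summary.json").write_text(json.dumps(summary, indent=2))


def _run_quantify(block, common, phys, params, outdir, seed, state):
    from .quantify import half_life_from_samples, quantify_plate
    from .synth import read_plate

    if block["plate_dir"] is None:
        raise RuntimeError("quantify requires quantify.plate_dir")
    wells, layout = read_plate(block["plate_dir"])
    samples, curve = quantify_plate(wells, layout)
    samples.to_csv(outdir / "sample_concentrations.csv", index=False)
    half_life_from_samples(samples, per_animal=block["per_animal"]).to_csv(
        outdir / "half_life.csv", index=False
    )


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "synth": _run_synth,
    "fit": _run_fit,
    "sensitivity": _run_sensitivity,
    "validate": _run_validate,
    "quantify": _run_quantify,
}
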