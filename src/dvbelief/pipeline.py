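"""End-to-end pipeline orchestration with provenance.

A pipeline config names an ordered list of stages (generate, simulate,
regress, kl, gridsearch) with per-stage options and one global seed; every
stage writes delimited-text outputs into the run directory and the run ends
with a manifest linking each artifact to its inputs by content hash, so two
runs with the same config and seed are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import InvalidSpecError
from .gridsearch import parameter_grid, run_grid
from .io import read_trial_table, write_trial_table
from .klhist import normalized_history_kl
from .observer import ObserverParams, simulate_session
from .regression import PRESETS, build_design_matrix, fit_history_model
from .synth import AgentSpec, make_schedule, probit_agent

__all__ = ["PipelineConfig", "run_pipeline", "observer_params_from_config"]

_STAGES = ("generate", "simulate", "regress", "kl", "gridsearch")


@dataclass
class PipelineConfig:
    stages: list = field(default_factory=list)
    seed: int = 0
    outdir: str = "pipeline_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(stages=raw.get("stages", []),
                   seed=int(raw.get("seed", 0)),
                   outdir=raw.get("outdir", "pipeline_out"))

    def validate(self) -> None:
        for st in self.stages:
            if "stage" not in st:
                raise InvalidSpecError("every stage needs a 'stage' key")
            if st["stage"] not in _STAGES:
                raise InvalidSpecError(f"unknown stage {st['stage']!r}")


def observer_params_from_config(cfg: dict) -> ObserverParams:
    """Build observer parameters from a flat key-value mapping."""
    known = {"variant", "s0", "sigma_s0", "sigma_s", "sigma_mms",
             "sigma_leak", "sigma_v", "g", "b", "stim_update_mode",
             "dv_update_mode", "dv_likelihood_convention"}
    extra = set(cfg) - known
    if extra:
        raise InvalidSpecError(f"unknown observer parameters: {sorted(extra)}")
    return ObserverParams(**cfg)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "dvbelief_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": [],
    }
    last_table: Path | None = None
    for i, st in enumerate(config.stages):
        stage = st["stage"]
        opts = {k: v for k, v in st.items() if k != "stage"}
        out = outdir / opts.pop("out", f"stage{i}_{stage}.csv")
        seed = int(opts.pop("seed", config.seed))
        inputs = []
        if stage == "generate":
            schedule = make_schedule(opts.pop("template", "exp1"), seed=seed)
            spec = AgentSpec(beta=opts.pop("beta", {}), seed=seed)
            table = probit_agent(schedule, spec)
            write_trial_table(table, out)
            last_table = out
        elif stage == "simulate":
            params = observer_params_from_config(opts.pop("observer", {}))
            schedule = make_schedule(opts.pop("template", "exp1"), seed=seed)
            table = simulate_session(params, schedule, seed=seed)
            write_trial_table(table, out)
            last_table = out
        elif stage == "regress":
            src = Path(opts.pop("input", last_table))
            inputs.append(str(src))
            trials = read_trial_table(src)
            design = build_design_matrix(trials,
                                         PRESETS[opts.pop("preset", "eq1")])
            fit = fit_history_model(design)
            pd.DataFrame({
                "coefficient": fit.coefficients.index,
                "beta": fit.coefficients.values,
                "se": fit.std_errors.values,
                "p": fit.p_values.values,
                "q": fit.q_values.values,
            }).to_csv(out, index=False)
        elif stage == "kl":
            src = Path(opts.pop("input", last_table))
            inputs.append(str(src))
            trials = read_trial_table(src)
            frames = [normalized_history_kl(trials, int(g)).to_frame()
                      for g in sorted(trials["G"].dropna().unique())]
            pd.concat(frames, ignore_index=True).to_csv(out, index=False)
        elif stage == "gridsearch":
            variant = opts.pop("variant", "standard")
            grid = parameter_grid(variant, int(opts.pop("n_per_param", 3)))
            res = run_grid(variant, grid,
                           n_trials=int(opts.pop("n_trials", 500)),
                           n_reps=int(opts.pop("n_reps", 10)), seed=seed)
            res.to_csv(out, index=False)
        if opts:
            raise InvalidSpecError(
                f"unused options for stage {stage!r}: {sorted(opts)}")
        manifest["stages"].append({
            "stage": stage,
            "seed": seed,
            "inputs": [{"path": p, "sha256": _sha256(Path(p))}
                       for p in inputs],
            "output": {"path": str(out), "sha256": _sha256(out)},
        })
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
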