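"""Experiment configuration: validated YAML-driven sweeps.

An experiment file names one or more runs, each pairing a motif model (and
optional rate function) with a reference signal, a dose-conservation protocol
and a frequency grid.  Configurations are validated field-by-field before any
computation; presets shipped with the package are ordinary config files that
regenerate the data behind the study's figures.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError
from .models import MODEL_REGISTRY
from .rates import rate_function_from_spec
from .signals import PulseTrain
from .periodic import numeric_periodic_solution, solution_to_frame
from .response import sweep

__all__ = [
    "GridSpec",
    "SignalSpec",
    "ModelSpec",
    "RunSpec",
    "ExperimentConfig",
    "load_config",
    "load_preset",
    "list_presets",
    "run_experiment",
]

logger = logging.getLogger(__name__)

def _preset_dir():
    return resources.files("pulsemotif").joinpath("presets")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridSpec(_Strict):
    f_min: float = Field(1e-3, gt=0)
    f_max: float = Field(1e-1, gt=0)
    n: int = Field(25, ge=2)
    spacing: Literal["log", "linear"] = "log"

    @model_validator(mode="after")
    def _ordered(self):
        if self.f_min >= self.f_max:
            raise ValueError(f"f_min ({self.f_min}) must be below f_max ({self.f_max})")
        return self


class SignalSpec(_Strict):
    A0: float = Field(ge=0)
    d0: float = Field(gt=0)
    f0: float = Field(gt=0)

    @model_validator(mode="after")
    def _feasible(self):
        if self.d0 > 1.0 / self.f0:
            raise ValueError(
                f"reference duration d0 = {self.d0} exceeds the reference "
                f"period 1/f0 = {1.0 / self.f0}"
            )
        return self

    def train(self) -> PulseTrain:
        return PulseTrain(self.A0, self.d0, 1.0 / self.f0)


class ModelSpec(_Strict):
    name: str
    params: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _known(self):
        if self.name not in MODEL_REGISTRY:
            raise ValueError(
                f"unknown model {self.name!r}; known: {sorted(MODEL_REGISTRY)}"
            )
        return self

    def build(self, rate_function: Optional[str] = None):
        cls = MODEL_REGISTRY[self.name]
        params = dict(self.params)
        if "lambda" in params:  # YAML-friendly alias for the kinetic scale
            params["lam"] = params.pop("lambda")
        if self.name in ("b", "ab"):
            spec = rate_function or "hill2:K=1"
            params.setdefault("F", rate_function_from_spec(spec))
        try:
            return cls(**params)
        except (TypeError, ValueError) as err:
            raise ConfigError(f"invalid parameters for model {self.name!r}: {err}") from err


class RunSpec(_Strict):
    label: str
    model: ModelSpec
    signal: SignalSpec
    protocol: Literal["amplitude_compensated", "duration_compensated", "uncompensated"]
    rate_function: Optional[str] = None
    grid: Optional[GridSpec] = None
    with_on_phase_means: bool = False
    #: "sweep" = frequency response; "pulse_shape" = single-period dose
    #: trade-off scan of the b-model (amplitude vs duration at fixed period)
    kind: Literal["sweep", "pulse_shape"] = "sweep"
    #: also export one-period steady-state trajectories at these frequencies
    trajectory_frequencies: List[float] = Field(default_factory=list)

    @model_validator(mode="after")
    def _pulse_shape_is_b(self):
        if self.kind == "pulse_shape" and self.model.name != "b":
            raise ValueError("pulse_shape scans apply to the b model only")
        return self


class ExperimentConfig(_Strict):
    """Top-level experiment: shared grid plus one or more runs."""

    name: str
    description: str = ""
    grid: GridSpec = Field(default_factory=GridSpec)
    runs: List[RunSpec] = Field(min_length=1)
    output_dir: str = "results"
    mean_tol: float = Field(1e-8, gt=0)
    #: reserved; every computation in the pipeline is deterministic
    seed: int = 0


def load_config(source) -> ExperimentConfig:
    """Load and validate an experiment config from a YAML path or dict."""
    if isinstance(source, (str, Path)):
        try:
            data = yaml.safe_load(Path(source).read_text())
        except OSError as err:
            raise ConfigError(f"cannot read config {source!r}: {err}") from err
    else:
        data = source
    try:
        return ExperimentConfig.model_validate(data)
    except ValidationError as err:
        raise ConfigError(str(err)) from err


def list_presets() -> dict:
    """Preset names mapped to their descriptions, in sorted order."""
    out = {}
    for entry in _preset_dir().iterdir():
        if entry.name.endswith(".yaml"):
            data = yaml.safe_load(entry.read_text())
            out[data["name"]] = data.get("description", "")
    return dict(sorted(out.items()))


def load_preset(name: str) -> ExperimentConfig:
    ref = _preset_dir() / f"{name}.yaml"
    if not ref.is_file():
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(list_presets())}")
    return load_config(yaml.safe_load(ref.read_text()))


def run_experiment(config: ExperimentConfig, output_dir=None) -> List[Path]:
    """Execute every run in the config; write per-run response-curve CSVs with
    JSON sidecars (protocol, parameters, shape, peak) and optional one-period
    trajectory CSVs.  Returns the list of files written."""
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    for run in config.runs:
        model = run.model.build(run.rate_function)
        ref = run.signal.train()
        grid = run.grid or config.grid
        logger.info("run %s: model=%s protocol=%s A0=%g d0=%g f0=%g",
                    run.label, run.model.name, run.protocol,
                    ref.amplitude, ref.duration, ref.frequency)
        if run.kind == "pulse_shape":
            from .response import pulse_shape_scan

            df = pulse_shape_scan(model.F, ref, n=grid.n)
            csv_path = out / f"{run.label}.csv"
            df.to_csv(csv_path, index=False)
            written.append(csv_path)
            continue
        curve = sweep(model, run.protocol, ref, grid.f_min, grid.f_max, grid.n,
                      spacing=grid.spacing,
                      with_on_phase_means=run.with_on_phase_means)
        csv_path = out / f"{run.label}.csv"
        curve.to_csv(csv_path)
        meta = curve.metadata()
        meta["model_params"] = {k: v for k, v in run.model.params.items()}
        if run.rate_function:
            meta["rate_function"] = run.rate_function
        json_path = out / f"{run.label}.json"
        json_path.write_text(json.dumps(meta, indent=2) + "\n")
        written += [csv_path, json_path]
        logger.info("run %s: shape=%s%s", run.label, curve.shape,
                    f" peak_f={curve.peak[0]:g}" if curve.peak else "")

        from .signals import CompensationProtocol

        protocol = CompensationProtocol(run.protocol, ref)
        for f in run.trajectory_frequencies:
            train = protocol.train_at_frequency(f)
            sol = numeric_periodic_solution(model, train, tol=config.mean_tol)
            traj_path = out / f"{run.label}_trajectory_f{f:g}.csv"
            solution_to_frame(sol).to_csv(traj_path, index=False)
            written.append(traj_path)
    return written
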