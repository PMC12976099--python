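"""Experiment configuration: YAML/JSON loading, model construction, presets,
and the run manifest written next to every CLI output set."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version

import yaml

from .cohort import HIRID_LOS_CLASS_COUNTS, LOSDistribution, from_class_counts
from .predictors import (
    REFERENCE_CONFUSION_SPECS,
    ConfusionSpec,
    PredictorModel,
    emulator_from_confusion,
    load_prediction_table,
    naive_from_distribution,
)
from .simulator import SimulationConfig

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "load_experiment_config",
    "build_models",
    "replicate_reference_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised for malformed or inconsistent experiment configuration."""


@dataclass
class ExperimentConfig:
    """Everything one simulation experiment needs.

    ``model_specs`` is a list of dicts, each with a ``type`` key in
    {``naive``, ``emulator``, ``table``} plus type-specific parameters
    (emulator: ``sensitivity``/``specificity`` triples or ``reference`` —
    one of LRs/LRc/XGB; table: ``path`` and optional ``threshold``).
    """

    simulation: SimulationConfig
    distribution: LOSDistribution
    model_specs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "runs": self.simulation.runs,
            "horizon": self.simulation.horizon,
            "beds": self.simulation.beds,
            "reference_capacity": self.simulation.reference_capacity,
            "seed": self.simulation.seed,
            "class_counts": list(self.distribution.source_counts)
            if self.distribution.source_counts else None,
            "class_probs": list(self.distribution.probs),
            "models": self.model_specs,
        }


def _distribution_from_config(raw: dict) -> LOSDistribution:
    if raw.get("class_counts") is not None:
        return from_class_counts(raw["class_counts"])
    if raw.get("class_probs") is not None:
        return LOSDistribution(probs=tuple(raw["class_probs"]))
    return from_class_counts(HIRID_LOS_CLASS_COUNTS)


def load_experiment_config(path) -> ExperimentConfig:
    """Load a YAML or JSON experiment config; counts beat probabilities."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    sim = SimulationConfig(
        runs=int(raw.get("runs", 1000)),
        horizon=int(raw.get("horizon", 10)),
        beds=int(raw.get("beds", 50)),
        reference_capacity=int(raw.get("reference_capacity", 60)),
        seed=int(raw.get("seed", 0)),
    )
    models = raw.get("models", [])
    if not isinstance(models, list):
        raise ConfigError(f"{path}: 'models' must be a list")
    return ExperimentConfig(
        simulation=sim,
        distribution=_distribution_from_config(raw),
        model_specs=models,
    )


def build_models(cfg: ExperimentConfig) -> list[PredictorModel]:
    """Instantiate predictor models from their config dicts."""
    out = []
    for i, spec in enumerate(cfg.model_specs):
        kind = spec.get("type")
        name = spec.get("name")
        if kind == "naive":
            out.append(naive_from_distribution(cfg.distribution,
                                               name=name or "NP"))
        elif kind == "emulator":
            if "reference" in spec:
                ref = spec["reference"]
                if ref not in REFERENCE_CONFUSION_SPECS:
                    raise ConfigError(
                        f"model {i}: unknown reference {ref!r}; "
                        f"expected one of {sorted(REFERENCE_CONFUSION_SPECS)}"
                    )
                cs = REFERENCE_CONFUSION_SPECS[ref]
                name = name or ref
            else:
                try:
                    cs = ConfusionSpec(tuple(spec["sensitivity"]),
                                       tuple(spec["specificity"]))
                except KeyError as exc:
                    raise ConfigError(
                        f"model {i}: emulator needs sensitivity/specificity "
                        f"or reference (missing {exc})"
                    ) from exc
            out.append(emulator_from_confusion(
                cs, name=name or f"emulator{i}",
                coupling=spec.get("coupling", "independent")))
        elif kind == "table":
            if "path" not in spec:
                raise ConfigError(f"model {i}: table model needs a 'path'")
            out.append(load_prediction_table(
                spec["path"], threshold=float(spec.get("threshold", 0.5)),
                name=name or "table"))
        else:
            raise ConfigError(f"model {i}: unknown model type {kind!r}")
    return out


def replicate_reference_config(seed: int = 0, runs: int = 1000) -> ExperimentConfig:
    """The reference study conditions as a ready-made experiment.

    R runs × T = 10 steps × B = 50 beds on the HiRID LOS class mix; four
    models: the naive majority-class rule and confusion emulators for the
    simple/complex logistic lasso and the gradient-boosting classifier.
    """
    sim = SimulationConfig(runs=runs, horizon=10, beds=50,
                           reference_capacity=60, seed=seed)
    models = [{"type": "naive", "name": "NP"}] + [
        {"type": "emulator", "reference": ref} for ref in ("LRs", "LRc", "XGB")
    ]
    return ExperimentConfig(
        simulation=sim,
        distribution=from_class_counts(HIRID_LOS_CLASS_COUNTS),
        model_specs=models,
    )


@dataclass
class RunManifest:
    """Reproducibility record written alongside CLI outputs."""

    command: str
    config: dict
    seed: int
    outputs: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def __post_init__(self) -> None:
        if not self.started:
            self.started = time.strftime("%Y-%m-%dT%H:%M:%S")
        try:
            self.version = version("icusim")
        except PackageNotFoundError:  # running from a source tree
            self.version = "unknown"

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
        self.outputs.append(str(path))
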