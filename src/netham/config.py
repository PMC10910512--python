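"""Run configuration: YAML round trip with named validation and defaults.

Hyperparameter keys use the method's vocabulary (reps, noiseVarInit,
topFraction, maxSurvivors, fixEdge, fixEdgeValue, smartVar, smartPts,
useLineDensity, minLineDensity, childMax); an empty hyperparameter block
gets the typical values: reps=16, noiseVarInit=1.0, topFraction=0.25,
maxSurvivors=20, minLineDensity=1.2, childMax=100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .evolution import GAConfig
from .fibril_assay import TEMPLATES, FibrilTemplate
from .hamiltonian import ModelSpec, PhiVector
from .netstats import STAT_NAMES, StatSpec
from .sampler import SamplerConfig

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """Configuration failed validation; names the offending field."""

    def __init__(self, field_name: str, message: str) -> None:
        super().__init__(f"{field_name}: {message}")
        self.field_name = field_name


_GA_KEYS = {
    "reps", "noiseVarInit", "topFraction", "maxSurvivors", "fixEdge",
    "fixEdgeValue", "smartVar", "smartPts", "useLineDensity",
    "minLineDensity", "linearChildren", "childMax", "max_generations",
    "max_retries_per_generation", "seed_center", "seed_radius", "seed_count",
    "initial",
}
_SAMPLER_KEYS = {"burnin_proposals", "max_edges_guard", "chunk_size"}
_TOP_KEYS = {"model", "n_nodes", "reps", "master_seed", "template", "sampler", "ga", "output_dir"}


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulate/assay/evolve run."""

    model: ModelSpec | None = None
    preset: str | None = None  # set when the model came from a named preset
    n_nodes: int = 48
    reps: int = 16
    master_seed: int = 0
    template: FibrilTemplate | None = None
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    ga: dict[str, Any] = field(default_factory=dict)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ConfigError("n_nodes", "must be at least 2")
        if self.reps < 1:
            raise ConfigError("reps", "must be at least 1")

    def ga_config(self) -> GAConfig:
        """Materialize the GA hyperparameters against this run's model."""
        if self.model is None:
            raise ConfigError("model", "a model (preset or statistics+phi) is required")
        if self.template is None:
            raise ConfigError("template", "a fibril template is required to score fitness")
        kwargs = {
            k: v
            for k, v in self.ga.items()
            if k not in ("seed_center", "seed_radius", "seed_count", "initial")
        }
        kwargs.setdefault("reps", self.reps)
        return GAConfig(
            spec=self.model.spec,
            template=self.template,
            n_nodes=self.n_nodes,
            master_seed=self.master_seed,
            sampler=self.sampler,
            **kwargs,
        )


def _require_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = sorted(set(block) - allowed)
    if unknown:
        raise ConfigError(where, f"unknown keys {unknown}; allowed: {sorted(allowed)}")


def _parse_model(block: Any) -> tuple[ModelSpec, str | None]:
    from .presets import get_preset  # deferred: presets imports fibril_assay

    if isinstance(block, str):
        return get_preset(block), block
    if not isinstance(block, dict):
        raise ConfigError("model", "expected a preset name or a mapping")
    _require_keys(block, {"preset", "statistics", "phi", "kBT"}, "model")
    if "preset" in block:
        return get_preset(block["preset"]), block["preset"]
    try:
        spec = StatSpec(block["statistics"])
    except KeyError:
        raise ConfigError("model.statistics", "statistic list is required") from None
    except ValueError as exc:
        raise ConfigError("model.statistics", str(exc)) from None
    phi_block = block.get("phi")
    if not isinstance(phi_block, dict):
        raise ConfigError("model.phi", "mapping statistic -> coefficient is required")
    try:
        phi = PhiVector(spec, phi_block)
        return ModelSpec(spec=spec, phi=phi, kBT=float(block.get("kBT", 1.0))), None
    except ValueError as exc:
        raise ConfigError("model.phi", str(exc)) from None


def _parse_template(block: Any) -> FibrilTemplate:
    if isinstance(block, str):
        if block not in TEMPLATES:
            raise ConfigError(
                "template", f"unknown template {block!r}; known: {sorted(TEMPLATES)}"
            )
        return TEMPLATES[block]
    if not isinstance(block, dict):
        raise ConfigError("template", "expected a template name or a mapping")
    _require_keys(
        block, {"name", "strands", "edge_offsets", "min_units", "min_wrap_units"}, "template"
    )
    try:
        return FibrilTemplate(
            name=block.get("name", "custom"),
            strands=int(block["strands"]),
            edge_offsets=tuple(tuple(int(x) for x in rule) for rule in block["edge_offsets"]),
            min_units=int(block.get("min_units", 3)),
            min_wrap_units=int(block.get("min_wrap_units", 3)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError("template", str(exc)) from None


def from_dict(data: dict[str, Any]) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config", "top level must be a mapping")
    _require_keys(data, _TOP_KEYS, "config")

    model = None
    preset = None
    if "model" in data and data["model"] is not None:
        model, preset = _parse_model(data["model"])

    template = None
    if "template" in data and data["template"] is not None:
        template = _parse_template(data["template"])

    sampler_block = data.get("sampler") or {}
    _require_keys(sampler_block, _SAMPLER_KEYS, "sampler")
    try:
        sampler = SamplerConfig(**sampler_block)
    except (TypeError, ValueError) as exc:
        raise ConfigError("sampler", str(exc)) from None

    ga_block = data.get("ga")
    ga = dict(ga_block) if ga_block else {}
    _require_keys(ga, _GA_KEYS, "ga")
    for key in ("topFraction", "noiseVarInit", "minLineDensity"):
        if key in ga and not (isinstance(ga[key], (int, float)) and ga[key] > 0):
            raise ConfigError(f"ga.{key}", "must be a positive number")
    if "topFraction" in ga and ga["topFraction"] > 1:
        raise ConfigError("ga.topFraction", "must be in (0, 1]")

    try:
        return RunConfig(
            model=model,
            preset=preset,
            n_nodes=int(data.get("n_nodes", 48)),
            reps=int(data.get("reps", 16)),
            master_seed=int(data.get("master_seed", 0)),
            template=template,
            sampler=sampler,
            ga=ga,
            output_dir=data.get("output_dir"),
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError("config", str(exc)) from None


def to_dict(cfg: RunConfig) -> dict[str, Any]:
    data: dict[str, Any] = {
        "n_nodes": cfg.n_nodes,
        "reps": cfg.reps,
        "master_seed": cfg.master_seed,
    }
    if cfg.model is not None:
        if cfg.preset is not None:
            data["model"] = {"preset": cfg.preset}
        else:
            data["model"] = {
                "statistics": list(cfg.model.spec.names),
                "phi": cfg.model.phi.as_dict(),
                "kBT": cfg.model.kBT,
            }
    if cfg.template is not None:
        if cfg.template.name in TEMPLATES and TEMPLATES[cfg.template.name] == cfg.template:
            data["template"] = cfg.template.name
        else:
            data["template"] = {
                "name": cfg.template.name,
                "strands": cfg.template.strands,
                "edge_offsets": [list(rule) for rule in cfg.template.edge_offsets],
                "min_units": cfg.template.min_units,
                "min_wrap_units": cfg.template.min_wrap_units,
            }
    sampler: dict[str, Any] = {}
    defaults = SamplerConfig()
    for key in _SAMPLER_KEYS:
        value = getattr(cfg.sampler, key)
        if value != getattr(defaults, key):
            sampler[key] = value
    if sampler:
        data["sampler"] = sampler
    if cfg.ga:
        data["ga"] = dict(cfg.ga)
    if cfg.output_dir is not None:
        data["output_dir"] = cfg.output_dir
    return data


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        data = {}
    return from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config that round-trips losslessly through load_config."""
    Path(path).write_text(yaml.safe_dump(to_dict(cfg), sort_keys=True))
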