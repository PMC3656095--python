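"""Model configuration: parameters, validation, YAML round-trip.

The defaults reproduce the standard setting used throughout the study of
this model class: essential range R = 100, niche width sigma = 5, effects
uniform in [-1, 1], and a quasi-steady biota (biotic components relax much
faster than environmental variables, so abundances track their
environment-determined steady state).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .niches import DEFAULT_SHAPE_PARAMS, FAMILIES, NicheShape
from .protocols import PerturbationProtocol


@dataclass
class ModelConfig:
    K: int = 100
    n_env: int = 1
    essential_range: float = 100.0
    niche_width: float = 5.0
    niche_family: str = "gaussian"
    shape_params: dict = dataclasses.field(default_factory=dict)
    effect_bound: float = 1.0
    tau_env: float = 1.0
    tau_biotic: float = 0.01
    quasi_steady_biota: bool = True
    dt: float | None = None  # resolved to 0.01 * tau_env when unset
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError(f"K must be a positive integer, got {self.K}")
        if self.n_env < 1:
            raise ValueError(f"n_env must be a positive integer, got {self.n_env}")
        for key in ("essential_range", "niche_width", "effect_bound", "tau_env"):
            v = getattr(self, key)
            if not v > 0:
                raise ValueError(f"{key} must be positive, got {v}")
        if self.essential_range <= self.niche_width:
            raise ValueError(
                f"essential_range ({self.essential_range}) must exceed "
                f"niche_width ({self.niche_width})"
            )
        if self.niche_family not in FAMILIES:
            raise ValueError(f"unknown niche_family {self.niche_family!r}")
        if not self.quasi_steady_biota and not self.tau_biotic > 0:
            raise ValueError(f"tau_biotic must be positive, got {self.tau_biotic}")
        if self.dt is None:
            self.dt = 0.01 * self.tau_env
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    def niche_shape(self) -> NicheShape:
        return NicheShape(self.niche_family, self.niche_width,
                          tuple(self.shape_params.items()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunSpec:
    """A resolved run: model parameters plus an optional forcing protocol
    and free-form analysis options."""

    model: ModelConfig
    protocol: PerturbationProtocol | None = None
    analysis: dict = dataclasses.field(default_factory=dict)


_MODEL_KEYS = {f.name for f in dataclasses.fields(ModelConfig)}
_PROTOCOL_KEYS = {"kind", "base", "rate", "shock_time", "shock_magnitude",
                  "times", "values"}


def _build_protocol(d: dict, n_env: int) -> PerturbationProtocol:
    unknown = set(d) - _PROTOCOL_KEYS
    if unknown:
        raise ValueError(f"unknown protocol key(s): {sorted(unknown)}")
    kind = d.get("kind", "constant")
    if kind == "constant":
        return PerturbationProtocol.constant(d.get("base", 0.0), n_env)
    if kind == "linear_ramp":
        return PerturbationProtocol.linear_ramp(
            d.get("rate", 0.0), d.get("base", 0.0), n_env)
    if kind == "shock":
        return PerturbationProtocol.shock(
            d["shock_time"], d["shock_magnitude"], d.get("base", 0.0), n_env)
    if kind == "piecewise":
        return PerturbationProtocol.piecewise(d["times"], d["values"], n_env)
    raise ValueError(f"unknown protocol kind {kind!r}")


def load_config(path) -> RunSpec:
    """Load a YAML config; unknown keys are errors, missing keys take defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return parse_config(raw)


def parse_config(raw: dict) -> RunSpec:
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    sections = {"model", "protocol", "analysis"}
    # allow flat model keys at top level for convenience
    flat = {k: v for k, v in raw.items() if k not in sections}
    unknown = set(flat) - _MODEL_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    model_kwargs = dict(raw.get("model", {}))
    bad = set(model_kwargs) - _MODEL_KEYS
    if bad:
        raise ValueError(f"unknown model key(s): {sorted(bad)}")
    model_kwargs.update(flat)
    if "shape_params" in model_kwargs and model_kwargs["shape_params"] is None:
        model_kwargs["shape_params"] = {}
    model = ModelConfig(**model_kwargs)
    if model.shape_params:
        allowed = set(DEFAULT_SHAPE_PARAMS[model.niche_family])
        bad = set(model.shape_params) - allowed
        if bad:
            raise ValueError(f"unknown shape_params: {sorted(bad)}")
    protocol = None
    if raw.get("protocol") is not None:
        protocol = _build_protocol(dict(raw["protocol"]), model.n_env)
    analysis = dict(raw.get("analysis", {}))
    return RunSpec(model=model, protocol=protocol, analysis=analysis)


def dump_config(spec: RunSpec | ModelConfig, path=None) -> str:
    """Serialise to YAML (normalised: all defaults made explicit)."""
    if isinstance(spec, ModelConfig):
        doc = {"model": spec.to_dict()}
    else:
        doc = {"model": spec.model.to_dict()}
        if spec.protocol is not None:
            doc["protocol"] = spec.protocol.to_dict()
        if spec.analysis:
            doc["analysis"] = spec.analysis
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
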