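"""Model parameters: validation, presets and file I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, asdict
from pathlib import Path

import yaml

_FIELD_DOC = {
    "d1": "diffusion coefficient of the population (length^2/time)",
    "d2": "diffusion coefficient of the control variable (length^2/time)",
    "r": "intrinsic growth rate (1/time)",
    "K": "carrying-capacity scale",
    "a1": "instantaneous self-limitation weight",
    "a2": "delayed self-limitation weight",
    "c": "control-to-growth coupling",
    "b": "population-to-control production rate",
    "a": "control decay rate (1/time)",
    "l": "domain scale; the spatial domain is (0, l*pi)",
}


@dataclass(frozen=True)
class ModelParameters:
    """The ten positive constants of the delayed diffusive logistic model.

    All fields must be strictly positive; ``__post_init__`` enforces this.
    """

    d1: float
    d2: float
    r: float
    K: float
    a1: float
    a2: float
    c: float
    b: float
    a: float
    l: float

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not isinstance(value, (int, float)):
                raise TypeError(f"parameter {f.name!r} must be a number, got {type(value).__name__}")
            if not value > 0:
                raise ValueError(
                    f"parameter {f.name!r} must be strictly positive, got {value!r}"
                    f" ({_FIELD_DOC[f.name]})"
                )
            object.__setattr__(self, f.name, float(value))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        """Strict construction: every field required, unknown keys rejected."""
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = known - set(data)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**data)

    def replace(self, **kwargs) -> "ModelParameters":
        d = self.to_dict()
        d.update(kwargs)
        return ModelParameters.from_dict(d)


#: Named parameter sets.  "reference" is the set used throughout the worked
#: examples: d1=1, d2=0.5, r=0.6, a=b=c=1, a1=a2=2, K=1 on the domain (0, 2*pi).
PRESETS: dict[str, ModelParameters] = {
    "reference": ModelParameters(d1=1.0, d2=0.5, r=0.6, K=1.0, a1=2.0, a2=2.0, c=1.0, b=1.0, a=1.0, l=2.0),
}


def load_parameters(source: str | Path | dict) -> ModelParameters:
    """Load parameters from a preset name, a YAML/JSON file, or a dict."""
    if isinstance(source, dict):
        return ModelParameters.from_dict(source)
    if isinstance(source, str) and source in PRESETS:
        return PRESETS[source]
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"no such preset or parameter file: {source!r}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {source!r} must contain a flat mapping")
    return ModelParameters.from_dict(data)
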