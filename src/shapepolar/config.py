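"""Run configuration: a fully serializable description of one simulation.

A RunConfig bundles the geometry, parameter overrides, stimulus protocol
and solver settings.  Re-running the same config reproduces the run
bit-compatibly on the same platform — the model is fully deterministic
(the ``seed`` field is reserved for future stochastic extensions and is
unused).  Output files embed a short hash of the config for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields

import yaml

from .geometry import GeometryMask, import_mask, make_shape
from .model import ParameterSet
from .solver import SolverConfig
from .stimulus import StimulusProtocol

__all__ = ["RunConfig", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    shape: str = "teardrop"
    length: float = 50.0
    width: float = 30.0
    n_mesh: int = 110
    mask_image: str | None = None     # overrides the parametric outline
    pixel_size: float | None = None   # required with mask_image
    params: dict = field(default_factory=dict)      # ParameterSet overrides
    protocol: dict = field(default_factory=dict)    # StimulusProtocol overrides
    solver: dict = field(default_factory=dict)      # SolverConfig overrides
    scenario: str | None = None
    seed: int | None = None  # reserved; the model has no randomness

    def __post_init__(self) -> None:
        if self.seed is not None:
            log.info("config seed %s is reserved and unused (deterministic model)",
                     self.seed)

    # -- constructors -------------------------------------------------------

    def build_geometry(self) -> GeometryMask:
        if self.mask_image:
            if not self.pixel_size:
                raise ValueError("mask_image requires pixel_size")
            return import_mask(self.mask_image, self.pixel_size)
        return make_shape(self.shape, self.length, self.width, self.n_mesh)

    def build_params(self) -> ParameterSet:
        return ParameterSet(**self.params)

    def build_protocol(self) -> StimulusProtocol:
        proto = dict(self.protocol)
        if proto.get("duration") == "sustained":
            proto["duration"] = None
        return StimulusProtocol(**proto)

    def build_solver(self) -> SolverConfig:
        solver = dict(self.solver)
        if "record_times" in solver:
            solver["record_times"] = tuple(solver["record_times"])
        return SolverConfig(**solver)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def hash(self) -> str:
        """Short deterministic digest naming this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:10]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})
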