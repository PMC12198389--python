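"""Serializable run configuration.

A :class:`RunConfig` captures everything a scan or optimization run needs —
backend choice and parameters, external terms, alignment mode, optimizer
settings including the seed, and the scan grid — so that a run can be
re-executed bit-identically from its config echo.  Atom indices are 0-based
here and everywhere in the API (1-based only in human-readable reports).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import List, Optional

import yaml

from .backends import (BeadSpringFlex, HarmonicDiatomic, MullerBrown,
                       PotentialBackend, QuarticDoubleWell)
from .external import ExternalTerm, PullingForce, UniaxialCompression
from .optimize import OptimizationSettings

BACKENDS = {
    "quartic_double_well": QuarticDoubleWell,
    "muller_brown": MullerBrown,
    "bead_spring_flex": BeadSpringFlex,
    "harmonic_diatomic": HarmonicDiatomic,
}


def make_backend(name: str, params: Optional[dict] = None) -> PotentialBackend:
    if name not in BACKENDS:
        raise ValueError(f"unknown backend {name!r}; available: {sorted(BACKENDS)}")
    return BACKENDS[name](**(params or {}))


def make_term(spec: dict) -> ExternalTerm:
    """Build an external term from a config mapping.

    ``{"type": "uniaxial", "k": 50.0}`` (N m⁻¹) or
    ``{"type": "pulling", "magnitude": 2.0, "attachment_pair": [0, 2]}`` (nN).
    """
    kind = spec.get("type")
    if kind == "uniaxial":
        return UniaxialCompression(float(spec["k"]))
    if kind == "pulling":
        return PullingForce(float(spec["magnitude"]),
                            tuple(spec["attachment_pair"]))
    raise ValueError(f"unknown external term type {kind!r}")


@dataclass
class RunConfig:
    backend: str = "bead_spring_flex"
    backend_params: dict = field(default_factory=dict)
    terms: List[dict] = field(default_factory=list)
    align: str = "auto"
    settings: dict = field(default_factory=dict)
    force_grid_nn: Optional[List[float]] = None
    k_grid_npm: Optional[List[float]] = None
    attachment_pair: Optional[List[int]] = None
    seed: int = 0

    def make_backend(self) -> PotentialBackend:
        return make_backend(self.backend, self.backend_params)

    def make_terms(self) -> List[ExternalTerm]:
        return [make_term(t) for t in self.terms]

    def make_settings(self) -> OptimizationSettings:
        kwargs = dict(self.settings)
        kwargs.setdefault("seed", self.seed)
        return OptimizationSettings(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        return cls(**(data or {}))
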