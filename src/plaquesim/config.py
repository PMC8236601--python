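"""Configuration: YAML parsing, unit normalization and printed defaults.

Every physical parameter defaults to its literature value; a configuration
file only ever *overrides*. Values may be plain numbers (assumed SI, except
the mmHg-denominated pore-pressure table noted below) or ``"value unit"``
strings (``"100 mmHg"``, ``"0.7 mm"``, ``"30 year"``), converted at this
boundary so that the rest of the package is strictly SI. Unknown sections or
keys are rejected by name.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace

import yaml

from .errors import ConfigurationError, InvalidParameterError
from .growth import GrowthParams
from .haemo_fixtures import AtheropronePatch, BloodProperties, WaveformProfile
from .endothelium import LDLTransportParams, PoreModelParams
from .stimulus import MODES, CorrelationParams
from .units import MMHG, YEAR, UnitError, parse_quantity
from .wall_model import ReactionParams, SolverOptions

__all__ = ["GeometryConfig", "PatientConfig", "SimulationConfig",
           "validate_config", "config_hash"]


@dataclass
class GeometryConfig:
    """Idealized vessel segment: a straight wall strip along the axis."""

    length: float = 0.06         # axial extent (m)
    nx: int = 50                 # axial stations
    nr: int = 20                 # transmural cells
    thickness: float = 0.7e-3    # wall thickness (m), CCA-like
    lumen_radius: float = 2e-3   # healthy lumen radius (m)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.thickness <= 0 or self.lumen_radius <= 0:
            raise InvalidParameterError("geometry lengths must be > 0")
        if self.nx < 2 or self.nr < 3:
            raise InvalidParameterError("geometry needs nx >= 2 and nr >= 3")


@dataclass
class PatientConfig:
    """Patient-level assumptions (hypercholesterolemic defaults)."""

    c_ldl_lumen: float = 6.98        # lumen LDL (mol/m^3)
    c_m_lumen: float = 550e9         # lumen monocytes (cells/m^3)
    p_lumen: float = 100.0 * MMHG    # intraluminal pressure (Pa)
    horizon: float = 30.0 * YEAR     # simulated disease horizon (s)

    def __post_init__(self) -> None:
        if self.c_ldl_lumen < 0 or self.c_m_lumen < 0:
            raise InvalidParameterError("lumen concentrations must be >= 0")
        if self.p_lumen <= 0 or self.horizon <= 0:
            raise InvalidParameterError("pressure and horizon must be > 0")


#: section name -> (dataclass, keys excluded from config override)
_SECTIONS = {
    "geometry": (GeometryConfig, ()),
    "blood": (BloodProperties, ()),
    "waveform": (WaveformProfile, ()),
    "patch": (AtheropronePatch, ()),
    "pore": (PoreModelParams, ("dp_table",)),
    "ldl": (LDLTransportParams, ("c_ldl_lumen", "c_m_lumen", "partition_fn",
                                 "hindrance_fn", "reflection_fn")),
    "reaction": (ReactionParams, ()),
    "growth": (GrowthParams, ()),
    "correlation": (CorrelationParams, ()),
    "patient": (PatientConfig, ()),
    "solver": (SolverOptions, ()),
}

_SCALARS = {"mode", "seed", "tawss_factor_literal", "ldl_adventitia_bc"}


@dataclass
class SimulationConfig:
    """Fully normalized simulation configuration (all SI internally).

    Exceptions to strict SI, kept as the literature states them: the pore
    model's ``dp_table`` and ``p_adv`` are in mmHg (converted at use).
    """

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    blood: BloodProperties = field(default_factory=BloodProperties)
    waveform: WaveformProfile = field(default_factory=WaveformProfile)
    patch: AtheropronePatch | None = None
    pore: PoreModelParams = field(default_factory=PoreModelParams)
    ldl: LDLTransportParams = field(default_factory=LDLTransportParams)
    reaction: ReactionParams = field(default_factory=ReactionParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    correlation: CorrelationParams = field(default_factory=CorrelationParams)
    patient: PatientConfig = field(default_factory=PatientConfig)
    solver: SolverOptions = field(default_factory=SolverOptions)
    mode: str = "combined"
    seed: int = 0
    tawss_factor_literal: bool = False
    ldl_adventitia_bc: str = "outflow"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}")
        if self.ldl_adventitia_bc not in ("outflow", "dirichlet"):
            raise ConfigurationError(
                "ldl_adventitia_bc must be 'outflow' or 'dirichlet'"
            )
        # the lumen concentrations live in the patient block; mirror them
        # into the transport parameters used by the endothelium stage
        self.ldl = replace(self.ldl, c_ldl_lumen=self.patient.c_ldl_lumen,
                           c_m_lumen=self.patient.c_m_lumen)

    @property
    def p_lumen_mmhg(self) -> float:
        return self.patient.p_lumen / MMHG

    def to_dict(self) -> dict:
        out: dict = {}
        for name, (_, excluded) in _SECTIONS.items():
            obj = getattr(self, name)
            if obj is None:
                out[name] = None
                continue
            section = {}
            for f in fields(obj):
                if f.name in excluded or callable(getattr(obj, f.name)):
                    continue
                section[f.name] = getattr(obj, f.name)
            out[name] = section
        for name in _SCALARS:
            out[name] = getattr(self, name)
        return out


def _build_section(name: str, cls, excluded, raw: dict):
    if not isinstance(raw, dict):
        raise ConfigurationError(f"section {name!r} must be a mapping")
    allowed = {f.name for f in fields(cls)} - set(excluded)
    kwargs = {}
    for key, value in raw.items():
        if key not in allowed:
            raise ConfigurationError(f"unknown key {name}.{key}")
        if isinstance(value, str):
            try:
                value = parse_quantity(value, field=f"{name}.{key}")
            except UnitError as exc:
                raise ConfigurationError(str(exc)) from exc
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (InvalidParameterError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"section {name!r}: {exc}") from exc


def from_dict(raw: dict | None) -> SimulationConfig:
    """Build a normalized configuration from a raw mapping."""
    raw = dict(raw or {})
    kwargs: dict = {}
    for name, (cls, excluded) in _SECTIONS.items():
        if name in raw:
            section = raw.pop(name)
            if section is None:
                if name == "patch":
                    kwargs[name] = None
                    continue
                section = {}
            kwargs[name] = _build_section(name, cls, excluded, section)
    for name in _SCALARS:
        if name in raw:
            kwargs[name] = raw.pop(name)
    if raw:
        raise ConfigurationError(f"unknown configuration keys: {sorted(raw)}")
    return SimulationConfig(**kwargs)


def validate_config(path) -> SimulationConfig:
    """Read, validate and normalize a YAML configuration file.

    An empty file yields the full default configuration.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"invalid YAML in {path}: {exc}") from exc
    if raw is not None and not isinstance(raw, dict):
        raise ConfigurationError(f"top level of {path} must be a mapping")
    return from_dict(raw)


def config_hash(config: SimulationConfig) -> str:
    """Stable SHA-256 over the normalized configuration."""
    canon = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()
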