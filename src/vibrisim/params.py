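"""Model parameters and configuration.

All quantities are in millimetres, seconds and degrees.  A :class:`Params`
instance is the single source of truth for one simulation run: it carries the
reference parameter set of the salience-map whisking model (grid geometry,
whisker morphology ranges, excitation/inhibition gains, oscillator timing and
the protraction-control constants) together with validation of the invariants
each field must satisfy.

Whisker-specific parameters (length, curvature, nominal protraction angle,
whisking amplitude) are stored as ``(caudal, rostral)`` pairs and expanded to
one value per whisker by linear interpolation — whisker index 1 is the most
caudal (longest) whisker, index ``n_whiskers_per_side`` the most rostral.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Params",
    "ObstacleSpec",
    "ExperimentSpec",
    "RunConfig",
    "ParamError",
    "UnknownKeyError",
    "ValidationError",
    "per_whisker",
    "load_params",
    "load_config",
    "dump_params",
]


class ParamError(ValueError):
    """Base class for configuration errors."""


class UnknownKeyError(ParamError):
    """A key in the configuration source is not a recognised parameter."""

    def __init__(self, key: str):
        self.key = key
        super().__init__(f"unknown configuration key: {key!r}")


class ValidationError(ParamError):
    """A parameter value violates an invariant."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"invalid value for {field_name!r}: {message}")


def per_whisker(range_pair: Sequence[float], n: int) -> np.ndarray:
    """Expand a ``(caudal, rostral)`` value pair to ``n`` per-whisker values.

    Values are linearly spaced from the caudal value (whisker 1) to the
    rostral value (whisker ``n``), inclusive of both endpoints.
    """
    if n < 2:
        raise ValueError(f"need at least 2 whiskers to interpolate a range, got n={n}")
    a, b = float(range_pair[0]), float(range_pair[1])
    return np.linspace(a, b, n)


@dataclass(frozen=True)
class Params:
    """Reference parameter set of the model (lengths mm, times s, angles deg)."""

    grid_resolution: float = 2.0         # salience-map cell size, mm
    sample_dt: float = 1.0 / 125.0       # Euler integration step, s
    oscillator_period: float = 1.0 / 8.0  # whisk / attention-switch period, s
    fovea_neck_sep: float = 50.0         # head length from neck joint to snout tip, mm
    whisker_length_range: tuple[float, float] = (44.0, 8.0)        # mm, caudal->rostral
    whisker_curvature_range: tuple[float, float] = (-0.01, 0.08)   # 1/mm, caudal->rostral
    # Scale of the per-whisker sensing gain g_i = k_g * sqrt(L_i / 1 mm); the
    # default is set by calibrate_sensing_gain() so that the median nonzero
    # contact signal during arena exploration falls in [0.5, 0.8].
    sensing_gain_scale: float = 0.25
    deformation_dist: float = 5.0        # arc length at which bending deviation is read, mm
    tactile_blob_width: float = 8.0      # Gaussian width (2*sigma) of contact blobs, mm
    other_blob_width: float = 20.0       # Gaussian width of 'other'-channel blobs, mm
    other_gain: float = 0.5              # amplitude of 'other'-channel blobs
    noise_gain: float = 0.025            # excitation noise gain
    noise_bandwidth: float = 8.0         # excitation noise bandwidth, Hz
    ior_memory: float = 4.0              # inhibition-of-return memory length, s
    ior_width: float = 20.0              # Gaussian width of IOR blobs, mm
    ior_gain: float = 0.5                # amplitude of each IOR blob
    ior_max: float = 0.66                # cap on total IOR inhibition
    foveation_period: float = 0.175      # duration of one (interruptible) head movement, s
    theta_min: float = 30.0              # smallest allowed protraction angle, deg
    theta_max: float = 175.0             # largest allowed protraction angle, deg
    theta_imp: float = 0.0               # impingement angle offset, deg
    theta_nom_range: tuple[float, float] = (75.0, 145.0)   # nominal protraction, deg
    amplitude_range: tuple[float, float] = (30.0, 45.0)    # whisking amplitude, deg
    activity_gain: float = 2.0           # salience-activity weight gain (arbitration)
    activity_exponent: float = 2.0       # salience-activity weight exponent
    caudal_bias_base: float = 500.0      # base of the caudal-preference weight
    modulation_strength: float = 0.5     # gamma: strength of attentional modulation
    duty_cycle: float = 0.70             # protraction fraction of the whisk cycle
    whisk_tau: float = 0.025             # first-order whisking dynamic period, s
    n_whiskers_per_side: int = 7

    def __post_init__(self):
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        def positive(name):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValidationError(name, f"must be > 0, got {getattr(self, name)}")

        for name in (
            "grid_resolution", "sample_dt", "oscillator_period", "fovea_neck_sep",
            "deformation_dist", "tactile_blob_width", "other_blob_width",
            "ior_memory", "ior_width", "foveation_period", "whisk_tau",
            "sensing_gain_scale",
        ):
            positive(name)
        if self.theta_min >= self.theta_max:
            raise ValidationError("theta_min", "theta_min must be < theta_max")
        if not (0.0 <= self.modulation_strength <= 1.0):
            raise ValidationError(
                "modulation_strength",
                f"must lie in [0, 1], got {self.modulation_strength}")
        if not (0.0 < self.duty_cycle < 1.0):
            raise ValidationError("duty_cycle",
                                  f"must lie in (0, 1), got {self.duty_cycle}")
        if self.sample_dt >= self.oscillator_period:
            raise ValidationError("sample_dt",
                                  "must be smaller than oscillator_period")
        if not (0.0 < self.ior_max <= 1.0):
            raise ValidationError("ior_max", f"must lie in (0, 1], got {self.ior_max}")
        if self.n_whiskers_per_side < 2:
            raise ValidationError("n_whiskers_per_side", "must be >= 2")
        for name in ("whisker_length_range",):
            if min(getattr(self, name)) <= 0:
                raise ValidationError(name, "lengths must be > 0")

    # -- per-whisker expansions -----------------------------------------

    @property
    def whisker_lengths(self) -> np.ndarray:
        return per_whisker(self.whisker_length_range, self.n_whiskers_per_side)

    @property
    def whisker_curvatures(self) -> np.ndarray:
        return per_whisker(self.whisker_curvature_range, self.n_whiskers_per_side)

    @property
    def theta_nom(self) -> np.ndarray:
        return per_whisker(self.theta_nom_range, self.n_whiskers_per_side)

    @property
    def amplitudes(self) -> np.ndarray:
        return per_whisker(self.amplitude_range, self.n_whiskers_per_side)

    @property
    def sensing_gains(self) -> np.ndarray:
        """Per-whisker contact-signal gain, proportional to sqrt(length)."""
        return self.sensing_gain_scale * np.sqrt(self.whisker_lengths / 1.0)

    def replace(self, **updates: Any) -> "Params":
        return dataclasses.replace(self, **updates)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


_PAIR_FIELDS = {"whisker_length_range", "whisker_curvature_range",
                "theta_nom_range", "amplitude_range"}
_PARAM_FIELDS = {f.name for f in dataclasses.fields(Params)}


@dataclass(frozen=True)
class ObstacleSpec:
    """Oriented rectangular obstacle (world frame)."""

    cx_mm: float
    cy_mm: float
    width_mm: float
    height_mm: float
    angle_deg: float = 0.0

    def __post_init__(self):
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValidationError("obstacles", "obstacle extents must be > 0")


@dataclass(frozen=True)
class ExperimentSpec:
    """Experiment block of a run configuration."""

    name: str = "run"
    duration_s: float = 30.0
    seed: int = 0
    n_trials: int = 100

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValidationError("experiment.duration_s", "must be > 0")
        if self.n_trials < 1:
            raise ValidationError("experiment.n_trials", "must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Full parsed configuration: model parameters, world, experiment."""

    params: Params = field(default_factory=Params)
    obstacles: tuple[ObstacleSpec, ...] = ()
    experiment: ExperimentSpec = field(default_factory=ExperimentSpec)


def _coerce(name: str, value: Any) -> Any:
    if name in _PAIR_FIELDS:
        if not isinstance(value, (list, tuple)) or len(value) != 2:
            raise ValidationError(name, "expected a [caudal, rostral] pair")
        return (float(value[0]), float(value[1]))
    if name == "n_whiskers_per_side":
        return int(value)
    return float(value)


def load_params(source: str | Mapping[str, Any] | None = None) -> Params:
    """Build a :class:`Params` from flat key-value text (YAML) or a mapping.

    Unspecified keys take the reference defaults.  Unknown keys raise
    :class:`UnknownKeyError`; invariant violations raise
    :class:`ValidationError` naming the offending field.
    """
    if source is None:
        return Params()
    if isinstance(source, str):
        data = yaml.safe_load(source) or {}
    else:
        data = dict(source)
    if not isinstance(data, Mapping):
        raise ParamError("configuration source must be a key-value mapping")
    kwargs = {}
    for key, value in data.items():
        if key in ("obstacles", "experiment"):
            continue  # handled by load_config
        if key not in _PARAM_FIELDS:
            raise UnknownKeyError(key)
        kwargs[key] = _coerce(key, value)
    return Params(**kwargs)


def load_config(source: str | Mapping[str, Any] | None = None) -> RunConfig:
    """Parse a full run configuration (params + obstacles + experiment)."""
    if source is None:
        return RunConfig()
    if isinstance(source, str):
        data = yaml.safe_load(source) or {}
    else:
        data = dict(source)
    params = load_params(data)
    obstacles = []
    for i, ob in enumerate(data.get("obstacles") or []):
        if not isinstance(ob, Mapping):
            raise ParamError(f"obstacles[{i}] must be a mapping")
        allowed = {"cx_mm", "cy_mm", "width_mm", "height_mm", "angle_deg"}
        bad = set(ob) - allowed
        if bad:
            raise UnknownKeyError(f"obstacles[{i}].{sorted(bad)[0]}")
        obstacles.append(ObstacleSpec(**{k: float(v) for k, v in ob.items()}))
    exp_raw = data.get("experiment") or {}
    allowed = {"name", "duration_s", "seed", "n_trials"}
    bad = set(exp_raw) - allowed
    if bad:
        raise UnknownKeyError(f"experiment.{sorted(bad)[0]}")
    exp_kwargs: dict[str, Any] = dict(exp_raw)
    if "seed" in exp_kwargs:
        exp_kwargs["seed"] = int(exp_kwargs["seed"])
    if "n_trials" in exp_kwargs:
        exp_kwargs["n_trials"] = int(exp_kwargs["n_trials"])
    if "duration_s" in exp_kwargs:
        exp_kwargs["duration_s"] = float(exp_kwargs["duration_s"])
    experiment = ExperimentSpec(**exp_kwargs)
    return RunConfig(params=params, obstacles=tuple(obstacles), experiment=experiment)


def dump_params(params: Params) -> str:
    """Serialize a :class:`Params` to flat key-value text (round-trips)."""
    buf = io.StringIO()
    yaml.safe_dump(params.to_dict(), buf, sort_keys=True, default_flow_style=None)
    return buf.getvalue()
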