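"""Physiological parameters of the corticothalamic loop model.

The model couples five neural populations — cortical excitatory (``e``) and
inhibitory (``i``) neurons, the thalamic reticular nucleus (``r``), thalamic
relay (specific) nuclei (``s``), and external/retinal input (``n``) — through
dimensionless synaptic gains ``G_ab`` (response in ``a`` per unit input from
``b``), a common dendritic response with synaptic decay rate ``alpha`` and
rise rate ``beta``, cortical wave damping ``gamma_e``, and the two
conduction delays ``tau_es`` (thalamus to cortex) and ``tau_se`` (cortex to
thalamus).

Gains are treated as inputs (the nominal alert eyes-open adult set is the
default); the nonlinear steady-state problem that would produce them from
connection strengths is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Union

import yaml

__all__ = [
    "ParameterError",
    "SigmoidParams",
    "ModelParams",
    "POPULATIONS",
    "GAIN_KEYS",
    "sigmoid",
    "sigmoid_slope",
    "gain_from_strength",
    "load_parameters",
    "save_parameters",
    "default_parameters",
]

#: populations with dynamical fields (external drive ``n`` excluded)
POPULATIONS = ("e", "i", "r", "s")

#: ordered population pairs carrying a nonzero synaptic gain
GAIN_KEYS = ("ee", "ei", "ie", "ii", "es", "is", "se", "sr", "sn", "re", "rs")

_INHIBITORY = {"ei", "ii", "sr"}  # gains that must be <= 0

# random-connectivity identities: cortical synapse counts are proportional to
# the product of source and target population sizes, so these pairs share one
# strength.
_IDENTITIES = (("ee", "ie"), ("es", "is"), ("ei", "ii"))


class ParameterError(ValueError):
    """Raised when a physiological parameter is missing or out of range."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


def _check_positive(name: str, value: float) -> None:
    if not isinstance(value, (int, float)) or not math.isfinite(value):
        raise ParameterError(name, f"must be a finite number, got {value!r}")
    if value <= 0:
        raise ParameterError(name, f"must be > 0, got {value}")


def _check_nonnegative(name: str, value: float) -> None:
    if not isinstance(value, (int, float)) or not math.isfinite(value):
        raise ParameterError(name, f"must be a finite number, got {value!r}")
    if value < 0:
        raise ParameterError(name, f"must be >= 0, got {value}")


@dataclass(frozen=True)
class SigmoidParams:
    """Population firing-rate sigmoid: ``S(V) = Q_max / (1 + exp(-(V - theta)/sigma_prime))``.

    Parameters
    ----------
    q_max:
        Maximum mean firing rate (s^-1).
    theta:
        Mean firing threshold relative to rest (mV).
    sigma_prime:
        Spread of thresholds across the population (mV).
    """

    q_max: float = 250.0
    theta: float = 15.0
    sigma_prime: float = 3.3

    def __post_init__(self):
        _check_positive("q_max", self.q_max)
        _check_positive("sigma_prime", self.sigma_prime)
        if not math.isfinite(self.theta):
            raise ParameterError("theta", "must be finite")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set: rates, delays, gains and the firing sigmoid.

    All rates are s^-1, delays are seconds, voltages mV; gains are
    dimensionless. ``r_e`` is the characteristic excitatory axonal range and
    enters only through the product ``k * r_e`` in the cortical wave
    operator, so its value is irrelevant for the spatially uniform (k = 0)
    analyses.
    """

    alpha: float = 80.0
    beta: float = 320.0
    gamma_e: float = 100.0
    r_e: float = 0.086
    tau_es: float = 0.020
    tau_se: float = 0.060
    gains: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GAINS)
    )
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)
    #: skip the random-connectivity identity checks (for experimentation)
    allow_asymmetric: bool = False

    def __post_init__(self):
        _check_positive("alpha", self.alpha)
        _check_positive("beta", self.beta)
        _check_positive("gamma_e", self.gamma_e)
        _check_positive("r_e", self.r_e)
        _check_nonnegative("tau_es", self.tau_es)
        _check_nonnegative("tau_se", self.tau_se)
        gains = dict(self.gains)
        for key in GAIN_KEYS:
            if key not in gains:
                raise ParameterError(f"G_{key}", "missing gain")
            v = gains[key]
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ParameterError(f"G_{key}", f"must be finite, got {v!r}")
            if key in _INHIBITORY:
                if v > 0:
                    raise ParameterError(
                        f"G_{key}", f"inhibitory gain must be <= 0, got {v}"
                    )
            elif v < 0:
                raise ParameterError(
                    f"G_{key}", f"excitatory gain must be >= 0, got {v}"
                )
        if not self.allow_asymmetric:
            for a, b in _IDENTITIES:
                if not math.isclose(gains[a], gains[b], rel_tol=1e-12, abs_tol=1e-12):
                    raise ParameterError(
                        f"G_{b}",
                        f"random-connectivity identity G_{a} = G_{b} violated "
                        f"({gains[a]} != {gains[b]}); pass allow_asymmetric=True "
                        "to override",
                    )
        object.__setattr__(self, "gains", gains)

    def G(self, key: str) -> float:
        """Gain for the ordered population pair ``key`` (e.g. ``"es"``)."""
        return self.gains[key]


# Nominal alert, eyes-open adult gains. G_ii carries the sign of G_ei via the
# random-connectivity identity nu_ei = nu_ii (its tabulated magnitude is 8.1).
_DEFAULT_GAINS: Mapping[str, float] = {
    "ee": 6.8,
    "ei": -8.1,
    "ie": 6.8,
    "ii": -8.1,
    "es": 1.7,
    "is": 1.7,
    "se": 2.5,
    "sr": -1.9,
    "sn": 0.8,
    "re": 1.0,
    "rs": 0.19,
}


def default_parameters() -> ModelParams:
    """The nominal alert eyes-open parameter set."""
    return ModelParams()


def sigmoid(v, p: SigmoidParams):
    """Mean firing rate (s^-1) at mean membrane potential ``v`` (mV).

    Bounded in (0, q_max), monotone increasing, with ``S(theta) = q_max/2``.
    Accepts scalars or numpy arrays.
    """
    import numpy as np
    from scipy.special import expit

    x = (np.asarray(v, dtype=float) - p.theta) / p.sigma_prime
    out = p.q_max * expit(x)
    return out if out.ndim else float(out)


def sigmoid_slope(v, p: SigmoidParams):
    """Derivative dS/dV (s^-1 mV^-1); maximal at ``v = theta``.

    Computed in the numerically stable form
    ``q_max/(4 sigma') * sech^2(x/2)`` with ``x = (v - theta)/sigma'``.
    """
    import numpy as np

    x = (np.asarray(v, dtype=float) - p.theta) / p.sigma_prime
    out = p.q_max / (4.0 * p.sigma_prime) / np.cosh(x / 2.0) ** 2
    return out if out.ndim else float(out)


def gain_from_strength(rho: float, nu: float) -> float:
    """Dimensionless gain ``G_ab = rho_a * nu_ab``.

    ``rho`` is the sigmoid slope at the operating point (s^-1 mV^-1) and
    ``nu`` the overall connection strength (mV s); the sign of the gain
    follows the sign of ``nu``.
    """
    return rho * nu


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

ConfigSource = Union[str, Path, Mapping, None]


def _as_mapping(source: ConfigSource) -> Mapping:
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return source
    text = Path(source).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ParameterError("config", "top level must be a mapping")
    return data


def load_parameters(source: ConfigSource = None, **overrides) -> ModelParams:
    """Build a validated :class:`ModelParams` from a YAML/JSON config.

    The config has sections ``rates`` (alpha, beta, gamma_e, r_e), ``delays``
    (tau_es, tau_se; interpreted in ms unless ``units: s`` is given),
    ``gains`` (``G_ee`` ... keyed by ordered pair) and ``sigmoid`` (Q_max,
    theta, sigma_prime). Omitted keys fall back to the nominal defaults.
    ``source`` may be a path, an already-parsed mapping, or ``None`` for pure
    defaults.
    """
    data = _as_mapping(source)
    unknown = set(data) - {"rates", "delays", "gains", "sigmoid"}
    if unknown:
        raise ParameterError("config", f"unknown sections: {sorted(unknown)}")

    rates = dict(data.get("rates") or {})
    delays = dict(data.get("delays") or {})
    gains_in = dict(data.get("gains") or {})
    sig_in = dict(data.get("sigmoid") or {})

    units = str(delays.pop("units", "ms")).lower()
    if units not in ("ms", "s"):
        raise ParameterError("delays.units", f"must be 'ms' or 's', got {units!r}")
    scale = 1e-3 if units == "ms" else 1.0

    kw = {}
    for name in ("alpha", "beta", "gamma_e", "r_e"):
        if name in rates:
            kw[name] = rates.pop(name)
    if rates:
        raise ParameterError("rates", f"unknown keys: {sorted(rates)}")
    for name in ("tau_es", "tau_se"):
        if name in delays:
            v = delays.pop(name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ParameterError(name, f"must be a finite number, got {v!r}")
            kw[name] = v * scale
    if delays:
        raise ParameterError("delays", f"unknown keys: {sorted(delays)}")

    gains = dict(_DEFAULT_GAINS)
    for key, v in gains_in.items():
        k = key[2:] if key.startswith("G_") else key
        if k not in GAIN_KEYS:
            raise ParameterError(key, "unknown gain")
        gains[k] = v
    kw["gains"] = gains

    sig_kw = {}
    alias = {"Q_max": "q_max", "q_max": "q_max", "theta": "theta",
             "sigma_prime": "sigma_prime"}
    for key, v in sig_in.items():
        if key not in alias:
            raise ParameterError(f"sigmoid.{key}", "unknown sigmoid key")
        sig_kw[alias[key]] = v
    kw["sigmoid"] = SigmoidParams(**sig_kw)

    kw.update(overrides)
    return ModelParams(**kw)


def save_parameters(params: ModelParams, path: Union[str, Path]) -> None:
    """Write a config that :func:`load_parameters` round-trips exactly.

    Delays are written in ms (the conventional unit for these quantities).
    """
    doc = {
        "rates": {
            "alpha": params.alpha,
            "beta": params.beta,
            "gamma_e": params.gamma_e,
            "r_e": params.r_e,
        },
        "delays": {
            "units": "ms",
            "tau_es": params.tau_es * 1e3,
            "tau_se": params.tau_se * 1e3,
        },
        "gains": {f"G_{k}": params.gains[k] for k in GAIN_KEYS},
        "sigmoid": {
            "Q_max": params.sigmoid.q_max,
            "theta": params.sigmoid.theta,
            "sigma_prime": params.sigmoid.sigma_prime,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def with_gains(params: ModelParams, **gain_updates) -> ModelParams:
    """Return a copy of ``params`` with selected gains replaced."""
    gains = dict(params.gains)
    for key, v in gain_updates.items():
        k = key[2:] if key.startswith("G_") else key
        if k not in GAIN_KEYS:
            raise ParameterError(key, "unknown gain")
        gains[k] = v
    return replace(params, gains=gains)
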