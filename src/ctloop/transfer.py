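"""Exact (delay-bearing) corticothalamic transfer functions.

Linear perturbations about the steady state obey, in the spatial-Fourier /
temporal-Laplace domain,

    phi_r = G_re L e^{-s tau_se} phi_e + G_rs L phi_s
    phi_s = G_se L e^{-s tau_se} phi_e + G_sr L phi_r + G_sn L phi_n
    D_e(k,s) phi_e = G_ee L phi_e + G_ei L phi_i + G_es L e^{-s tau_es} phi_s
    phi_i = G_ii L phi_i + G_ie L phi_e + G_is L e^{-s tau_es} phi_s

with the dendritic filter L(s) = 1/((1 + s/alpha)(1 + s/beta)) and the
cortical damped-wave operator D_e(k,s) = (1 + s/gamma_e)^2 + k^2 r_e^2.
Eliminating populations yields closed forms built from the blocks

    M = D_e (1 - G_ei L) - G_ee L          (cortical loop)
    U = 1 - G_sr G_rs L^2                  (intrathalamic loop)
    R = G_sn L                             (input stage)
    P = G_se L + G_sr G_re L^2             (corticothalamic feedback)
    N = G_es L                             (thalamocortical projection)
    O = 1 - G_ii L
    V = G_ie L N + G_is L M
    W = G_re L N e^{-s(tau_es+tau_se)} + G_rs L M

so that with D = M U - N P e^{-s(tau_es+tau_se)}:

    T_sn = M R / D
    T_en = N R e^{-s tau_es} / D
    T_in = V R e^{-s tau_es} / (O D)
    T_rn = W R / D

The delay exponentials are kept exact here; rational approximation lives in
:mod:`ctloop.ratfit`. Responses are evaluated at s = +i 2 pi f on the
imaginary axis; all coefficients are real, so conjugate symmetry
T(conj(s)) = conj(T(s)) holds and magnitudes are independent of the sign
convention for the Fourier kernel.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .model import ModelParams, POPULATIONS

__all__ = [
    "BlockValues",
    "TransferModel",
    "FrequencyResponse",
    "dendritic_filter",
    "wave_operator",
    "build_blocks",
    "transfer_function",
    "frequency_response",
    "find_magnitude_peaks",
]


def dendritic_filter(s, alpha: float, beta: float):
    """Second-order dendritic low-pass L(s) = 1/((1 + s/alpha)(1 + s/beta)).

    ``alpha`` is the synaptic decay rate and ``beta`` the rise rate (s^-1);
    L(0) = 1 and |L| -> 0 as |s| -> infinity.
    """
    s = np.asarray(s, dtype=complex)
    out = 1.0 / ((1.0 + s / alpha) * (1.0 + s / beta))
    return out if out.ndim else complex(out)


def wave_operator(k: float, s, gamma: float, r: float):
    """Damped-wave operator D(k, s) = (1 + s/gamma)^2 + k^2 r^2."""
    s = np.asarray(s, dtype=complex)
    out = (1.0 + s / gamma) ** 2 + (k * r) ** 2
    return out if out.ndim else complex(out)


@dataclass(frozen=True)
class BlockValues:
    """Values of the algebraic blocks at one complex frequency.

    Delay exponentials are *not* folded in (``W`` is reported in its
    delay-free form ``G_re L N + G_rs L M``); the closed-loop assembly in
    :class:`TransferModel` applies the conduction-delay phases.
    """

    M: complex
    U: complex
    R: complex
    N: complex
    P: complex
    O: complex
    V: complex
    W: complex
    L: complex
    Dee: complex


def build_blocks(params: ModelParams, s, k: float = 0.0) -> BlockValues:
    """Evaluate all elimination blocks at complex frequency ``s``."""
    G = params.G
    L = dendritic_filter(s, params.alpha, params.beta)
    Dee = wave_operator(k, s, params.gamma_e, params.r_e)
    M = Dee * (1.0 - G("ei") * L) - G("ee") * L
    U = 1.0 - G("sr") * G("rs") * L * L
    R = G("sn") * L
    P = G("se") * L + G("sr") * G("re") * L * L
    N = G("es") * L
    O = 1.0 - G("ii") * L
    V = G("ie") * L * N + G("is") * L * M
    W = G("re") * L * N + G("rs") * L * M
    return BlockValues(M=M, U=U, R=R, N=N, P=P, O=O, V=V, W=W, L=L, Dee=Dee)


@dataclass(frozen=True)
class TransferModel:
    """Exactly evaluable transfer function ``T_an(k, s)`` to population ``a``.

    ``target`` is one of ``e, i, r, s``; the input is always the external
    field ``n``. Callable on complex scalars or arrays.
    """

    target: str
    params: ModelParams
    k: float = 0.0

    def __post_init__(self):
        if self.target not in POPULATIONS:
            raise ValueError(
                f"unknown target {self.target!r}; expected one of {POPULATIONS}"
            )

    def __call__(self, s):
        s = np.asarray(s, dtype=complex)
        p = self.params
        G = p.G
        L = dendritic_filter(s, p.alpha, p.beta)
        Dee = wave_operator(self.k, s, p.gamma_e, p.r_e)
        M = Dee * (1.0 - G("ei") * L) - G("ee") * L
        U = 1.0 - G("sr") * G("rs") * L * L
        R = G("sn") * L
        P = G("se") * L + G("sr") * G("re") * L * L
        N = G("es") * L
        e_es = np.exp(-s * p.tau_es)
        e_loop = np.exp(-s * (p.tau_es + p.tau_se))
        D = M * U - N * P * e_loop
        if self.target == "s":
            out = M * R / D
        elif self.target == "e":
            out = N * R * e_es / D
        elif self.target == "i":
            O = 1.0 - G("ii") * L
            V = G("ie") * L * N + G("is") * L * M
            out = V * R * e_es / (O * D)
        else:  # r
            W = G("re") * L * N * e_loop + G("rs") * L * M
            out = W * R / D
        return out if out.ndim else complex(out)

    def at_frequency(self, f_hz):
        """Evaluate on the imaginary axis at ``s = i 2 pi f``."""
        return self(1j * 2.0 * np.pi * np.asarray(f_hz, dtype=float))


def transfer_function(
    params: ModelParams, target: str, k: float = 0.0
) -> TransferModel:
    """Closed-loop transfer function from external input to ``target``."""
    return TransferModel(target=target, params=params, k=k)


def transfer_es(params: ModelParams, k: float = 0.0):
    """Open cortical stage T_es(s) = (N/M) e^{-s tau_es} (thalamus to cortex)."""

    def _eval(s):
        b = build_blocks(params, s, k)
        return b.N / b.M * np.exp(-np.asarray(s, dtype=complex) * params.tau_es)

    return _eval


def _fingerprint(params: ModelParams, k: float) -> str:
    doc = {
        "alpha": params.alpha,
        "beta": params.beta,
        "gamma_e": params.gamma_e,
        "r_e": params.r_e,
        "tau_es": params.tau_es,
        "tau_se": params.tau_se,
        "gains": dict(sorted(params.gains.items())),
        "k": k,
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:12]


@dataclass(frozen=True)
class FrequencyResponse:
    """Sampled complex response on a strictly increasing frequency grid (Hz)."""

    frequencies: np.ndarray
    values: np.ndarray
    target: str = ""
    metadata: dict | None = None

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        v = np.asarray(self.values, dtype=complex)
        if f.ndim != 1 or v.shape != f.shape:
            raise ValueError("frequencies and values must be 1-d and equal length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "values", v)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write columns f_hz, re, im, abs with a metadata comment header."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "f_hz": self.frequencies,
                "re": self.values.real,
                "im": self.values.imag,
                "abs": self.magnitude,
            }
        )
        header = "# " + json.dumps(
            {"target": self.target, **(self.metadata or {})}, sort_keys=True
        )
        with open(path, "w") as fh:
            fh.write(header + "\n")
            df.to_csv(fh, index=False)


def frequency_response(tm: TransferModel, f_grid) -> FrequencyResponse:
    """Evaluate ``tm`` on the imaginary axis over ``f_grid`` (Hz)."""
    f = np.asarray(f_grid, dtype=float)
    if not np.all(np.isfinite(f)) or np.any(f < 0):
        raise ValueError("frequency grid must be finite and non-negative")
    return FrequencyResponse(
        frequencies=f,
        values=tm.at_frequency(f),
        target=tm.target,
        metadata={"params": _fingerprint(tm.params, tm.k)},
    )


def find_magnitude_peaks(fr: FrequencyResponse, f_lo: float = 0.0,
                         f_hi: float = np.inf) -> np.ndarray:
    """Frequencies of interior local maxima of |T| within [f_lo, f_hi].

    A strict three-point local-maximum test on the sampled grid; returns an
    empty array when the magnitude is monotone over the window (a resonance
    that appears only as a shoulder is not reported here — use the band
    filter characterization for those).
    """
    m = fr.magnitude
    f = fr.frequencies
    idx = np.where((m[1:-1] > m[:-2]) & (m[1:-1] > m[2:]))[0] + 1
    sel = (f[idx] >= f_lo) & (f[idx] <= f_hi)
    return f[idx[sel]]
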