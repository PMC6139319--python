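"""Second-order predictive (PID-equivalent) filters from pole pairs.

Each pole pair (two real poles or one conjugate pair) of a pole-residue
model defines a partial transfer function

    T_J(s) = K (s + 1/tau_p) / ((s + p_j)(s + p_j+1)),

with p_j = -lambda_j the classical (positive-damping) pole bookkeeping,

    K     = r_j + r_j+1                       (gain)
    tau_p = (r_j + r_j+1)/(r_j p_j+1 + r_j+1 p_j)   (prediction time).

T_J factors into a second-order low-pass convolution stage
G(s) = K/((s+p_j)(s+p_j+1)) = (K/Omega_0^2) * Omega_0^2/(s^2 + 2 zeta
Omega_0 s + Omega_0^2) followed by the proportional-plus-derivative stage
H(s) = s + 1/tau_p, which linearly extrapolates the smoothed signal a time
tau_p into the future: the whole pair acts as a continuous-time serial PID
controller. Standard second-order quantities:

    Omega_0^2 = p_j p_j+1,   2 zeta Omega_0 = p_j + p_j+1,
    Gamma+- = -(zeta +- sqrt(zeta^2 - 1)) Omega_0        (overdamped)
    Omega_c = Omega_0 sqrt(1 - zeta^2)                   (underdamped)
    Omega_peak = Omega_0 sqrt(1 - 2 zeta^2)  for zeta < 1/sqrt(2), else 0
    M_peak = 1/(2 zeta sqrt(1 - zeta^2))     for zeta < 1/sqrt(2), else 1.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ratfit import BandDecomposition, PoleResidueModel

__all__ = [
    "SecondOrderFilter",
    "FilterCharacteristics",
    "pair_to_second_order",
    "characterize",
    "prediction_time",
    "impulse_response",
    "predict",
    "pid_output",
    "identify_bands",
]

_SQRT_HALF = 1.0 / math.sqrt(2.0)


@dataclass(frozen=True)
class SecondOrderFilter:
    """One pole pair in second-order form.

    ``poles``/``residues`` hold the underlying s-plane pair (conjugate pairs
    expanded); ``K`` and ``tau_p`` follow the pair-sum conventions above.
    ``K`` is the numerator gain of T_J; the low-frequency gain of the
    convolution stage alone is ``K / omega0**2``.
    """

    K: float
    tau_p: float
    omega0: float
    zeta: float
    band: str
    poles: tuple
    residues: tuple

    @property
    def dc_gain(self) -> float:
        """Zero-frequency gain of the full pair, K/(tau_p * omega0^2)."""
        return self.K / (self.tau_p * self.omega0**2)

    def __call__(self, s):
        """Evaluate the pair's rational response sum r_j/(s - lambda_j)."""
        s = np.asarray(s, dtype=complex)
        out = np.zeros_like(s)
        for lam, r in zip(self.poles, self.residues):
            out = out + r / (s - lam)
        return out.real + 1j * out.imag if out.ndim else complex(out)


@dataclass(frozen=True)
class FilterCharacteristics:
    """Resonance/damping summary of a second-order filter (rates in s^-1)."""

    Gamma_minus: float  # slow damping rate (overdamped) or pair damping rate
    Gamma_plus: float   # fast damping rate; equals Gamma_minus when underdamped
    Omega_c: float      # cut-off (damped oscillation) frequency; 0 if overdamped
    B: float            # bandwidth, 2 zeta Omega_0
    Omega_peak: float   # resonance frequency; 0 for zeta >= 1/sqrt(2)
    M_peak: float       # resonance magnitude of the normalized stage
    K: float
    zeta: float
    omega0: float
    tau_p: float
    band: str


def _pair_arrays(poles: Sequence[complex], residues: Sequence[complex]):
    lam = np.asarray(poles, dtype=complex)
    res = np.asarray(residues, dtype=complex)
    if lam.shape != (2,) or res.shape != (2,):
        raise ValueError("expected exactly two poles and two residues")
    conj_pair = np.isclose(lam[0], np.conj(lam[1])) and np.isclose(
        res[0], np.conj(res[1])
    )
    both_real = abs(lam[0].imag) < 1e-9 and abs(lam[1].imag) < 1e-9
    if not (conj_pair or both_real):
        raise ValueError(
            "poles/residues must form a conjugate pair or be both real"
        )
    if np.any(lam.real >= 0):
        raise ValueError("pole pair must be stable (Re lambda < 0)")
    return lam, res


def _expand(m: PoleResidueModel):
    """(poles, residues) with conjugate partners expanded, as 2-vectors."""
    lam, res = [], []
    for z, r in zip(m.poles, m.residues):
        lam.append(z)
        res.append(r)
        if z.imag > 0:
            lam.append(np.conj(z))
            res.append(np.conj(r))
    return np.array(lam), np.array(res)


def prediction_time(residues, poles):
    """Exact prediction time of a pair plus its small-damping approximation.

    Returns ``(tau_exact, tau_smallzeta)`` where the exact value is
    ``(r_j + r_j+1)/(r_j p_j+1 + r_j+1 p_j)`` and the approximation is
    ``tau_p Omega_0 ~ Re(r)/Im(r)`` (valid for lightly damped conjugate
    pairs). The approximation is ``nan`` when inapplicable (real poles or
    purely real residues).
    """
    lam, res = _pair_arrays(poles, residues)
    p = -lam  # classical positive-damping poles
    K = res[0] + res[1]
    denom = res[0] * p[1] + res[1] * p[0]
    if abs(K) < 1e-300:
        raise ZeroDivisionError("zero pair gain K; prediction time undefined")
    if abs(denom) < 1e-300:
        raise ZeroDivisionError("vanishing denominator in prediction time")
    tau = K / denom
    tau_exact = float(tau.real)

    approx = float("nan")
    # small-damping limit tau_p Omega_0 ~ -Re(r)/Im(r) for the residue at
    # the Im(lambda) > 0 pole (the sign flips relative to the classical
    # p = -lambda bookkeeping, where the same pole is written Gamma - i Omega_c)
    idx = int(np.argmax(lam.imag))
    if lam[idx].imag > 0 and abs(res[idx].imag) > 1e-300:
        omega0 = abs(lam[idx])
        approx = -(res[idx].real / res[idx].imag) / omega0
    return tau_exact, approx


def pair_to_second_order(
    poles, residues, band: str = ""
) -> SecondOrderFilter:
    """Convert a pole pair and its residues into a second-order filter."""
    lam, res = _pair_arrays(poles, residues)
    p = -lam
    omega0_sq = p[0] * p[1]
    omega0 = float(np.sqrt(omega0_sq).real)
    zeta = float(((p[0] + p[1]) / (2 * omega0)).real)
    K = res[0] + res[1]
    tau_exact, _ = prediction_time(res, lam)
    return SecondOrderFilter(
        K=float(K.real),
        tau_p=tau_exact,
        omega0=omega0,
        zeta=zeta,
        band=band,
        poles=tuple(lam),
        residues=tuple(res),
    )


def filter_from_parameters(
    K: float, tau_p: float, omega0: float, zeta: float, band: str = ""
) -> SecondOrderFilter:
    """Inverse of :func:`pair_to_second_order`: rebuild the pole pair and
    residues from (K, tau_p, Omega_0, zeta)."""
    disc = cmath.sqrt(zeta**2 - 1.0)
    p1 = (zeta - disc) * omega0
    p2 = (zeta + disc) * omega0
    # residues solve r1 + r2 = K, r1 p2 + r2 p1 = K/tau_p
    r1 = (K / tau_p - K * p1) / (p2 - p1)
    r2 = K - r1
    return pair_to_second_order([-p1, -p2], [r1, r2], band=band)


def characterize(f: SecondOrderFilter) -> FilterCharacteristics:
    """All resonance/damping characteristics of a second-order filter."""
    z, w0 = f.zeta, f.omega0
    if z >= 1.0:
        root = math.sqrt(z * z - 1.0)
        gm = (z - root) * w0  # slow (dominant) damping rate
        gp = (z + root) * w0
        omega_c = 0.0
    else:
        gm = gp = z * w0
        omega_c = w0 * math.sqrt(1.0 - z * z)
    if z < _SQRT_HALF:
        omega_peak = w0 * math.sqrt(1.0 - 2.0 * z * z)
        m_peak = 1.0 / (2.0 * z * math.sqrt(1.0 - z * z))
    else:
        omega_peak = 0.0
        m_peak = 1.0
    return FilterCharacteristics(
        Gamma_minus=gm,
        Gamma_plus=gp,
        Omega_c=omega_c,
        B=2.0 * z * w0,
        Omega_peak=omega_peak,
        M_peak=m_peak,
        K=f.K,
        zeta=z,
        omega0=w0,
        tau_p=f.tau_p,
        band=f.band,
    )


def impulse_response(f: SecondOrderFilter, t_grid):
    """Impulse responses of the convolution stage and the full pair.

    Returns ``(stage, full)`` sampled on ``t_grid`` (seconds, >= 0):

    * ``stage`` — the second-order low-pass G(s) = K/((s+p1)(s+p2)):
      a difference of exponentials when overdamped, a damped sine
      (K/Omega_c) exp(-zeta Omega_0 t) sin(Omega_c t) when underdamped.
    * ``full`` — the complete pair sum r1 e^{lambda1 t} + r2 e^{lambda2 t},
      i.e. 2|r| exp(-zeta Omega_0 t) cos(Omega_c t + arg r) for a conjugate
      pair. Its envelope decays at rate zeta Omega_0 and full(0) = K.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_grid must be non-negative")
    lam = np.asarray(f.poles)
    res = np.asarray(f.residues)
    full = np.sum(
        [r * np.exp(z * t) for z, r in zip(lam, res)], axis=0
    ).real
    if f.zeta >= 1.0:
        p1, p2 = sorted((-lam).real)
        if abs(p2 - p1) < 1e-12:
            stage = f.K * t * np.exp(-p1 * t)
        else:
            stage = f.K * (np.exp(-p1 * t) - np.exp(-p2 * t)) / (p2 - p1)
    else:
        omega_c = f.omega0 * math.sqrt(1.0 - f.zeta**2)
        stage = (
            f.K / omega_c * np.exp(-f.zeta * f.omega0 * t) * np.sin(omega_c * t)
        )
    return stage, full


def predict(signal, tau_p: float, dt: float):
    """Linear extrapolation ``tau_p`` ahead: ``phi + tau_p * dphi/dt``.

    The derivative uses central differences in the interior and one-sided
    differences at the edges; ``dt`` is the uniform sampling interval.
    Constants pass through unchanged; a ramp t maps to t + tau_p.
    """
    x = np.asarray(signal, dtype=float)
    return x + tau_p * np.gradient(x, dt)


def pid_output(stimulus, f: SecondOrderFilter, dt: float):
    """Time-domain serial-PID response of the pair to a sampled stimulus.

    Implements (d/dt + 1/tau_p) applied to the convolution-stage output,
    scaled by 1/tau_p's companion factor so the result equals the direct
    simulation of the 2-pole rational filter: the full pair output
    phi_J = d(phi_I)/dt + phi_I/tau_p with phi_I the stage response.
    """
    from .simulate import _simulate_modes

    u = np.asarray(stimulus, dtype=float)
    # stage G(s) = K/((s+p1)(s+p2)) in partial fractions over the pair
    lam = np.asarray(f.poles)
    if abs(lam[0] - lam[1]) < 1e-12:
        raise ValueError("degenerate pole pair")
    g1 = f.K / (lam[0] - lam[1])
    stage = _simulate_modes(u, dt, [(lam[0], g1), (lam[1], -g1)])
    return np.gradient(stage, dt) + stage / f.tau_p


def identify_bands(bd: BandDecomposition) -> dict:
    """Second-order filters for each band of a decomposition."""
    out = {}
    for name, sub in bd:
        lam, res = _expand(sub)
        out[name] = pair_to_second_order(lam, res, band=name)
    return out
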