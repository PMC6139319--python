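"""Stable pole-residue approximation of sampled frequency responses.

The delay-bearing transfer functions of :mod:`ctloop.transfer` are
transcendental; control-systems analysis needs rational models

    T(s) ~= sum_j r_j / (s - lambda_j),   Re(lambda_j) < 0,

with poles stored as s-plane locations ``lambda_j`` (left half-plane). The
classical bookkeeping ``p_j = -lambda_j`` (positive damping rates) is used
when reporting filter characteristics.

Fitting is a two-stage, fully deterministic procedure:

1. *Vector fitting* (iterative rational least squares with pole relocation
   via the sigma-function eigenvalue step, unstable poles reflected into the
   left half-plane) at a base order, initialized from log-spaced real poles
   plus lightly damped pairs seeded near the known 9 and 18 Hz corticothalamic
   resonances.
2. *Modal truncation* when a lower order is requested: the least-damped /
   highest-energy poles (score |r_j| / |Re lambda_j|, conjugate pairs kept
   together) are retained and the residues re-fit by linear least squares.
   This preserves the physical low/alpha/beta mode structure that band
   decomposition relies on.

The fit quality measure is the rms fractional error
``rms(|T_fit - T|) / rms(|T|)`` over the sampled grid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from scipy.linalg import block_diag, lstsq

from .transfer import FrequencyResponse

__all__ = [
    "PoleResidueModel",
    "BandDecomposition",
    "RationalFitError",
    "fit_rational",
    "evaluate_pole_residue",
    "rms_fractional_error",
    "band_decompose",
]

#: band edges in Hz on |Im lambda| / 2 pi
BAND_EDGES = {"low": (0.0, 5.0), "alpha": (5.0, 15.0), "beta": (15.0, np.inf)}

_REAL_TOL = 1e-9  # |Im| below this counts as a real pole


class RationalFitError(RuntimeError):
    """Fit failed to converge or to produce a usable stable model."""


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


def _canonical(poles: np.ndarray, residues: np.ndarray):
    """Sort into (ascending-|Im|, then Re) order keeping only Im >= 0 reps."""
    order = np.lexsort((poles.real, np.abs(poles.imag)))
    return poles[order], residues[order]


@dataclass(frozen=True)
class PoleResidueModel:
    """Stable rational model ``sum_j r_j/(s - lambda_j)``.

    Conjugate pairs are stored once with ``Im(lambda) > 0``; evaluation adds
    the conjugate term, so the model is real-coefficient by construction.
    ``poles``/``residues`` hold the stored representatives.
    """

    poles: np.ndarray
    residues: np.ndarray
    fit_band: tuple = (0.0, 0.0)
    error_rms: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        p = np.atleast_1d(np.asarray(self.poles, dtype=complex))
        r = np.atleast_1d(np.asarray(self.residues, dtype=complex))
        if p.shape != r.shape:
            raise ValueError("poles and residues must have equal length")
        if np.any(p.real >= 0):
            raise ValueError("all poles must lie strictly in the left half-plane")
        if np.any(p.imag < -_REAL_TOL):
            raise ValueError("store conjugate pairs once, with Im(lambda) >= 0")
        p = np.where(np.abs(p.imag) < _REAL_TOL, p.real + 0j, p)
        r = np.where(np.abs(p.imag) < _REAL_TOL, r.real + 0j, r)
        if len(np.unique(np.round(p, 12))) != len(p):
            raise ValueError("repeated poles are not supported")
        p, r = _canonical(p, r)
        object.__setattr__(self, "poles", p)
        object.__setattr__(self, "residues", r)

    @property
    def n(self) -> int:
        """Total pole count, conjugate partners included."""
        return int(sum(2 if z.imag > 0 else 1 for z in self.poles))

    @property
    def poles_full(self) -> np.ndarray:
        """All poles, conjugate partners expanded."""
        out = []
        for z in self.poles:
            out.append(z)
            if z.imag > 0:
                out.append(np.conj(z))
        return np.array(out)

    def __call__(self, s):
        return evaluate_pole_residue(self, s)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        doc = {
            "poles": [[z.real, z.imag] for z in self.poles],
            "residues": [[z.real, z.imag] for z in self.residues],
            "fit_band": list(self.fit_band),
            "error_rms": self.error_rms,
            "meta": self.meta,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "PoleResidueModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        return cls(
            poles=np.array([complex(a, b) for a, b in doc["poles"]]),
            residues=np.array([complex(a, b) for a, b in doc["residues"]]),
            fit_band=tuple(doc.get("fit_band", (0.0, 0.0))),
            error_rms=doc.get("error_rms", float("nan")),
            meta=doc.get("meta", {}),
        )


def evaluate_pole_residue(m: PoleResidueModel, s):
    """Evaluate the partial-fraction sum at complex ``s`` (scalar or array)."""
    s = np.asarray(s, dtype=complex)
    if np.any([np.isclose(s, z).any() or (z.imag > 0 and np.isclose(s, np.conj(z)).any())
               for z in m.poles]):
        raise ZeroDivisionError("evaluation at a pole of the model")
    out = np.zeros_like(s)
    for z, r in zip(m.poles, m.residues):
        if z.imag > 0:
            out = out + r / (s - z) + np.conj(r) / (s - np.conj(z))
        else:
            out = out + r.real / (s - z.real)
    return out if out.ndim else complex(out)


def rms_fractional_error(m: PoleResidueModel, fr: FrequencyResponse) -> float:
    """rms(|T_fit - T|) / rms(|T|) over the response's grid."""
    ref = fr.values
    scale = np.sqrt(np.mean(np.abs(ref) ** 2))
    if scale == 0:
        raise ValueError("reference response is identically zero on the grid")
    fit = evaluate_pole_residue(m, 1j * 2 * np.pi * fr.frequencies)
    return float(np.sqrt(np.mean(np.abs(fit - ref) ** 2)) / scale)


# ---------------------------------------------------------------------------
# vector fitting
# ---------------------------------------------------------------------------


def _initial_poles(n: int, f_hi: float) -> np.ndarray:
    """Deterministic starting poles: conjugate pairs at 9 and 18 Hz, extra
    pairs log-spaced up to the band edge, plus log-spaced real poles."""
    n_real = 2 if n >= 6 else 0
    n_pair = (n - n_real) // 2
    if 2 * n_pair + n_real != n:
        raise ValueError("n_poles must be even and >= 2")
    pair_f = [9.0, 18.0][:n_pair]
    if n_pair > 2:
        pair_f += list(np.geomspace(27.0, max(0.93 * f_hi, 30.0), n_pair - 2))
    pairs = [-0.1 * 2 * np.pi * f + 1j * 2 * np.pi * f for f in pair_f]
    reals = list(-np.geomspace(5.0, 50.0, n_real)) if n_real else []
    return np.array(reals + pairs, dtype=complex)


def _basis(s: np.ndarray, poles: np.ndarray) -> np.ndarray:
    """Real-coefficient partial-fraction basis (two columns per pair)."""
    cols = []
    for z in poles:
        if abs(z.imag) < _REAL_TOL:
            cols.append(1.0 / (s - z.real))
        else:
            cols.append(1.0 / (s - z) + 1.0 / (s - np.conj(z)))
            cols.append(1j / (s - z) - 1j / (s - np.conj(z)))
    return np.column_stack(cols)


def _real_lstsq(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    Ar = np.vstack([A.real, A.imag])
    br = np.concatenate([b.real, b.imag])
    x, *_ = lstsq(Ar, br, lapack_driver="gelsd")
    return x


def _fit_residues(s, H, poles, w) -> np.ndarray:
    x = _real_lstsq(_basis(s, poles) * w[:, None], H * w)
    res, i = [], 0
    for z in poles:
        if abs(z.imag) < _REAL_TOL:
            res.append(x[i] + 0j)
            i += 1
        else:
            res.append(x[i] + 1j * x[i + 1])
            i += 2
    return np.array(res)


def _relocate_poles(s, H, poles, w) -> np.ndarray:
    """One vector-fitting iteration: solve the sigma problem, return the
    zeros of sigma as the new pole set (reflected into the left half-plane)."""
    Phi = _basis(s, poles)
    ncol = Phi.shape[1]
    A = np.hstack([Phi, -H[:, None] * Phi]) * w[:, None]
    x = _real_lstsq(A, H * w)
    c_sigma = x[ncol:]

    blocks, bvec, crow = [], [], []
    i = 0
    for z in poles:
        if abs(z.imag) < _REAL_TOL:
            blocks.append(np.array([[z.real]]))
            bvec.append([1.0])
            crow.append([c_sigma[i]])
            i += 1
        else:
            al, be = z.real, z.imag
            blocks.append(np.array([[al, be], [-be, al]]))
            bvec.append([2.0, 0.0])
            crow.append([c_sigma[i], c_sigma[i + 1]])
            i += 2
    Am = block_diag(*blocks)
    bv = np.concatenate(bvec)
    cv = np.concatenate(crow)
    lam = np.linalg.eigvals(Am - np.outer(bv, cv))
    lam = np.where(lam.real > 0, -lam.real + 1j * lam.imag, lam)  # stability
    reals = sorted(z.real for z in lam if abs(z.imag) < 1e-7)
    pairs = sorted((z for z in lam if z.imag > 1e-7), key=lambda z: z.imag)
    out = np.array([complex(x) for x in reals] + list(pairs))
    # guard against accidental coalescence
    for i in range(1, len(out)):
        if abs(out[i] - out[i - 1]) < 1e-9 * max(1.0, abs(out[i])):
            out[i] = out[i] * (1 + 1e-9) + 1e-9
            warnings.warn("perturbed nearly degenerate pole during relocation")
    return out


def _vector_fit(s, H, n_poles, w, n_iter, f_hi):
    poles = _initial_poles(n_poles, f_hi)
    for _ in range(n_iter):
        new = _relocate_poles(s, H, poles, w)
        if len(new) != len(poles):
            # real/complex bookkeeping changed the stored count; accept as is
            poles = new
            continue
        shift = np.max(np.abs(new - poles) / np.maximum(np.abs(poles), 1.0))
        poles = new
        if shift < 1e-12:
            break
    residues = _fit_residues(s, H, poles, w)
    return poles, residues


def _truncate_modal(poles, residues, n_keep):
    """Keep the ``n_keep`` highest-energy poles (score |r|/|Re lambda|)."""
    score = np.array(
        [abs(r) / max(abs(z.real), 1e-12) for z, r in zip(poles, residues)]
    )
    order = np.argsort(score)[::-1]
    sel, count = [], 0
    for i in order:
        c = 2 if poles[i].imag > _REAL_TOL else 1
        if count + c <= n_keep:
            sel.append(i)
            count += c
        if count == n_keep:
            break
    if count != n_keep:
        raise RationalFitError(
            f"could not assemble a {n_keep}-pole truncation from the base fit"
        )
    return poles[sorted(sel)]


def fit_rational(
    fr: FrequencyResponse,
    n_poles: int,
    n_base: int = 16,
    n_iter: int = 60,
) -> PoleResidueModel:
    """Fit a stable ``n_poles``-pole rational model to a sampled response.

    Vector fitting runs at order ``max(n_poles, n_base)``; if ``n_poles`` is
    smaller, the model is reduced by modal truncation (least-damped,
    highest-energy poles retained; residues re-fit). Deterministic for fixed
    inputs and settings.

    Parameters
    ----------
    fr:
        Sampled frequency response; a dense grid (>= 512 points over the
        band of interest) is expected.
    n_poles:
        Requested order (even, >= 2).
    n_base:
        Order of the underlying vector fit. Pass ``n_base <= n_poles`` to
        force a direct fit at the requested order.
    """
    if n_poles < 2 or n_poles % 2:
        raise ValueError("n_poles must be even and >= 2")
    f = fr.frequencies
    H = fr.values
    s = 1j * 2 * np.pi * f
    w = np.ones_like(f)

    order = max(n_poles, n_base)
    poles, residues = _vector_fit(s, H, order, w, n_iter, f[-1])
    if n_poles < order:
        poles = _truncate_modal(poles, residues, n_poles)
        residues = _fit_residues(s, H, poles, w)
    if np.any(poles.real >= 0):
        raise RationalFitError("unstable poles remain after reflection")

    m = PoleResidueModel(
        poles=poles,
        residues=residues,
        fit_band=(float(f[0]), float(f[-1])),
        meta={"n_poles": n_poles, "n_base": order, "target": fr.target},
    )
    err = rms_fractional_error(m, fr)
    object.__setattr__(m, "error_rms", err)
    return m


# ---------------------------------------------------------------------------
# band decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandDecomposition:
    """Split of a 6-pole model into low/alpha/beta 2-pole partial models.

    Residues are preserved, so ``low + alpha + beta`` reproduces the parent
    model identically.
    """

    low: PoleResidueModel
    alpha: PoleResidueModel
    beta: PoleResidueModel

    def __iter__(self):
        yield from (("low", self.low), ("alpha", self.alpha), ("beta", self.beta))

    def __call__(self, s):
        return self.low(s) + self.alpha(s) + self.beta(s)


def band_decompose(m: PoleResidueModel) -> BandDecomposition:
    """Group a 6-pole model's poles into low / alpha / beta 2-pole models.

    The low band takes the real pole pair; conjugate pairs are assigned by
    |Im lambda|/2pi with edges at 5 and 15 Hz (an exact edge goes to the
    lower band). When both pairs land in one band the assignment falls back
    to frequency ordering (lower pair -> alpha, higher -> beta) with a
    warning.
    """
    if m.n != 6:
        raise ValueError(f"band decomposition expects a 6-pole model, got n={m.n}")
    reals = [(z, r) for z, r in zip(m.poles, m.residues) if z.imag == 0]
    pairs = [(z, r) for z, r in zip(m.poles, m.residues) if z.imag > 0]
    if len(reals) != 2 or len(pairs) != 2:
        raise ValueError(
            "expected one real pole pair and two conjugate pairs, got "
            f"{len(reals)} real poles and {len(pairs)} pairs"
        )

    def _sub(terms, **kw):
        z = np.array([t[0] for t in terms])
        r = np.array([t[1] for t in terms])
        return PoleResidueModel(z, r, fit_band=m.fit_band, meta={**m.meta, **kw})

    pairs = sorted(pairs, key=lambda t: t[0].imag)
    f0, f1 = (t[0].imag / (2 * np.pi) for t in pairs)
    lo_a, hi_a = BAND_EDGES["alpha"]
    in_alpha = [lo_a < f <= hi_a or f <= lo_a for f in (f0, f1)]
    in_beta = [f > hi_a for f in (f0, f1)]
    if not (any(in_alpha) and any(in_beta)):
        warnings.warn(
            "conjugate pairs do not split across the alpha/beta edge at "
            f"{hi_a} Hz (pair frequencies {f0:.2f}, {f1:.2f} Hz); assigning "
            "by frequency order"
        )
    alpha_pair, beta_pair = pairs[0], pairs[1]
    return BandDecomposition(
        low=_sub(reals, band="low"),
        alpha=_sub([alpha_pair], band="alpha"),
        beta=_sub([beta_pair], band="beta"),
    )
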