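"""Canonical analysis chain: transfer function -> rational fit -> band filters.

Convenience wrappers wiring the modules together with the standard settings
used throughout the package: a uniform 1024-point grid over 0-150 Hz, a
16-pole base vector fit, 6-pole modal truncation, band decomposition and
second-order identification.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .filters import characterize, identify_bands
from .model import ModelParams, default_parameters
from .ratfit import PoleResidueModel, band_decompose, fit_rational
from .transfer import frequency_response, transfer_function

__all__ = [
    "default_grid",
    "fit_target",
    "band_filters_for",
    "characteristics_table",
]

F_MAX = 150.0
N_GRID = 1024


def default_grid(f_max: float = F_MAX, n: int = N_GRID) -> np.ndarray:
    """The uniform fitting/error grid over [0, f_max] Hz."""
    return np.linspace(0.0, f_max, n)


def fit_target(
    params: ModelParams | None = None,
    target: str = "e",
    n_poles: int = 6,
    f_max: float = F_MAX,
    n_grid: int = N_GRID,
) -> PoleResidueModel:
    """Fit a stable rational model to one population's transfer function."""
    params = params or default_parameters()
    fr = frequency_response(
        transfer_function(params, target), default_grid(f_max, n_grid)
    )
    return fit_rational(fr, n_poles)


def band_filters_for(
    params: ModelParams | None = None, target: str = "e"
) -> Mapping[str, object]:
    """Low/alpha/beta second-order filters of a population's 6-pole model."""
    model = fit_target(params, target, n_poles=6)
    return identify_bands(band_decompose(model))


_ROWS = (
    ("Gamma_minus", "damping rate (slow pole)", "s^-1"),
    ("Gamma_plus", "damping rate (fast pole)", "s^-1"),
    ("Omega_c", "cut-off frequency", "s^-1"),
    ("K", "gain (sum of residues)", "-"),
    ("zeta", "damping coefficient", "-"),
    ("omega0", "natural frequency", "s^-1"),
    ("B", "bandwidth", "s^-1"),
    ("Omega_peak", "resonance frequency", "s^-1"),
    ("M_peak", "resonance magnitude", "-"),
    ("tau_p", "prediction time", "s"),
)


def characteristics_table(
    params: ModelParams | None = None, targets: str = "eirs"
) -> pd.DataFrame:
    """Second-order characteristics of every band filter of each population.

    One column per (population, band); one row per characteristic, mirroring
    the conventional filter-identification summary. The gain row reports the
    pair-sum convention K = r_j + r_j+1; the low-frequency stage gain
    K/Omega_0^2 is derivable from the rows.
    """
    params = params or default_parameters()
    cols = {}
    for t in targets:
        for band, filt in band_filters_for(params, t).items():
            ch = characterize(filt)
            cols[(f"T_{t}n", band)] = [getattr(ch, name) for name, *_ in _ROWS]
    df = pd.DataFrame(
        cols, index=pd.Index([f"{n} [{u}]" for n, _, u in _ROWS], name="quantity")
    )
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["transfer", "band"])
    return df
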