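"""Three-fraction dye-partitioning model of the silica deposition vesicle.

The valve-formation reporter is a weak base: its neutral form crosses
membranes freely, its protonated form is trapped, so the dye accumulates
in the acidic SDV in proportion to 1 + 10^(pKa − pH).  Total dye
concentration in the SDV is the sum of three fractions,

    F_total = F_free + F_bound + F_fixed,

where F_free is the neutral (diffusible) form, F_bound the protonated
form held by the pH gradient, and F_fixed the dye entrapped in newly
formed silica.  Entrapment is irreversible (no dissolution): the fixed
*amount* F_fixed·V never decreases.

The dynamics implemented here are the minimal ones consistent with that
picture: F_free + F_bound track the weak-base equilibrium with the
external medium instantaneously, while the fixed amount grows with flux
kappa · F_bound · V.  SDV pH and volume enter as prescribed trajectories
(piecewise-linear pH; exponential or logistic volume growth).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "SDVParams",
    "SDVSeries",
    "bound_enrichment",
    "forward_simulate",
    "fold_change_from_delta_pH",
    "piecewise_linear",
    "exponential_volume",
    "logistic_volume",
]


def piecewise_linear(t_points, values) -> Callable[[np.ndarray], np.ndarray]:
    """Piecewise-linear trajectory through (t_points, values), clamped outside."""
    t_points = np.asarray(t_points, dtype=float)
    values = np.asarray(values, dtype=float)
    return lambda t: np.interp(np.asarray(t, dtype=float), t_points, values)


def exponential_volume(V0: float, rate_per_min: float) -> Callable[[np.ndarray], np.ndarray]:
    """V(t) = V0·e^(rate·t), the simplest non-linear SDV expansion law."""
    return lambda t: V0 * np.exp(rate_per_min * np.asarray(t, dtype=float))


def logistic_volume(
    V0: float, V_max: float, rate_per_min: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Logistic expansion from V0 saturating at V_max."""
    if not 0 < V0 < V_max:
        raise ValueError("need 0 < V0 < V_max")
    a = V_max / V0 - 1.0

    def v(t):
        return V_max / (1.0 + a * np.exp(-rate_per_min * np.asarray(t, dtype=float)))

    return v


def _as_trajectory(x) -> Callable[[np.ndarray], np.ndarray]:
    if callable(x):
        return x
    val = float(x)
    return lambda t: np.full_like(np.asarray(t, dtype=float), val)


@dataclass
class SDVParams:
    """Parameters of the SDV dye-partitioning model.

    pH_sdv and V may be constants, callables of time (minutes), or the
    output of :func:`piecewise_linear` / the volume-law helpers.
    """

    pKa: float = 7.5  # protonation constant of the dye
    pH_out: float = 7.35  # cytosolic/external pH seen by the free dye
    pH_sdv: float | Callable = 5.0  # intra-SDV pH trajectory
    V: float | Callable = 1.0  # SDV volume trajectory, µm³
    kappa: float = 0.01  # fixation rate, per minute
    F_ext: float = 1.0  # external free-dye total concentration, µM
    cytosol_fraction: float = 0.0  # dye pool outside the SDV, taken negligible

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not 0.0 <= self.cytosol_fraction < 1.0:
            raise ValueError("cytosol_fraction must lie in [0, 1)")


@dataclass
class SDVSeries:
    """Time series of the three dye fractions (µM, per SDV volume)."""

    times: np.ndarray
    F_free: np.ndarray
    F_bound: np.ndarray
    F_fixed: np.ndarray
    F_total: np.ndarray
    V: np.ndarray

    def conservation_residual(self) -> float:
        """max |F_total − (F_free + F_bound + F_fixed)| / max(F_total)."""
        resid = np.abs(self.F_total - (self.F_free + self.F_bound + self.F_fixed))
        scale = max(float(np.max(self.F_total)), 1e-300)
        return float(np.max(resid) / scale)


def bound_enrichment(pH_sdv, pH_out, pKa: float) -> np.ndarray:
    """Equilibrium total-dye enrichment of the acidic compartment.

    For a monoprotic weak base whose neutral form equilibrates freely,
    total-in/total-out = (1 + 10^(pKa − pH_sdv)) / (1 + 10^(pKa − pH_out)).
    """
    pH_sdv = np.asarray(pH_sdv, dtype=float)
    pH_out = np.asarray(pH_out, dtype=float)
    if not (np.all(np.isfinite(pH_sdv)) and np.all(np.isfinite(pH_out))):
        raise ValueError("pH values must be finite")
    return (1.0 + 10.0 ** (pKa - pH_sdv)) / (1.0 + 10.0 ** (pKa - pH_out))


def fold_change_from_delta_pH(delta_pH: float) -> float:
    """Predicted fold change of accumulated dye for an SDV pH shift.

    In the protonation-dominated regime (pH well below pKa) the bound
    fraction scales as 10^(−pH), so a pH drop of delta_pH multiplies the
    accumulated concentration by 10^(delta_pH).
    """
    if not np.isfinite(delta_pH) or abs(delta_pH) >= 5:
        raise ValueError("delta_pH must be finite with |delta_pH| < 5")
    return float(10.0**delta_pH)


def forward_simulate(params: SDVParams, times) -> SDVSeries:
    """Integrate the model over ``times`` (minutes, strictly increasing from 0).

    The mobile pool (free + bound) is at instantaneous weak-base equilibrium
    with the external dye; the fixed amount A(t) = F_fixed·V obeys
    dA/dt = kappa · F_bound · V, integrated with a fixed-step midpoint rule
    on the given time grid.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("times must be a 1-D array with at least 2 samples")
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing from 0")
    if params.kappa * np.max(np.diff(t)) > 0.5:
        raise ValueError(
            "integration step too large for stability (kappa*dt > 0.5); "
            "use a finer time grid"
        )
    ph_sdv = _as_trajectory(params.pH_sdv)
    vol = _as_trajectory(params.V)
    v = np.asarray(vol(t), dtype=float)
    if np.any(v <= 0):
        raise ValueError("SDV volume must stay positive")
    neutral_out = params.F_ext / (1.0 + 10.0 ** (params.pKa - params.pH_out))
    ph_in = np.asarray(ph_sdv(t), dtype=float)
    f_free = np.full_like(t, neutral_out)
    f_bound = neutral_out * 10.0 ** (params.pKa - ph_in)
    # midpoint quadrature of dA/dt = kappa * F_bound(t) * V(t)
    a_fixed = np.zeros_like(t)
    if params.kappa > 0:
        t_mid = 0.5 * (t[:-1] + t[1:])
        f_bound_mid = neutral_out * 10.0 ** (
            params.pKa - np.asarray(ph_sdv(t_mid), dtype=float)
        )
        v_mid = np.asarray(vol(t_mid), dtype=float)
        increments = params.kappa * f_bound_mid * v_mid * np.diff(t)
        a_fixed[1:] = np.cumsum(increments)
    f_fixed = a_fixed / v
    f_total = f_free + f_bound + f_fixed
    return SDVSeries(
        times=t, F_free=f_free, F_bound=f_bound, F_fixed=f_fixed, F_total=f_total, V=v
    )
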