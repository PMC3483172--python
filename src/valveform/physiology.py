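"""Population physiology: growth rates, silicon quotas and pH calibration.

Growth is exponential over the sampled window, so the specific growth rate
µ is the slope of ln(density) vs time and the doubling time ln 2/µ.  The
silicon arithmetic converts extract concentrations to per-cell quotas
(pmol cell⁻¹) and the silicon incorporation rate is the biogenic-silica
quota divided by µ.  Intracellular pH comes from the dual-excitation
(485/436) ratio of the H⁺ indicator BCECF through a fitted monotone
calibration (four-parameter logistic in pH, with a linear fallback).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "GrowthModel",
    "GrowthResults",
    "fit_growth_rate",
    "quota_per_cell",
    "incorporation_rate",
    "PHCalibration",
    "BCECFCalibrationModel",
    "fit_bcecf_calibration",
    "ratio_to_pH",
    "proton_fold",
]


@dataclass(frozen=True)
class GrowthResults:
    """Exponential growth fit for one culture."""

    mu: float  # per hour
    doubling_time_h: float  # ln2/mu; inf when mu <= 0 (flagged)
    r2: float
    mu_stderr: float
    n_points: int
    degenerate: bool  # True when the culture did not grow

    def summary(self) -> str:
        dt = "inf" if not np.isfinite(self.doubling_time_h) else f"{self.doubling_time_h:.2f}"
        return "\n".join(
            [
                "Exponential growth fit  ln N(t) = ln N0 + mu t",
                "=" * 48,
                f"mu [1/h]          {self.mu:.5f}  (se {self.mu_stderr:.5f})",
                f"doubling time [h] {dt}",
                f"r^2               {self.r2:.4f}",
                f"n                 {self.n_points}",
            ]
        )


class GrowthModel:
    """Log-linear model of exponential-phase cell densities.

    Parameters
    ----------
    times_h : array-like
        Sampling times in hours, increasing.
    densities : array-like
        Cell densities (cells mL⁻¹), strictly positive.
    """

    def __init__(self, times_h, densities):
        t = np.asarray(times_h, dtype=float)
        n = np.asarray(densities, dtype=float)
        if t.shape != n.shape or len(t) < 3:
            raise ValueError("need >= 3 aligned (time, density) points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be increasing")
        if np.any(n <= 0):
            raise ValueError("densities must be positive")
        self.times = t
        self.densities = n

    def fit(self) -> GrowthResults:
        logn = np.log(self.densities)
        if np.ptp(logn) == 0:
            return GrowthResults(
                mu=0.0, doubling_time_h=np.inf, r2=1.0, mu_stderr=0.0,
                n_points=len(logn), degenerate=True,
            )
        res = stats.linregress(self.times, logn)
        mu = float(res.slope)
        return GrowthResults(
            mu=mu,
            doubling_time_h=float(np.log(2) / mu) if mu > 0 else np.inf,
            r2=float(res.rvalue**2),
            mu_stderr=float(res.stderr),
            n_points=len(logn),
            degenerate=mu <= 0,
        )


def fit_growth_rate(times_h, densities) -> GrowthResults:
    """Functional wrapper over :class:`GrowthModel`."""
    return GrowthModel(times_h, densities).fit()


def quota_per_cell(
    concentration_uM: float, extract_volume_mL: float, cell_count: float
) -> float:
    """Per-cell silicon quota in pmol cell⁻¹.

    1 µM in 1 mL is 1 nmol = 1000 pmol; divided over the extracted cells.
    """
    if cell_count <= 0:
        raise ValueError("cell count must be positive")
    if concentration_uM < 0 or extract_volume_mL < 0:
        raise ValueError("concentration and volume must be non-negative")
    return concentration_uM * extract_volume_mL * 1000.0 / cell_count


def incorporation_rate(BSi_quota_pmol: float, mu: float) -> float:
    """Silicon incorporation rate: BSi quota per unit specific growth rate."""
    if mu <= 0:
        warnings.warn("mu <= 0: incorporation rate diverges", RuntimeWarning)
        return np.inf
    return BSi_quota_pmol / mu


# ---------------------------------------------------------------------------
# BCECF ratiometric pH calibration


def _logistic(ph, r_min, r_max, pk, hill):
    return r_min + (r_max - r_min) / (1.0 + 10.0 ** (hill * (pk - ph)))


@dataclass(frozen=True)
class PHCalibration:
    """Monotone map between the 485/436 ratio and pH.

    ``model`` is "logistic" (four-parameter, increasing in pH) or "linear"
    (fallback when the sigmoid is not identifiable on the sampled range).
    """

    model: str
    params: tuple[float, ...]
    domain: tuple[float, float]  # pH range of the calibration data

    def forward(self, pH) -> np.ndarray:
        ph = np.asarray(pH, dtype=float)
        if self.model == "logistic":
            return _logistic(ph, *self.params)
        a, b = self.params
        return a + b * ph

    def inverse(self, ratio) -> np.ndarray:
        """pH for a measured ratio; out-of-range ratios are clamped (NaN-safe)."""
        r = np.asarray(ratio, dtype=float)
        lo, hi = sorted((float(self.forward(self.domain[0])), float(self.forward(self.domain[1]))))
        r = np.clip(r, lo, hi)
        if self.model == "logistic":
            r_min, r_max, pk, hill = self.params
            eps = 1e-12 * max(abs(r_max - r_min), 1.0)
            frac = np.clip((r - r_min) / (r_max - r_min), eps, 1 - eps)
            return pk - np.log10(1.0 / frac - 1.0) / hill
        a, b = self.params
        return (r - a) / b

    def achievable_range(self) -> tuple[float, float]:
        vals = sorted(
            (float(self.forward(self.domain[0])), float(self.forward(self.domain[1])))
        )
        return (vals[0], vals[1])

    def summary(self) -> str:
        names = (
            ("R_min", "R_max", "pK'", "hill")
            if self.model == "logistic"
            else ("intercept", "slope")
        )
        lines = [
            f"BCECF ratio calibration ({self.model})",
            "=" * 40,
        ] + [f"{n:<10} {v:.4f}" for n, v in zip(names, self.params)] + [
            f"domain     pH {self.domain[0]:.2f} - {self.domain[1]:.2f}"
        ]
        return "\n".join(lines)


class BCECFCalibrationModel:
    """Fit of the ratio-vs-pH calibration curve.

    Requires >= 4 pH levels spanning >= 1 pH unit with level means that
    increase with pH (beyond a noise tolerance).  ``fit()`` attempts the
    four-parameter logistic and falls back to an OLS line when the sigmoid
    is not identifiable.
    """

    def __init__(self, ph_levels, ratios, monotone_tol: float = 0.05):
        ph = np.asarray(ph_levels, dtype=float)
        r = np.asarray(ratios, dtype=float)
        if ph.shape != r.shape:
            raise ValueError("pH and ratio arrays must align")
        levels = np.unique(ph)
        if len(levels) < 4:
            raise ValueError("need at least 4 pH levels")
        if np.ptp(levels) < 1.0:
            raise ValueError("pH levels must span at least 1 unit")
        means = np.array([r[ph == p].mean() for p in levels])
        drops = np.diff(means) < -monotone_tol * np.ptp(means)
        if np.any(drops):
            raise ValueError("level means are non-monotone beyond noise tolerance")
        self.ph = ph
        self.ratios = r
        self.level_ph = levels
        self.level_means = means

    def fit(self) -> PHCalibration:
        domain = (float(self.level_ph.min()), float(self.level_ph.max()))
        span = float(np.ptp(self.level_means))
        p0 = (
            float(self.level_means.min()) - 0.05 * span,
            float(self.level_means.max()) + 0.05 * span,
            float(np.median(self.level_ph)),
            1.0,
        )
        try:
            popt, _pcov = curve_fit(
                _logistic, self.ph, self.ratios, p0=p0, maxfev=20000
            )
            r_min, r_max, pk, hill = popt
            if r_max <= r_min or hill <= 0:
                raise RuntimeError("non-monotone logistic")
            # not identifiable when the data look linear: the plateaus must
            # lie near the sampled range for the sigmoid to be constrained
            if not (domain[0] - 2.0 < pk < domain[1] + 2.0) or hill > 25:
                raise RuntimeError("logistic not identifiable on this range")
            if (r_max - r_min) > 5.0 * span:
                # plateaus far outside the sampled ratios: data are linear
                raise RuntimeError("logistic not identifiable: no plateaus sampled")
            return PHCalibration(
                model="logistic", params=tuple(float(v) for v in popt), domain=domain
            )
        except (RuntimeError, ValueError):
            res = stats.linregress(self.ph, self.ratios)
            return PHCalibration(
                model="linear",
                params=(float(res.intercept), float(res.slope)),
                domain=domain,
            )


def fit_bcecf_calibration(ph_levels, ratios) -> PHCalibration:
    """Functional wrapper over :class:`BCECFCalibrationModel`."""
    return BCECFCalibrationModel(ph_levels, ratios).fit()


def ratio_to_pH(ratio, calib: PHCalibration) -> np.ndarray:
    """Invert the calibration; out-of-range ratios are clamped to the domain."""
    return calib.inverse(ratio)


def proton_fold(delta_pH: float) -> float:
    """Fold change of [H⁺] for a pH decrease of ``delta_pH`` units: 10^ΔpH."""
    if not np.isfinite(delta_pH):
        raise ValueError("delta_pH must be finite")
    return float(10.0**delta_pH)
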