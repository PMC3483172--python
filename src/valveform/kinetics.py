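"""Two-phase kinetics of valve formation and its pH dependence.

A valve-formation trace has an exponential accumulation phase
F(t) = F0·e^(k·t) ending at the first maximum F1 (duration t_Exp),
followed in most cells by a decay to a minimum F2 (duration t_Dec).
The exponential phase is fitted log-linearly, which makes the quality
statistic the Pearson correlation r of ln F vs t; the population filter
keeps only fits with r > 0.95 and at least 45 min of data before F1.

The pH dependence of k and of the phase amplitudes F1−F0 and F1−F2 is
fitted as y = a·e^(b·pHe) over a restricted pH domain (the most basic
treatment is excluded from these fits).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import FluorescenceTrace

__all__ = [
    "CalibrationLine",
    "IntensityCalibrationModel",
    "fit_intensity_calibration",
    "to_concentration",
    "PhaseSegmentation",
    "segment_phases",
    "ExponentialPhaseModel",
    "KineticsResults",
    "fit_exponential_phase",
    "phase_deltas",
    "PHResponseModel",
    "PHResponseResults",
    "fit_ph_dependence",
    "MIN_PRE_PEAK_MIN",
    "MIN_FIT_R",
]

#: population inclusion rules for single-cell fits
MIN_PRE_PEAK_MIN = 45.0  # minutes of data required before F1
MIN_FIT_R = 0.95  # Pearson r of ln(signal) vs time


# ---------------------------------------------------------------------------
# Intensity -> concentration calibration


@dataclass(frozen=True)
class CalibrationLine:
    """OLS line relating fluorescence intensity to dye concentration."""

    slope: float  # intensity per µM
    intercept: float  # intensity
    domain: tuple[float, float]  # µM range of the fitted design
    r2: float
    slope_stderr: float
    residual_std: float

    def intensity(self, concentration_uM) -> np.ndarray:
        return self.slope * np.asarray(concentration_uM, dtype=float) + self.intercept

    def concentration(self, intensity) -> np.ndarray:
        return (np.asarray(intensity, dtype=float) - self.intercept) / self.slope


class IntensityCalibrationModel:
    """OLS model for the linear dye-dilution calibration.

    Parameters
    ----------
    concentrations, intensities : array-like
        Paired measurements; at least 3 distinct concentration levels.
    """

    def __init__(self, concentrations, intensities):
        c = np.asarray(concentrations, dtype=float)
        y = np.asarray(intensities, dtype=float)
        if c.shape != y.shape:
            raise ValueError("concentrations and intensities must align")
        if len(np.unique(c)) < 3:
            raise ValueError("need at least 3 distinct concentrations")
        if np.ptp(c) == 0:
            raise ValueError("zero variance in concentrations")
        self.concentrations = c
        self.intensities = y

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        concentration_col: str = "concentration_uM",
        intensity_col: str = "intensity",
    ) -> "IntensityCalibrationModel":
        return cls(table[concentration_col].values, table[intensity_col].values)

    def fit(self) -> CalibrationLine:
        res = stats.linregress(self.concentrations, self.intensities)
        resid = self.intensities - (res.slope * self.concentrations + res.intercept)
        return CalibrationLine(
            slope=float(res.slope),
            intercept=float(res.intercept),
            domain=(float(self.concentrations.min()), float(self.concentrations.max())),
            r2=float(res.rvalue**2),
            slope_stderr=float(res.stderr),
            residual_std=float(np.std(resid, ddof=2)) if len(resid) > 2 else 0.0,
        )


def fit_intensity_calibration(concentrations, intensities) -> CalibrationLine:
    """Functional wrapper over :class:`IntensityCalibrationModel`."""
    return IntensityCalibrationModel(concentrations, intensities).fit()


def to_concentration(
    trace: FluorescenceTrace, calib: CalibrationLine, biovolume_um3: float
) -> FluorescenceTrace:
    """Convert integrated intensity to µM dye per µm³ of cell biovolume.

    concentration = ((signal − intercept)/slope)/biovolume, clipped at 0;
    samples whose implied concentration leaves the calibration's fitted
    domain are flagged ``extrapolated``.
    """
    if biovolume_um3 <= 0:
        raise ValueError("biovolume must be positive")
    raw = calib.concentration(trace.signal)
    extrapolated = (raw < calib.domain[0]) | (raw > calib.domain[1])
    conc = np.clip(raw, 0.0, None) / biovolume_um3
    return replace(
        trace, concentration=conc, biovolume=biovolume_um3, extrapolated=extrapolated
    )


# ---------------------------------------------------------------------------
# Phase segmentation


@dataclass(frozen=True)
class PhaseSegmentation:
    """Indices of the phase landmarks on a trace."""

    i_f1: int  # index of the first prominent maximum (end of t_Exp)
    i_f2: int | None  # index of the post-decay minimum, None if no decay
    pre_peak_ok: bool  # >= 45 min of data before F1
    t_dec_refined: float | None = None  # minutes, model-refined decay duration
    peak_found: bool = True  # False when the trace never peaked in-record:
    # i_f1 then falls back to the last sample and F1/t_Exp are not landmarks


def _moving_median(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    return np.array([np.median(xp[i : i + window]) for i in range(len(x))])


def _refine_decay_end(tau: np.ndarray, y_tail: np.ndarray) -> float | None:
    """Continuous decay duration from a kneed-exponential fit to the tail.

    Model: y(τ) = F2 + (F1−F2)·(e^(−rτ) − e^(−rT))/(1 − e^(−rT)) for τ ≤ T,
    constant F2 after — a decay reaching its minimum at T.  F1 is pinned to
    the peak sample; (F2, r, T) are fitted by least squares.  Returns None
    when the fit fails or is unidentifiable (T running into its bounds).
    """
    from scipy.optimize import curve_fit

    if len(tau) < 6:
        return None
    f1 = float(y_tail[0])

    def model(tt, f2, r, T):
        tt = np.asarray(tt, dtype=float)
        e_t = np.exp(-r * T)
        out = np.full_like(tt, f2)
        m = tt <= T
        out[m] = f2 + (f1 - f2) * (np.exp(-r * tt[m]) - e_t) / (1.0 - e_t)
        return out

    t_max = float(tau[-1])
    try:
        popt, _ = curve_fit(
            model,
            tau,
            y_tail,
            p0=(float(np.min(y_tail)), 0.03, max(10.0, 0.6 * t_max)),
            bounds=([0.0, 1e-4, tau[1]], [f1, 1.0, 2.0 * t_max]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return None
    T = float(popt[2])
    if T >= 1.95 * t_max:  # ran into the bound: decay did not end in-record
        return None
    return T


def segment_phases(
    trace: FluorescenceTrace,
    smoothing_window: int = 3,
    prominence_frac: float = 0.10,
    min_peak_height_frac: float = 0.5,
    min_pre_peak_min: float = MIN_PRE_PEAK_MIN,
    refine: bool = True,
) -> PhaseSegmentation:
    """Locate F1 (first prominent maximum) and F2 (subsequent minimum).

    The trace is smoothed with a centred moving median before peak search;
    F1 is the first local maximum whose prominence exceeds
    ``prominence_frac`` of the trace range and whose height reaches
    ``min_peak_height_frac`` of the smoothed maximum (the valve-formation
    maximum is the brightest point of the accumulation — the height guard
    rejects noise bumps on the rise), falling back to the last sample for
    non-decreasing traces, with no decay phase.  The peak index is then
    refined to the raw-series argmax within the smoothing half-window
    (median filtering skews plateau peaks by one sample).  F2 is the
    minimum after F1 and before any re-increase; with ``refine`` the decay
    endpoint is re-estimated by fitting a kneed exponential to the tail,
    which localises the knee well below the sampling interval.
    ``pre_peak_ok`` records the ≥45 min pre-F1 inclusion rule.
    """
    from scipy.signal import find_peaks

    y = np.asarray(trace.signal, dtype=float)
    if len(y) < 5:
        raise ValueError("need at least 5 samples to segment phases")
    if len(y) < smoothing_window:
        raise ValueError("trace shorter than the smoothing window")
    s = _moving_median(y, smoothing_window)
    rng = float(np.ptp(s))
    if rng == 0:
        raise ValueError("flat trace: no phases")
    peaks, _props = find_peaks(s, prominence=prominence_frac * rng)
    peaks = [p for p in peaks if s[p] >= min_peak_height_frac * float(s.max())]
    t_dec_refined: float | None = None
    peak_found = True
    if len(peaks) == 0:
        i_f1, i_f2 = len(y) - 1, None
        peak_found = False
    else:
        i_f1 = int(peaks[0])
        half = smoothing_window // 2
        lo = max(0, i_f1 - half)
        hi = min(len(y), i_f1 + half + 1)
        i_f1 = lo + int(np.argmax(y[lo:hi]))
        tail = s[i_f1:]
        # minimum before any re-increase: first local minimum of the tail,
        # or the tail end if the decay never reverses
        i_rel = None
        for j in range(1, len(tail) - 1):
            if tail[j] <= tail[j - 1] and tail[j] < tail[j + 1]:
                i_rel = j
                break
        if i_rel is None:
            i_rel = len(tail) - 1 if len(tail) > 1 else None
        if i_rel is None or np.all(np.diff(tail) >= 0):
            i_f2 = None
        else:
            i_f2 = i_f1 + int(i_rel)
            if refine:
                tau = trace.times[i_f1:] - trace.times[i_f1]
                t_dec_refined = _refine_decay_end(tau, y[i_f1:])
                if t_dec_refined is not None:
                    i_f2 = i_f1 + int(
                        np.argmin(np.abs(tau - t_dec_refined))
                    )
    pre_peak_ok = (trace.times[i_f1] - trace.times[0]) >= min_pre_peak_min
    return PhaseSegmentation(
        i_f1=i_f1,
        i_f2=i_f2,
        pre_peak_ok=pre_peak_ok,
        t_dec_refined=t_dec_refined,
        peak_found=peak_found,
    )


# ---------------------------------------------------------------------------
# Exponential-phase fitting


@dataclass(frozen=True)
class KineticsResults:
    """Estimates for one cell's valve-formation kinetics."""

    cell_id: int
    k: float  # per minute
    F0: float  # signal (or concentration) at the fit origin
    F1: float  # value at the first maximum
    F2: float | None  # value at the post-decay minimum
    t_exp: float  # minutes, duration of the exponential phase
    t_dec: float | None  # minutes, duration of the decay phase
    fit_r: float  # |Pearson r| of ln(signal) vs time
    accepted: bool  # fit_r > 0.95 and >= 45 min pre-F1
    k_stderr: float
    n_points: int
    peaked: bool = True  # False when the trace never reached a maximum
    # in-record; F1 and t_exp then describe the record end, not landmarks

    def summary(self) -> str:
        lines = [
            "Valve-formation kinetics (exponential-phase log-linear fit)",
            "=" * 60,
            f"cell id          {self.cell_id}",
            f"k  [1/min]       {self.k:.5f}  (se {self.k_stderr:.5f})",
            f"F0               {self.F0:.4g}",
            f"F1               {self.F1:.4g}",
            f"F2               {'-' if self.F2 is None else f'{self.F2:.4g}'}",
            f"t_Exp [min]      {self.t_exp:.1f}",
            f"t_Dec [min]      {'-' if self.t_dec is None else f'{self.t_dec:.1f}'}",
            f"fit r            {self.fit_r:.4f}",
            f"accepted         {self.accepted}  (r > {MIN_FIT_R}, >= {MIN_PRE_PEAK_MIN:.0f} min pre-F1)",
        ]
        return "\n".join(lines)


class ExponentialPhaseModel:
    """Log-linear model of the exponential accumulation phase.

    ``fit()`` regresses ln(signal) on time over the exponential window and
    returns a :class:`KineticsResults` carrying k (slope), F0
    (exp(intercept)), the phase landmarks and the acceptance flag.
    """

    def __init__(
        self,
        trace: FluorescenceTrace,
        segmentation: PhaseSegmentation | None = None,
        use_concentration: bool = False,
    ):
        self.trace = trace
        self.use_concentration = use_concentration
        y = trace.concentration if use_concentration else trace.signal
        if y is None:
            raise ValueError("trace has no concentration; calibrate first")
        self.values = np.asarray(y, dtype=float)
        self.segmentation = segmentation or segment_phases(
            replace(trace, signal=self.values)
        )

    def fit(self) -> KineticsResults:
        seg = self.segmentation
        t = self.trace.times
        y = self.values
        i0, i1 = 0, seg.i_f1
        win_t, win_y = t[i0 : i1 + 1], y[i0 : i1 + 1]
        if len(win_y) < 4:
            raise ValueError("need at least 4 points in the exponential window")
        if np.any(win_y <= 0):
            raise ValueError(
                "non-positive values in the exponential window; "
                "background over-subtraction — consider an offset or re-windowing"
            )
        res = stats.linregress(win_t, np.log(win_y))
        fit_r = float(abs(res.rvalue))
        f1 = float(y[seg.i_f1])
        f2 = float(y[seg.i_f2]) if seg.i_f2 is not None else None
        t_exp = float(t[seg.i_f1] - t[0])
        if seg.i_f2 is None:
            t_dec = None
        elif seg.t_dec_refined is not None:
            t_dec = float(seg.t_dec_refined)
        else:
            t_dec = float(t[seg.i_f2] - t[seg.i_f1])
        accepted = fit_r > MIN_FIT_R and seg.pre_peak_ok
        return KineticsResults(
            cell_id=self.trace.cell_id,
            k=float(res.slope),
            F0=float(np.exp(res.intercept)),
            F1=f1,
            F2=f2,
            t_exp=t_exp,
            t_dec=t_dec,
            fit_r=fit_r,
            accepted=bool(accepted),
            k_stderr=float(res.stderr),
            n_points=len(win_y),
            peaked=seg.peak_found,
        )


def fit_exponential_phase(
    trace: FluorescenceTrace, segmentation: PhaseSegmentation | None = None
) -> KineticsResults:
    """Functional wrapper over :class:`ExponentialPhaseModel`."""
    return ExponentialPhaseModel(trace, segmentation).fit()


def phase_deltas(fit: KineticsResults) -> tuple[float | None, float | None]:
    """Amplitudes of the two phases: (F1 − F0, F1 − F2 or None).

    The decay delta is None (flagged undefined) when the cell showed no
    decay phase.  Both deltas are None when the trace never reached a
    maximum in-record: without an F1 landmark the "amplitude" would just
    measure the recording length.
    """
    if not fit.peaked:
        return None, None
    d_exp = max(fit.F1 - fit.F0, 0.0)
    d_dec = None if fit.F2 is None else max(fit.F1 - fit.F2, 0.0)
    return d_exp, d_dec


# ---------------------------------------------------------------------------
# pH-response fitting


@dataclass(frozen=True)
class PHResponseResults:
    """Exponential pH-response fit y = a·e^(b·pH) on level means."""

    a: float
    b: float  # per pH unit
    r2: float
    domain: tuple[float, float]
    n_levels: int

    def predict(self, pH) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(pH, dtype=float))

    def fold_change(self, pH_low: float | None = None, pH_high: float | None = None) -> float:
        """Predicted fold change of y across the fitted (or given) pH span."""
        lo = self.domain[0] if pH_low is None else pH_low
        hi = self.domain[1] if pH_high is None else pH_high
        return float(np.exp(self.b * (hi - lo)))

    def summary(self) -> str:
        return "\n".join(
            [
                "pH-response fit  y = a * exp(b * pHe)",
                "=" * 45,
                f"a                {self.a:.4g}",
                f"b  [1/pH]        {self.b:.4f}",
                f"r^2              {self.r2:.4f}",
                f"domain           pHe {self.domain[0]:.1f} - {self.domain[1]:.1f}",
                f"levels used      {self.n_levels}",
                f"fold over domain {self.fold_change():.2f}",
            ]
        )


class PHResponseModel:
    """Exponential model of a kinetic quantity versus external pH.

    The fit is a log-linear regression on the *level means* inside the
    stated pH domain; levels outside the domain (e.g. the most basic
    treatment) are excluded.
    """

    def __init__(self, ph_values, y_values, domain: tuple[float, float] = (6.4, 8.2)):
        ph = np.asarray(ph_values, dtype=float)
        y = np.asarray(y_values, dtype=float)
        if ph.shape != y.shape:
            raise ValueError("pH and y must align")
        self.domain = (float(domain[0]), float(domain[1]))
        keep = (ph >= self.domain[0]) & (ph <= self.domain[1]) & (y > 0)
        levels = np.unique(ph[keep])
        if len(levels) < 3:
            raise ValueError("need at least 3 pH levels inside the domain")
        self.level_ph = levels
        self.level_means = np.array([y[keep][ph[keep] == p].mean() for p in levels])

    @classmethod
    def from_dataframe(
        cls, table: pd.DataFrame, ph_col: str = "pHe", value_col: str = "k",
        domain: tuple[float, float] = (6.4, 8.2),
    ) -> "PHResponseModel":
        return cls(table[ph_col].values, table[value_col].values, domain=domain)

    def fit(self) -> PHResponseResults:
        res = stats.linregress(self.level_ph, np.log(self.level_means))
        return PHResponseResults(
            a=float(np.exp(res.intercept)),
            b=float(res.slope),
            r2=float(res.rvalue**2),
            domain=self.domain,
            n_levels=len(self.level_ph),
        )


def fit_ph_dependence(
    ph_values, y_values, domain: tuple[float, float] = (6.4, 8.2)
) -> PHResponseResults:
    """Functional wrapper over :class:`PHResponseModel`."""
    return PHResponseModel(ph_values, y_values, domain=domain).fit()
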