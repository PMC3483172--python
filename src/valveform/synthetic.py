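"""Synthetic-data generators with ground truth.

Every generator emulates one of the raw data modalities the analysis
consumes and returns, next to the images or tables, a truth object that
records exactly what was injected.  The defaults encode the study
conditions of the emulated experiments: frames every 5 min, an
exponential accumulation phase of ~90 min followed (in ~75% of cells) by
a ~47 min decay, dark quasi-hexagonal pore arrays grouped into radial
fingers, a 9-point dye-dilution design spanning 0–62.5 µM, and
dual-excitation ratio pairs over pH 6.4–8.5.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "KineticParams",
    "SceneTruth",
    "PoreTruth",
    "TimelapseConfig",
    "ValveConfig",
    "RatioPairConfig",
    "PlacementError",
    "simulate_trace",
    "trace_noise_sigma",
    "generate_timelapse",
    "generate_valve_image",
    "generate_dilution_series",
    "generate_ratio_pair",
    "valve_config_for_porosity",
    "DILUTION_DESIGN_UM",
]

#: the 9-concentration dilution design of the fluorescence calibration, µM
DILUTION_DESIGN_UM = tuple(np.round(np.linspace(0.0, 62.5, 9), 5))


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""


@dataclass(frozen=True)
class KineticParams:
    """Per-cell parameters of the two-phase valve-formation trace.

    The trace rises as ``F0 * exp(k * t)`` until ``t_peak`` (the end of the
    exponential phase).  Cells with ``has_decay`` then decay monotonically,
    reaching the floor ``F2 = decay_floor * F(t_peak)`` at
    ``t_peak + t_dec`` — the minimum the trace then holds.  The decay is an
    exponential segment normalised to attain the floor exactly at its end
    (observed traces show a defined minimum, not an asymptote); its
    curvature is set by ``decay_rate`` (default 1.5/t_dec, a moderately
    convex decline with nonzero slope at the minimum).  Cells without decay
    keep accumulating.
    """

    k: float  # per minute
    F0: float  # intensity (or concentration) units
    t_peak: float  # minutes
    t_dec: float = 47.0  # minutes, duration of the decay phase
    decay_rate: float | None = None  # per minute; None -> 1.5/t_dec
    decay_floor: float = 0.5  # dimensionless fraction of F1
    has_decay: bool = True

    def __post_init__(self) -> None:
        if self.k <= 0 or self.F0 <= 0 or self.t_peak <= 0 or self.t_dec <= 0:
            raise ValueError("kinetic parameters must be strictly positive")
        if self.decay_rate is None:
            object.__setattr__(self, "decay_rate", 1.5 / self.t_dec)
        if self.decay_rate <= 0:
            raise ValueError("decay_rate must be positive")
        if not 0.0 <= self.decay_floor < 1.0:
            raise ValueError("decay_floor must lie in [0, 1)")


def simulate_trace(params: KineticParams, times: np.ndarray) -> np.ndarray:
    """Evaluate the closed-form two-phase trace at ``times`` (minutes).

    Continuous at ``t_peak`` and at ``t_peak + t_dec``; the decay is
    monotone toward ``F2 = decay_floor * F(t_peak)``, which it reaches at
    ``t_peak + t_dec`` and then holds.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    f = params.F0 * np.exp(params.k * t)
    if params.has_decay:
        f1 = params.F0 * np.exp(params.k * params.t_peak)
        f2 = params.decay_floor * f1
        tau = t - params.t_peak
        r, T = params.decay_rate, params.t_dec
        e_t = np.exp(-r * T)
        dec = (tau > 0) & (tau <= T)
        f[dec] = f2 + (f1 - f2) * (np.exp(-r * tau[dec]) - e_t) / (1.0 - e_t)
        f[tau > T] = f2
    return f


def trace_noise_sigma(
    peak_signal: float, cell_radius_px: float, pixel_snr: float
) -> float:
    """Integrated-trace noise implied by a per-pixel signal-to-noise ratio.

    A cell of radius r covers n = πr² pixels; at peak the per-pixel signal
    is peak/n and the per-pixel noise std is (peak/n)/SNR.  Integrating
    independent pixel noise over the cell gives a trace noise of
    peak/(SNR·√n) — photometry gains √n over the raw image.
    """
    n_px = max(np.pi * cell_radius_px**2, 1.0)
    return float(peak_signal / (pixel_snr * np.sqrt(n_px)))


@dataclass
class SceneTruth:
    """Ground truth emitted by :func:`generate_timelapse`."""

    cell_ids: list[int]
    positions: np.ndarray  # (n_frames, n_cells, 2) of (x, y), pixels
    kinetic_params: list[KineticParams]
    cell_radius_px: float
    drift_px_per_frame: tuple[float, float]
    frame_interval_min: float

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def times_min(self, n_frames: int | None = None) -> np.ndarray:
        n = self.positions.shape[0] if n_frames is None else n_frames
        return np.arange(n) * self.frame_interval_min

    def to_json(self) -> str:
        d = {
            "cell_ids": self.cell_ids,
            "positions": self.positions.tolist(),
            "kinetic_params": [asdict(p) for p in self.kinetic_params],
            "cell_radius_px": self.cell_radius_px,
            "drift_px_per_frame": list(self.drift_px_per_frame),
            "frame_interval_min": self.frame_interval_min,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "SceneTruth":
        d = json.loads(text)
        return cls(
            cell_ids=list(d["cell_ids"]),
            positions=np.asarray(d["positions"], dtype=float),
            kinetic_params=[KineticParams(**p) for p in d["kinetic_params"]],
            cell_radius_px=d["cell_radius_px"],
            drift_px_per_frame=tuple(d["drift_px_per_frame"]),
            frame_interval_min=d["frame_interval_min"],
        )


@dataclass(frozen=True)
class TimelapseConfig:
    """Settings for :func:`generate_timelapse`.

    The kinetic parameters of each cell are drawn from log-normal
    distributions centred on ``k_mean`` etc. with coefficient of variation
    ``param_cv`` (``param_cv = 0`` gives identical cells).
    """

    n_frames: int = 96
    frame_shape: tuple[int, int] = (256, 256)  # (rows, cols)
    n_cells: int = 8
    cell_radius_px: float = 6.0
    frame_interval_min: float = 5.0
    noise_sigma: float = 2.0
    background_level: float = 100.0
    gradient_amplitude: float = 0.0
    drift_px_per_frame: tuple[float, float] = (0.5, 0.0)
    jitter_px: float = 0.0
    min_separation_factor: float = 4.0  # in units of cell radius
    # kinetic-parameter population
    k_mean: float = 0.013  # per minute
    F0_mean: float = 200.0  # integrated intensity at t = 0
    t_peak_mean: float = 90.0  # minutes
    decay_duration_mean: float = 47.0  # minutes; per-cell t_dec is drawn around this
    decay_floor: float = 0.5
    has_decay_fraction: float = 0.75
    param_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.n_cells < 0 or self.noise_sigma < 0 or self.gradient_amplitude < 0:
            raise ValueError("counts and amplitudes must be non-negative")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    if cv <= 0:
        return np.full(size, mean)
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def sample_kinetic_params(
    config: TimelapseConfig, rng: np.random.Generator
) -> list[KineticParams]:
    n = config.n_cells
    k = _lognormal(rng, config.k_mean, config.param_cv, n)
    f0 = _lognormal(rng, config.F0_mean, config.param_cv, n)
    tp = _lognormal(rng, config.t_peak_mean, config.param_cv, n)
    dur = _lognormal(rng, config.decay_duration_mean, config.param_cv, n)
    has_decay = rng.random(n) < config.has_decay_fraction
    return [
        KineticParams(
            k=float(k[i]),
            F0=float(f0[i]),
            t_peak=float(tp[i]),
            t_dec=float(dur[i]),
            decay_floor=config.decay_floor,
            has_decay=bool(has_decay[i]),
        )
        for i in range(n)
    ]


def _place_cells(
    config: TimelapseConfig, rng: np.random.Generator, total_drift: np.ndarray
) -> np.ndarray:
    """Initial (x, y) centers such that every cell stays in frame under drift."""
    h, w = config.frame_shape
    r = config.cell_radius_px
    margin = r + 1.0 + config.jitter_px * 3
    lo = np.array([margin, margin]) + np.maximum(-total_drift, 0)
    hi = np.array([w - 1 - margin, h - 1 - margin]) - np.maximum(total_drift, 0)
    if np.any(hi <= lo):
        raise PlacementError("frame too small for the requested drift and radius")
    min_sep = config.min_separation_factor * r
    centers: list[np.ndarray] = []
    for _ in range(config.n_cells):
        for _attempt in range(2000):
            c = rng.uniform(lo, hi)
            if all(np.hypot(*(c - o)) >= min_sep for o in centers):
                centers.append(c)
                break
        else:
            raise PlacementError(
                f"could not place {config.n_cells} cells at separation {min_sep:.1f} px"
            )
    return np.array(centers).reshape(config.n_cells, 2)


def _disk_mask(shape: tuple[int, int], center_xy: np.ndarray, radius: float):
    """Boolean disk mask (pixel-center membership) and its pixel count."""
    h, w = shape
    cx, cy = center_xy
    x0, x1 = int(max(0, np.floor(cx - radius - 1))), int(min(w, np.ceil(cx + radius + 2)))
    y0, y1 = int(max(0, np.floor(cy - radius - 1))), int(min(h, np.ceil(cy + radius + 2)))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    return (slice(y0, y1), slice(x0, x1)), mask


def background_field(config: TimelapseConfig) -> np.ndarray:
    """Fixed-pattern background: constant level plus a planar gradient."""
    h, w = config.frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = (xx + yy) / max(w + h - 2, 1)
    return config.background_level + config.gradient_amplitude * ramp


def generate_timelapse(
    config: TimelapseConfig, seed: int
) -> tuple[np.ndarray, SceneTruth]:
    """Render a fluorescence time-lapse stack of drifting cells.

    Each cell is a uniform disk whose *integrated* intensity at frame time t
    equals :func:`simulate_trace` exactly (before noise), on top of a fixed
    background field plus i.i.d. Gaussian noise.  Identical (config, seed)
    pairs give bit-identical stacks.
    """
    rng = np.random.default_rng(seed)
    h, w = config.frame_shape
    times = np.arange(config.n_frames) * config.frame_interval_min
    params = sample_kinetic_params(config, rng)
    drift = np.asarray(config.drift_px_per_frame, dtype=float)
    total_drift = drift * (config.n_frames - 1)
    centers0 = _place_cells(config, rng, total_drift)
    jitter = (
        rng.normal(0.0, config.jitter_px, (config.n_frames, config.n_cells, 2))
        if config.jitter_px > 0
        else np.zeros((config.n_frames, config.n_cells, 2))
    )
    positions = (
        centers0[None, :, :]
        + drift[None, None, :] * np.arange(config.n_frames)[:, None, None]
        + jitter
    )
    positions = np.clip(
        positions,
        [config.cell_radius_px, config.cell_radius_px],
        [w - 1 - config.cell_radius_px, h - 1 - config.cell_radius_px],
    )
    bg = background_field(config)
    stack = np.empty((config.n_frames, h, w), dtype=np.float32)
    traces = [simulate_trace(p, times) for p in params]
    for t in range(config.n_frames):
        frame = bg.copy()
        for i in range(config.n_cells):
            sl, mask = _disk_mask((h, w), positions[t, i], config.cell_radius_px)
            n_px = int(mask.sum())
            if n_px:
                frame[sl][mask] += traces[i][t] / n_px
        if config.noise_sigma > 0:
            frame = frame + rng.normal(0.0, config.noise_sigma, (h, w))
        stack[t] = frame
    truth = SceneTruth(
        cell_ids=list(range(config.n_cells)),
        positions=positions,
        kinetic_params=params,
        cell_radius_px=config.cell_radius_px,
        drift_px_per_frame=tuple(drift),
        frame_interval_min=config.frame_interval_min,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# TEM-like valve images


@dataclass
class PoreTruth:
    """Ground truth emitted by :func:`generate_valve_image`."""

    centers: np.ndarray  # (n, 2) of (x, y), pixels
    radii: np.ndarray  # (n,), pixels
    lattice_spacing: float
    finger_axes: list[tuple[tuple[float, float], tuple[float, float]]]
    rib_width: float
    image_shape: tuple[int, int]

    def porosity(self, margin: float = 0.0) -> float:
        """Analytic porosity Σπr²/A over the interior window inset by ``margin``."""
        h, w = self.image_shape
        x, y = self.centers[:, 0], self.centers[:, 1]
        inside = (x >= margin) & (x < w - margin) & (y >= margin) & (y < h - margin)
        area = (w - 2 * margin) * (h - 2 * margin)
        return float(np.sum(np.pi * self.radii[inside] ** 2) / area)

    def to_json(self) -> str:
        return json.dumps(
            {
                "centers": self.centers.tolist(),
                "radii": self.radii.tolist(),
                "lattice_spacing": self.lattice_spacing,
                "finger_axes": self.finger_axes,
                "rib_width": self.rib_width,
                "image_shape": list(self.image_shape),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PoreTruth":
        d = json.loads(text)
        return cls(
            centers=np.asarray(d["centers"], dtype=float),
            radii=np.asarray(d["radii"], dtype=float),
            lattice_spacing=d["lattice_spacing"],
            finger_axes=[tuple(map(tuple, a)) for a in d["finger_axes"]],
            rib_width=d["rib_width"],
            image_shape=tuple(d["image_shape"]),
        )


@dataclass(frozen=True)
class ValveConfig:
    """Settings for :func:`generate_valve_image`.

    Pores sit on a perturbed triangular lattice whose rows run along x.
    Rows are grouped into fingers of ``rows_per_finger`` rows; consecutive
    fingers are separated by bright ribs of ``rib_width`` px (0 disables
    the finger structure).
    """

    image_shape: tuple[int, int] = (384, 384)
    lattice_spacing: float = 24.0  # px, within-row and between-row pitch
    pore_radius: float = 5.0  # px
    radius_cv: float = 0.0
    jitter_px: float = 0.0
    rows_per_finger: int = 3
    rib_width: float = 30.0  # px, pore-edge-to-pore-edge bright gap between fingers
    background_level: float = 200.0
    pore_level: float = 40.0
    noise_sigma: float = 0.0
    # when set, radii are rescaled after placement so the realized interior
    # porosity matches this value exactly (lattice packing is quantized by
    # the frame, so the analytic radius alone lands within a few percent)
    target_porosity: float | None = None

    def __post_init__(self) -> None:
        if self.lattice_spacing <= 2 * self.pore_radius:
            raise ValueError("lattice spacing must exceed the pore diameter")
        if self.pore_radius <= 0:
            raise ValueError("pore radius must be positive")


def valve_config_for_porosity(
    porosity: float, base: ValveConfig | None = None
) -> ValveConfig:
    """Derive a :class:`ValveConfig` whose analytic porosity matches ``porosity``.

    Solves Σπr²/A = target for the pore radius given the base lattice,
    accounting for the rib gaps between fingers.
    """
    base = base or ValveConfig()
    s = base.lattice_spacing
    rp = s * np.sqrt(3) / 2
    n = base.rows_per_finger
    if base.rib_width > 0 and n > 0:
        # period along y contains n rows: (n-1) row pitches plus the rib gap
        # rib_width + 2r; porosity = pi n r^2 / (period * s) is quadratic in r
        a = np.pi * n
        b = -2.0 * porosity * s
        c = -porosity * s * ((n - 1) * rp + base.rib_width)
        r = float((-b + np.sqrt(b * b - 4 * a * c)) / (2 * a))
    else:
        r = float(np.sqrt(porosity * rp * s / np.pi))
    if s <= 2 * r:
        raise ValueError("target porosity too high for the base lattice spacing")
    return replace(base, pore_radius=r, target_porosity=porosity)


def generate_valve_image(config: ValveConfig, seed: int) -> tuple[np.ndarray, PoreTruth]:
    """Render dark pores on a bright background with finger/rib structure."""
    rng = np.random.default_rng(seed)
    h, w = config.image_shape
    s = config.lattice_spacing
    row_pitch = s * np.sqrt(3) / 2
    centers: list[tuple[float, float]] = []
    finger_axes: list[tuple[tuple[float, float], tuple[float, float]]] = []
    y = config.pore_radius + 2.0
    row_idx = 0
    finger_rows: list[float] = []
    while y < h - config.pore_radius - 2.0:
        x0 = config.pore_radius + 2.0 + (s / 2 if row_idx % 2 else 0.0)
        xs = np.arange(x0, w - config.pore_radius - 2.0, s)
        for x in xs:
            centers.append((float(x), float(y)))
        finger_rows.append(y)
        row_idx += 1
        if config.rib_width > 0 and config.rows_per_finger > 0 and (
            row_idx % config.rows_per_finger == 0
        ):
            axis_y = float(np.mean(finger_rows))
            finger_axes.append(((0.0, axis_y), (float(w - 1), axis_y)))
            finger_rows = []
            # rib gap is measured pore-edge to pore-edge
            y += config.rib_width + 2 * config.pore_radius
        else:
            y += row_pitch
    if finger_rows:
        axis_y = float(np.mean(finger_rows))
        finger_axes.append(((0.0, axis_y), (float(w - 1), axis_y)))
    centers_arr = np.asarray(centers, dtype=float)
    if config.jitter_px > 0:
        centers_arr = centers_arr + rng.normal(0, config.jitter_px, centers_arr.shape)
    radii = _lognormal(rng, config.pore_radius, config.radius_cv, len(centers_arr))
    if config.target_porosity is not None:
        margin = 2.0 * config.pore_radius
        x, y = centers_arr[:, 0], centers_arr[:, 1]
        in_win = (x >= margin) & (x < w - margin) & (y >= margin) & (y < h - margin)
        realized = np.sum(np.pi * radii[in_win] ** 2) / (
            (w - 2 * margin) * (h - 2 * margin)
        )
        radii = radii * np.sqrt(config.target_porosity / realized)
    # enforce the bounds and non-overlap invariants after jitter
    keep = np.ones(len(centers_arr), dtype=bool)
    kept: list[int] = []
    for i, (c, r) in enumerate(zip(centers_arr, radii)):
        if not (r <= c[0] < w - r and r <= c[1] < h - r):
            keep[i] = False
            continue
        for j in kept:
            if np.hypot(*(c - centers_arr[j])) < r + radii[j]:
                keep[i] = False
                break
        if keep[i]:
            kept.append(i)
    img = np.full((h, w), config.background_level, dtype=np.float32)
    for i in kept:
        sl, mask = _disk_mask((h, w), centers_arr[i], radii[i])
        img[sl][mask] = config.pore_level
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, (h, w)).astype(np.float32)
    truth = PoreTruth(
        centers=centers_arr[keep],
        radii=radii[keep],
        lattice_spacing=s,
        finger_axes=finger_axes,
        rib_width=config.rib_width,
        image_shape=(h, w),
    )
    return img, truth


# ---------------------------------------------------------------------------
# Dye-dilution calibration series


def generate_dilution_series(
    concentrations=DILUTION_DESIGN_UM,
    slope: float = 50.0,
    intercept: float = 120.0,
    noise: float = 0.0,
    n_replicates: int = 36,
    seed: int = 0,
) -> pd.DataFrame:
    """Linear dye-dilution fluorescence table.

    Mean intensity at concentration c equals ``slope * c + intercept``;
    each of ``n_replicates`` measurements per level gets additive Gaussian
    noise of standard deviation ``noise``.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for c in conc:
        mu = slope * c + intercept
        if noise > 0:
            vals = mu + rng.normal(0.0, noise, n_replicates)
        else:
            vals = np.full(n_replicates, mu)
        for v in vals:
            rows.append({"concentration_uM": float(c), "intensity": float(v)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dual-excitation ratiometric image pairs


@dataclass(frozen=True)
class RatioPairConfig:
    """Settings for :func:`generate_ratio_pair`."""

    frame_shape: tuple[int, int] = (128, 128)
    n_cells: int = 6
    cell_radius_px: float = 6.0
    ch2_level: float = 400.0  # per-pixel cell brightness in the pH-insensitive channel
    background_ch1: float = 50.0
    background_ch2: float = 60.0
    noise_sigma: float = 0.0


def generate_ratio_pair(
    pH: float, calib, seed: int, config: RatioPairConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-channel (485/436-style) image pair of dye-loaded cells at ``pH``.

    ``calib`` must expose ``forward(pH) -> ratio`` (see
    :class:`valveform.physiology.PHCalibration`); the per-cell
    background-subtracted channel-1/channel-2 ratio equals ``calib.forward(pH)``
    up to noise.  Returns (channel-1 image, channel-2 image, cell centers).
    """
    config = config or RatioPairConfig()
    lo, hi = getattr(calib, "domain", (-np.inf, np.inf))
    if not lo <= pH <= hi:
        raise ValueError(f"pH {pH} outside calibration domain [{lo}, {hi}]")
    ratio = float(calib.forward(pH))
    rng = np.random.default_rng(seed)
    h, w = config.frame_shape
    r = config.cell_radius_px
    margin = r + 2
    centers = []
    for _ in range(config.n_cells):
        for _attempt in range(2000):
            c = rng.uniform([margin, margin], [w - 1 - margin, h - 1 - margin])
            if all(np.hypot(*(c - o)) >= 3 * r for o in centers):
                centers.append(c)
                break
        else:
            raise PlacementError("could not place ratio-pair cells")
    ch1 = np.full((h, w), config.background_ch1, dtype=np.float32)
    ch2 = np.full((h, w), config.background_ch2, dtype=np.float32)
    for c in centers:
        sl, mask = _disk_mask((h, w), c, r)
        ch2[sl][mask] += config.ch2_level
        ch1[sl][mask] += config.ch2_level * ratio
    if config.noise_sigma > 0:
        ch1 = ch1 + rng.normal(0, config.noise_sigma, (h, w)).astype(np.float32)
        ch2 = ch2 + rng.normal(0, config.noise_sigma, (h, w)).astype(np.float32)
    return ch1, ch2, np.asarray(centers, dtype=float)


def measure_ratio(
    ch1: np.ndarray,
    ch2: np.ndarray,
    centers: np.ndarray,
    cell_radius_px: float,
    background_ch1: float | None = None,
    background_ch2: float | None = None,
) -> np.ndarray:
    """Per-cell background-corrected channel ratio.

    Backgrounds default to the image medians (robust when cells cover a
    small area fraction).  Raises if no cells are given — a background-only
    pair has no defined ratio.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        raise ValueError("ratio undefined: no cells in the image pair")
    b1 = float(np.median(ch1)) if background_ch1 is None else background_ch1
    b2 = float(np.median(ch2)) if background_ch2 is None else background_ch2
    out = []
    for c in centers:
        sl, mask = _disk_mask(ch1.shape, c, cell_radius_px)
        s1 = float(np.mean(ch1[sl][mask])) - b1
        s2 = float(np.mean(ch2[sl][mask])) - b2
        if s2 <= 0:
            raise ValueError("ratio undefined: no signal above background")
        out.append(s1 / s2)
    return np.asarray(out)
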