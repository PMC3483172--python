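"""End-to-end orchestration: configuration, stage chaining, tables, overlays.

``run_timelapse`` chains detection → tracking → background → level-line
photometry → phase segmentation → exponential fitting for one stack per
external-pH treatment, applies the population inclusion rules (>= 45 min
of data before F1, fit r > 0.95) with an auditable exclusion log, and fits
the pH response of k and of the phase amplitudes across treatments.

``run_morphometry`` chains denoise → binarize → pore detection → spacing /
finger analysis → the trait table, one row per image.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import imaging, kinetics, morphometry

logger = logging.getLogger("valveform")

__all__ = [
    "RunConfig",
    "TimelapseRunResult",
    "run_timelapse",
    "run_morphometry",
    "load_stack",
    "save_stack",
]


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults; JSON round-trippable."""

    # I/O
    inputs: dict[str, str] = field(default_factory=dict)  # label (e.g. pH) -> path
    out_dir: str | None = None
    seed: int = 0
    # acquisition
    frame_interval_min: float = 5.0
    um_per_px: float = 0.65
    # imaging stage
    denoiser: str = "nl_means"  # "nl_means" | "tv" | "none"
    expected_cell_radius_px: float = 6.0
    detect_min_area: int = 20
    detect_max_area: int = 2000
    gating_radius_px: float = 10.0
    min_track_frames: int | None = None  # default: ceil(45/frame_interval) + 1
    annulus_inner_factor: float = 1.5
    annulus_outer_factor: float = 3.0
    shape_n_levels: int = 128
    shape_per_frame: bool = False  # re-extract L every frame (slower)
    # kinetics stage
    calibration_slope: float | None = None  # intensity per µM
    calibration_intercept: float = 0.0
    smoothing_window: int = 3
    ph_domain: tuple[float, float] = (6.4, 8.2)
    # morphometry stage
    scale_nm_per_px: float = 2.0
    pores_dark: bool = True
    pore_min_radius: float = 2.0
    pore_max_radius: float = 50.0
    min_circularity: float = 0.6
    # plumbing
    write_overlays: bool = False

    def min_frames(self) -> int:
        if self.min_track_frames is not None:
            return self.min_track_frames
        return int(math.ceil(kinetics.MIN_PRE_PEAK_MIN / self.frame_interval_min)) + 1

    def to_json(self) -> str:
        d = asdict(self)
        d["ph_domain"] = list(self.ph_domain)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "ph_domain" in d:
            d["ph_domain"] = tuple(d["ph_domain"])
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


def load_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(float)


def save_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a float stack as 16-bit grayscale multi-page TIFF."""
    s = np.asarray(stack)
    lo, hi = float(s.min()), float(s.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    tifffile.imwrite(str(path), ((s - lo) * scale).astype(np.uint16))


@dataclass
class TimelapseRunResult:
    """Tables and summaries produced by :func:`run_timelapse`."""

    per_cell: pd.DataFrame  # one row per track with k, F0, F1, F2, t_Exp, t_Dec, fit_r
    ph_fits: dict[str, kinetics.PHResponseResults]
    exclusions: pd.DataFrame  # structured log, one row per excluded track

    def accepted(self) -> pd.DataFrame:
        return self.per_cell[self.per_cell["accepted"]]


def _analyze_stack(
    stack: np.ndarray, label: str, pH: float | None, config: RunConfig
) -> tuple[list[dict], list[dict]]:
    """Per-cell kinetics rows and exclusion rows for one stack."""
    if config.denoiser != "none":
        frames = [imaging.denoise_frame(f, method=config.denoiser) for f in stack]
    else:
        frames = [np.asarray(f, dtype=float) for f in stack]
    detections = [
        imaging.detect_cells(f, config.detect_min_area, config.detect_max_area)
        for f in frames
    ]
    tracks = imaging.link_tracks(
        detections, max_step=config.gating_radius_px, min_length=2
    )
    rows: list[dict] = []
    exclusions: list[dict] = []
    r_cell = config.expected_cell_radius_px
    for track in tracks:
        if len(track) < config.min_frames():
            exclusions.append(
                {"label": label, "track_id": track.track_id, "reason": "track_too_short"}
            )
            continue
        # brightest observation (aperture sum) anchors the shape extraction
        ap_sums = []
        for f_idx, (cx, cy) in zip(track.frames, track.centers):
            sl, mask = _aperture(frames[f_idx].shape, (cx, cy), r_cell)
            ap_sums.append(float(frames[f_idx][sl][mask].sum()))
        ref = int(np.argmax(ap_sums))
        ref_frame_idx = track.frames[ref]
        try:
            ref_shape = imaging.extract_shape(
                frames[ref_frame_idx],
                tuple(track.centers[ref]),
                n_levels=config.shape_n_levels,
                window_radius=4 * r_cell,
            )
        except imaging.ShapeExtractionError:
            exclusions.append(
                {"label": label, "track_id": track.track_id, "reason": "no_closed_contour"}
            )
            continue
        shapes: list[imaging.LevelLineShape] = []
        backgrounds: list[imaging.BackgroundEstimate] = []
        for i, (f_idx, center) in enumerate(zip(track.frames, track.centers)):
            if config.shape_per_frame:
                try:
                    shp = imaging.extract_shape(
                        frames[f_idx], tuple(center),
                        n_levels=config.shape_n_levels, window_radius=4 * r_cell,
                    )
                except imaging.ShapeExtractionError:
                    shp = _translated(ref_shape, track.centers[ref], center)
            else:
                shp = _translated(ref_shape, track.centers[ref], center)
            shapes.append(shp)
            backgrounds.append(
                imaging.local_background(
                    frames[f_idx], tuple(center),
                    config.annulus_inner_factor * r_cell,
                    config.annulus_outer_factor * r_cell,
                    cell_mask=detections[f_idx].mask,
                )
            )
        trace = imaging.integrate_fluorescence(
            stack, track, shapes, backgrounds, config.frame_interval_min
        )
        biovolume = (
            ref_shape.area * config.um_per_px**2 * ref_shape.width * config.um_per_px
        )
        if config.calibration_slope is not None:
            calib = kinetics.CalibrationLine(
                slope=config.calibration_slope,
                intercept=config.calibration_intercept,
                domain=(0.0, np.inf), r2=1.0, slope_stderr=0.0, residual_std=0.0,
            )
            trace = kinetics.to_concentration(trace, calib, biovolume)
        try:
            seg = kinetics.segment_phases(trace, smoothing_window=config.smoothing_window)
            fit = kinetics.ExponentialPhaseModel(
                trace, seg, use_concentration=config.calibration_slope is not None
            ).fit()
        except ValueError as e:
            exclusions.append(
                {"label": label, "track_id": track.track_id, "reason": f"fit_failed:{e}"}
            )
            continue
        if not seg.pre_peak_ok:
            exclusions.append(
                {"label": label, "track_id": track.track_id, "reason": "pre_f1_below_45min"}
            )
        elif fit.fit_r <= kinetics.MIN_FIT_R:
            exclusions.append(
                {"label": label, "track_id": track.track_id, "reason": "fit_r_below_0.95"}
            )
        d_exp, d_dec = kinetics.phase_deltas(fit)
        rows.append(
            {
                "label": label,
                "pHe": pH,
                "track_id": track.track_id,
                "n_frames": len(track),
                "k": fit.k,
                "F0": fit.F0,
                "F1": fit.F1,
                "F2": fit.F2 if fit.F2 is not None else np.nan,
                "t_Exp": fit.t_exp if fit.peaked else np.nan,
                "t_Dec": fit.t_dec if fit.t_dec is not None else np.nan,
                "dF_exp": d_exp if d_exp is not None else np.nan,
                "dF_dec": d_dec if d_dec is not None else np.nan,
                "fit_r": fit.fit_r,
                "accepted": fit.accepted,
                "peaked": fit.peaked,
                "A_L_px2": ref_shape.area,
                "W_L_px": ref_shape.width,
                "biovolume_um3": biovolume,
            }
        )
    return rows, exclusions


def _aperture(shape, center, radius):
    h, w = shape
    cx, cy = center
    x0, x1 = int(max(0, cx - radius - 1)), int(min(w, cx + radius + 2))
    y0, y1 = int(max(0, cy - radius - 1)), int(min(h, cy + radius + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return (slice(y0, y1), slice(x0, x1)), (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def _translated(
    shape: imaging.LevelLineShape, old_center: np.ndarray, new_center: np.ndarray
) -> imaging.LevelLineShape:
    delta = np.asarray(new_center, dtype=float) - np.asarray(old_center, dtype=float)
    return imaging.LevelLineShape(
        boundary=shape.boundary + delta,
        area=shape.area,
        width=shape.width,
        contrast=shape.contrast,
        level=shape.level,
    )


def run_timelapse(
    config: RunConfig,
    stacks: dict[str, np.ndarray] | None = None,
) -> TimelapseRunResult:
    """Per-cell kinetics table and pH-response summaries for a cohort.

    ``stacks`` maps treatment labels (parseable as pHe values where
    numeric) to (n_frames, h, w) arrays; when omitted the stacks are read
    from ``config.inputs`` as multi-page TIFFs.  Missing calibration is
    tolerated: intensities are reported without concentrations and a
    warning is logged.
    """
    if stacks is None:
        stacks = {label: load_stack(path) for label, path in config.inputs.items()}
    if config.calibration_slope is None:
        logger.warning("no intensity calibration: concentrations omitted")
    all_rows: list[dict] = []
    all_excl: list[dict] = []
    for label, stack in stacks.items():
        try:
            pH = float(label)
        except (TypeError, ValueError):
            pH = None
        rows, excl = _analyze_stack(stack, str(label), pH, config)
        all_rows.extend(rows)
        all_excl.extend(excl)
        logger.info("stack %s: %d cells kept, %d excluded", label, len(rows), len(excl))
    columns = [
        "label", "pHe", "track_id", "n_frames", "k", "F0", "F1", "F2", "t_Exp",
        "t_Dec", "dF_exp", "dF_dec", "fit_r", "accepted", "peaked", "A_L_px2",
        "W_L_px", "biovolume_um3",
    ]
    per_cell = pd.DataFrame(all_rows, columns=columns)
    exclusions = pd.DataFrame(all_excl, columns=["label", "track_id", "reason"])
    ph_fits: dict[str, kinetics.PHResponseResults] = {}
    acc = per_cell[per_cell["accepted"] & per_cell["pHe"].notna()] if len(per_cell) else per_cell
    for quantity in ("k", "dF_exp", "dF_dec") if len(acc) else ():
        sub = acc[np.isfinite(acc[quantity].astype(float))]
        if len(sub) and sub["pHe"].nunique() >= 3:
            try:
                ph_fits[quantity] = kinetics.fit_ph_dependence(
                    sub["pHe"].values, sub[quantity].values, domain=config.ph_domain
                )
            except ValueError:
                pass
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_cell.to_csv(out / "per_cell_kinetics.csv", index=False)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        summary = {
            q: {"a": f.a, "b": f.b, "r2": f.r2, "domain": list(f.domain)}
            for q, f in ph_fits.items()
        }
        (out / "ph_response.json").write_text(json.dumps(summary, indent=2))
        if config.write_overlays:
            _write_overlays(stacks, per_cell, out)
    return TimelapseRunResult(per_cell=per_cell, ph_fits=ph_fits, exclusions=exclusions)


def _write_overlays(stacks, per_cell: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for label, stack in stacks.items():
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(stack.max(axis=0), cmap="gray")
        sub = per_cell[per_cell["label"] == str(label)]
        for _, row in sub.iterrows():
            ax.annotate(
                str(int(row["track_id"])), (5, 5), color="yellow", fontsize=6
            )
        ax.set_title(f"max projection, {label}")
        ax.axis("off")
        fig.savefig(out / f"overlay_{label}.png", dpi=120)
        plt.close(fig)


def run_morphometry(
    config: RunConfig,
    images: dict[str, np.ndarray] | None = None,
    annotations: dict[str, morphometry.MacroAnnotations] | None = None,
) -> pd.DataFrame:
    """One trait row per TEM image (columns per the valve trait schema).

    Images with no detectable pores yield a row of NaN traits rather than
    an error, so batch runs always produce a complete table.
    """
    if images is None:
        images = {label: tifffile.imread(path).astype(float)
                  for label, path in config.inputs.items()}
    annotations = annotations or {}
    rows = []
    for label, img in images.items():
        if config.denoiser != "none":
            img = imaging.denoise_frame(img, method=config.denoiser)
        mask = morphometry.binarize(img, pores_dark=config.pores_dark)
        pores = morphometry.detect_pores(
            mask,
            min_radius=config.pore_min_radius,
            max_radius=config.pore_max_radius,
            min_circularity=config.min_circularity,
        )
        traits = morphometry.valve_traits(
            pores, config.scale_nm_per_px, annotations.get(label)
        )
        row = traits.to_series()
        row["label"] = label
        row["n_pores"] = len(pores)
        rows.append(row)
        logger.info("image %s: %d pores, porosity %.4f", label, len(pores),
                    traits.porosity)
    table = pd.DataFrame(rows)
    if len(table):
        table = table[["label", "n_pores"] + morphometry.TRAIT_COLUMNS]
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "valve_traits.csv", index=False)
    return table
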