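"""Valve-pattern morphometry from TEM images.

Pipeline: denoise → binarize (Otsu) → circular pore detection → Delaunay/
Voronoi adjacency → traits.  The traits follow the standard schema for
Thalassiosiroid valves: pore radius R, nearest-pore distance d1, cribrum
(finger) width D, rib width d2, porosity r, plus the macro traits (valve
width W, fultoportula count N and spacing cp, rimoportula spacing rp)
whose positions are supplied as annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import Delaunay, QhullError, Voronoi
from scipy.spatial.distance import pdist
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening

__all__ = [
    "PoreSet",
    "MorphoTraits",
    "MacroAnnotations",
    "PoreSpacing",
    "FingerAnalysis",
    "binarize",
    "detect_pores",
    "pore_spacing",
    "finger_analysis",
    "valve_traits",
    "TRAIT_COLUMNS",
]

#: Table schema: the eight macro/micro traits plus porosity
TRAIT_COLUMNS = [
    "W_um",
    "N_fultoportulae",
    "cp_um",
    "rp_um",
    "R_mean_nm",
    "d1_mean_nm",
    "D_mean_nm",
    "d2_mean_nm",
    "porosity",
]


def binarize(
    image: np.ndarray, pores_dark: bool = True, min_separation: float = 4.0
) -> np.ndarray:
    """Binary pore mask via Otsu thresholding plus a 1-px opening.

    ``pores_dark`` states the image polarity (TEM pores transmit more and
    appear dark); set False for pre-inverted images.  The Otsu split is
    only trusted when the two classes separate by ``min_separation`` pooled
    standard deviations — a pore-free image yields an empty mask instead of
    a bisected noise histogram.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=bool)
    thr = threshold_otsu(img)
    lo, hi = img[img < thr], img[img >= thr]
    if len(lo) and len(hi):
        pooled = 0.5 * (np.std(lo) + np.std(hi))
        if pooled > 0 and (hi.mean() - lo.mean()) < min_separation * pooled:
            return np.zeros(img.shape, dtype=bool)
    mask = img < thr if pores_dark else img > thr
    return opening(mask, disk(1))


@dataclass
class PoreSet:
    """Detected circular pores."""

    centers: np.ndarray  # (n, 2) of (x, y), px
    radii: np.ndarray  # (n,), px (equivalent-circle radius)
    circularity: np.ndarray  # (n,), 4πA/P² clipped to (0, 1]
    image_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.radii)


def detect_pores(
    mask: np.ndarray,
    min_radius: float = 2.0,
    max_radius: float = 50.0,
    min_circularity: float = 0.6,
) -> PoreSet:
    """Connected components of the pore mask filtered to circular pores.

    R is the equivalent-circle radius sqrt(A/π); circularity is 4πA/P²
    (Crofton perimeter); components touching the image border are excluded.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, _n = ndimage.label(mask)
    h, w = mask.shape
    centers, radii, circ = [], [], []
    for p in measure.regionprops(labels):
        minr, minc, maxr, maxc = p.bbox
        if minr == 0 or minc == 0 or maxr == h or maxc == w:
            continue  # touches the border
        r_eq = np.sqrt(p.area / np.pi)
        if not (min_radius <= r_eq <= max_radius):
            continue
        per = p.perimeter_crofton if p.perimeter_crofton > 0 else p.perimeter
        c = min(4 * np.pi * p.area / per**2, 1.0) if per > 0 else 0.0
        if c < min_circularity:
            continue
        cy, cx = p.centroid
        centers.append((cx, cy))
        radii.append(r_eq)
        circ.append(c)
    return PoreSet(
        centers=np.asarray(centers, dtype=float).reshape(-1, 2),
        radii=np.asarray(radii, dtype=float),
        circularity=np.asarray(circ, dtype=float),
        image_shape=(h, w),
    )


def _interior_pores(pores: PoreSet) -> np.ndarray:
    """Pores whose Voronoi cell is bounded and lies inside the image."""
    h, w = pores.image_shape
    vor = Voronoi(pores.centers)
    interior = np.zeros(len(pores), dtype=bool)
    for i, region_idx in enumerate(vor.point_region):
        region = vor.regions[region_idx]
        if -1 in region or len(region) == 0:
            continue
        verts = vor.vertices[region]
        if np.all(
            (verts[:, 0] >= 0) & (verts[:, 0] <= w - 1)
            & (verts[:, 1] >= 0) & (verts[:, 1] <= h - 1)
        ):
            interior[i] = True
    return interior


@dataclass
class PoreSpacing:
    """Center-to-center distances over interior Delaunay edges."""

    distances: np.ndarray  # px
    edges: np.ndarray  # (m, 2) indices into the PoreSet, both ends interior
    all_edges: np.ndarray  # every Delaunay edge, border cells included
    interior: np.ndarray  # bool per pore: Voronoi cell bounded and in-image

    def histogram(self, bins: int = 30):
        return np.histogram(self.distances, bins=bins)


def pore_spacing(pores: PoreSet) -> PoreSpacing:
    """Nearest-pore distances d1 from the Delaunay triangulation.

    Edges incident to pores whose Voronoi cell touches the image border are
    excluded, so truncated cells do not bias the spacing statistics.
    """
    if len(pores) < 4:
        raise ValueError("need at least 4 pores for spacing analysis")
    try:
        tri = Delaunay(pores.centers)
    except QhullError as e:
        raise ValueError("degenerate (collinear) pore centers") from e
    interior = _interior_pores(pores)
    edges = set()
    all_edges = set()
    for simplex in tri.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            i, j = sorted((int(simplex[a]), int(simplex[b])))
            all_edges.add((i, j))
            if interior[i] and interior[j]:
                edges.add((i, j))
    if not edges:
        raise ValueError("no interior Delaunay edges (all Voronoi cells truncated)")
    edges_arr = np.array(sorted(edges))
    d = np.linalg.norm(
        pores.centers[edges_arr[:, 0]] - pores.centers[edges_arr[:, 1]], axis=1
    )
    return PoreSpacing(
        distances=d,
        edges=edges_arr,
        all_edges=np.array(sorted(all_edges)),
        interior=interior,
    )


@dataclass
class FingerAnalysis:
    """Cribrum (finger) widths D and rib widths d2."""

    D: np.ndarray  # across-finger extents, px
    d2: np.ndarray | None  # gaps between adjacent fingers, px; None if < 2 fingers
    labels: np.ndarray  # finger label per pore (0-based; -1 = unclustered)
    axes: list[tuple[np.ndarray, np.ndarray]]  # (centroid, unit direction) per finger


def finger_analysis(
    pores: PoreSet, alpha: float = 1.4, min_finger_size: int = 3
) -> FingerAnalysis:
    """Cluster pores into fingers and measure cribrum (D) and rib (d2) widths.

    Fingers are single-linkage clusters of pore centers cut at
    alpha × median(d1): within a finger consecutive pores sit ~d1 apart
    while ribs separate fingers by more.  Each finger gets a principal axis;
    D is the extent of the finger's pores (center ± R) perpendicular to its
    own axis, and d2 the gap between adjacent finger hulls along the common
    across-finger direction.
    """
    if len(pores) < 2 * min_finger_size:
        raise ValueError("too few pores for finger analysis")
    # clustering cut from the typical nearest-neighbour spacing (the
    # within-finger pitch); Delaunay medians would be contaminated by the
    # long cross-rib edges in strongly anisotropic layouts
    from scipy.spatial import cKDTree

    nn_d, _ = cKDTree(pores.centers).query(pores.centers, k=2)
    d1_typ = float(np.median(nn_d[:, 1]))
    cut = alpha * d1_typ
    z = linkage(pdist(pores.centers), method="single")
    lab = fcluster(z, t=cut, criterion="distance") - 1
    labels = np.full(len(pores), -1)
    axes: list[tuple[np.ndarray, np.ndarray]] = []
    extents: list[float] = []
    half_widths: list[float] = []
    centroids: list[np.ndarray] = []
    finger_id = 0
    for c in np.unique(lab):
        idx = np.where(lab == c)[0]
        if len(idx) < min_finger_size:
            continue
        pts = pores.centers[idx]
        centroid = pts.mean(axis=0)
        u, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
        major = vt[0]
        minor = vt[1] if vt.shape[0] > 1 else np.array([-major[1], major[0]])
        proj = (pts - centroid) @ minor
        r = pores.radii[idx]
        extent = float((proj + r).max() - (proj - r).min())
        labels[idx] = finger_id
        axes.append((centroid, major))
        extents.append(extent)
        half_widths.append(extent / 2.0)
        centroids.append(centroid)
        finger_id += 1
    if finger_id == 0:
        raise ValueError("no finger clusters found")
    D = np.asarray(extents)
    if finger_id < 2:
        return FingerAnalysis(D=D, d2=None, labels=labels, axes=axes)
    # common across-finger direction: mean of per-finger minor axes, sign-aligned
    minors = []
    for centroid, major in axes:
        m = np.array([-major[1], major[0]])
        if minors and np.dot(m, minors[0]) < 0:
            m = -m
        minors.append(m)
    v_bar = np.mean(minors, axis=0)
    v_bar /= np.linalg.norm(v_bar)
    order = np.argsort([c @ v_bar for c in centroids])
    gaps = []
    for a, b in zip(order[:-1], order[1:]):
        sep = (centroids[b] - centroids[a]) @ v_bar
        gap = sep - half_widths[a] - half_widths[b]
        gaps.append(max(gap, 0.0))
    return FingerAnalysis(D=D, d2=np.asarray(gaps), labels=labels, axes=axes)


@dataclass
class MacroAnnotations:
    """Manually supplied macro-scale landmarks (px unless noted)."""

    valve_width_um: float | None = None
    fultoportulae: np.ndarray | None = None  # (n, 2) of (x, y), central ring
    rimoportulae: np.ndarray | None = None  # (m, 2) of (x, y), on the margin


@dataclass
class MorphoTraits:
    """The valve trait record (one TEM image)."""

    W_um: float
    N_fultoportulae: float
    cp_um: float
    rp_um: float
    R_mean_nm: float
    d1_mean_nm: float
    D_mean_nm: float
    d2_mean_nm: float
    porosity: float

    def to_series(self) -> pd.Series:
        return pd.Series({c: getattr(self, c) for c in TRAIT_COLUMNS})


def _porosity(pores: PoreSet, margin: float) -> float:
    """Σπr²/A over the interior window inset by ``margin`` from the border."""
    h, w = pores.image_shape
    if 2 * margin >= min(h, w):
        raise ValueError("margin too large for the image")
    x, y = pores.centers[:, 0], pores.centers[:, 1]
    inside = (x >= margin) & (x < w - margin) & (y >= margin) & (y < h - margin)
    area = (w - 2 * margin) * (h - 2 * margin)
    return float(np.sum(np.pi * pores.radii[inside] ** 2) / area)


def valve_traits(
    pores: PoreSet,
    scale_nm_per_px: float,
    annotations: MacroAnnotations | None = None,
    porosity_margin: float | None = None,
) -> MorphoTraits:
    """Assemble the trait record from detected pores and macro annotations.

    Porosity is Σπr² over the pores whose centers lie in an interior window
    (inset ``porosity_margin``, default 2×max radius) divided by the window
    area — unbiased for a homogeneous pore field.  Macro traits are NaN when
    their annotations are missing.
    """
    if scale_nm_per_px <= 0:
        raise ValueError("scale must be positive")
    ann = annotations or MacroAnnotations()
    nm = scale_nm_per_px
    if len(pores) == 0:
        return MorphoTraits(
            W_um=ann.valve_width_um if ann.valve_width_um is not None else np.nan,
            N_fultoportulae=np.nan,
            cp_um=np.nan,
            rp_um=np.nan,
            R_mean_nm=np.nan,
            d1_mean_nm=np.nan,
            D_mean_nm=np.nan,
            d2_mean_nm=np.nan,
            porosity=np.nan,
        )
    margin = (
        porosity_margin if porosity_margin is not None else 2.0 * float(pores.radii.max())
    )
    porosity = _porosity(pores, margin)
    d1_nm = D_nm = d2_nm = np.nan
    try:
        d1 = pore_spacing(pores)
        d1_nm = float(d1.distances.mean()) * nm
        fingers = finger_analysis(pores)
        D_nm = float(fingers.D.mean()) * nm
        if fingers.d2 is not None and len(fingers.d2):
            d2_nm = float(fingers.d2.mean()) * nm
    except ValueError:
        pass
    cp_um = np.nan
    n_fp = np.nan
    if ann.fultoportulae is not None and len(ann.fultoportulae) >= 2:
        fp = np.asarray(ann.fultoportulae, dtype=float)
        n_fp = float(len(fp))
        cp_um = float(pdist(fp).min()) * nm / 1000.0
    elif ann.fultoportulae is not None:
        n_fp = float(len(ann.fultoportulae))
    rp_um = np.nan
    if ann.rimoportulae is not None and len(ann.rimoportulae) >= 2:
        rp = np.asarray(ann.rimoportulae, dtype=float)
        centroid = rp.mean(axis=0)
        ang = np.arctan2(rp[:, 1] - centroid[1], rp[:, 0] - centroid[0])
        rp_sorted = rp[np.argsort(ang)]
        consec = np.linalg.norm(np.diff(np.vstack([rp_sorted, rp_sorted[:1]]), axis=0), axis=1)
        rp_um = float(consec.mean()) * nm / 1000.0
    return MorphoTraits(
        W_um=ann.valve_width_um if ann.valve_width_um is not None else np.nan,
        N_fultoportulae=n_fp,
        cp_um=cp_um,
        rp_um=rp_um,
        R_mean_nm=float(pores.radii.mean()) * nm,
        d1_mean_nm=d1_nm,
        D_mean_nm=D_nm,
        d2_mean_nm=d2_nm,
        porosity=porosity,
    )
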