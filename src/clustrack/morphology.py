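"""Super-resolved reconstruction and cluster-shape quantification.

Clusters are defined by *residency*, not by image segmentation: a region
where one molecule's consecutive localizations stay within a
diffraction-limited radius for at least ``residency_min`` frames — far
longer than free diffusion would keep a molecule inside the point-spread
function. Positions from free diffusion are thereby excluded, and
overlapping residency runs of different molecules merge into one region.

Shape is measured two ways. (1) A second-moment ellipse: for a uniform
filled ellipse with semi-axis a the positional variance along that axis
is a²/4, so semi-axes are recovered as 2·√(eigenvalue); localization
scatter inflates each eigenvalue by σ², which is subtracted in
quadrature before the conversion ("corrected" diameters). (2)
Circularity 4πA/P² of the region's concave outline (alpha-shape at a
50 nm probe radius), 1 for a circle and smaller for elongated or ragged
shapes — scatter-inflated perimeters depress it well below the value of
the corresponding smooth ellipse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter, label
from scipy.spatial import Delaunay
from shapely.geometry import Polygon
from shapely.ops import unary_union

__all__ = [
    "ClusterRegion",
    "EllipseFit",
    "reconstruct_positions",
    "identify_clusters",
    "fit_ellipse",
    "alpha_shape",
    "polygon_circularity",
    "circularity",
    "clustered_fraction_from_intensity",
]


@dataclass
class EllipseFit:
    center_nm: tuple[float, float]
    a_nm: float                  # corrected semi-major axis
    b_nm: float                  # corrected semi-minor axis
    a_raw_nm: float
    b_raw_nm: float
    theta: float                 # orientation of the major axis, rad in [0, pi)
    d_max_nm: float = 0.0        # corrected major-axis diameter 2a
    d_min_nm: float = 0.0
    flag: str = "ok"             # ok | clamped | degenerate

    def __post_init__(self) -> None:
        self.d_max_nm = 2.0 * self.a_nm
        self.d_min_nm = 2.0 * self.b_nm


@dataclass
class ClusterRegion:
    """A residency-defined confinement zone and its shape descriptors."""

    region_id: int
    positions_nm: np.ndarray        # (n, 2)
    frames: np.ndarray
    molecule_ids: np.ndarray
    residency_frames: int           # longest contributing residency span
    ellipse: EllipseFit | None = None
    circularity_value: float = np.nan
    area_nm2: float = np.nan
    perimeter_nm: float = np.nan

    @property
    def n_positions(self) -> int:
        return len(self.positions_nm)

    @property
    def center_nm(self) -> np.ndarray:
        return self.positions_nm.mean(axis=0)


def reconstruct_positions(
    loc: pd.DataFrame, bin_nm: float | None = None
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Accumulate all accepted localizations into a point map.

    No averaging across frames — every localization is one point, the
    rendering convention of localization microscopy. With ``bin_nm`` a
    2D count histogram at that bin size is returned alongside the points
    (for display only; all analysis runs on the points).
    """
    if len(loc) == 0:
        raise ValueError("empty localization table")
    pts = loc[["x_nm", "y_nm"]].to_numpy(dtype=float)
    if bin_nm is None:
        return pts
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    nx = max(int(np.ceil((x1 - x0) / bin_nm)), 1)
    ny = max(int(np.ceil((y1 - y0) / bin_nm)), 1)
    img, _, _ = np.histogram2d(
        pts[:, 1], pts[:, 0], bins=(ny, nx), range=((y0, y0 + ny * bin_nm), (x0, x0 + nx * bin_nm))
    )
    return pts, img


def _residency_runs(
    frames: np.ndarray, xy: np.ndarray, radius_nm: float, residency_min: int, max_gap: int = 3
) -> list[np.ndarray]:
    """Index runs where consecutive localizations stay within radius of their centroid."""
    runs: list[np.ndarray] = []
    n = len(frames)
    i = 0
    while i < n:
        j = i + 1
        cx, cy = xy[i]
        count = 1
        while j < n:
            if frames[j] - frames[j - 1] > max_gap + 1:
                break
            nx_, ny_ = (cx * count + xy[j, 0]) / (count + 1), (cy * count + xy[j, 1]) / (count + 1)
            if np.hypot(xy[j, 0] - nx_, xy[j, 1] - ny_) > radius_nm:
                break
            cx, cy, count = nx_, ny_, count + 1
            j += 1
        span = frames[j - 1] - frames[i] + 1
        if span >= residency_min:
            runs.append(np.arange(i, j))
            i = j
        else:
            i += 1
    return runs


def identify_clusters(
    loc: pd.DataFrame,
    residency_min: int = 30,
    radius_nm: float = 125.0,
    id_column: str = "molecule_id",
) -> list[ClusterRegion]:
    """Find residency-defined cluster regions in a localization table.

    For each molecule, maximal runs of consecutive localizations (blink
    gaps of up to 3 frames tolerated) that stay within ``radius_nm`` of
    their running centroid and span at least ``residency_min`` frames
    become candidate regions; candidates whose centroids lie within
    ``radius_nm`` of each other (different molecules visiting the same
    nanodomain) are merged. All other positions — free diffusion — are
    discarded.
    """
    candidates: list[dict] = []
    for mid, grp in loc.groupby(id_column, sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=int)
        xy = grp[["x_nm", "y_nm"]].to_numpy(dtype=float)
        for run in _residency_runs(frames, xy, radius_nm, residency_min):
            candidates.append(
                {
                    "mid": mid,
                    "frames": frames[run],
                    "xy": xy[run],
                    "centroid": xy[run].mean(axis=0),
                    "span": int(frames[run][-1] - frames[run][0] + 1),
                }
            )
    if not candidates:
        return []

    # union-find merge of candidates with nearby centroids
    parent = list(range(len(candidates)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    cents = np.array([c["centroid"] for c in candidates])
    for i in range(len(candidates)):
        d = np.hypot(*(cents[i + 1:] - cents[i]).T)
        for off in np.nonzero(d <= radius_nm)[0]:
            ra, rb = find(i), find(i + 1 + off)
            if ra != rb:
                parent[rb] = ra

    groups: dict[int, list[int]] = {}
    for i in range(len(candidates)):
        groups.setdefault(find(i), []).append(i)

    regions = []
    for rid, members in enumerate(sorted(groups.values(), key=lambda m: m[0])):
        xy = np.concatenate([candidates[i]["xy"] for i in members])
        frames = np.concatenate([candidates[i]["frames"] for i in members])
        mids = np.concatenate(
            [np.full(len(candidates[i]["frames"]), candidates[i]["mid"]) for i in members]
        )
        regions.append(
            ClusterRegion(
                region_id=rid,
                positions_nm=xy,
                frames=frames,
                molecule_ids=mids,
                residency_frames=max(candidates[i]["span"] for i in members),
            )
        )
    return regions


def fit_ellipse(
    positions: np.ndarray | ClusterRegion, sigma_loc_nm: float = 30.0
) -> EllipseFit:
    """Second-moment ellipse of a point set, corrected for localization scatter.

    Semi-axes follow the uniform-ellipse convention a = 2·√λ (λ an
    eigenvalue of the positional covariance); the correction subtracts
    σ² from each eigenvalue before conversion. Eigenvalues driven
    non-positive by the correction are clamped to a (5 nm)² floor and
    flagged; near-collinear point sets are flagged degenerate.
    """
    region = None
    if isinstance(positions, ClusterRegion):
        region = positions
        positions = positions.positions_nm
    pts = np.asarray(positions, dtype=float)
    if len(pts) < 10:
        raise ValueError("need at least 10 positions to fit an ellipse")
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    evals, evecs = np.linalg.eigh(cov)   # ascending
    flag = "ok"
    if evals[0] < 1e-9 * max(evals[1], 1.0):
        flag = "degenerate"
    floor = 5.0**2
    corr = evals - sigma_loc_nm**2
    if (corr < floor).any() and flag == "ok":
        flag = "clamped"
        warnings.warn("noise correction exceeds a covariance eigenvalue; axis clamped",
                      stacklevel=2)
    corr = np.maximum(corr, floor)
    a_raw, b_raw = 2 * np.sqrt(evals[1]), 2 * np.sqrt(evals[0])
    a, b = 2 * np.sqrt(corr[1]), 2 * np.sqrt(corr[0])
    major = evecs[:, 1]
    theta = float(np.arctan2(major[1], major[0])) % np.pi
    fit = EllipseFit(
        center_nm=(float(center[0]), float(center[1])),
        a_nm=float(a), b_nm=float(b),
        a_raw_nm=float(a_raw), b_raw_nm=float(b_raw),
        theta=theta, flag=flag,
    )
    if region is not None:
        region.ellipse = fit
    return fit


def alpha_shape(points: np.ndarray, probe_radius_nm: float = 50.0) -> Polygon:
    """Concave hull: union of Delaunay triangles with circumradius ≤ probe radius.

    The standard alpha-shape construction: a disc of the probe radius
    can roll into any boundary recess it fits through, carving away
    triangles with larger circumradius. Falls back to the convex hull
    when the filter removes everything (sparse point sets).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points for a boundary")
    try:
        tri = Delaunay(pts)
    except Exception as exc:  # collinear input
        raise ValueError("degenerate point set") from exc
    keep = []
    for simplex in tri.simplices:
        pa, pb, pc = pts[simplex]
        la, lb, lc = (
            np.hypot(*(pb - pc)), np.hypot(*(pa - pc)), np.hypot(*(pa - pb))
        )
        s = 0.5 * (la + lb + lc)
        area = max(s * (s - la) * (s - lb) * (s - lc), 0.0) ** 0.5
        if area < 1e-12:
            continue
        circum_r = la * lb * lc / (4.0 * area)
        if circum_r <= probe_radius_nm:
            keep.append(Polygon(pts[simplex]))
    if not keep:
        hull = Polygon(pts[Delaunay(pts).convex_hull[:, 0]]).convex_hull
        return hull
    merged = unary_union(keep)
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    return merged


def polygon_circularity(vertices: np.ndarray) -> float:
    """4πA/P² of a polygon given by ordered boundary vertices."""
    poly = Polygon(np.asarray(vertices, dtype=float))
    if not poly.is_valid or poly.area == 0:
        raise ValueError("invalid boundary polygon")
    return float(4.0 * np.pi * poly.area / poly.length**2)


def circularity(
    region: ClusterRegion | np.ndarray, probe_radius_nm: float = 50.0
) -> float:
    """Circularity 4πA/P² of a reconstructed region's concave outline.

    Normalized so an ideal circle scores 1; elongation and the ragged,
    scatter-inflated perimeter of a localization cloud both push it down.
    """
    pts = region.positions_nm if isinstance(region, ClusterRegion) else np.asarray(region)
    poly = alpha_shape(pts, probe_radius_nm)
    value = float(4.0 * np.pi * poly.area / poly.length**2)
    if isinstance(region, ClusterRegion):
        region.circularity_value = value
        region.area_nm2 = float(poly.area)
        region.perimeter_nm = float(poly.length)
    return value


def clustered_fraction_from_intensity(
    image: np.ndarray,
    k_sigma: float = 4.0,
    offset: float = 0.0,
    smooth_px: float = 1.0,
    dilate_px: int = 3,
) -> float:
    """Fraction of fluorescence in puncta versus the uniform monomer background.

    On a time-averaged projection, diffusing monomers average into a
    uniform background while clusters remain as puncta. Puncta pixels are
    segmented where the smoothed image exceeds the robust background
    (median) by ``k_sigma`` robust standard deviations, then dilated to
    capture the PSF tails; the returned fraction is the
    background-subtracted integrated puncta intensity over the total
    offset-subtracted intensity (photon bookkeeping: puncta excess plus
    uniform level times area).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D time-averaged image")
    if not (img > 0).any():
        raise ValueError("all-zero image")
    sm = gaussian_filter(img, smooth_px)
    bg = float(np.median(sm))
    mad = float(np.median(np.abs(sm - bg))) / 0.6745 + 1e-12
    mask = sm > bg + k_sigma * mad
    if dilate_px > 0 and mask.any():
        mask = binary_dilation(mask, iterations=dilate_px)
    if not mask.any():
        return 0.0
    # re-estimate the uniform level away from the puncta
    uniform = float(np.median(img[~mask])) if (~mask).any() else bg
    puncta_excess = float((img[mask] - uniform).sum())
    total = float(img.sum()) - offset * img.size
    if total <= 0:
        raise ValueError("no signal above the camera offset")
    return max(puncta_excess, 0.0) / total
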