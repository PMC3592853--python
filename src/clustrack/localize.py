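"""Single-emitter detection, bleach-step counting and gap-tolerant track linking.

Detection assumes the sparse-activation regime of photoactivated
single-molecule imaging (≲0.1 emitters/µm², so spots rarely overlap):
local maxima above threshold are refined by least-squares 2D Gaussian
fits, candidates closer than one PSF width are merged, and an intensity
trace's single-molecule identity can be verified by counting step-wise
bleaching events. Linking is frame-to-frame assignment (optimal per frame
pair) with gaps of up to ``max_gap`` consecutive missing frames bridged —
longer absences start a new track, mirroring the tracker rule the
dwell-time analysis relies on.

Coordinates are continuous nm with the origin at the top-left corner of
pixel (0, 0); pixel centers sit at (i + 0.5)·pixel_size. Frames are
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, linear_sum_assignment
from skimage.feature import peak_local_max
from skimage.filters import gaussian as _gaussian_filter

__all__ = [
    "Spot",
    "Trajectory",
    "localize_frame",
    "detect_bleach_steps",
    "link_trajectories",
    "filter_trajectories",
    "tracks_from_table",
]


@dataclass
class Spot:
    """A single sub-pixel emitter detection."""

    frame: int
    x_nm: float
    y_nm: float
    intensity: float        # integrated photons above background
    background: float       # photons/pixel
    sigma_nm: float         # localization uncertainty per coordinate
    flagged: bool = False   # True when merged/too close to a neighbour


@dataclass
class Trajectory:
    """Time-ordered detections of one molecule; frames strictly increasing.

    ``length`` counts detections, not frame span; internal gaps (missed
    frames) are implicit in the frame numbers.
    """

    track_id: int
    frames: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    sigma_nm: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        if len(self.frames) and (np.diff(self.frames) <= 0).any():
            raise ValueError("frames must be strictly increasing")

    @property
    def length(self) -> int:
        return len(self.frames)

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """(start, end) of each run of missing frames, inclusive."""
        out = []
        d = np.diff(self.frames)
        for i in np.nonzero(d > 1)[0]:
            out.append((int(self.frames[i]) + 1, int(self.frames[i + 1]) - 1))
        return out


def _gauss2d_residual(params, xx, yy, img):
    x0, y0, amp, sig, off = params
    model = off + amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sig**2))
    return (model - img).ravel()


def localize_frame(
    image: np.ndarray,
    threshold: float,
    psf_sigma_nm: float = 130.0,
    pixel_size_nm: float = 160.0,
    frame_index: int = 0,
) -> list[Spot]:
    """Detect and sub-pixel-localize emitters in one frame.

    ``threshold`` is in photons above the frame background (median).
    Local maxima of the lightly smoothed image are refined by a
    least-squares 2D Gaussian fit in a window of ±3 PSF sigmas; pairs of
    candidates closer than one PSF FWHM are merged into the brighter one
    and flagged. Localization uncertainty is approximated by
    σ_psf/√N_photons.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    bg = float(np.median(image))
    s_px = psf_sigma_nm / pixel_size_nm
    smooth = _gaussian_filter(image, sigma=max(s_px / 2, 0.5), preserve_range=True)
    peaks = peak_local_max(
        smooth, min_distance=max(int(round(s_px)), 1),
        threshold_abs=bg + threshold * 0.5,
    )

    half = max(int(np.ceil(3 * s_px)), 3)
    h, w = image.shape
    spots: list[Spot] = []
    for pi, pj in peaks:
        i0, i1 = max(pi - half, 0), min(pi + half + 1, h)
        j0, j1 = max(pj - half, 0), min(pj + half + 1, w)
        win = image[i0:i1, j0:j1]
        yy, xx = np.mgrid[i0:i1, j0:j1]
        p0 = (pj + 0.5, pi + 0.5, max(win.max() - bg, 1.0), s_px, bg)
        try:
            res = least_squares(
                _gauss2d_residual, p0, args=(xx + 0.5, yy + 0.5, win),
                bounds=([j0, i0, 0.0, 0.3 * s_px, 0.0],
                        [j1, i1, np.inf, 3.0 * s_px, np.inf]),
                max_nfev=200,
            )
        except ValueError:
            continue
        x0, y0, amp, sig, off = res.x
        n_phot = 2 * np.pi * amp * sig**2
        if n_phot < threshold:
            continue
        spots.append(
            Spot(
                frame=frame_index,
                x_nm=x0 * pixel_size_nm,
                y_nm=y0 * pixel_size_nm,
                intensity=float(n_phot),
                background=float(off),
                sigma_nm=float(psf_sigma_nm / np.sqrt(max(n_phot, 1.0))),
            )
        )

    # merge pairs closer than one PSF FWHM (2.355 sigma): keep the brighter, flag it
    fwhm_nm = 2.355 * psf_sigma_nm
    spots.sort(key=lambda s: -s.intensity)
    kept: list[Spot] = []
    for s in spots:
        close = [k for k in kept if np.hypot(k.x_nm - s.x_nm, k.y_nm - s.y_nm) < fwhm_nm]
        if close:
            for k in close:
                k.flagged = True
            continue
        kept.append(s)
    kept.sort(key=lambda s: (s.y_nm, s.x_nm))
    return kept


def detect_bleach_steps(
    trace: np.ndarray, penalty: float | None = None, min_segment: int = 3
) -> tuple[int, list[int]]:
    """Count downward intensity steps in a trace by penalized change-point search.

    Fits a piecewise-constant model by recursive binary segmentation; a
    split is accepted when it reduces the residual sum of squares by more
    than ``penalty`` (default 2·σ̂²·log n, a BIC-style rate with σ̂ from
    the median absolute first difference). Returns (number of downward
    steps, change frames). A single step to background validates a
    single-molecule spot.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if n < 10:
        raise ValueError("trace must have at least 10 samples")
    if penalty is None:
        sigma = np.median(np.abs(np.diff(trace))) / (np.sqrt(2) * 0.6745) + 1e-12
        penalty = 2.0 * sigma**2 * np.log(n)

    def sse(seg: np.ndarray) -> float:
        return float(((seg - seg.mean()) ** 2).sum())

    def best_split(lo: int, hi: int) -> tuple[float, int]:
        seg = trace[lo:hi]
        base = sse(seg)
        best_gain, best_k = 0.0, -1
        for k in range(lo + min_segment, hi - min_segment + 1):
            gain = base - sse(trace[lo:k]) - sse(trace[k:hi])
            if gain > best_gain:
                best_gain, best_k = gain, k
        return best_gain, best_k

    changes: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * min_segment:
            continue
        gain, k = best_split(lo, hi)
        if k >= 0 and gain > penalty:
            changes.append(k)
            stack.append((lo, k))
            stack.append((k, hi))
    changes.sort()

    down: list[int] = []
    bounds = [0, *changes, n]
    for i in range(1, len(bounds) - 1):
        before = trace[bounds[i - 1]:bounds[i]].mean()
        after = trace[bounds[i]:bounds[i + 1]].mean()
        if after < before:
            down.append(changes[i - 1])
    return len(down), down


def link_trajectories(
    spots: pd.DataFrame | list[Spot],
    max_disp: float = 500.0,
    max_gap: int = 3,
) -> list[Trajectory]:
    """Link detections across frames into gap-tolerant trajectories.

    Assignment between live tracks and the detections of each frame is
    solved optimally (Hungarian algorithm) under a gate of
    ``max_disp·√Δframes`` nm (Brownian displacements grow with the square
    root of the elapsed time). Tracks silent for more than ``max_gap``
    frames are closed; a reappearance within the gap is bridged into the
    same track. Every detection joins at most one track.
    """
    if isinstance(spots, list):
        spots = pd.DataFrame(
            [(s.frame, s.x_nm, s.y_nm, s.sigma_nm) for s in spots],
            columns=["frame", "x_nm", "y_nm", "sigma_nm"],
        )
    if len(spots) == 0:
        return []
    spots = spots.sort_values("frame")

    live: list[dict] = []   # {'frames': [...], 'x': [...], 'y': [...], 'last_f': int}
    done: list[dict] = []

    for f, grp in spots.groupby("frame", sort=True):
        f = int(f)
        # retire tracks whose absence exceeded the gap
        still = []
        for tr in live:
            if f - tr["last_f"] > max_gap + 1:
                done.append(tr)
            else:
                still.append(tr)
        live = still

        det_x = grp["x_nm"].to_numpy()
        det_y = grp["y_nm"].to_numpy()
        n_det, n_tr = len(det_x), len(live)
        assigned = np.full(n_det, False)
        if n_tr and n_det:
            cost = np.empty((n_tr, n_det))
            gate = np.empty((n_tr, n_det), dtype=bool)
            for i, tr in enumerate(live):
                dt = f - tr["last_f"]
                d = np.hypot(det_x - tr["x"][-1], det_y - tr["y"][-1])
                lim = max_disp * np.sqrt(dt)
                cost[i] = d
                gate[i] = d <= lim
            big = cost.max() + max_disp * 100
            cost_m = np.where(gate, cost, big)
            rows, cols = linear_sum_assignment(cost_m)
            for i, j in zip(rows, cols):
                if gate[i, j]:
                    tr = live[i]
                    tr["frames"].append(f)
                    tr["x"].append(det_x[j])
                    tr["y"].append(det_y[j])
                    tr["last_f"] = f
                    assigned[j] = True
        for j in np.nonzero(~assigned)[0]:
            live.append(
                {"frames": [f], "x": [det_x[j]], "y": [det_y[j]], "last_f": f}
            )
    done.extend(live)

    sigma = float(spots["sigma_nm"].median()) if "sigma_nm" in spots else 0.0
    out = [
        Trajectory(
            track_id=k,
            frames=np.array(tr["frames"]),
            x_nm=np.array(tr["x"]),
            y_nm=np.array(tr["y"]),
            sigma_nm=sigma,
        )
        for k, tr in enumerate(done)
    ]
    out.sort(key=lambda t: (t.frames[0], t.track_id))
    for k, t in enumerate(out):
        t.track_id = k
    return out


def filter_trajectories(tracks: list[Trajectory], min_points: int = 30) -> list[Trajectory]:
    """Keep tracks with at least ``min_points`` detections (span not counted)."""
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    return [t for t in tracks if t.length >= min_points]


def tracks_from_table(loc: pd.DataFrame, id_column: str = "molecule_id") -> list[Trajectory]:
    """Build trajectories directly from a localization table with molecule ids.

    Shortcut for simulator output (and any pre-linked data): groups rows
    by ``id_column`` instead of re-linking by proximity.
    """
    out = []
    for k, (mid, grp) in enumerate(loc.groupby(id_column, sort=True)):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                track_id=k,
                frames=grp["frame"].to_numpy(),
                x_nm=grp["x_nm"].to_numpy(),
                y_nm=grp["y_nm"].to_numpy(),
                sigma_nm=float(grp["sigma_nm"].median()) if "sigma_nm" in grp else 0.0,
            )
        )
    return out
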