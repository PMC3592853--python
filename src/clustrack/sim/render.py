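"""Render synthetic movies from ground truth: Gaussian PSFs, shot noise, fusion events.

The renderer integrates an isotropic 2D Gaussian PSF over the pixel grid
(error-function quadrature, so photon counts are conserved exactly before
noise) and applies Poisson shot noise. A bulk channel renders planted
clusters as static diffraction-limited puncta — the non-activated pool a
reporter construct would show.

The fusion simulator produces two-channel movies of exocytic events: the
reporter channel flashes when the fusion pore opens (step increase, fast
decay to baseline), and the molecule channel either disperses (point
emitters released after a short delay diffuse away) or retains a punctum
at the site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from ..units import NM_PER_UM, per_min_to_per_s
from .scenario import AcquisitionSchedule
from .trajectories import GroundTruth

__all__ = ["ImageStack", "render_movie", "simulate_fusion_movie"]


@dataclass
class ImageStack:
    """Multi-channel movie: each channel is a (frames, H, W) photon-count array."""

    channels: dict[str, np.ndarray]
    pixel_size_nm: float
    schedule: AcquisitionSchedule | None = None

    def __post_init__(self) -> None:
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        if len({s for s in shapes.values()}) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for ch, arr in self.channels.items():
            if (arr < 0).any():
                raise ValueError(f"negative pixel values in channel {ch!r}")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]


def _add_emitters(
    frame: np.ndarray,
    xs_nm: np.ndarray,
    ys_nm: np.ndarray,
    photons: np.ndarray,
    psf_sigma_nm: float,
    pixel_size_nm: float,
) -> None:
    """Accumulate PSFs into ``frame`` in place; photons conserved exactly.

    Pixel (i, j) covers [j, j+1)×[i, i+1) pixel units with the origin at
    the top-left corner of pixel (0, 0); emitters outside the frame simply
    deposit their in-frame tail.
    """
    h, w = frame.shape
    s = psf_sigma_nm / pixel_size_nm  # PSF sigma in pixel units
    half = max(int(np.ceil(4 * s)) + 1, 2)
    root2s = np.sqrt(2.0) * s
    for x_nm, y_nm, n_ph in zip(xs_nm, ys_nm, photons):
        xc = x_nm / pixel_size_nm
        yc = y_nm / pixel_size_nm
        j0 = max(int(np.floor(xc)) - half, 0)
        j1 = min(int(np.floor(xc)) + half + 1, w)
        i0 = max(int(np.floor(yc)) - half, 0)
        i1 = min(int(np.floor(yc)) + half + 1, h)
        if j0 >= j1 or i0 >= i1:
            continue
        jx = np.arange(j0, j1 + 1)
        iy = np.arange(i0, i1 + 1)
        fx = 0.5 * (1.0 + erf((jx - xc) / root2s))
        fy = 0.5 * (1.0 + erf((iy - yc) / root2s))
        frame[i0:i1, j0:j1] += n_ph * np.outer(np.diff(fy), np.diff(fx))


def render_movie(
    truth: GroundTruth,
    psf_sigma_nm: float = 130.0,
    photons_per_frame: float = 500.0,
    background: float = 5.0,
    pixel_size_nm: float = 160.0,
    field_size_um: tuple[float, float] = (10.0, 10.0),
    n_frames: int | None = None,
    cluster_photons: float = 2000.0,
    shot_noise: bool = True,
    rng: np.random.Generator | int | None = None,
    schedule: AcquisitionSchedule | None = None,
) -> ImageStack:
    """Render the activated-molecule and bulk channels of a simulated recording.

    Observed emitters (from ``truth.positions``) contribute
    ``photons_per_frame`` each through the PSF; the bulk channel shows the
    planted clusters as static puncta of ``cluster_photons`` per frame.
    ``background`` is in photons/pixel/frame. With ``shot_noise=False``
    the expected (noise-free) photon image is returned.
    """
    if psf_sigma_nm <= 0 or pixel_size_nm <= 0:
        raise ValueError("PSF width and pixel size must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    w_px = int(round(field_size_um[0] * NM_PER_UM / pixel_size_nm))
    h_px = int(round(field_size_um[1] * NM_PER_UM / pixel_size_nm))
    pos = truth.positions
    if n_frames is None:
        n_frames = int(pos["frame"].max()) + 1 if len(pos) else 1

    act = np.full((n_frames, h_px, w_px), float(background))
    obs = pos[pos["observed"]]
    for f, grp in obs.groupby("frame"):
        if f >= n_frames:
            continue
        _add_emitters(
            act[int(f)],
            grp["x_nm"].to_numpy(),
            grp["y_nm"].to_numpy(),
            np.full(len(grp), photons_per_frame),
            psf_sigma_nm,
            pixel_size_nm,
        )

    bulk_frame = np.full((h_px, w_px), float(background))
    if len(truth.clusters):
        _add_emitters(
            bulk_frame,
            truth.clusters["cx_nm"].to_numpy(),
            truth.clusters["cy_nm"].to_numpy(),
            np.full(len(truth.clusters), cluster_photons),
            psf_sigma_nm,
            pixel_size_nm,
        )
    bulk = np.broadcast_to(bulk_frame, (n_frames, h_px, w_px)).copy()

    if shot_noise:
        act = rng.poisson(act).astype(float)
        bulk = rng.poisson(bulk).astype(float)
    return ImageStack(
        channels={"activated": act, "bulk": bulk},
        pixel_size_nm=pixel_size_nm,
        schedule=schedule,
    )


def simulate_fusion_movie(
    n_events: int,
    mode_mix: float,
    schedule: AcquisitionSchedule | None = None,
    psf_sigma_nm: float = 130.0,
    pixel_size_nm: float = 160.0,
    field_size_um: tuple[float, float] = (18.0, 18.0),
    flash_photons: float = 4000.0,
    flash_decay_s: float = 0.25,
    cargo_emitters: int = 20,
    cargo_photons: float = 300.0,
    background: float = 5.0,
    d_free: float = 0.092,
    dispersal_delay_range_s: tuple[float, float] = (0.5, 1.5),
    post_window_s: float = 20.0,
    min_separation_nm: float = 2200.0,
    shot_noise: bool = True,
    rng: np.random.Generator | int | None = None,
) -> tuple[ImageStack, pd.DataFrame]:
    """Two-channel exocytosis movie plus event truth table.

    ``mode_mix`` is the fraction of events that retain their cargo as a
    punctum at the fusion site; the rest release it after a delay drawn
    uniformly from ``dispersal_delay_range_s`` and the emitters diffuse
    away at ``d_free`` µm²/s. The reporter flash is a step increase that
    decays back to baseline with time constant ``flash_decay_s`` (1–2
    frames at 200 ms), emulating luminal pH equilibration on fusion-pore
    opening.

    Truth columns: ``event_id, frame, x_nm, y_nm, mode, delay_s``.
    """
    if not (0.0 <= mode_mix <= 1.0):
        raise ValueError("mode_mix must lie in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if schedule is None:
        schedule = AcquisitionSchedule(t_exp=0.2, t_int=0.2, n_frames=250)

    w_nm = field_size_um[0] * NM_PER_UM
    h_nm = field_size_um[1] * NM_PER_UM
    w_px = int(round(w_nm / pixel_size_nm))
    h_px = int(round(h_nm / pixel_size_nm))
    n_frames = schedule.n_frames
    t_int = schedule.t_int

    # events need pre-event baseline and post-event observation window;
    # simultaneous events are kept a couple of ROI radii apart so each
    # classification window sees a single event
    f_lo = 15
    f_hi = max(f_lo + 1, n_frames - int(round(post_window_s / t_int)) - 5)
    margin = 1500.0  # keep ROIs inside the frame
    conflict_frames = int(round(post_window_s / t_int)) + f_lo
    modes = np.where(rng.uniform(size=n_events) < mode_mix, "retention", "dispersal")
    placed: list[tuple[int, float, float, str]] = []
    for mode in modes:
        for _attempt in range(200):
            f = int(rng.integers(f_lo, f_hi))
            px = float(rng.uniform(margin, w_nm - margin))
            py = float(rng.uniform(margin, h_nm - margin))
            ok = True
            for qf, qx, qy, qmode in placed:
                far = np.hypot(px - qx, py - qy) >= min_separation_nm
                if far:
                    continue
                # a retained punctum occupies its site for the rest of the
                # movie; dispersal events only block their analysis window
                if mode == "retention" or qmode == "retention":
                    ok = False
                    break
                if abs(f - qf) < conflict_frames:
                    ok = False
                    break
            if ok:
                break
        placed.append((f, px, py, mode))
    events = pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "frame": [p[0] for p in placed],
            "x_nm": [p[1] for p in placed],
            "y_nm": [p[2] for p in placed],
            "mode": [p[3] for p in placed],
            "delay_s": rng.uniform(*dispersal_delay_range_s, n_events),
        }
    )
    events.loc[events["mode"] == "retention", "delay_s"] = np.nan

    reporter = np.full((n_frames, h_px, w_px), float(background))
    molecule = np.full((n_frames, h_px, w_px), float(background))

    for ev in events.itertuples():
        f0 = int(ev.frame)
        # reporter flash: step then exponential return to baseline
        for f in range(f0, n_frames):
            amp = flash_photons * np.exp(-(f - f0) * t_int / flash_decay_s)
            if amp < 1.0:
                break
            _add_emitters(
                reporter[f], np.array([ev.x_nm]), np.array([ev.y_nm]),
                np.array([amp]), psf_sigma_nm, pixel_size_nm,
            )
        # cargo: emitters at the site, then retained or dispersed
        ex = np.full(cargo_emitters, ev.x_nm) + rng.normal(0, 40.0, cargo_emitters)
        ey = np.full(cargo_emitters, ev.y_nm) + rng.normal(0, 40.0, cargo_emitters)
        step = np.sqrt(2.0 * d_free * t_int) * NM_PER_UM
        release_f = f0 if ev.mode == "retention" else f0 + int(round(ev.delay_s / t_int))
        for f in range(f0, n_frames):
            if ev.mode == "dispersal" and f >= release_f:
                ex = ex + rng.normal(0, step, cargo_emitters)
                ey = ey + rng.normal(0, step, cargo_emitters)
            _add_emitters(
                molecule[f], ex, ey,
                np.full(cargo_emitters, cargo_photons), psf_sigma_nm, pixel_size_nm,
            )

    if shot_noise:
        reporter = rng.poisson(reporter).astype(float)
        molecule = rng.poisson(molecule).astype(float)
    stack = ImageStack(
        channels={"reporter": reporter, "molecule": molecule},
        pixel_size_nm=pixel_size_nm,
        schedule=schedule,
    )
    return stack, events
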