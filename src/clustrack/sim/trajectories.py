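"""Spatial Brownian-dynamics simulator with cluster capture, hazards and blinking.

Molecules perform 2D Brownian motion in a rectangular membrane patch.
Elliptical nanodomains ("clusters") capture molecules — either by a
first-order association rate (``association='rate'``, the preset default,
which pins the stationary clustered fraction at k_a/(k_a+k_d)) or
geometrically on entry into a cluster ellipse with probability
``p_capture``. Captured molecules diffuse with a reflecting boundary at
the ellipse. Per frame, hazards are applied in a fixed order:
photobleaching (rate k_b per unit illuminated time, i.e. probability
1−exp(−k_b·t_exp) per frame) → endocytosis (clustered molecules only) →
dissociation. Localizations are true positions plus independent Gaussian
noise per coordinate; blinking hides localizations for short runs of
frames (geometric off-times truncated at ``blink_max_gap``).

Every simulated quantity is logged in a :class:`GroundTruth` so each
downstream analysis stage can be scored by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..units import NM_PER_UM, per_min_to_per_s
from .scenario import AcquisitionSchedule, ScenarioConfig

__all__ = [
    "GroundTruth",
    "simulate_trajectories",
    "place_clusters",
    "brownian_tracks",
    "confined_tracks",
    "sample_uniform_ellipse",
]

# Localization-table column schema shared by the simulator and the localizer.
LOC_COLUMNS = ["frame", "molecule_id", "x_nm", "y_nm", "sigma_nm", "channel"]


@dataclass
class GroundTruth:
    """Complete event log of a simulated recording.

    Attributes
    ----------
    molecules : per-molecule summary: ``molecule_id, birth_frame, last_frame,
        cause`` with cause in {bleach, endocytosis, censored}.
    positions : true per-frame state: ``frame, molecule_id, x_nm, y_nm,
        cluster_id, observed`` (cluster_id −1 when free; observed False
        while blinking or after removal).
    dwells : cluster-residency intervals: ``molecule_id, cluster_id,
        start_frame, end_frame, cause`` with cause in
        {dissociation, endocytosis, bleach, censored}.
    clusters : planted geometry: ``cluster_id, cx_nm, cy_nm, a_nm, b_nm,
        theta`` (semi-axes a ≥ b, orientation in rad).
    """

    molecules: pd.DataFrame
    positions: pd.DataFrame
    dwells: pd.DataFrame
    clusters: pd.DataFrame

    def accounting(self) -> pd.Series:
        """Molecule counts by final cause; sums to the simulated total."""
        return self.molecules["cause"].value_counts()


def place_clusters(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Scatter elliptical clusters uniformly over the field.

    Axes are drawn per cluster from the configured mean ± spread
    (truncated so major ≥ minor > 10 nm); orientations are uniform.
    """
    w_nm = config.field_size[0] * NM_PER_UM
    h_nm = config.field_size[1] * NM_PER_UM
    n = rng.poisson(config.cluster_density * config.field_size[0] * config.field_size[1])
    major = rng.normal(config.cluster_axes[0], config.cluster_axes_sd[0], n)
    minor = rng.normal(config.cluster_axes[1], config.cluster_axes_sd[1], n)
    minor = np.clip(minor, 20.0, None)
    major = np.maximum(major, minor)
    return pd.DataFrame(
        {
            "cluster_id": np.arange(n),
            "cx_nm": rng.uniform(0, w_nm, n),
            "cy_nm": rng.uniform(0, h_nm, n),
            "a_nm": major / 2.0,
            "b_nm": minor / 2.0,
            "theta": rng.uniform(0, np.pi, n),
        }
    )


def sample_uniform_ellipse(
    n: int, a: float, b: float, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points inside an ellipse with semi-axes a, b rotated by theta; (n, 2) nm."""
    r = np.sqrt(rng.uniform(0, 1, n))
    phi = rng.uniform(0, 2 * np.pi, n)
    u = r * np.cos(phi) * a
    v = r * np.sin(phi) * b
    c, s = np.cos(theta), np.sin(theta)
    return np.column_stack([u * c - v * s, u * s + v * c])


def _reflect_unit_disc(uv: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fold points back into the unit disc (radial reflection; uniform fallback).

    Radial folding r -> 2 − r approximates specular reflection for small
    overshoots; large overshoots (steps much longer than the domain, where
    successive positions decorrelate anyway) fall back to a uniform draw,
    the stationary distribution of reflecting Brownian motion in the disc.
    """
    out = uv.copy()
    for _ in range(5):
        r = np.hypot(out[:, 0], out[:, 1])
        bad = r > 1.0
        if not bad.any():
            return out
        fold = bad & (r < 2.0)
        out[fold] *= ((2.0 - r[fold]) / r[fold])[:, None]
        far = bad & (r >= 2.0)
        if far.any():
            m = int(far.sum())
            rr = np.sqrt(rng.uniform(0, 1, m))
            ph = rng.uniform(0, 2 * np.pi, m)
            out[far, 0] = rr * np.cos(ph)
            out[far, 1] = rr * np.sin(ph)
    r = np.hypot(out[:, 0], out[:, 1])
    bad = r > 1.0
    if bad.any():
        m = int(bad.sum())
        rr = np.sqrt(rng.uniform(0, 1, m))
        ph = rng.uniform(0, 2 * np.pi, m)
        out[bad, 0] = rr * np.cos(ph)
        out[bad, 1] = rr * np.sin(ph)
    return out


def _blink_draw(n: int, max_gap: int, rng: np.random.Generator) -> np.ndarray:
    """Geometric(1/2) off-times truncated at max_gap frames."""
    g = rng.geometric(0.5, n)
    return np.minimum(g, max_gap)


def simulate_trajectories(
    config: ScenarioConfig,
    schedule: AcquisitionSchedule,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a recording; return (localization table, ground truth).

    The localization table has columns ``frame, molecule_id, x_nm, y_nm,
    sigma_nm, channel`` and contains one row per *observed* localization
    (blinking and removal create gaps). All molecules are activated at
    frame 0 with their free/clustered state drawn from the scenario's
    stationary exchange mixture.
    """
    if config.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else rng)

    n_mol = config.n_molecules
    n_frames = schedule.n_frames
    w_nm = config.field_size[0] * NM_PER_UM
    h_nm = config.field_size[1] * NM_PER_UM

    clusters = place_clusters(config, rng)
    n_clu = len(clusters)
    ccx = clusters["cx_nm"].to_numpy()
    ccy = clusters["cy_nm"].to_numpy()
    ca = clusters["a_nm"].to_numpy()
    cb = clusters["b_nm"].to_numpy()
    cth = clusters["theta"].to_numpy()
    ccos = np.cos(cth)
    csin = np.sin(cth)

    # per-frame hazard probabilities
    p_bleach = 1.0 - np.exp(-per_min_to_per_s(config.k_b) * schedule.t_exp)
    p_endo = 1.0 - np.exp(-per_min_to_per_s(config.k_e) * schedule.t_int)
    p_diss = 1.0 - np.exp(-per_min_to_per_s(config.k_d) * schedule.t_int)
    p_assoc = 1.0 - np.exp(-per_min_to_per_s(config.k_a) * schedule.t_int)

    step_free = np.sqrt(2.0 * config.d_free * schedule.t_int) * NM_PER_UM
    step_in = np.sqrt(2.0 * config.d_in * schedule.t_int) * NM_PER_UM

    # state
    x = rng.uniform(0, w_nm, n_mol)
    y = rng.uniform(0, h_nm, n_mol)
    member = np.full(n_mol, -1, dtype=int)
    alive = np.ones(n_mol, dtype=bool)
    off_left = np.zeros(n_mol, dtype=int)
    dwell_start = np.full(n_mol, -1, dtype=int)
    last_frame = np.full(n_mol, n_frames - 1, dtype=int)
    cause = np.array(["censored"] * n_mol, dtype=object)

    f_eq = config.equilibrium_clustered_fraction
    if n_clu > 0 and f_eq > 0:
        start_clustered = rng.uniform(size=n_mol) < f_eq
        idx = rng.integers(0, n_clu, int(start_clustered.sum()))
        member[start_clustered] = idx
        pos = np.array(
            [
                sample_uniform_ellipse(1, ca[c], cb[c], cth[c], rng)[0] + (ccx[c], ccy[c])
                for c in idx
            ]
        ).reshape(-1, 2)
        x[start_clustered] = pos[:, 0]
        y[start_clustered] = pos[:, 1]
        dwell_start[start_clustered] = 0

    pos_rows: list[np.ndarray] = []
    dwell_rows: list[tuple] = []

    def _record_positions(frame: int) -> None:
        ids = np.nonzero(alive)[0]
        obs = (off_left[ids] == 0).astype(float)
        pos_rows.append(
            np.column_stack(
                [np.full(len(ids), frame, dtype=float), ids.astype(float),
                 x[ids], y[ids], member[ids].astype(float), obs]
            )
        )

    def _end_dwell(ids: np.ndarray, frame: int, why: str) -> None:
        for i in ids:
            dwell_rows.append((int(i), int(member[i]), int(dwell_start[i]), int(frame), why))
            dwell_start[i] = -1

    _record_positions(0)

    for frame in range(1, n_frames):
        live = np.nonzero(alive)[0]
        if live.size == 0:
            break

        # --- hazards, fixed order: bleach -> endocytosis -> dissociation ---
        u = rng.uniform(size=live.size)
        bleached = live[u < p_bleach]
        if bleached.size:
            clustered_b = bleached[member[bleached] >= 0]
            _end_dwell(clustered_b, frame - 1, "bleach")
            alive[bleached] = False
            last_frame[bleached] = frame - 1
            cause[bleached] = "bleach"

        live = np.nonzero(alive)[0]
        clustered = live[member[live] >= 0]
        if clustered.size and p_endo > 0:
            u = rng.uniform(size=clustered.size)
            endo = clustered[u < p_endo]
            if endo.size:
                _end_dwell(endo, frame - 1, "endocytosis")
                alive[endo] = False
                last_frame[endo] = frame - 1
                cause[endo] = "endocytosis"

        live = np.nonzero(alive)[0]
        clustered = live[member[live] >= 0]
        if clustered.size and p_diss > 0:
            u = rng.uniform(size=clustered.size)
            diss = clustered[u < p_diss]
            if diss.size:
                _end_dwell(diss, frame - 1, "dissociation")
                member[diss] = -1

        # --- motion ---
        live = np.nonzero(alive)[0]
        free = live[member[live] < 0]
        if free.size:
            x[free] += rng.normal(0, step_free, free.size)
            y[free] += rng.normal(0, step_free, free.size)
            # reflecting field boundary
            x[free] = np.abs(x[free])
            y[free] = np.abs(y[free])
            x[free] = w_nm - np.abs(w_nm - x[free] % (2 * w_nm))
            y[free] = h_nm - np.abs(h_nm - y[free] % (2 * h_nm))
        clustered = live[member[live] >= 0]
        if clustered.size:
            c = member[clustered]
            dx = x[clustered] - ccx[c]
            dy = y[clustered] - ccy[c]
            # rotate into the ellipse frame, scale to the unit disc
            u0 = (dx * ccos[c] + dy * csin[c]) / ca[c]
            v0 = (-dx * csin[c] + dy * ccos[c]) / cb[c]
            u0 += rng.normal(0, step_in, clustered.size) / ca[c]
            v0 += rng.normal(0, step_in, clustered.size) / cb[c]
            uv = _reflect_unit_disc(np.column_stack([u0, v0]), rng)
            ue = uv[:, 0] * ca[c]
            ve = uv[:, 1] * cb[c]
            x[clustered] = ccx[c] + ue * ccos[c] - ve * csin[c]
            y[clustered] = ccy[c] + ue * csin[c] + ve * ccos[c]

        # --- association / capture ---
        live = np.nonzero(alive)[0]
        free = live[member[live] < 0]
        if free.size and n_clu > 0:
            if config.association == "rate":
                if p_assoc > 0:
                    u = rng.uniform(size=free.size)
                    newly = free[u < p_assoc]
                    if newly.size:
                        # bind to the nearest cluster and relocate into it
                        d2 = (x[newly][:, None] - ccx[None, :]) ** 2 + (
                            y[newly][:, None] - ccy[None, :]
                        ) ** 2
                        c = np.argmin(d2, axis=1)
                        member[newly] = c
                        dwell_start[newly] = frame
                        pos = np.array(
                            [
                                sample_uniform_ellipse(1, ca[k], cb[k], cth[k], rng)[0]
                                + (ccx[k], ccy[k])
                                for k in c
                            ]
                        ).reshape(-1, 2)
                        x[newly] = pos[:, 0]
                        y[newly] = pos[:, 1]
            else:  # geometric capture on entry
                dx = x[free][:, None] - ccx[None, :]
                dy = y[free][:, None] - ccy[None, :]
                uu = (dx * ccos[None, :] + dy * csin[None, :]) / ca[None, :]
                vv = (-dx * csin[None, :] + dy * ccos[None, :]) / cb[None, :]
                inside = uu**2 + vv**2 <= 1.0
                hit = inside.any(axis=1)
                if hit.any():
                    cand = free[hit]
                    c = np.argmax(inside[hit], axis=1)
                    u = rng.uniform(size=cand.size)
                    cap = u < config.p_capture
                    member[cand[cap]] = c[cap]
                    dwell_start[cand[cap]] = frame

        # --- blinking ---
        live = np.nonzero(alive)[0]
        on = live[off_left[live] == 0]
        off_left[live] = np.maximum(off_left[live] - 1, 0)
        if on.size and config.blink_off_prob > 0:
            u = rng.uniform(size=on.size)
            go_dark = on[u < config.blink_off_prob]
            if go_dark.size:
                off_left[go_dark] = _blink_draw(go_dark.size, config.blink_max_gap, rng)

        _record_positions(frame)

    # close censored dwells
    open_ids = np.nonzero(alive & (dwell_start >= 0) & (member >= 0))[0]
    _end_dwell(open_ids, n_frames - 1, "censored")

    positions = pd.DataFrame(
        np.concatenate(pos_rows) if pos_rows else np.empty((0, 6)),
        columns=["frame", "molecule_id", "x_nm", "y_nm", "cluster_id", "observed"],
    )
    positions = positions.astype(
        {"frame": int, "molecule_id": int, "cluster_id": int, "observed": bool}
    )

    obs = positions[positions["observed"]].copy()
    loc = pd.DataFrame(
        {
            "frame": obs["frame"].to_numpy(),
            "molecule_id": obs["molecule_id"].to_numpy(),
            "x_nm": obs["x_nm"].to_numpy() + rng.normal(0, config.sigma_loc, len(obs)),
            "y_nm": obs["y_nm"].to_numpy() + rng.normal(0, config.sigma_loc, len(obs)),
            "sigma_nm": config.sigma_loc,
            "channel": "activated",
        }
    )

    molecules = pd.DataFrame(
        {
            "molecule_id": np.arange(n_mol),
            "birth_frame": 0,
            "last_frame": last_frame,
            "cause": cause,
        }
    )
    dwells = pd.DataFrame(
        dwell_rows, columns=["molecule_id", "cluster_id", "start_frame", "end_frame", "cause"]
    )
    truth = GroundTruth(molecules=molecules, positions=positions, dwells=dwells, clusters=clusters)
    return loc, truth


def brownian_tracks(
    n_tracks: int,
    n_frames: int,
    d: float,
    t_int: float,
    sigma_loc: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Pure 2D random walks; returns positions (n_tracks, n_frames, 2) in nm.

    Steps have per-coordinate variance 2·d·t_int (d in µm²/s); optional
    localization noise of std ``sigma_loc`` nm is added independently per
    frame and coordinate.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    step = np.sqrt(2.0 * d * t_int) * NM_PER_UM
    steps = rng.normal(0, step, (n_tracks, n_frames - 1, 2))
    pos = np.concatenate([np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    if sigma_loc > 0:
        pos = pos + rng.normal(0, sigma_loc, pos.shape)
    return pos


def confined_tracks(
    n_tracks: int,
    n_frames: int,
    diameter_nm: float,
    d: float,
    t_int: float,
    sigma_loc: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Tracks confined in reflecting discs of the given diameter; (n, T, 2) nm."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    radius = diameter_nm / 2.0
    step = np.sqrt(2.0 * d * t_int) * NM_PER_UM / radius  # in disc units
    r = np.sqrt(rng.uniform(0, 1, n_tracks))
    ph = rng.uniform(0, 2 * np.pi, n_tracks)
    uv = np.column_stack([r * np.cos(ph), r * np.sin(ph)])
    out = np.empty((n_tracks, n_frames, 2))
    out[:, 0] = uv
    for t in range(1, n_frames):
        uv = _reflect_unit_disc(uv + rng.normal(0, step, uv.shape), rng)
        out[:, t] = uv
    out *= radius
    if sigma_loc > 0:
        out = out + rng.normal(0, sigma_loc, out.shape)
    return out
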