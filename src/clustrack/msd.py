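"""Mean-squared-displacement analysis and motion classification.

For homogeneous 2D diffusion the time-averaged MSD is linear in the lag,
MSD(t) = 4Dt + C, where D is the diffusion coefficient and C = 4σ² the
offset contributed by localization noise of per-coordinate std σ. The
diffusion coefficient is estimated by a weighted linear fit over the
first few lags (weights = number of displacement pairs).

Classification follows the confidence-envelope approach: pure random
walks with matched track length, D and noise are simulated; the per-lag
2.5% and 97.5% quantiles of their *individual* time-averaged MSD curves
form a 95% envelope. A trajectory whose MSD runs above the upper bound
for ``run_rule`` (default 5) consecutive lags is *directed*, below the
lower bound *confined*, otherwise *free*. Because an individual TA-MSD
curve is only informative over roughly the first quarter of its lags,
classification is restricted to that range.

Confinement size is read off the MSD plateau: for positions uniform in a
disc of radius R the mean squared separation of two independent samples
is R² (+4σ² with noise), so diameter = 2·√(plateau − 4σ²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .localize import Trajectory
from .sim.trajectories import brownian_tracks
from .units import nm2_to_um2

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "Envelope",
    "MotionClass",
    "ConfinementEstimate",
    "compute_msd",
    "pool_msd",
    "fit_linear_msd",
    "build_envelope",
    "classify_trajectory",
    "population_fractions",
    "estimate_confinement_size",
]


@dataclass
class MSDCurve:
    """Time-averaged MSD of one track: lag (s) vs MSD (µm²) with pair counts."""

    lags_s: np.ndarray
    msd_um2: np.ndarray
    counts: np.ndarray
    track_id: int = -1
    n_points: int = 0

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if (np.diff(self.lags_s) <= 0).any():
            raise ValueError("lags must be strictly increasing")
        if (self.msd_um2 < 0).any():
            raise ValueError("MSD must be non-negative")


@dataclass
class DiffusionFit:
    """Result of the linear MSD fit MSD(t) = 4Dt + C."""

    d_um2_s: float
    c_um2: float
    d_se: float
    c_se: float
    n_lags: int
    negative_d: bool = False  # noise-dominated fit; reported, not clamped


@dataclass
class Envelope:
    """95% confidence band for individual random-walk TA-MSD curves."""

    lags_s: np.ndarray
    lower_um2: np.ndarray
    upper_um2: np.ndarray
    d_um2_s: float
    track_length: int
    sigma_loc_nm: float
    replicates: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.lower_um2 > self.upper_um2).any():
            raise ValueError("envelope lower bound exceeds upper bound")


@dataclass
class MotionClass:
    """Classification of one trajectory with its supporting evidence."""

    label: str                    # free | directed | confined
    run_length: int = 0           # longest out-of-envelope consecutive run
    direction: str = "none"       # above | below | none
    track_id: int = -1


@dataclass
class ConfinementEstimate:
    diameter_nm: float
    plateau_um2: float
    n_plateau_lags: int
    flag: str = "ok"              # ok | clamped | no_plateau


def compute_msd(track: Trajectory, t_int: float = 0.2) -> MSDCurve:
    """Time-averaged MSD over all ordered pairs at each integer-frame lag.

    Gaps are handled by the frame numbers: a pair (i, i+n) contributes to
    lag n·t_int only when both frames were detected, so pairs spanning
    blink gaps use the true elapsed time. Lags with no pairs are dropped.
    """
    if track.length < 2:
        raise ValueError("track must have at least 2 detections")
    f = track.frames - track.frames[0]
    span = int(f[-1])
    pos = np.full((span + 1, 2), np.nan)
    pos[f, 0] = track.x_nm
    pos[f, 1] = track.y_nm

    lags, msd, counts = [], [], []
    for n in range(1, span + 1):
        d = pos[n:] - pos[:-n]
        sq = d[:, 0] ** 2 + d[:, 1] ** 2
        ok = ~np.isnan(sq)
        m = int(ok.sum())
        if m == 0:
            continue
        lags.append(n * t_int)
        msd.append(nm2_to_um2(float(sq[ok].mean())))
        counts.append(m)
    return MSDCurve(
        lags_s=np.array(lags), msd_um2=np.array(msd), counts=np.array(counts),
        track_id=track.track_id, n_points=track.length,
    )


def pool_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Count-weighted average of MSD curves across trajectories."""
    if not curves:
        raise ValueError("no curves to pool")
    table: dict[float, list[float]] = {}
    for c in curves:
        for lag, m, n in zip(c.lags_s, c.msd_um2, c.counts):
            table.setdefault(round(float(lag), 9), []).append((m, n))
    lags = np.array(sorted(table))
    msd = np.empty_like(lags)
    counts = np.empty(len(lags), dtype=int)
    for i, lag in enumerate(lags):
        pairs = table[round(float(lag), 9)]
        w = np.array([n for _, n in pairs], dtype=float)
        v = np.array([m for m, _ in pairs])
        msd[i] = np.average(v, weights=w)
        counts[i] = int(w.sum())
    return MSDCurve(lags_s=lags, msd_um2=msd, counts=counts, track_id=-1)


def fit_linear_msd(
    curve: MSDCurve | list[MSDCurve], n_lags: int = 4
) -> DiffusionFit:
    """Weighted least-squares fit of MSD(t) = 4Dt + C over the first ``n_lags`` lags.

    Weights are the displacement-pair counts. A list of curves is pooled
    (count-weighted per-lag average) before fitting. D = slope/4; a
    negative D (noise-dominated short track) is reported with a flag
    rather than clamped.
    """
    if isinstance(curve, list):
        curve = pool_msd(curve)
    if n_lags < 2:
        raise ValueError("n_lags must be >= 2")
    k = min(n_lags, len(curve.lags_s))
    if k < 2:
        raise ValueError("need at least 2 lags to fit")
    t = curve.lags_s[:k]
    y = curve.msd_um2[:k]
    w = curve.counts[:k].astype(float)
    if np.ptp(t) == 0:
        raise ValueError("degenerate lag axis")
    X = sm.add_constant(t)
    res = sm.WLS(y, X, weights=w).fit()
    c, slope = res.params
    c_se, s_se = res.bse if len(res.bse) == 2 else (np.nan, np.nan)
    d = slope / 4.0
    return DiffusionFit(
        d_um2_s=float(d), c_um2=float(c),
        d_se=float(s_se / 4.0), c_se=float(c_se),
        n_lags=k, negative_d=bool(d < 0),
    )


def _ta_msd_stack(pos: np.ndarray) -> np.ndarray:
    """TA-MSD curves for a stack of gap-free tracks (R, T, 2) -> (R, T-1) nm²."""
    n_rep, n_t, _ = pos.shape
    out = np.empty((n_rep, n_t - 1))
    for lag in range(1, n_t):
        d = pos[:, lag:, :] - pos[:, :-lag, :]
        out[:, lag - 1] = (d**2).sum(axis=2).mean(axis=1)
    return out


def build_envelope(
    d_um2_s: float,
    track_length: int,
    sigma_loc_nm: float = 0.0,
    replicates: int = 1000,
    seed: int | None = None,
    t_int: float = 0.2,
) -> Envelope:
    """Simulate matched pure random walks; return the per-lag 95% band.

    The band is the empirical 2.5–97.5 percentile range of *individual*
    time-averaged MSD curves of ``replicates`` random walks with the
    given global D, track length and localization noise — the yardstick
    a single observed curve is compared against.
    """
    if replicates < 100:
        raise ValueError("replicates must be >= 100 for stable 2.5/97.5 percentiles")
    rng = np.random.default_rng(seed)
    pos = brownian_tracks(replicates, track_length, d_um2_s, t_int, sigma_loc_nm, rng)
    curves = _ta_msd_stack(pos)  # nm²
    lo = np.percentile(curves, 2.5, axis=0)
    hi = np.percentile(curves, 97.5, axis=0)
    lags = t_int * np.arange(1, track_length)
    return Envelope(
        lags_s=lags,
        lower_um2=nm2_to_um2(lo),
        upper_um2=nm2_to_um2(hi),
        d_um2_s=d_um2_s,
        track_length=track_length,
        sigma_loc_nm=sigma_loc_nm,
        replicates=replicates,
        seed=seed,
    )


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def classify_trajectory(
    curve: MSDCurve, envelope: Envelope, run_rule: int = 5
) -> MotionClass:
    """Label a trajectory free / directed / confined against the envelope.

    ``run_rule`` consecutive lags above the upper bound ⇒ directed; below
    the lower bound ⇒ confined; otherwise free. Only the first
    ``run_rule + 1`` lags are examined: individual TA-MSD curves are
    strongly correlated across lags, so widening the window would let
    ordinary random walks drift out of the band somewhere and be
    misclassified, while confinement and directed transport already show
    at the earliest lags.
    """
    k_max = run_rule + 1
    k = min(k_max, len(curve.lags_s), len(envelope.lags_s))
    if k < run_rule:
        raise ValueError("curve/envelope overlap shorter than the run rule")
    if not np.allclose(curve.lags_s[:k], envelope.lags_s[:k]):
        raise ValueError("curve and envelope lag axes do not match")
    y = curve.msd_um2[:k]
    above = y > envelope.upper_um2[:k]
    below = y < envelope.lower_um2[:k]
    run_above = _longest_run(above)
    run_below = _longest_run(below)
    if run_above >= run_rule and run_above >= run_below:
        return MotionClass("directed", run_above, "above", curve.track_id)
    if run_below >= run_rule:
        return MotionClass("confined", run_below, "below", curve.track_id)
    run = max(run_above, run_below)
    direction = "above" if run_above >= run_below else "below"
    return MotionClass("free", run, direction if run else "none", curve.track_id)


def classify_tracks(
    tracks: list[Trajectory],
    d_um2_s: float,
    sigma_loc_nm: float = 30.0,
    replicates: int = 500,
    seed: int | None = None,
    t_int: float = 0.2,
    run_rule: int = 5,
    length_bucket: int = 10,
) -> list[MotionClass]:
    """Classify a set of tracks against length-matched envelopes.

    The envelope's band width depends on track length (shorter tracks
    have noisier TA-MSD curves), so each track is compared against an
    envelope simulated at its own length — bucketed to multiples of
    ``length_bucket`` frames so envelopes are reused across tracks.
    """
    cache: dict[int, Envelope] = {}
    out = []
    for tr in tracks:
        n = max(int(round(tr.length / length_bucket)) * length_bucket, 2 * run_rule)
        if n not in cache:
            cache[n] = build_envelope(
                d_um2_s, n, sigma_loc_nm, replicates,
                seed=None if seed is None else seed + n, t_int=t_int,
            )
        curve = compute_msd(tr, t_int)
        out.append(classify_trajectory(curve, cache[n], run_rule=run_rule))
    return out


def population_fractions(
    classes_per_cell: list[list[MotionClass | str]],
    exclude_directed: bool = True,
) -> dict:
    """Per-class population fractions with SEM across cells.

    Each cell contributes one fraction per class (the cell is the
    replication unit); the returned means and SEMs are across cells.
    With ``exclude_directed`` (default), directed tracks — vesicular
    transport seen under wide-field activation — are removed from the
    free/confined denominator; the directed fraction is still reported
    over all tracks. A single cell yields SEM = nan with a flag.
    """
    if not classes_per_cell:
        raise ValueError("no cells supplied")
    per_cell = {"free": [], "confined": [], "directed": []}
    for cell in classes_per_cell:
        labels = [c.label if isinstance(c, MotionClass) else c for c in cell]
        n_all = len(labels)
        if n_all == 0:
            continue
        n_dir = labels.count("directed")
        denom = n_all - n_dir if exclude_directed else n_all
        per_cell["directed"].append(n_dir / n_all)
        if denom > 0:
            per_cell["free"].append(labels.count("free") / denom)
            per_cell["confined"].append(labels.count("confined") / denom)
    out = {}
    for label, vals in per_cell.items():
        vals = np.asarray(vals, dtype=float)
        n = len(vals)
        out[label] = {
            "mean": float(vals.mean()) if n else np.nan,
            "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "n_cells": n,
        }
    out["single_cell"] = len(classes_per_cell) == 1
    return out


def estimate_confinement_size(
    curve: MSDCurve, sigma_loc_nm: float = 30.0, d_free_um2_s: float = 0.092
) -> ConfinementEstimate:
    """Confinement-zone diameter from the MSD plateau of a confined track.

    The plateau region starts at the knee — the first lag where the MSD
    falls below half the free-diffusion expectation 4·D_free·t — and the
    plateau level is the count-weighted mean MSD beyond it. Under the
    uniform-disc model the plateau equals R² + 4σ², so
    diameter = 2·√(plateau − 4σ²); a noise term exceeding the plateau
    clamps the estimate to 0 with a warning flag.
    """
    free_line = 4.0 * d_free_um2_s * curve.lags_s
    knee = np.nonzero(curve.msd_um2 < 0.5 * free_line)[0]
    if len(knee) == 0:
        return ConfinementEstimate(np.nan, np.nan, 0, flag="no_plateau")
    k0 = int(knee[0])
    plateau = float(
        np.average(curve.msd_um2[k0:], weights=curve.counts[k0:].astype(float))
    )
    sigma_um2 = nm2_to_um2(4.0 * sigma_loc_nm**2)
    corrected = plateau - sigma_um2
    if corrected <= 0:
        warnings.warn("localization-noise floor exceeds MSD plateau; diameter clamped to 0",
                      stacklevel=2)
        return ConfinementEstimate(0.0, plateau, len(curve.lags_s) - k0, flag="clamped")
    diameter_nm = 2.0 * np.sqrt(corrected) * 1000.0
    return ConfinementEstimate(
        float(diameter_nm), plateau, len(curve.lags_s) - k0, flag="ok"
    )
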