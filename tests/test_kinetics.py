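"""Dwell extraction, disappearance-rate fitting and the K(p) decomposition."""

import numpy as np
import pandas as pd
import pytest

from clustrack.kinetics import (
    RateFit,
    decompose_rates,
    estimate_association_rate,
    extract_dwell_times,
    fit_disappearance_rate,
    flattened_vesicle_diameter,
)
from clustrack.localize import Trajectory
from clustrack.morphology import ClusterRegion, identify_clusters
from clustrack.sim import make_scenario, make_schedule, simulate_dwell_times, simulate_trajectories


def _disc_region(cx=0.0, cy=0.0, r=150.0):
    rng = np.random.default_rng(0)
    pts = np.array([cx, cy]) + rng.normal(0, r / 3, (30, 2))
    return ClusterRegion(0, pts, np.arange(30), np.zeros(30), 30)


def _dwell_df(durations_s, t_int=0.2, censored=None, p=1.0):
    durations_s = np.asarray(durations_s, dtype=float)
    if censored is None:
        censored = np.zeros(len(durations_s), dtype=bool)
    return pd.DataFrame(
        {"duration_s": durations_s, "n_frames": (durations_s / t_int).astype(int),
         "censored": censored, "cause": "lost", "p": p, "t_int_s": t_int,
         "condition": "test"}
    )


class TestExtractDwellTimes:
    def test_persistent_molecule_censored(self):
        tr = Trajectory(0, np.arange(100), np.full(100, 10.0), np.full(100, 5.0))
        out = extract_dwell_times([tr], [_disc_region()], n_frames_total=100)
        assert len(out) == 1
        assert bool(out["censored"].iloc[0])

    def test_three_frame_absence_continues_four_ends(self):
        region = _disc_region()
        frames3 = np.array([f for f in range(60)] + [f for f in range(63, 120)])
        tr = Trajectory(0, frames3, np.zeros(len(frames3)), np.zeros(len(frames3)))
        out = extract_dwell_times([tr], [region], loss_gap=3, n_frames_total=200)
        assert len(out) == 1

        frames4 = np.array([f for f in range(60)] + [f for f in range(64, 120)])
        tr = Trajectory(0, frames4, np.zeros(len(frames4)), np.zeros(len(frames4)))
        out = extract_dwell_times([tr], [region], loss_gap=3, n_frames_total=200)
        assert len(out) == 2

    def test_no_clusters_rejected(self):
        tr = Trajectory(0, np.arange(10), np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            extract_dwell_times([tr], [])

    def test_simulated_dwells_recovered_within_one_frame(self):
        # end-to-end: spatial simulation -> residency regions -> dwell durations
        sc = make_scenario("basal", n_molecules=200, seed=31, blink_off_prob=0.0)
        sch = make_schedule(0.2, 0.2, 600)
        loc, truth = simulate_trajectories(sc, sch, 31)
        regions = identify_clusters(loc)
        tracks = []
        for mid, grp in loc.groupby("molecule_id"):
            grp = grp.sort_values("frame")
            tracks.append(Trajectory(int(mid), grp["frame"].to_numpy(),
                                     grp["x_nm"].to_numpy(), grp["y_nm"].to_numpy()))
        out = extract_dwell_times(tracks, regions, n_frames_total=600)
        td = truth.dwells.assign(
            span=truth.dwells["end_frame"] - truth.dwells["start_frame"] + 1
        )
        td = td[td["span"] >= 5]
        meas: dict[int, list] = {}
        for r in out.itertuples():
            meas.setdefault(r.track_id, []).append(r)
        hits = []
        for t in td.itertuples():
            cand = [r for r in meas.get(t.molecule_id, [])
                    if r.start_frame <= t.end_frame and r.end_frame >= t.start_frame]
            hits.append(
                bool(cand) and min(abs(r.n_frames - t.span) for r in cand) <= 1
            )
        assert len(hits) >= 50
        assert np.mean(hits) >= 0.95


class TestFitDisappearanceRate:
    @pytest.mark.parametrize("method", ["histogram", "mle"])
    def test_known_rate_recovered(self, method, rng):
        k_true = 0.69  # min⁻¹
        t = rng.exponential(60.0 / k_true, 2000)
        d = np.ceil(t / 0.2) * 0.2
        fit = fit_disappearance_rate(_dwell_df(d), method=method, n_boot=100, rng=rng)
        assert fit.k_per_min == pytest.approx(k_true, rel=0.05)
        assert fit.se_per_min > 0

    def test_below_min_records_rejected(self, rng):
        d = np.ceil(rng.exponential(60.0, 10) / 0.2) * 0.2
        with pytest.raises(ValueError, match="uncensored"):
            fit_disappearance_rate(_dwell_df(d), n_boot=0)

    def test_competing_clocks_sum(self, rng):
        # minimum of independent exponentials: single rate = sum of rates
        sc = make_scenario("custom", k_b=2.0, k_d=0.12, k_e=0.57)
        sch = make_schedule(0.2, 0.5, 4000)
        dw = simulate_dwell_times(sc, sch, 5000, rng)
        fit = fit_disappearance_rate(dw, n_boot=0)
        assert fit.k_per_min == pytest.approx(0.4 * 2.0 + 0.12 + 0.57, rel=0.05)

    def test_frame_quantization_negligible_at_small_k_dt(self, rng):
        k_true = 0.69 / 60  # s⁻¹; K·t_int ≈ 0.0023
        t = rng.exponential(1 / k_true, 20000)
        d = np.ceil(t / 0.2) * 0.2
        fit = fit_disappearance_rate(_dwell_df(d), n_boot=0)
        assert fit.k_per_min == pytest.approx(0.69, rel=0.02)

    def test_mle_robust_to_20pct_censoring(self, rng):
        k_true = 0.5 / 60
        t_max = np.log(5.0) / k_true  # censors ~20%
        t = rng.exponential(1 / k_true, 5000)
        cens = t > t_max
        d = np.ceil(np.minimum(t, t_max) / 0.2) * 0.2
        df = _dwell_df(d, censored=cens)
        mle = fit_disappearance_rate(df, method="mle", n_boot=0)
        assert mle.k_per_min == pytest.approx(0.5, rel=0.05)
        # histogram (censored excluded) stays close too; measured here
        hist = fit_disappearance_rate(df, method="histogram", n_boot=0)
        assert hist.k_per_min == pytest.approx(0.5, rel=0.10)

    def test_all_censored_not_identifiable(self):
        df = _dwell_df(np.full(50, 10.0), censored=np.ones(50, dtype=bool))
        with pytest.raises(ValueError):
            fit_disappearance_rate(df, method="mle", n_boot=0)


def _fits(ps, ks, se=0.01):
    return [RateFit(k_per_min=k, se_per_min=se, n_used=1000, n_censored=0,
                    method="histogram", p=p) for p, k in zip(ps, ks)]


class TestDecomposeRates:
    def test_exact_on_noiseless_lines(self):
        # control K(p) = 2p + 0.69, endocytosis-off K(p) = 2p + 0.12
        ps = np.array([0.1, 0.2, 0.4, 1.0])
        dec = decompose_rates(_fits(ps, 2 * ps + 0.69), _fits(ps, 2 * ps + 0.12))
        assert dec.k_d == pytest.approx(0.12, abs=1e-9)
        assert dec.k_e == pytest.approx(0.57, abs=1e-9)
        assert dec.k_b == pytest.approx(2.0, abs=1e-9)

    def test_no_bleaching_means_flat_in_p(self, rng):
        sc = make_scenario("custom", k_b=0.0, k_d=0.4, k_e=0.2)
        fits = []
        for t_int in (0.2, 0.5, 1.0, 2.0):
            sch = make_schedule(0.2, t_int, int(6000 / t_int))
            dw = simulate_dwell_times(sc, sch, 3000, rng)
            fits.append(fit_disappearance_rate(dw, n_boot=0))
        ks = [f.k_per_min for f in fits]
        assert np.ptp(ks) < 0.08  # no illumination dependence

    def test_insufficient_p_values_rejected(self):
        ps = np.array([0.1, 0.2])
        with pytest.raises(ValueError):
            decompose_rates(_fits(ps, 2 * ps + 0.7), _fits(ps, 2 * ps + 0.1))

    def test_pooled_slope_shares_bleaching(self):
        ps = np.array([0.1, 0.2, 0.4, 1.0])
        dec = decompose_rates(_fits(ps, 2 * ps + 0.69), _fits(ps, 2 * ps + 0.12),
                              pooled_slope=True)
        assert dec.k_b == pytest.approx(2.0, abs=1e-9)
        assert dec.pooled_slope

    def test_recovery_sweep_median_error(self, rng):
        # K_d x K_e grid, 2000 dwells/protocol: median relative error <= 15%
        errs_d, errs_e = [], []
        for k_d in (0.1, 0.2, 0.3):
            for k_e in (0.0, 0.3, 0.6):
                branches = {}
                for branch, ke in (("control", k_e), ("kcn", 0.0)):
                    sc = make_scenario("custom", k_b=2.0, k_d=k_d, k_e=ke)
                    fits = []
                    for t_int in (0.2, 0.5, 1.0, 2.0):
                        sch = make_schedule(0.2, t_int, int(2400 / t_int))
                        dw = simulate_dwell_times(sc, sch, 2000, rng)
                        fits.append(fit_disappearance_rate(dw, n_boot=0))
                    branches[branch] = fits
                dec = decompose_rates(branches["control"], branches["kcn"])
                errs_d.append(abs(dec.k_d - k_d) / k_d)
                if k_e > 0:
                    errs_e.append(abs(dec.k_e - k_e) / k_e)
        assert np.median(errs_d) <= 0.15
        assert np.median(errs_e) <= 0.15


class TestAssociationRate:
    def test_symmetric_fractions_conventions_agree(self):
        out = estimate_association_rate(0.12, 0.5, 0.5)
        assert out["printed"] == out["detailed_balance"] == pytest.approx(0.12)

    def test_basal_printed_convention(self):
        out = estimate_association_rate(0.12, 0.52, 0.48)
        assert out["printed"] == pytest.approx(0.13, abs=0.005)
        assert out["detailed_balance"] == pytest.approx(0.12 * 48 / 52, rel=1e-9)

    def test_spatial_simulator_detailed_balance_stationarity(self):
        # start everyone free; the exchange relaxes to f_c/f_f = K_a/K_d
        sc = make_scenario("custom", k_a=3.0, k_d=3.0, k_b=0.0, k_e=0.0,
                           blink_off_prob=0.0, n_molecules=300,
                           stationary_clustered_fraction=0.0, seed=41)
        _, truth = simulate_trajectories(sc, make_schedule(0.2, 0.2, 600), 41)
        pos = truth.positions
        late = pos[pos["frame"] >= 200]
        f_c = (late["cluster_id"] >= 0).mean()
        ratio = f_c / (1 - f_c)
        assert ratio == pytest.approx(sc.k_a / sc.k_d, abs=0.12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            estimate_association_rate(0.12, 0.5, 0.0)


class TestFlattenedVesicle:
    def test_area_conservation_value(self):
        assert flattened_vesicle_diameter(50.0) == pytest.approx(100.0)

    def test_numeric_area_identity(self):
        # sphere surface 4πr² (r = 25) equals disc πR² at R = 50
        r = 25.0
        sphere = 4 * np.pi * r**2
        R = np.sqrt(sphere / np.pi)
        assert 2 * R == pytest.approx(flattened_vesicle_diameter(2 * r), rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            flattened_vesicle_diameter(0.0)
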