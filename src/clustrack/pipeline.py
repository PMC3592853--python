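"""End-to-end orchestration: simulate → track → classify → clusters → kinetics → fusion.

All randomness flows from one root seed through named per-stage
substreams (``numpy`` ``SeedSequence`` spawning keyed by stage name), so
any stage can be rerun independently yet the whole report is
bit-reproducible for a given configuration. Stage outputs are persisted
as self-describing CSVs; the consolidated JSON report records every
parameter alongside the quantity it produced.

The kinetics stage runs the relative-exposure protocol grid (four
inter-frame intervals at constant exposure, with and without
endocytosis) through the kinetic dwell sampler and the K(p)
decomposition; the spatial dwell-extraction route is available through
the library (``kinetics.extract_dwell_times``) for movie-based data.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import kinetics as ckin
from . import morphology as cmorph
from . import msd as cmsd
from .fusion import classify_fusion, detect_flashes
from .localize import filter_trajectories, link_trajectories
from .sim import (
    AcquisitionSchedule,
    make_scenario,
    simulate_dwell_times,
    simulate_fusion_movie,
    simulate_trajectories,
)

__all__ = ["RunConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "preset", "seed", "stages", "outdir", "n_frames", "t_exp", "t_int",
    "n_molecules", "min_points", "max_disp_nm", "max_gap", "envelope_replicates",
    "run_rule", "residency_min", "radius_nm", "probe_radius_nm",
    "protocol_t_int", "dwells_per_protocol", "rate_method", "bootstrap",
    "fusion_events", "fusion_mode_mix", "field_size_um",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run; unknown keys are rejected."""

    preset: str = "basal"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "track", "classify", "clusters", "kinetics")
    outdir: str | None = None
    n_frames: int = 600
    t_exp: float = 0.2
    t_int: float = 0.2
    n_molecules: int = 200
    field_size_um: tuple[float, float] = (25.0, 25.0)  # keeps density in the sparse regime
    min_points: int = 30
    max_disp_nm: float = 800.0
    max_gap: int = 3
    envelope_replicates: int = 1000
    run_rule: int = 5
    residency_min: int = 30
    radius_nm: float = 125.0
    probe_radius_nm: float = 50.0
    protocol_t_int: tuple[float, ...] = (0.2, 0.5, 1.0, 2.0)
    dwells_per_protocol: int = 2000
    rate_method: str = "histogram"
    bootstrap: int = 200
    fusion_events: int = 20
    fusion_mode_mix: float = 0.5

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("stages", "protocol_t_int", "field_size_um"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    # stable digest (process-independent) so every stage has its own substream
    key = zlib.crc32(stage.encode()) % 2**31
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the configured stages in order; return the consolidated report.

    Stages that need an upstream artifact raise if it was not produced.
    When ``outdir`` is set, intermediate CSVs and the report JSON are
    written there; upstream artifacts are never mutated.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    valid_order = ["simulate", "track", "classify", "clusters", "kinetics", "fusion"]
    order = {s: i for i, s in enumerate(valid_order)}
    stages = list(config.stages)
    for s in stages:
        if s not in order:
            raise ValueError(f"unknown stage {s!r}")
    if stages != sorted(stages, key=order.__getitem__):
        raise ValueError("stages out of dependency order")

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"config": asdict(config), "stages": {}, "artifacts": []}
    scenario = make_scenario(
        config.preset, n_molecules=config.n_molecules, field_size=config.field_size_um
    )
    schedule = AcquisitionSchedule(config.t_exp, config.t_int, config.n_frames)

    loc = truth = tracks = None
    regions = None

    if "simulate" in stages:
        rng = _stage_rng(config.seed, "simulate")
        loc, truth = simulate_trajectories(scenario, schedule, rng)
        report["stages"]["simulate"] = {
            "n_localizations": int(len(loc)),
            "n_molecules": int(scenario.n_molecules),
            "accounting": {k: int(v) for k, v in truth.accounting().items()},
        }
        if outdir:
            cio.write_table(loc, outdir / "localizations.csv",
                            {"stage": "simulate", "preset": config.preset, "seed": config.seed})
            cio.write_table(truth.dwells, outdir / "truth_dwells.csv", {"stage": "simulate"})
            cio.write_table(truth.clusters, outdir / "truth_clusters.csv", {"stage": "simulate"})
            report["artifacts"] += ["localizations.csv", "truth_dwells.csv", "truth_clusters.csv"]

    if "track" in stages:
        if loc is None:
            raise RuntimeError("track stage requires the simulate stage's localizations")
        tracks = link_trajectories(loc, max_disp=config.max_disp_nm, max_gap=config.max_gap)
        kept = filter_trajectories(tracks, min_points=config.min_points)
        report["stages"]["track"] = {
            "n_tracks": len(tracks), "n_tracks_kept": len(kept),
            "min_points": config.min_points,
        }
        tracks = kept
        if outdir:
            cio.write_table(cio.tracks_to_table(tracks), outdir / "tracks.csv",
                            {"stage": "track", "max_disp_nm": config.max_disp_nm,
                             "max_gap": config.max_gap})
            report["artifacts"].append("tracks.csv")

    if "classify" in stages:
        if tracks is None:
            raise RuntimeError("classify stage requires tracks")
        curves = [cmsd.compute_msd(t, t_int=config.t_int) for t in tracks]
        pooled_free = cmsd.fit_linear_msd(curves)
        env_seed = int(_stage_rng(config.seed, "classify").integers(2**30))
        classes = cmsd.classify_tracks(
            tracks, scenario.d_free, scenario.sigma_loc,
            replicates=config.envelope_replicates, seed=env_seed,
            t_int=config.t_int, run_rule=config.run_rule,
        )
        fracs = cmsd.population_fractions([classes])
        report["stages"]["classify"] = {
            "pooled_D_um2_s": pooled_free.d_um2_s,
            "pooled_C_um2": pooled_free.c_um2,
            "fractions": {k: fracs[k] for k in ("free", "confined", "directed")},
            "envelope_seed": env_seed,
            "n_classified": len(classes),
        }
        if outdir:
            rows = pd.DataFrame(
                [(c.track_id, c.label, c.run_length) for c in classes],
                columns=["track_id", "class", "run_length"],
            )
            cio.write_table(rows, outdir / "classes.csv", {"stage": "classify"})
            report["artifacts"].append("classes.csv")

    if "clusters" in stages:
        if loc is None:
            raise RuntimeError("clusters stage requires localizations")
        regions = cmorph.identify_clusters(
            loc, residency_min=config.residency_min, radius_nm=config.radius_nm
        )
        rows = []
        for reg in regions:
            if reg.n_positions >= 10:
                fit = cmorph.fit_ellipse(reg, sigma_loc_nm=scenario.sigma_loc)
                try:
                    circ = cmorph.circularity(reg, probe_radius_nm=config.probe_radius_nm)
                except ValueError:
                    circ = np.nan
                rows.append((reg.region_id, fit.d_max_nm, fit.d_min_nm, circ,
                             reg.n_positions, reg.residency_frames))
        df = pd.DataFrame(rows, columns=["region_id", "d_max_nm", "d_min_nm",
                                         "circularity", "n_positions", "residency"])
        report["stages"]["clusters"] = {
            "n_regions": len(regions),
            "n_measured": len(df),
            "mean_d_max_nm": float(df["d_max_nm"].mean()) if len(df) else np.nan,
            "mean_d_min_nm": float(df["d_min_nm"].mean()) if len(df) else np.nan,
            "mean_circularity": float(df["circularity"].mean()) if len(df) else np.nan,
        }
        if outdir:
            cio.write_table(df, outdir / "clusters.csv",
                            {"stage": "clusters", "residency_min": config.residency_min,
                             "radius_nm": config.radius_nm})
            report["artifacts"].append("clusters.csv")

    if "kinetics" in stages:
        rng = _stage_rng(config.seed, "kinetics")
        branches = {}
        for branch, preset in (("control", config.preset),
                               ("kcn", f"{config.preset}_kcn")):
            sc = make_scenario(preset)
            fits = []
            for t_int in config.protocol_t_int:
                sch = AcquisitionSchedule(config.t_exp, t_int,
                                          max(config.n_frames, int(1200 / t_int)))
                dw = simulate_dwell_times(sc, sch, config.dwells_per_protocol, rng)
                fits.append(
                    ckin.fit_disappearance_rate(
                        dw, method=config.rate_method, n_boot=config.bootstrap, rng=rng
                    )
                )
            branches[branch] = fits
        dec = ckin.decompose_rates(branches["control"], branches["kcn"])
        f_c = scenario.equilibrium_clustered_fraction
        ka = ckin.estimate_association_rate(dec.k_d, 1 - f_c, f_c)
        report["stages"]["kinetics"] = {
            "K_per_p": {
                b: [{"p": f.p, "K": f.k_per_min, "se": f.se_per_min} for f in fits]
                for b, fits in branches.items()
            },
            "K_b": dec.k_b, "K_d": dec.k_d, "K_e": dec.k_e,
            "K_d_se": dec.k_d_se, "K_e_se": dec.k_e_se,
            "K_a_printed": ka["printed"], "K_a_detailed_balance": ka["detailed_balance"],
            "method": config.rate_method, "bootstrap": config.bootstrap,
        }

    if "fusion" in stages:
        rng = _stage_rng(config.seed, "fusion")
        sch = AcquisitionSchedule(0.2, 0.2, 250)
        stack, events = simulate_fusion_movie(
            config.fusion_events, config.fusion_mode_mix, sch, rng=rng
        )
        detected = detect_flashes(stack)
        counts = {"dispersal": 0, "retention": 0, "ambiguous": 0}
        for ev in detected:
            mode = classify_fusion(ev, stack, retention_window_s=5.0)
            counts[mode] += 1
        report["stages"]["fusion"] = {
            "n_true": int(len(events)), "n_detected": len(detected), "modes": counts,
        }

    report["seed"] = config.seed
    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        report["artifacts"].append("report.json")
    return report
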