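"""Direct kinetic sampler for cluster dwell times.

Bypasses the spatial simulator: a molecule sitting in a cluster is lost to
the first of three competing exponential clocks — photobleaching at
p·k_b (the bleaching rate scaled by the relative exposure p = t_exp/t_int),
dissociation at k_d, and endocytosis at k_e. Durations are quantized to
frame intervals (a molecule is observed for an integer number of frames)
and right-censored at the end of the acquisition. This gives the kinetics
module a fast, exactly specified test bed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..units import per_min_to_per_s
from .scenario import AcquisitionSchedule, ScenarioConfig

__all__ = ["simulate_dwell_times"]


def simulate_dwell_times(
    config: ScenarioConfig,
    schedule: AcquisitionSchedule,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw ``n`` frame-quantized, right-censored cluster dwell records.

    Returns a DataFrame with columns ``duration_s`` (k·t_int for k observed
    frames), ``n_frames`` (k), ``censored`` (bool), ``cause`` (bleach |
    dissociation | endocytosis | censored), ``p``, ``t_int_s`` and
    ``condition`` (the scenario name).

    The competing-clock construction makes the observed loss rate exactly
    K(p) = p·k_b + k_d + k_e, which is what the relative-exposure
    extrapolation in :mod:`clustrack.kinetics` decomposes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    p = schedule.p
    rates_per_s = np.array(
        [
            p * per_min_to_per_s(config.k_b),
            per_min_to_per_s(config.k_d),
            per_min_to_per_s(config.k_e),
        ]
    )
    causes = np.array(["bleach", "dissociation", "endocytosis"], dtype=object)
    total = rates_per_s.sum()
    t_max = schedule.duration_s

    if total == 0:
        warnings.warn(
            "all loss rates are zero: every dwell is censored at the acquisition end",
            stacklevel=2,
        )
        t_true = np.full(n, np.inf)
        cause = np.array(["censored"] * n, dtype=object)
    else:
        # minimum of competing exponentials: Exp(total), cause ~ rates
        t_true = rng.exponential(1.0 / total, n)
        cause = causes[rng.choice(3, size=n, p=rates_per_s / total)]

    censored = t_true > t_max
    cause = cause.copy()
    cause[censored] = "censored"
    # a molecule lost during frame k is observed for k frames
    n_frames = np.ceil(np.minimum(t_true, t_max) / schedule.t_int).astype(int)
    n_frames = np.clip(n_frames, 1, schedule.n_frames)

    return pd.DataFrame(
        {
            "duration_s": n_frames * schedule.t_int,
            "n_frames": n_frames,
            "censored": censored,
            "cause": cause,
            "p": p,
            "t_int_s": schedule.t_int,
            "condition": config.name,
        }
    )
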