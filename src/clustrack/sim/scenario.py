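"""Scenario presets and acquisition schedules for the synthetic-data generator.

A :class:`ScenarioConfig` bundles everything the spatial and kinetic
simulators need: the free and intra-cluster diffusion coefficients, the
first-order rates governing cluster exchange (association ``k_a``,
dissociation ``k_d``), removal (endocytosis ``k_e``), photobleaching
(``k_b``, per unit *illuminated* time), cluster geometry, field geometry,
blinking and localization noise.

Presets encode the experimental conditions the analysis is meant to
recover: a ``basal`` adipocyte membrane (slow cluster exchange, fast
endocytosis, ~48% of transporter in clusters), an ``insulin``-stimulated
one (faster dissociation, ~27% clustered), and ATP-depleted (``*_kcn``)
variants of each in which endocytosis is shut off (k_e = 0) — the
contrast that lets dwell-time kinetics separate dissociation from
endocytosis.

The preset association rates are fixed by detailed balance against the
target stationary clustered fractions: k_a = k_d · f_c / (1 − f_c), so
that exchange alone leaves the clustered fraction at its target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["ScenarioConfig", "AcquisitionSchedule", "make_scenario", "make_schedule", "PRESETS"]


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Frame timing: exposure ``t_exp`` within an interval ``t_int`` (seconds).

    The relative exposure ``p = t_exp / t_int`` is the fraction of wall-clock
    time the sample is illuminated; it scales the effective bleaching rate
    in the dwell-time decomposition K(p) = p·K_b + K_d + K_e.
    """

    t_exp: float = 0.2
    t_int: float = 0.2
    n_frames: int = 300

    def __post_init__(self) -> None:
        if not (0.0 < self.t_exp <= self.t_int):
            raise ValueError(f"require 0 < t_exp <= t_int, got t_exp={self.t_exp}, t_int={self.t_int}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def p(self) -> float:
        """Relative exposure t_exp / t_int, dimensionless in (0, 1]."""
        return self.t_exp / self.t_int

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.t_int


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth parameters of a synthetic single-molecule recording.

    Rates are in min⁻¹, lengths in nm unless noted.
    """

    name: str = "custom"
    d_free: float = 0.092          # free-diffusion coefficient, µm²/s
    d_in: float = 0.092            # intra-cluster diffusion coefficient, µm²/s
    k_d: float = 0.0               # cluster dissociation rate, min⁻¹
    k_e: float = 0.0               # endocytosis rate from clusters, min⁻¹
    k_b: float = 2.0               # bleaching rate per unit illuminated time, min⁻¹
    k_a: float = 0.0               # rate-based association rate for free molecules, min⁻¹
    p_capture: float = 1.0         # capture probability on geometric cluster entry
    association: str = "rate"      # "rate" (first-order k_a) or "geometric" (p_capture on entry)
    cluster_density: float = 0.3   # clusters per µm²
    cluster_axes: tuple[float, float] = (170.0, 90.0)   # mean (major, minor) full diameters, nm
    cluster_axes_sd: tuple[float, float] = (30.0, 30.0)  # spread of the diameters, nm
    field_size: tuple[float, float] = (10.0, 10.0)       # (width, height), µm
    n_molecules: int = 200
    blink_off_prob: float = 0.05   # per-frame probability of entering a dark state
    blink_max_gap: int = 3         # dark-state durations truncated at this many frames
    sigma_loc: float = 30.0        # localization noise per coordinate, nm (std)
    stationary_clustered_fraction: float | None = None  # initial-state mixture; None -> k_a/(k_a+k_d)
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("d_free", "d_in", "k_d", "k_e", "k_b", "k_a"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if not (0.0 <= self.p_capture <= 1.0):
            raise ValueError("p_capture must lie in [0, 1]")
        major, minor = self.cluster_axes
        if not (major >= minor > 0):
            raise ValueError("cluster axes must satisfy major >= minor > 0")
        w, h = self.field_size
        if w * h <= 0:
            raise ValueError("field area must be positive")
        if self.association not in ("rate", "geometric"):
            raise ValueError("association must be 'rate' or 'geometric'")
        if not (0.0 <= self.blink_off_prob < 1.0):
            raise ValueError("blink_off_prob must lie in [0, 1)")

    @property
    def equilibrium_clustered_fraction(self) -> float:
        """Stationary clustered fraction of the exchange process, k_a/(k_a+k_d)."""
        if self.stationary_clustered_fraction is not None:
            return self.stationary_clustered_fraction
        tot = self.k_a + self.k_d
        return self.k_a / tot if tot > 0 else 0.0


def _detailed_balance_ka(k_d: float, f_clustered: float) -> float:
    return k_d * f_clustered / (1.0 - f_clustered)


# Measured conditions the presets emulate: dissociation/endocytosis rates and the
# stationary clustered fractions of the basal and insulin-stimulated membrane.
_BASAL_F_CLUSTERED = 0.48
_INSULIN_F_CLUSTERED = 0.27 / (0.27 + 0.71)  # clustered share of the free+clustered pool

PRESETS: dict[str, dict] = {
    "basal": dict(
        k_d=0.12, k_e=0.57,
        k_a=_detailed_balance_ka(0.12, _BASAL_F_CLUSTERED),
    ),
    "insulin": dict(
        k_d=0.31, k_e=0.34,
        k_a=_detailed_balance_ka(0.31, _INSULIN_F_CLUSTERED),
    ),
    "basal_kcn": dict(
        k_d=0.12, k_e=0.0,
        k_a=_detailed_balance_ka(0.12, _BASAL_F_CLUSTERED),
    ),
    "insulin_kcn": dict(
        k_d=0.31, k_e=0.0,
        k_a=_detailed_balance_ka(0.31, _INSULIN_F_CLUSTERED),
    ),
}


def make_scenario(preset_name: str, **overrides) -> ScenarioConfig:
    """Build a fully populated :class:`ScenarioConfig` from a named preset.

    Parameters
    ----------
    preset_name
        One of ``basal``, ``insulin``, ``basal_kcn``, ``insulin_kcn`` or
        ``custom``. The ``*_kcn`` presets model ATP depletion: endocytosis
        off (k_e = 0), cluster/monomer exchange unchanged.
    **overrides
        Any :class:`ScenarioConfig` field, applied after the preset.
    """
    if preset_name == "custom":
        return ScenarioConfig(name="custom", **overrides)
    if preset_name not in PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; choose from "
            f"{sorted(PRESETS)} or 'custom'"
        )
    params = dict(PRESETS[preset_name])
    params.update(overrides)
    return ScenarioConfig(name=preset_name, **params)


def make_schedule(t_exp: float = 0.2, t_int: float = 0.2, n_frames: int = 300) -> AcquisitionSchedule:
    """Convenience constructor mirroring :class:`AcquisitionSchedule`."""
    return AcquisitionSchedule(t_exp=t_exp, t_int=t_int, n_frames=n_frames)
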