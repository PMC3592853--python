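"""Unit conventions and conversions.

Internal conventions, used consistently across the package:

* time in **seconds**
* lengths in **nanometres** (positions, localization noise, cluster axes)
* diffusion coefficients in **µm²/s** (the field's customary unit)
* first-order rates reported in **min⁻¹** (as in dwell-time kinetics)

The only conversions anybody should ever need live here.
"""

NM_PER_UM: float = 1000.0
S_PER_MIN: float = 60.0


def per_min_to_per_s(rate_per_min: float) -> float:
    """Convert a first-order rate from min⁻¹ to s⁻¹."""
    return rate_per_min / S_PER_MIN


def per_s_to_per_min(rate_per_s: float) -> float:
    """Convert a first-order rate from s⁻¹ to min⁻¹."""
    return rate_per_s * S_PER_MIN


def um2_to_nm2(x_um2: float) -> float:
    return x_um2 * NM_PER_UM**2


def nm2_to_um2(x_nm2: float) -> float:
    return x_nm2 / NM_PER_UM**2
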