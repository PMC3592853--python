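"""Evanescent-field helper for TIRF/photoactivation depth selectivity.

In objective-type TIRF the excitation intensity decays with distance z
from the coverslip as I_λ(z) = I₀·exp(−z/δ(λ)), with a penetration depth
that scales with wavelength, δ(λ) ∝ λ, at a fixed incidence angle.
Activating at a shorter wavelength than the imaging line therefore
suppresses photoconversion of molecules deeper in the cell — the effect
exploited to photoconvert membrane-resident molecules selectively.
"""

from __future__ import annotations

import numpy as np

__all__ = ["evanescent_ratio"]


def evanescent_ratio(z: float, lambda_a: float, lambda_b: float, delta_ref: float) -> float:
    """Intensity ratio I_b(z)/I_a(z) of two evanescent fields at depth z.

    ``delta_ref`` is the penetration depth at ``lambda_b``; the depth at
    ``lambda_a`` follows from δ(λ) ∝ λ. The ratio is returned in its
    customary first-order form

        exp((z/δ_b) · (1 − λ_a/λ_b)),

    the linearization (in Δλ/λ) of the exact two-exponential quotient;
    at z = δ_b and λ_a/λ_b = 405/488 this evaluates to ≈1.185. All
    arguments must be positive; z may be zero (ratio 1).
    """
    if lambda_a <= 0 or lambda_b <= 0 or delta_ref <= 0:
        raise ValueError("wavelengths and penetration depth must be positive")
    if z < 0:
        raise ValueError("depth must be non-negative")
    return float(np.exp((z / delta_ref) * (1.0 - lambda_a / lambda_b)))
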