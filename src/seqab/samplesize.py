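"""Sample sizes for the two-proportion comparison.

Fixed-design per-group size from the classical normal-approximation formula
with a pooled variance term under the null, and the inflated maximum
per-group size implied by a calibrated group-sequential design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import ndtri

from .boundaries import GroupSequentialDesign

__all__ = ["PowerSpec", "fixed_n_per_group", "max_n_per_group"]


@dataclass(frozen=True)
class PowerSpec:
    """Design effect for sizing: null vs alternative response rate."""

    p_null: float
    p_alt: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        for label, p in (("p_null", self.p_null), ("p_alt", self.p_alt)):
            if not 0.0 < p < 1.0:
                raise ValueError(f"{label} must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not self.alpha < self.power < 1.0:
            raise ValueError("power must be in (alpha, 1)")


def fixed_n_per_group(spec: PowerSpec) -> int:
    """Smallest per-group n giving the target power in a single-look test.

    n = ceil( (z_{1-a/2} sqrt(2 pbar qbar) + z_{pow} sqrt(p1 q1 + p2 q2))^2
              / (p1 - p2)^2 )
    """
    p1, p2 = spec.p_null, spec.p_alt
    delta = p1 - p2
    if delta == 0.0:
        raise ValueError("p_null == p_alt: no effect to detect, n is infinite")
    z_a = ndtri(1.0 - spec.alpha / 2.0)
    z_b = ndtri(spec.power)
    pbar = 0.5 * (p1 + p2)
    num = z_a * math.sqrt(2.0 * pbar * (1.0 - pbar)) + z_b * math.sqrt(
        p1 * (1.0 - p1) + p2 * (1.0 - p2)
    )
    return math.ceil((num / delta) ** 2)


def max_n_per_group(design: GroupSequentialDesign, spec: PowerSpec) -> int:
    """Maximum per-group size: inflated fixed n, rounded up to a multiple of K.

    Equal stage sizes require divisibility by the number of looks.
    """
    n_fixed = fixed_n_per_group(spec)
    n = math.ceil(design.inflation_factor * n_fixed)
    k = design.total_looks
    if n % k:
        n += k - n % k
    return n
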