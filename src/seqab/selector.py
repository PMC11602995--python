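"""Loss-based selection among interim monitoring strategies.

The loss for a candidate design is a weighted sum of its sample-size ratios
against the fixed (single-look) design:

    L1 = w1 * ESS_null / SS_fixed + w2 * ESS_alt / SS_fixed
       + w3 * MSS / SS_fixed,         w1 + w2 + w3 = 1

where ESS_null / ESS_alt are the expected per-group sample sizes under
equal rates and under the design effect, and MSS is the maximum per-group
sample size.  Weights express what the experimenter cares about: w1 the
cost of monitoring truly null variants, w2 the cost when the effect is
real, w3 the worst case if no stop occurs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boundaries import GroupSequentialDesign, crossing_probabilities
from .engine import run_segment
from .samplesize import PowerSpec, fixed_n_per_group, max_n_per_group

__all__ = ["LossWeights", "DesignMetrics", "loss_L1", "design_metrics", "select_design"]


@dataclass(frozen=True)
class LossWeights:
    w1: float
    w2: float
    w3: float

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0.0:
            raise ValueError("weights must be nonnegative")
        if abs(self.w1 + self.w2 + self.w3 - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class DesignMetrics:
    ess_null: float
    ess_alt: float
    mss: float
    ss_fixed: float

    def __post_init__(self) -> None:
        if self.ss_fixed <= 0.0:
            raise ValueError("ss_fixed must be positive")
        if self.ess_null > self.mss * (1 + 1e-9) or self.ess_alt > self.mss * (1 + 1e-9):
            raise ValueError("expected sample sizes cannot exceed the maximum")


def loss_L1(w: LossWeights, m: DesignMetrics) -> float:
    """Weighted sample-size-ratio loss; 1.0 for the fixed design."""
    return (
        w.w1 * m.ess_null / m.ss_fixed
        + w.w2 * m.ess_alt / m.ss_fixed
        + w.w3 * m.mss / m.ss_fixed
    )


def design_metrics(
    design: GroupSequentialDesign,
    spec: PowerSpec,
    mode: str = "analytic",
    n_sims: int = 10_000,
    seed: int = 0,
) -> DesignMetrics:
    """ESS under null and alternative, and the maximum sample size.

    ``analytic`` integrates the stagewise stopping probabilities at drift 0
    and at the calibrated drift; ``simulate`` estimates the same quantities
    by Monte Carlo with stagewise binomial outcomes.  The two agree within
    Monte Carlo error.
    """
    n_fixed = fixed_n_per_group(spec)
    n_max = max_n_per_group(design, spec)
    if mode == "analytic":
        ess = {}
        for label, drift in (("null", 0.0), ("alt", design.drift)):
            probs = crossing_probabilities(
                design.efficacy_bounds,
                design.futility_bounds,
                drift,
                design.schedule,
            )
            ess[label] = probs.expected_fraction * n_max
        return DesignMetrics(ess["null"], ess["alt"], float(n_max), float(n_fixed))
    if mode == "simulate":
        ess = {}
        for i, (label, (p1, p2)) in enumerate(
            (("null", (spec.p_null, spec.p_null)), ("alt", (spec.p_null, spec.p_alt)))
        ):
            enrolled = np.empty(n_sims)
            for r in range(n_sims):
                rng = np.random.default_rng([seed, i, r])
                enrolled[r] = run_segment(design, n_max, p1, p2, rng).n_per_group_enrolled
            ess[label] = float(enrolled.mean())
        return DesignMetrics(ess["null"], ess["alt"], float(n_max), float(n_fixed))
    raise ValueError(f"unknown mode {mode!r}")


def select_design(
    candidates: Sequence[GroupSequentialDesign],
    w: LossWeights,
    spec: PowerSpec,
    mode: str = "analytic",
) -> GroupSequentialDesign:
    """Return the candidate minimising L1; ties break by list order."""
    if not candidates:
        raise ValueError("candidate list is empty")
    losses = [loss_L1(w, design_metrics(d, spec, mode=mode)) for d in candidates]
    return candidates[int(np.argmin(losses))]
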