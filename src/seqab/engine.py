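"""Simulation of platform-trial segments with interim monitoring.

A *segment* is one two-arm A/B comparison run under a calibrated
group-sequential design: per-stage binomial outcomes, a cumulative Welch
two-sample t statistic at each look, and the design's stopping rule.  A
*platform* chains five segments, with each segment's winner carried forward
as the next control.  The outcome is binary and lower response rates are
better (e.g. reducing the rate of calls into a help center), so a
challenger is only promoted when the test rejects *and* its observed rate
is below the control's.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .boundaries import GroupSequentialDesign

__all__ = [
    "ScenarioSpec",
    "SegmentResult",
    "PlatformResult",
    "t_statistic",
    "run_segment",
    "run_platform",
    "CHALLENGER_ORDER",
]

ARMS = ("S", "A", "B", "C", "D", "E")
CHALLENGER_ORDER = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class ScenarioSpec:
    """True response probabilities for the six arms S, A..E."""

    rates: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.rates) != set(ARMS):
            raise ValueError(f"rates must cover exactly the arms {ARMS}")
        if any(not 0.0 < p < 1.0 for p in self.rates.values()):
            raise ValueError("all response rates must be in (0, 1)")

    def __getitem__(self, arm: str) -> float:
        return self.rates[arm]


@dataclass(frozen=True)
class SegmentResult:
    control_arm: str
    challenger_arm: str
    winner: str
    stop_stage: int
    stop_reason: str  # completed | early_difference | early_futility
    n_per_group_enrolled: int
    z_path: tuple[float, ...]

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass(frozen=True)
class PlatformResult:
    segments: tuple[SegmentResult, ...]
    final_winner: str
    total_sample_size: int  # per-group enrollment summed over segments

    def to_json(self) -> str:
        return json.dumps(
            {
                "final_winner": self.final_winner,
                "total_sample_size": self.total_sample_size,
                "segments": [asdict(s) for s in self.segments],
            }
        )


def t_statistic(n1: int, s1: int, n2: int, s2: int) -> float:
    """Welch two-sample t statistic on binary outcomes, from counts.

    Group 1 is the control, group 2 the challenger.  Group means are
    ``s/n`` and group sample variances ``s (n - s) / (n (n - 1))`` (the
    usual n-1 denominator applied to 0/1 data).  The sign convention is
    *benefit-positive*: positive when the challenger's rate is lower, since
    lower response rates are better.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if not (0 <= s1 <= n1 and 0 <= s2 <= n2):
        raise ValueError("success counts must lie in [0, n]")
    m1, m2 = s1 / n1, s2 / n2
    v1 = s1 * (n1 - s1) / (n1 * (n1 - 1))
    v2 = s2 * (n2 - s2) / (n2 * (n2 - 1))
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        return 0.0 if m1 == m2 else math.copysign(math.inf, m1 - m2)
    return (m1 - m2) / math.sqrt(se2)


def run_segment(
    design: GroupSequentialDesign,
    max_n_per_group: int,
    p_control: float,
    p_challenger: float,
    rng: np.random.Generator,
    control_arm: str = "S",
    challenger_arm: str = "A",
) -> SegmentResult:
    """Simulate one monitored A/B comparison.

    Outcomes are drawn as stagewise binomial counts (stage size
    ``max_n_per_group / K`` per arm), statistically equivalent to
    per-subject streams for a statistic computed from counts.  Stopping:

    * difference stop at an interim when ``|t| >= c_k`` (rules
      ``difference-only``/``both``);
    * futility stop at an interim when ``|t| < f_k`` (rules
      ``futility-only``/``both``);
    * at the final look, reject iff ``|t| >= c_K``.

    The challenger wins only on rejection with a lower observed rate; an
    early difference stop in the harm direction awards the segment to the
    control, as does any non-rejection.
    """
    K = design.total_looks
    if max_n_per_group % K:
        raise ValueError("max_n_per_group must be divisible by the number of looks")
    stage_n = max_n_per_group // K
    c = design.efficacy_bounds
    f = design.futility_bounds

    cum_n = 0
    s_control = 0
    s_challenger = 0
    z_path: list[float] = []
    for k in range(K):
        cum_n += stage_n
        s_control += int(rng.binomial(stage_n, p_control))
        s_challenger += int(rng.binomial(stage_n, p_challenger))
        t = t_statistic(cum_n, s_control, cum_n, s_challenger)
        z_path.append(t)
        final = k == K - 1
        if not final:
            if design.stops_for_difference_early and abs(t) >= c[k]:
                winner = challenger_arm if t > 0 else control_arm
                return SegmentResult(
                    control_arm, challenger_arm, winner, k + 1,
                    "early_difference", cum_n, tuple(z_path),
                )
            if design.stops_for_futility and abs(t) < f[k]:
                return SegmentResult(
                    control_arm, challenger_arm, control_arm, k + 1,
                    "early_futility", cum_n, tuple(z_path),
                )
    reject = abs(z_path[-1]) >= c[K - 1]
    winner = challenger_arm if reject and z_path[-1] > 0 else control_arm
    return SegmentResult(
        control_arm, challenger_arm, winner, K, "completed", cum_n, tuple(z_path)
    )


def run_platform(
    design: GroupSequentialDesign,
    max_n_per_group: int,
    scenario: ScenarioSpec,
    rng: np.random.Generator,
) -> PlatformResult:
    """Chain five segments, the winner of each becoming the next control."""
    control = "S"
    segments: list[SegmentResult] = []
    total = 0
    for challenger in CHALLENGER_ORDER:
        seg = run_segment(
            design,
            max_n_per_group,
            scenario[control],
            scenario[challenger],
            rng,
            control_arm=control,
            challenger_arm=challenger,
        )
        segments.append(seg)
        total += seg.n_per_group_enrolled
        control = seg.winner
    return PlatformResult(tuple(segments), control, total)
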