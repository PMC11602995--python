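"""Monte Carlo studies over the platform-trial scenarios.

Twelve scenarios place an effective variant (or none) at different points
in the five-segment platform.  The base null response rate is 10%, the
design alternative 9.5%; sensitivity scenarios move the base rate to 15%
or 5% while *reusing* the sample size computed for 10% vs 9.5%.  A study
runs ``n_sims`` independent platform replicates under one design and
summarises final-winner proportions, the expected total sample size, and
per-segment stopping-reason profiles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .boundaries import GroupSequentialDesign, design_from_name
from .engine import ARMS, CHALLENGER_ORDER, PlatformResult, ScenarioSpec, run_platform
from .samplesize import PowerSpec, fixed_n_per_group, max_n_per_group

__all__ = [
    "SCENARIOS",
    "scenario_rates",
    "StudyConfig",
    "SummaryTable",
    "run_study",
    "stop_reason_profile",
]

logger = logging.getLogger(__name__)

STOP_REASONS = ("completed", "early_futility", "early_difference")

#: Scenario id -> (base rate, {arm: deviating rate}).  S always sits at the
#: base rate; unlisted challengers do too.
_SCENARIO_DEFS: dict[str, tuple[float, dict[str, float]]] = {
    "1": (0.10, {}),
    "1.1": (0.10, {"A": 0.095}),
    "1.2": (0.10, {"C": 0.095}),
    "1.3": (0.10, {"E": 0.095}),
    "1.4": (0.10, {"C": 0.08}),
    "2.1": (0.10, {"B": 0.095, "D": 0.095}),
    "2.2": (0.10, {"B": 0.08, "D": 0.095}),
    "2.3": (0.10, {"B": 0.095, "D": 0.08}),
    "3.1": (0.15, {}),
    "3.2": (0.15, {"C": 0.1425}),
    "3.3": (0.05, {}),
    "3.4": (0.05, {"C": 0.0475}),
}

SCENARIOS = tuple(_SCENARIO_DEFS)


def scenario_rates(scenario_id: str) -> ScenarioSpec:
    """True response rates of the six arms for a scenario label."""
    key = str(scenario_id)
    try:
        base, overrides = _SCENARIO_DEFS[key]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; choose from {SCENARIOS}"
        ) from None
    rates = {arm: overrides.get(arm, base) for arm in ARMS}
    return ScenarioSpec(rates)


@dataclass(frozen=True)
class StudyConfig:
    """One Monte Carlo study: scenario x design x number of looks."""

    scenario: str = "1"
    design: str = "fixed"
    total_looks: int = 1
    alpha: float = 0.05
    power: float = 0.80
    p_null_design: float = 0.10   # sizing rates; sensitivity scenarios reuse them
    p_alt_design: float = 0.095
    n_sims: int = 1000
    seed: int = 0
    out_dir: str | None = None
    trace: bool = False

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        scenario_rates(self.scenario)  # validate early

    @property
    def power_spec(self) -> PowerSpec:
        return PowerSpec(self.p_null_design, self.p_alt_design, self.alpha, self.power)


@dataclass(frozen=True)
class SummaryTable:
    """Table-2 / stopping-profile style summaries of one study."""

    config: StudyConfig
    winner_proportions: dict[str, float]
    ess_mean: float
    ess_sd: float
    segment_ess: tuple[float, ...]
    stop_reasons: pd.DataFrame  # index: segment 1..5, columns: STOP_REASONS
    max_n_per_group: int
    fixed_n_per_group: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format tidy frame (scenario, design, looks, metric, value)."""
        rows = []
        base = dict(
            scenario=self.config.scenario,
            design=self.config.design,
            looks=self.config.total_looks,
        )
        for arm, p in self.winner_proportions.items():
            rows.append({**base, "metric": f"winner_prop_{arm}", "value": p})
        rows.append({**base, "metric": "ess_mean", "value": self.ess_mean})
        rows.append({**base, "metric": "ess_sd", "value": self.ess_sd})
        rows.append({**base, "metric": "max_n_per_group", "value": self.max_n_per_group})
        rows.append({**base, "metric": "fixed_n_per_group", "value": self.fixed_n_per_group})
        for i, ess in enumerate(self.segment_ess, start=1):
            rows.append({**base, "metric": f"segment{i}_ess", "value": ess})
        for seg, row in self.stop_reasons.iterrows():
            for reason in STOP_REASONS:
                rows.append(
                    {**base, "metric": f"segment{seg}_prop_{reason}", "value": row[reason]}
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "scenario": self.config.scenario,
            "design": self.config.design,
            "looks": self.config.total_looks,
            "n_sims": self.config.n_sims,
            "seed": self.config.seed,
            "winner_proportions": self.winner_proportions,
            "ess_mean": self.ess_mean,
            "ess_sd": self.ess_sd,
            "segment_ess": list(self.segment_ess),
            "stop_reasons": {
                str(seg): {r: float(row[r]) for r in STOP_REASONS}
                for seg, row in self.stop_reasons.iterrows()
            },
            "max_n_per_group": self.max_n_per_group,
            "fixed_n_per_group": self.fixed_n_per_group,
        }


def stop_reason_profile(results: list[PlatformResult]) -> pd.DataFrame:
    """Per segment (1..5), the fraction of replicates in each stop class."""
    if not results:
        raise ValueError("no platform results to profile")
    n = len(results)
    counts = pd.DataFrame(
        0.0, index=range(1, len(CHALLENGER_ORDER) + 1), columns=list(STOP_REASONS)
    )
    for res in results:
        for i, seg in enumerate(res.segments, start=1):
            counts.loc[i, seg.stop_reason] += 1
    counts.index.name = "segment"
    return counts / n


def run_study(
    cfg: StudyConfig, design: GroupSequentialDesign | None = None
) -> SummaryTable:
    """Run ``cfg.n_sims`` platform replicates and summarise them.

    Replicate ``r`` draws from an independent RNG substream seeded with
    ``(seed, r)``, so results are reproducible and order-independent.  A
    pre-calibrated design may be passed to avoid repeating the calibration.
    """
    if design is None:
        design = design_from_name(
            cfg.design, cfg.total_looks, alpha=cfg.alpha, power=cfg.power
        )
    spec = cfg.power_spec
    n_fixed = fixed_n_per_group(spec)
    n_max = max_n_per_group(design, spec)
    scenario = scenario_rates(cfg.scenario)
    logger.info(
        "study scenario=%s design=%s looks=%d: max n/group=%d (fixed %d), "
        "efficacy bounds=%s, futility bounds=%s",
        cfg.scenario, cfg.design, design.total_looks, n_max, n_fixed,
        np.round(design.efficacy_bounds, 4),
        None if design.futility_bounds is None else np.round(design.futility_bounds, 4),
    )

    results = [
        run_platform(design, n_max, scenario, np.random.default_rng([cfg.seed, r]))
        for r in range(cfg.n_sims)
    ]

    winners = {arm: 0 for arm in ARMS}
    totals = np.array([res.total_sample_size for res in results], dtype=float)
    seg_n = np.array(
        [[seg.n_per_group_enrolled for seg in res.segments] for res in results],
        dtype=float,
    )
    for res in results:
        winners[res.final_winner] += 1

    summary = SummaryTable(
        config=cfg,
        winner_proportions={arm: winners[arm] / cfg.n_sims for arm in ARMS},
        ess_mean=float(totals.mean()),
        ess_sd=float(totals.std(ddof=1)) if cfg.n_sims > 1 else 0.0,
        segment_ess=tuple(seg_n.mean(axis=0)),
        stop_reasons=stop_reason_profile(results),
        max_n_per_group=n_max,
        fixed_n_per_group=n_fixed,
    )
    if cfg.out_dir is not None:
        _write_outputs(summary, results, Path(cfg.out_dir))
    return summary


def _write_outputs(
    summary: SummaryTable, results: list[PlatformResult], out_dir: Path
) -> None:
    cfg = summary.config
    stem = f"scenario{cfg.scenario}_{cfg.design}_k{cfg.total_looks}"
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_frame().to_csv(out_dir / f"{stem}.csv", index=False)
        with open(out_dir / f"{stem}.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2)
        if cfg.trace:
            with open(out_dir / f"{stem}.trace.jsonl", "w") as fh:
                for res in results:
                    fh.write(res.to_json() + "\n")
    except OSError as exc:
        raise OSError(f"failed writing study outputs under {out_dir}: {exc}") from exc
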