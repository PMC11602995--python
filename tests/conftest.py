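"""Shared fixtures: calibrated designs, cached studies, and a brute-force
two-look Gaussian oracle used to validate the boundary recursion."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from seqab.boundaries import design_from_name
from seqab.samplesize import PowerSpec
from seqab.study import StudyConfig, run_study


@pytest.fixture(scope="session")
def design_spec() -> PowerSpec:
    """The platform's sizing effect: 10% vs 9.5%, alpha 5%, power 80%."""
    return PowerSpec(0.10, 0.095, 0.05, 0.80)


@pytest.fixture(scope="session")
def designs() -> dict:
    """Calibrated designs, keyed by (name, total_looks)."""
    cache = {("fixed", 1): design_from_name("fixed", 1)}
    for name in ("obf-both", "pocock-futility", "pocock-both", "obf-futility"):
        for k in (2, 4):
            cache[(name, k)] = design_from_name(name, k)
    return cache


@pytest.fixture(scope="session")
def study_cache():
    """Memoised Monte Carlo studies shared across acceptance tests."""
    cache: dict = {}

    def get(scenario: str, design: str, looks: int, n_sims: int = 1000, seed: int = 11):
        key = (scenario, design, looks, n_sims, seed)
        if key not in cache:
            cache[key] = run_study(
                StudyConfig(
                    scenario=scenario,
                    design=design,
                    total_looks=looks,
                    n_sims=n_sims,
                    seed=seed,
                )
            )
        return cache[key]

    return get


def two_look_oracle(
    c1: float,
    c2: float,
    f1: float,
    drift: float,
    t1: float = 0.5,
    nodes: int = 2001,
    half_width: float = 8.0,
) -> dict[str, float]:
    """Brute-force stagewise probabilities for a two-look design.

    Integrates the bivariate normal density of (Z_1, Z_2) — means
    ``drift*sqrt(t1)`` and ``drift``, correlation ``sqrt(t1)`` — by
    trapezoidal quadrature over explicit rectangles, >= 2000 nodes per axis
    and an integration range of +/- ``half_width`` standard deviations.
    Entirely independent of the recursive integration in the package.
    """
    m1, m2 = drift * np.sqrt(t1), drift
    rho = np.sqrt(t1)
    mvn = multivariate_normal(mean=[m1, m2], cov=[[1.0, rho], [rho, 1.0]])
    lo1, hi1 = m1 - half_width, m1 + half_width
    lo2, hi2 = m2 - half_width, m2 + half_width

    def rect(x0, x1, y0, y1) -> float:
        x0, x1 = max(x0, lo1), min(x1, hi1)
        y0, y1 = max(y0, lo2), min(y1, hi2)
        if x1 <= x0 or y1 <= y0:
            return 0.0
        x = np.linspace(x0, x1, nodes)
        y = np.linspace(y0, y1, nodes)
        xx, yy = np.meshgrid(x, y, indexing="ij")
        dens = mvn.pdf(np.stack([xx, yy], axis=-1))
        return float(np.trapezoid(np.trapezoid(dens, y, axis=1), x))

    inf = 1e9
    cont1 = [(-c1, -f1), (f1, c1)] if f1 > 0 else [(-c1, c1)]
    p_eff1 = rect(-inf, -c1, -inf, inf) + rect(c1, inf, -inf, inf)
    p_fut1 = rect(-f1, f1, -inf, inf) if f1 > 0 else 0.0
    p_eff2 = sum(
        rect(a, b, -inf, -c2) + rect(a, b, c2, inf) for a, b in cont1
    )
    p_nostop = sum(rect(a, b, -c2, c2) for a, b in cont1)
    return {
        "eff1": p_eff1,
        "fut1": p_fut1,
        "eff2": p_eff2,
        "no_stop": p_nostop,
    }
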