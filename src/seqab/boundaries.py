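"""Error-spending boundaries for group-sequential two-arm monitoring.

This module computes everything that depends only on the *monitoring plan*,
not on the simulated data: cumulative error-spending curves, two-sided
efficacy boundaries, beta-spending futility boundaries, stagewise stopping
probabilities under an arbitrary drift, and the joint (drift, futility)
calibration that fixes a design's inflation factor.

The sequence of interim statistics ``Z_1 .. Z_K`` is modelled with the
canonical joint distribution of group-sequential theory:

    E[Z_k] = theta * sqrt(t_k),      Cov(Z_j, Z_k) = sqrt(t_j / t_k),  j <= k

where ``t_k`` is the information fraction at look ``k`` and ``theta`` is the
drift (the mean of the final-look statistic at the design effect size).
Stagewise probabilities are obtained by the standard recursive numerical
integration over the continuation region, using Gauss-Legendre quadrature
on each continuation interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

__all__ = [
    "SpendingFunction",
    "InterimSchedule",
    "GroupSequentialDesign",
    "StagewiseProbabilities",
    "CalibrationError",
    "INFINITE_BOUND",
    "solve_efficacy_bounds",
    "solve_futility_bounds",
    "crossing_probabilities",
    "calibrate_design",
    "design_from_name",
    "DESIGN_NAMES",
]

#: Sentinel for "no error spent at this look" (effectively +infinity on the
#: Z scale; any value >= 10 is treated as uncrossable).
INFINITE_BOUND = 10.0

#: Half-width, in standard deviations around the stagewise mean, of the
#: numerical integration range.
_HALF_WIDTH = 8.0

#: Gauss-Legendre nodes per continuation interval.  Two intervals per stage
#: (a futility band splits the continuation region) give >= 500 nodes/stage.
_GL_NODES = 301

_GL_X, _GL_W = np.polynomial.legendre.leggauss(_GL_NODES)
_SQRT_2PI = math.sqrt(2.0 * math.pi)


class CalibrationError(RuntimeError):
    """Raised when a boundary or drift calibration cannot be completed."""


@dataclass(frozen=True)
class SpendingFunction:
    """Cumulative error-spending curve ``alpha(t*)``.

    Parameters
    ----------
    family:
        ``"pocock"`` for the Pocock-type curve ``level * ln(1 + (e-1) t*)``
        or ``"obf"`` for the O'Brien-Fleming-type (Lan-DeMets) curve
        ``2 * (1 - Phi(z_{1-level/2} / sqrt(t*)))``.
    level:
        Total error to spend by ``t* = 1`` (alpha for efficacy spending,
        beta = 1 - power for futility spending).
    """

    family: str
    level: float

    _FAMILIES = ("pocock", "obf")

    def __post_init__(self) -> None:
        fam = self.family.removesuffix("-type")
        if fam not in self._FAMILIES:
            raise ValueError(f"unknown spending family {self.family!r}")
        object.__setattr__(self, "family", fam)
        if not 0.0 < self.level < 1.0:
            raise ValueError("spending level must be in (0, 1)")

    def __call__(self, t: float) -> float:
        """Cumulative error spent by information fraction ``t``."""
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"information fraction {t} outside [0, 1]")
        if t == 0.0:
            return 0.0
        if self.family == "pocock":
            return self.level * math.log1p((math.e - 1.0) * t)
        z = ndtri(1.0 - self.level / 2.0)
        return float(2.0 * (1.0 - ndtr(z / math.sqrt(t))))

    # alias used in prose/tests
    spend = __call__


@dataclass(frozen=True)
class InterimSchedule:
    """Information fractions ``t_1 < ... < t_K = 1`` of the planned looks."""

    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        fr = tuple(float(t) for t in self.fractions)
        if len(fr) < 1:
            raise ValueError("schedule needs at least one look")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("information fractions must be strictly increasing")
        if fr[0] <= 0.0 or fr[-1] != 1.0:
            raise ValueError("fractions must lie in (0, 1] and end at exactly 1")
        object.__setattr__(self, "fractions", fr)

    @classmethod
    def equal(cls, total_looks: int) -> "InterimSchedule":
        """Equal information increments ``t_k = k / K``."""
        if total_looks < 1:
            raise ValueError("total_looks must be >= 1")
        return cls(tuple((k + 1) / total_looks for k in range(total_looks)))

    @property
    def total_looks(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class GroupSequentialDesign:
    """A calibrated monitoring plan for one two-arm segment.

    ``rule`` is one of ``fixed``, ``difference-only``, ``futility-only`` or
    ``both``.  ``efficacy_bounds`` are the two-sided critical values
    ``c_1..c_K`` (interim entries equal to :data:`INFINITE_BOUND` when no
    alpha is spent at that look, as in futility-only monitoring);
    ``futility_bounds`` are the inner band values ``f_1..f_{K-1}`` applied as
    ``|Z_k| < f_k`` at interims only.  ``drift`` is the mean of the
    final-look statistic at the design effect, and ``inflation_factor`` is
    ``(drift / drift_fixed)**2``, the ratio of maximum to fixed-design
    information required to preserve power.
    """

    schedule: InterimSchedule
    rule: str
    alpha: float
    power: float
    efficacy_bounds: tuple[float, ...]
    futility_bounds: tuple[float, ...] | None
    drift: float
    inflation_factor: float
    alpha_family: str | None = None
    beta_family: str | None = None
    name: str | None = None

    _RULES = ("fixed", "difference-only", "futility-only", "both")

    def __post_init__(self) -> None:
        if self.rule not in self._RULES:
            raise ValueError(f"unknown rule {self.rule!r}")

    @property
    def total_looks(self) -> int:
        return self.schedule.total_looks

    @property
    def stops_for_difference_early(self) -> bool:
        return self.rule in ("difference-only", "both") and self.total_looks > 1

    @property
    def stops_for_futility(self) -> bool:
        return self.rule in ("futility-only", "both") and self.total_looks > 1


@dataclass(frozen=True)
class StagewiseProbabilities:
    """First-stopping probabilities per look under a given drift."""

    fractions: tuple[float, ...]
    efficacy: tuple[float, ...]   # P(first stop at k is an efficacy stop)
    futility: tuple[float, ...]   # P(first stop at k is a futility stop)
    no_stop: float                # P(reach look K without rejecting): accept H0

    @property
    def total_efficacy(self) -> float:
        return float(sum(self.efficacy))

    @property
    def total_futility(self) -> float:
        return float(sum(self.futility))

    @property
    def expected_fraction(self) -> float:
        """E[information fraction at the stopping look]."""
        t = np.asarray(self.fractions)
        p_stop = np.asarray(self.efficacy) + np.asarray(self.futility)
        p_stop[-1] += self.no_stop
        return float(np.dot(t, p_stop))


# ---------------------------------------------------------------------------
# numerical recursion
# ---------------------------------------------------------------------------

def _continuation_intervals(c: float, f: float, mean: float) -> list[tuple[float, float]]:
    """Continuation region {f <= |z| < c} clipped to mean +/- _HALF_WIDTH."""
    lo, hi = mean - _HALF_WIDTH, mean + _HALF_WIDTH
    a, b = max(-c, lo), min(c, hi)
    if f > 0.0:
        ivs = [(a, min(-f, b)), (max(f, a), b)]
    else:
        ivs = [(a, b)]
    return [(x, y) for x, y in ivs if y - x > 1e-12]


def _quadrature(intervals: Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    xs, ws = [], []
    for a, b in intervals:
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        xs.append(mid + half * _GL_X)
        ws.append(half * _GL_W)
    return np.concatenate(xs), np.concatenate(ws)


class _Recursion:
    """Stagewise recursion for the canonical group-sequential statistic.

    Maintains the sub-density ``psi_k`` of ``Z_k`` restricted to "no stop
    through look k", sampled on a quadrature grid over the continuation
    region, and exposes the conditional transition needed to score the next
    look.  Used both for probability evaluation and inside boundary root
    solves (where the density up to look ``k-1`` is fixed while ``c_k`` or
    ``f_k`` varies).
    """

    def __init__(self, fractions: Sequence[float], drift: float):
        self.t = np.asarray(fractions, dtype=float)
        self.drift = float(drift)
        self.means = self.drift * np.sqrt(self.t)
        self.k = 0                       # next look index (0-based)
        self._x: np.ndarray | None = None
        self._pw: np.ndarray | None = None  # psi(u) * quadrature weight

    # conditional law of Z_k given Z_{k-1} = u
    def _transition(self, k: int) -> tuple[float, float, float]:
        dt = self.t[k] - self.t[k - 1]
        scale = math.sqrt(dt / self.t[k])
        slope = math.sqrt(self.t[k - 1] / self.t[k])
        shift = self.drift * dt / math.sqrt(self.t[k])
        return slope, shift, scale

    def _cond_mean_scale(self, k: int) -> tuple[np.ndarray, float]:
        slope, shift, scale = self._transition(k)
        return slope * self._x + shift, scale

    def upper_tail(self, c: float) -> float:
        """P(|Z_k| >= c, no stop before look k)."""
        k = self.k
        if k == 0:
            m = self.means[0]
            return float(ndtr(m - c) + ndtr(-c - m))
        cm, s = self._cond_mean_scale(k)
        vals = ndtr((cm - c) / s) + ndtr((-c - cm) / s)
        return float(np.dot(self._pw, vals))

    def inner_band(self, f: float) -> float:
        """P(|Z_k| < f, no stop before look k)."""
        if f <= 0.0:
            return 0.0
        k = self.k
        if k == 0:
            m = self.means[0]
            return float(ndtr(f - m) - ndtr(-f - m))
        cm, s = self._cond_mean_scale(k)
        vals = ndtr((f - cm) / s) - ndtr((-f - cm) / s)
        return float(np.dot(self._pw, vals))

    def advance(self, c: float, f: float) -> None:
        """Condition on continuing past look k with bounds (c, f)."""
        k = self.k
        ivs = _continuation_intervals(c, f, self.means[k])
        if not ivs:
            raise CalibrationError(
                f"continuation region empty at look {k + 1} (c={c}, f={f})"
            )
        x, w = _quadrature(ivs)
        if k == 0:
            psi = np.exp(-0.5 * (x - self.means[0]) ** 2) / _SQRT_2PI
        else:
            cm, s = self._cond_mean_scale(k)
            kernel = np.exp(-0.5 * ((x[:, None] - cm[None, :]) / s) ** 2) / (s * _SQRT_2PI)
            psi = kernel @ self._pw
        self._x, self._pw = x, psi * w
        self.k = k + 1


def crossing_probabilities(
    efficacy: Sequence[float],
    futility: Sequence[float] | None,
    drift: float,
    schedule: InterimSchedule,
) -> StagewiseProbabilities:
    """Stagewise first-stopping probabilities under the given drift.

    Futility stopping at look ``k < K`` means ``|Z_k| < f_k`` with no earlier
    stop; futility is never applied at the final look.  Probabilities sum to
    one up to quadrature error (< 1e-8).
    """
    t = schedule.fractions
    K = len(t)
    c = np.asarray(efficacy, dtype=float)
    if c.shape != (K,):
        raise ValueError("efficacy bounds must have one entry per look")
    if futility is None:
        f = np.zeros(max(K - 1, 0))
    else:
        f = np.asarray(futility, dtype=float)
        if f.shape != (K - 1,):
            raise ValueError("futility bounds must have K-1 entries")
    if not np.isfinite(drift):
        raise ValueError("drift must be finite")

    rec = _Recursion(t, drift)
    p_eff = np.zeros(K)
    p_fut = np.zeros(K)
    for k in range(K):
        p_eff[k] = rec.upper_tail(c[k])
        if k < K - 1:
            p_fut[k] = rec.inner_band(f[k])
            rec.advance(c[k], f[k])
    # mass reaching the final look without rejecting
    rec_final = 1.0 - p_eff.sum() - p_fut.sum()
    return StagewiseProbabilities(
        fractions=tuple(t),
        efficacy=tuple(p_eff),
        futility=tuple(p_fut),
        no_stop=float(rec_final),
    )


def solve_efficacy_bounds(
    sf: SpendingFunction, schedule: InterimSchedule
) -> tuple[float, ...]:
    """Two-sided efficacy bounds ``c_1..c_K`` matching the spending curve.

    Under zero drift, the cumulative two-sided crossing probability through
    look ``k`` equals ``sf(t_k)``.  A look with (numerically) zero
    incremental spend receives the :data:`INFINITE_BOUND` sentinel.
    """
    t = schedule.fractions
    K = len(t)
    rec = _Recursion(t, 0.0)
    bounds: list[float] = []
    spent = 0.0
    for k in range(K):
        target = sf(t[k]) - spent
        spent = sf(t[k])
        if target < 1e-14:
            c_k = INFINITE_BOUND
        else:
            g = lambda c: rec.upper_tail(c) - target
            if g(INFINITE_BOUND) > 0.0:  # pragma: no cover - defensive
                raise CalibrationError(f"cannot spend {target} at look {k + 1}")
            try:
                c_k = brentq(g, 1e-3, INFINITE_BOUND, xtol=1e-12, rtol=1e-14)
            except ValueError as exc:  # pragma: no cover - defensive
                raise CalibrationError(
                    f"efficacy bound root search failed at look {k + 1}"
                ) from exc
        bounds.append(float(c_k))
        if k < K - 1:
            rec.advance(c_k, 0.0)
    return tuple(bounds)


def solve_futility_bounds(
    beta_sf: SpendingFunction,
    efficacy: Sequence[float] | None,
    drift: float,
    schedule: InterimSchedule,
    collide: str = "raise",
) -> tuple[float, ...]:
    """Futility band values ``f_1..f_{K-1}`` from a beta-spending curve.

    Under the given drift, the cumulative probability of a futility stop by
    look ``k`` (with any efficacy bounds respected) equals ``beta_sf(t_k)``
    for ``k < K``.  When the required band would collide with the efficacy
    bound, ``collide="raise"`` reports the stage while ``collide="cap"``
    clips the band just below the bound (used transiently while the drift
    calibration probes overpowered drifts).
    """
    if drift <= 0.0:
        raise ValueError("futility calibration requires drift > 0")
    t = schedule.fractions
    K = len(t)
    if K == 1:
        return ()
    c = (
        np.full(K, INFINITE_BOUND)
        if efficacy is None
        else np.asarray(efficacy, dtype=float)
    )
    rec = _Recursion(t, drift)
    bounds: list[float] = []
    spent = 0.0
    for k in range(K - 1):
        target = beta_sf(t[k]) - spent
        spent = beta_sf(t[k])
        if target < 1e-14:
            f_k = 0.0
        else:
            f_max = min(c[k], rec.means[k] + _HALF_WIDTH) - 1e-9
            g = lambda f: rec.inner_band(f) - target
            if g(f_max) < 0.0:
                if collide != "cap":
                    raise CalibrationError(
                        f"futility band collides with efficacy bound at look {k + 1}"
                    )
                f_k = f_max
            else:
                f_k = brentq(g, 0.0, f_max, xtol=1e-12, rtol=1e-14)
        bounds.append(float(f_k))
        rec.advance(c[k], f_k)
    return tuple(bounds)


# ---------------------------------------------------------------------------
# design calibration
# ---------------------------------------------------------------------------

def _fixed_drift(alpha: float, power: float) -> float:
    return float(ndtri(1.0 - alpha / 2.0) + ndtri(power))


def calibrate_design(
    rule: str,
    alpha: float,
    power: float,
    schedule: InterimSchedule | None = None,
    alpha_family: str | None = None,
    beta_family: str | None = None,
    name: str | None = None,
) -> GroupSequentialDesign:
    """Calibrate drift, bounds and inflation factor to the target power.

    Efficacy bounds are solved from the alpha-spending curve ignoring
    futility (non-binding convention); futility bounds are solved from the
    beta-spending curve at the candidate drift, and the drift is adjusted
    until the probability of rejecting at any look — with futility stops
    honoured — equals ``power`` (to 1e-6).  For ``futility-only`` no alpha
    is spent at interims and the final critical value is the fixed-design
    ``z_{1-alpha/2}``.
    """
    if not 0.0 < alpha < 1.0 or not alpha < power < 1.0:
        raise ValueError("require 0 < alpha < power < 1")
    drift_fixed = _fixed_drift(alpha, power)
    z_final = float(ndtri(1.0 - alpha / 2.0))

    if rule == "fixed" or schedule is None or schedule.total_looks == 1:
        sched = InterimSchedule.equal(1)
        return GroupSequentialDesign(
            schedule=sched,
            rule=rule if rule == "fixed" else rule,
            alpha=alpha,
            power=power,
            efficacy_bounds=(z_final,),
            futility_bounds=None,
            drift=drift_fixed,
            inflation_factor=1.0,
            alpha_family=alpha_family,
            beta_family=beta_family,
            name=name,
        )

    K = schedule.total_looks
    needs_alpha_spending = rule in ("difference-only", "both")
    needs_beta_spending = rule in ("futility-only", "both")
    if needs_alpha_spending:
        if alpha_family is None:
            raise ValueError(f"rule {rule!r} requires alpha_family")
        efficacy = solve_efficacy_bounds(SpendingFunction(alpha_family, alpha), schedule)
    else:
        efficacy = tuple([INFINITE_BOUND] * (K - 1) + [z_final])
    if needs_beta_spending and beta_family is None:
        raise ValueError(f"rule {rule!r} requires beta_family")
    beta_sf = (
        SpendingFunction(beta_family, 1.0 - power) if needs_beta_spending else None
    )

    def attained_power(drift: float, collide: str = "cap") -> tuple[float, tuple[float, ...] | None]:
        fut = (
            solve_futility_bounds(beta_sf, efficacy, drift, schedule, collide=collide)
            if beta_sf is not None
            else None
        )
        probs = crossing_probabilities(efficacy, fut, drift, schedule)
        return probs.total_efficacy, fut

    g = lambda drift: attained_power(drift)[0] - power
    lo, hi = 0.9 * drift_fixed, 1.5 * drift_fixed
    for _ in range(8):
        if g(hi) > 0.0:
            break
        hi *= 1.2
    else:  # pragma: no cover - defensive
        raise CalibrationError("power calibration failed to bracket the drift")
    drift = float(brentq(g, lo, hi, xtol=1e-10, rtol=8.9e-16))
    pw, futility = attained_power(drift, collide="raise")
    if abs(pw - power) > 1e-6:  # pragma: no cover - defensive
        raise CalibrationError(f"power calibration converged to {pw}, not {power}")

    return GroupSequentialDesign(
        schedule=schedule,
        rule=rule,
        alpha=alpha,
        power=power,
        efficacy_bounds=tuple(efficacy),
        futility_bounds=futility,
        drift=drift,
        inflation_factor=float((drift / drift_fixed) ** 2),
        alpha_family=alpha_family,
        beta_family=beta_family,
        name=name,
    )


#: Named monitoring strategies.  The three headline designs are ``fixed``,
#: ``obf-both`` and ``pocock-futility``; the rest complete the candidate
#: menu for design selection.
DESIGN_NAMES: dict[str, dict] = {
    "fixed": dict(rule="fixed"),
    "obf-both": dict(rule="both", alpha_family="obf", beta_family="obf"),
    "pocock-both": dict(rule="both", alpha_family="pocock", beta_family="pocock"),
    "obf-futility": dict(rule="futility-only", beta_family="obf"),
    "pocock-futility": dict(rule="futility-only", beta_family="pocock"),
    "obf-difference": dict(rule="difference-only", alpha_family="obf"),
    "pocock-difference": dict(rule="difference-only", alpha_family="pocock"),
}


def design_from_name(
    name: str, total_looks: int = 1, alpha: float = 0.05, power: float = 0.80
) -> GroupSequentialDesign:
    """Calibrate one of the named monitoring strategies."""
    try:
        kw = DESIGN_NAMES[name]
    except KeyError:
        raise ValueError(
            f"unknown design {name!r}; choose from {sorted(DESIGN_NAMES)}"
        ) from None
    schedule = InterimSchedule.equal(total_looks if kw["rule"] != "fixed" else 1)
    return calibrate_design(
        alpha=alpha, power=power, schedule=schedule, name=name, **kw
    )
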