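# Methods

## Model

Each platform segment is a two-arm comparison of binary outcomes with
true response rates (p_control, p_challenger); lower is better. Interim
analyses occur at equal information fractions t_k = k/K, K ∈ {1, 2, 4}
by default. The monitored statistic is the Welch two-sample t computed
from cumulative counts; at the per-group sizes involved (≥ ~14,000 per
look) its joint distribution across looks is indistinguishable from the
canonical group-sequential Gaussian sequence

    E[Z_k] = θ√t_k,    Cov(Z_j, Z_k) = √(t_j / t_k),

on which all boundary computations are carried out. θ (the drift) is the
mean of the final-look statistic at the design effect.

## Boundaries and calibration

Efficacy bounds come from an error-spending curve (Pocock-type
α·ln[1+(e−1)t\*] or O'Brien–Fleming-type 2(1−Φ(z₁₋α/₂/√t\*))), solved
stagewise so the cumulative two-sided crossing probability under θ = 0
tracks the curve to ≤ 1e-6. Futility is a two-sided inner band
|Z_k| < f_k, never applied at the final look, derived from a β-spending
curve of the same family as the design's name with level β = 1 − power:
under the design drift, the cumulative futility-stop probability by look
k equals the curve at t_k.

Conventions, chosen where more than one standard exists:

- **Non-binding futility for α**: efficacy bounds are solved ignoring the
  band, so type I error is protected even if a futility stop is
  overridden in practice. With the band honoured the realised type I
  error is below α.
- **Futility respected for power**: the drift (hence the inflation factor
  IF = (θ/θ_fixed)², θ_fixed = z₁₋α/₂ + z_power) is root-solved so that
  the probability of rejecting at *any* look, with futility stops
  honoured, equals the target power to 1e-6. This makes the futility-only
  designs noticeably inflated (e.g. IF ≈ 1.29 for Pocock-type β-spending
  at K = 4).
- **Futility-only designs spend no α at interims**: interim efficacy
  bounds carry an uncrossable sentinel (≥ 10 on the Z scale) and the
  final critical value is the fixed z₁₋α/₂.
- **Two-sided band**: a futility-only design never stops early for a true
  difference in either direction — the band is symmetric in |Z| — which
  reproduces the characteristic cost of futility-only monitoring when an
  effective variant enters the platform early.

Stopping-profile proportions and expected sample sizes of monitored
designs are moderately sensitive to these conventions (a few percent on
ESS; more on single-look stop fractions); alternatives such as binding
bands, one-sided β-spending, or skipping the power recalibration move the
numbers but no choice dominates the others against external references.

## Numerics

Stagewise probabilities use the standard recursion on the sub-density of
Z_k restricted to "no stop yet", integrated by Gauss–Legendre quadrature
with 301 nodes per continuation interval (≥ 500 nodes per look once a
futility band splits the region), over a range of ±8 SD around the
stagewise mean. Stage transitions use the exact conditional normal law.
Probabilities sum to 1 within 1e-8; the test suite validates all two-look
quantities against a brute-force bivariate-normal trapezoid integration
(≥ 2000 nodes per axis) to 1e-4. Bound and drift root solves use Brent's
method (xtol ≤ 1e-10); a look with zero incremental spend gets the
infinite-bound sentinel; while the drift search transiently probes
overpowered drifts, an unspendable β increment clips the band just below
the efficacy bound, and the final solution is recomputed strictly.

Degenerate statistics: equal means with zero variance give t = 0;
unequal means with zero variance give ±∞ (always a rejection). A final
statistic exactly on the bound rejects (≥); a rejection with exactly
equal observed rates retains the control.

## Sample-size conventions

Fixed per-group n uses the classical two-proportion normal approximation
with pooled average variance under the null; for 10% vs 9.5%, 80% power,
two-sided 5% it gives 55,252 per group. Monitored designs use
⌈IF·n_fixed⌉ rounded up to a multiple of K so stages are equal. All
enrollment accounting (segment and platform ESS) is **per group**: the
fixed-design platform total is 5 × 55,252 = 276,260. Doubling gives
two-arm totals; the per-group convention is used throughout the
summaries.

## Simulation engine

Outcomes are drawn as stagewise binomial counts per arm rather than
per-subject streams — statistically identical for count-based statistics
and orders of magnitude faster. A challenger is promoted only on
rejection with a lower observed rate (benefit-positive sign convention);
an early "difference" stop in the harm direction awards the segment to
the control. Segments run in the fixed order A, B, C, D, E with the
previous winner as control. Replicate r of a study uses the independent
NumPy substream seeded with (seed, r), so studies are bit-reproducible
and order-independent.

The scenario catalogue places the effective variant(s) at different
platform positions: an all-null base (10% everywhere), "diamond in the
rough" scenarios with one effective variant (9.5% or 8%) at segment 1, 3
or 5, two-effective-variant scenarios at segments 2 and 4, and
sensitivity baselines at 15% and 5% that deliberately *reuse* the
10%-vs-9.5% sample size (so the 15% variants are overpowered and the 5%
ones underpowered). Defaults: 1000 Monte Carlo replicates per study,
α = 0.05, power = 0.80. These are the studied conditions; Monte Carlo
test tolerances use 3× the binomial standard error at 1000 replicates.

What the generator does *not* emulate: correlated randomization units
(users within households/organisations), time trends or seasonality in
response rates, unequal or data-driven interim spacing, and non-binary
outcomes. Passing tests therefore demonstrate correctness of the
boundary mathematics and of the platform's operating characteristics
under independent Bernoulli sampling with equal-information looks — not
robustness to clustered traffic or drifting baselines.

## Design selection

`select_design` minimises L1 over a configurable candidate menu
(default: fixed, obf-both, pocock-futility, pocock-both, obf-futility),
with deterministic tie-break by candidate order. Over the three headline
designs the expected optima are stable: equal weights → obf-both,
null-heavy (0.9, 0.05, 0.05) → pocock-futility, max-heavy
(0.05, 0.05, 0.9) → fixed, at both 2 and 4 looks. Over the extended menu
at 4 looks the null-heavy case is a near-tie: pocock-both scores 0.76684
vs pocock-futility's 0.76864 (0.2% margin), inside the sensitivity of the
futility conventions above; the package reports the full loss table so
such margins are visible.

## Limitations

- Boundary computations assume the canonical Gaussian sequence; at much
  smaller per-look sample sizes (hundreds) the binomial/t discreteness
  would matter and the realised error rates drift from nominal.
- Futility-convention sensitivity (above) means stop-fraction summaries
  should be read to a few percentage points, not exactly.
- The platform's family-wise error across segments is deliberately not
  corrected: each segment prospectively enrolls fresh data, mirroring a
  series of standalone A/B tests.
- Expected-sample-size optimality statements are specific to the equal
  increment schedule; uneven or adaptive look spacing is unsupported.
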