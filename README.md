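# seqab — group-sequential platform trials for automated A/B testing

`seqab` simulates and calibrates an *automated sequential platform trial*
for A/B testing: a standard variant **S** is challenged by five new
variants **A–E** in successive two-arm segments, and the winner of each
segment becomes the comparator for the next, until a final overall winner
emerges. Each segment can be monitored with group-sequential interim
analyses, so that clearly futile (or clearly different) comparisons stop
before full enrollment. The package is aimed at analytics teams who run
many A/B experiments on binary outcomes (e.g. reducing the rate of calls
into a help center — *lower* response rates are better) and want
clinical-trial-grade interim monitoring without hand-designing every test.

## What it computes

**Error-spending boundaries.** Interim monitoring is driven by spending
functions α(t\*) of the information fraction t\* (enrolled / maximum
sample size):

- Pocock-type: α(t\*) = α·ln[1 + (e−1)·t\*]
- O'Brien–Fleming-type (Lan–DeMets): α(t\*) = 2·(1 − Φ(z₁₋α/₂ / √t\*))

Two-sided efficacy bounds c₁..c_K are solved so the cumulative crossing
probability of the canonical statistic sequence (E[Z_k] = θ√t_k,
Cov(Z_j, Z_k) = √(t_j/t_k)) tracks the spending curve; futility is an
inner band |Z_k| < f_k derived from a β-spending curve (β = 1 − power) at
the design drift θ. The drift — hence the inflation factor
IF = (θ/θ_fixed)² and the maximum sample size — is calibrated so that
power is attained with futility stops honoured.

**Stopping rules.** `fixed` (no interim looks), `difference-only`,
`futility-only` (no α spent at interims; final test at z₁₋α/₂), and
`both`. The three headline strategies are `fixed`, `obf-both`, and
`pocock-futility`.

**The platform.** Per-segment outcomes are Bernoulli; analyses use a Welch
two-sample t statistic computed from stagewise binomial counts. A
challenger is promoted only when the test rejects *and* its observed rate
is lower. Sample size per segment detects 10% vs 9.5% with 80% power at
two-sided α = 5% (55,252 per group fixed; 5 × 55,252 = 276,260 for the
whole platform).

**Design selection.** Candidate monitoring strategies are ranked by the
loss

L1 = w₁·ESS_null/SS_fixed + w₂·ESS_alt/SS_fixed + w₃·MSS/SS_fixed,  w₁+w₂+w₃ = 1,

trading expected sample size under the null and the alternative against
the maximum commitment.

## Worked example

Print a calibrated two-look O'Brien–Fleming design that stops for either
a difference or futility:

```
$ seqab design --design obf-both --looks 2
# design=obf-both drift=2.892153 inflation=1.065700
stage,fraction,efficacy_bound,futility_bound,p_stop_efficacy,p_stop_futility,p_continue
1,0.5,2.771807648699362,0.5986205861709243,0.2336914147457044,0.06992632672050636,
2,1.0,1.9793113426785196,,0.5663085852532748,0.0,0.13007367328051445
```

The interim (t\* = 0.5) rejects at |t| ≥ 2.772 and declares futility at
|t| < 0.599; preserving 80% power costs a 6.6% larger maximum sample
size. The probability columns are evaluated at the calibrated drift:
23.4% of truly-effective comparisons stop early for the difference, 7.0%
are (wrongly) stopped for futility, and 56.6% reject at the final look —
0.234 + 0.566 = 0.800, the design power.

Simulate 200 platform replicates where only variant A (segment 1) is
effective, under four-look OBF monitoring:

```
$ seqab run --scenario 1.1 --design obf-both --looks 4 --nsims 200 --seed 42
1.1,obf-both,4,winner_prop_A,0.825        # platform power for A
1.1,obf-both,4,ess_mean,228534.495        # vs 276,260 fixed
...
```

A wins the platform 82.5% of the time and monitoring saves ~48,000
enrollments per group on average. `seqab select --w 0.9 0.05 0.05` ranks
candidate designs by L1 (here the Pocock futility-only design wins), and
`seqab samplesize` prints fixed/inflated per-group sizes.

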