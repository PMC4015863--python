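# Methods

## Scope and model

`trialsig` evaluates the result of a single two-arm randomised superiority
trial from published summary statistics. The unit of analysis is an
intervention-effect estimate θ̂ with a standard error SE on its *analysis
scale*: the natural logarithm for odds ratios, risk ratios and hazard
ratios, the identity scale for mean differences. All inference is Wald /
Gaussian: θ̂ ~ N(θ, SE²). Published hazard and risk ratios are
log-transformed and then treated exactly like log odds ratios downstream;
the original measure is kept for provenance. This matches how such
summaries are combined in meta-analysis and keeps every step closed-form,
but it inherits the usual caveats of the normal approximation at small
sample sizes (see Limitations).

### Effect algebra (step 1)

Conversions implemented: SE from a symmetric CI,
SE = (g(u) − g(l)) / (2 z_{(1+level)/2}); two-sided Wald P = 2(1 − Φ(|θ̂|/SE));
SE from P via the inverse survival function (numerically stable for very
small P); and the closed-form 2×2-table estimators
OR = ad/bc, SE(log OR) = √(1/a + 1/b + 1/c + 1/d), plus risks, risk
difference and risk ratio. A zero cell triggers the Haldane–Anscombe
correction (0.5 added to all four cells, flagged in the output). When a
result supplies several uncertainty sources, precedence is explicit SE,
then CI, then P; CI- and P-derived SEs are cross-checked and a warning is
raised when they disagree by more than 10% relative (published inputs are
rounded, so modest disagreement is expected), with the source recorded.

### The Bayes factor (step 2)

BF = exp(−θ̂²/2SE²) / exp(−(θ̂ − θ_A)²/2SE²), equivalently
log BF = (θ_A² − 2 θ̂ θ_A) / 2SE² — a pure likelihood ratio between two
point hypotheses, with no prior on θ and no integration. θ_A is the effect
hypothesised in the trial's sample-size calculation, converted to the
analysis scale; a risk-ratio assumption is first converted to the odds
ratio implied at the design's control-group risk. Consequences used as
test oracles: log BF is exactly linear in θ̂ with slope −θ_A/SE²; BF = 1
exactly at θ̂ = θ_A/2; BF(θ̂)·BF(θ_A − θ̂) = 1; BF is invariant to common
rescaling of (θ̂, θ_A, SE). Direction is preserved — an effect opposite in
sign to θ_A yields BF ≫ 1 — and results are classified against a
configurable threshold (default 0.1, with 1/0.1 bounding the
"supports-null" band).

The *sceptical* alternative halves the hypothesised effect on the ratio
scale, (1 + r)/2 (a geometric, log-scale midpoint is available behind a
flag); a risk-ratio alternative is halved as an RR and re-converted to an
OR through the control risk, mirroring how the design alternative itself
is formed. It is reported whenever the design effect is not flagged as
based on a systematic review.

Operating characteristic worth knowing: with the standardised alternative
a = θ_A/SE, the probability of BF < 1/k under θ = θ_A is
Φ(|a|/2 − ln k/|a|). At a design with 80% power (|a| ≈ 2.80) this is ≈ 0.72
for k = 10 — reaching BF < 0.1 is a *stricter* event than P < α, so its
frequency sits below the design power even when the hypothesised effect is
true. The simulation tests assert agreement with this closed form rather
than with the design power.

### Design calculations (step 3 inputs)

Unpooled normal-approximation sample sizes without continuity correction:
n per group = (z_{1−α/2} + z_{pow})² (p₀q₀ + p₁q₁) / (p₁ − p₀)² for two
proportions (with the standard allocation-ratio generalisation) and
2 (z_{1−α/2} + z_{pow})² σ²/δ² for a mean difference, each rounded up.
These are the simplest standard forms and reproduce the round planned
sizes of typical protocols. The matching closed-form power function
inverts them exactly and counts both rejection tails. The information
fraction is n randomised / n planned, clamped to 1 with a logged warning
when a trial over-recruits. Secondary outcomes with computed power below
80% at the planned size are classified exploratory (the 80% cutoff is
inclusive on the confirmatory side).

### Group-sequential adjustment (step 3)

Two O'Brien–Fleming-type constructions, two-sided and symmetric:

- *Classic*: constant boundary on the score scale, z_k = C √(t_K/t_k),
  with C calibrated so the total crossing probability is α (for K = 2
  equally spaced looks at α = 0.05 this gives z = 2.797, 1.977).
- *Spending*: α*(t) = 2(1 − Φ(z_{1−α/2}/√t)), the O'Brien–Fleming-like
  spending function applied directly to the two-sided α, which equals α at
  t = 1 and spends almost nothing early (α*(0.5) ≈ 0.0056). A symmetric
  per-side variant (spending α/2 on each side, giving ≈ 0.0031 at t = 0.5
  two-sided) exists in the literature; the direct form was chosen because
  it tracks the classic boundaries more closely. Either way, stopping at
  half information demands a threshold an order of magnitude below 5%.

Crossing probabilities use the standard recursion for the sub-density of
the score statistic over successive continuation regions
(corr(Z_i, Z_j) = √(t_i/t_j)), with 241-node Gauss–Legendre quadrature per
region and Brent root-finding for boundary values (xtol 1e−12; single-look
results match Φ to better than 1e−8; cumulative spent alpha closes to α
within 1e−6). The classic and spending boundaries *approximate* each other
at equal spacing but differ by up to ≈ 0.2 on the z scale at the first
look; the suite asserts closeness at 0.25, not equality. Against a 10⁶-
replicate Monte-Carlo oracle of the joint statistic the computed
boundaries reproduce α within 3 Monte-Carlo SEs.

The step-3 rule: full information and no interim looks → the design α
unchanged; otherwise the looks are the performed interim fractions plus
the achieved fraction, and the required threshold is the final look's
nominal two-sided P. The accompanying interval is widened
repeated-confidence-interval style to level 1 − threshold, so interval and
threshold always agree; this specific widening convention is this
package's choice and is flagged in the report.

### Multiplicity (step 4)

Bonferroni and Hommel adjusted P-values are delegated to
`statsmodels.stats.multitest`; fixed-sequence and weighted fallback are
implemented directly (testing in pre-specified order at full α stopping at
the first failure; and at w_i α plus alpha carried from previously
rejected hypotheses, never stopping, respectively). An exhaustive
closed-testing oracle (all 2^m − 1 intersections, Simes or Bonferroni
local tests, m ≤ 12) provides the independent cross-check: Hommel equals
closed testing with Simes; the Bonferroni-local variant reproduces Holm.
Exploratory comparisons are excluded from the family by default and
flagged for conservative interpretation. Local alphas (and hence adjusted
CIs) are reported where they exist — Bonferroni, fixed sequence, fallback;
for Hommel the report states that no standard simultaneous CI is produced.
When several non-exploratory outcomes exist and no procedure was
pre-specified the report issues a warning (Bonferroni being too
conservative for correlated outcomes is precisely why a procedure should
be chosen in advance); with no declared primary outcome step 4 fails
outright.

Ordering of steps 3 and 4 is hierarchical, not multiplicative: the
sequential adjustment applies to the primary outcome's threshold, the
family adjustment across outcomes; the report documents this ordering.

### Clinical significance (step 5)

Gated strictly: steps 1–4 all passed *and* BF < 0.1. NNT/NNH =
⌈1/|risk difference|⌉ (ceiling: conservative, and consistent with printing
13 for 1/0.08 = 12.5), typed NNT or NNH according to the pre-declared
direction of benefit. The MCID comparison is inclusive at the point
estimate and separately reports whether the whole CI is at least as
extreme as the MCID. The benefit–harm balance has no quantitative model
and is emitted as a narrative flag. When the gate is closed but arm risks
are available, the NNT/NNH is still reported descriptively (as one does
when describing an observed harm).

## The orchestrator and the worked examples

A trial document (JSON canonical, YAML accepted) validates against a
strict schema (unknown fields rejected with their paths, all errors
enumerated). Verdicts per step are pass / fail / warning / not_assessed;
reports render as schema-stable JSON (byte-identical for identical inputs
— no timestamps) or as a five-point markdown mirror. Three packaged
example documents exercise the three canonical patterns: a trial with no
declared primary outcome and BF ≫ 1 (steps 2 and 4 fail, step 5 not
assessed); a trial passing all five steps with BF ≈ 0.01; and a trial with
anticipated benefit but observed harm (BF ≈ 3.6 × 10⁴ for the null,
NNH 13 descriptive). For the first example the published Bayes factors are
not exactly reproducible from the published rounded inputs (they imply an
unprinted SE ≈ 0.039); the package computes BF ≈ 79 and ≈ 1.6 × 10¹⁰ from
the printed CI, and only order-of-magnitude claims are asserted. For the
second, the document encodes the derived odds-ratio form (OR 0.89,
P 0.0035) whose implied SE is 0.0399; encoding the raw risk-ratio CI
instead gives BF ≈ 0.035 — same verdict, different print — because the
published RR→OR standard-error conversion chain is not fully specified.
The third example's arm sizes (396, 402) are reconstructed from the
published event counts and percentages (202/51%, 173/43%), reproducing the
published SE of 0.142; note the published CI for the same result implies
SE ≈ 0.076 — both routes are available, the count route is used.

## The simulator

Synthetic trials are binomial at the count level (no normal approximation
in the data generation), with accumulating-data paths for interim-look
studies and an exact vectorised Brownian oracle for boundary crossing.
Defaults used in the calibration tests: control-group risks 0.2–0.5, risk
ratios 0.8–1.0, 385–10,000 participants per arm, 3,000–10,000 replicates
(10⁶ for the boundary oracle, where each replicate is two normal draws) —
sizes at which the Monte-Carlo standard error is small enough for 3-SE
bounds to be informative while the whole suite stays fast. Every
stochastic assertion is a one-sided bound with a 3-SE buffer, never an
equality. Seeding: `default_rng([seed, k])` per replicate k, so any
replicate is reproducible in isolation.

What the simulator does *not* emulate — and what passing tests therefore
do not establish about real trials: survival outcomes and censoring,
covariates and adjusted analyses, missing data, non-compliance,
correlated outcome families (the FWER studies use independent statistics;
strong control holds a fortiori for the procedures under positive
dependence, but this is not exercised), and between-look drift in event
rates.

## Known limitations

- The Bayes factor is the simplified point-vs-point likelihood ratio; it
  is sensitive to the quality of the design alternative and is not a
  posterior probability. Full Bayesian analysis, priors over θ, and
  uniformly-most-powerful Bayesian tests are out of scope by design.
- Wald intervals and P-values throughout; no exact or profile-likelihood
  methods. At very small samples or extreme risks the normal
  approximation, and hence every downstream step, degrades.
- Sequential machinery covers symmetric two-sided efficacy boundaries
  only: no futility bounds, no Pocock/Haybittle–Peto, no stage-wise
  adjusted point estimates or median-unbiased estimators.
- The stability of a low Bayes factor across interim looks is exposed (BF
  can be recomputed at any fraction) but no stability correction is
  applied.
- Adjusted sample-size re-estimation (adaptive designs) and
  assurance-based sizing are not implemented; multiplicity procedures
  exploiting the correlation structure of the outcomes are not
  implemented.
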