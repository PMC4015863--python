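# trialsig

Five-step assessment of statistical and clinical significance for
randomised clinical superiority trials.

A significant P-value alone is weak evidence for an intervention effect: it
says nothing about how compatible the data are with the effect the trial
was actually powered to detect, it may be an artefact of early stopping or
of testing many outcomes, and statistical significance is not clinical
significance. `trialsig` implements a structured five-step evaluation of a
single two-arm superiority trial result, for trialists, systematic
reviewers and readers of trial reports:

1. **Report the confidence interval and the exact P-value** for every
   pre-specified outcome, with full conversion algebra between point
   estimate, CI, SE and P on the analysis scale (log OR/RR/HR, identity
   for mean differences), including estimation from a 2×2 table.
2. **Bayes factor against the design alternative.** For observed effect
   θ̂ with standard error SE and the effect θ_A hypothesised in the
   sample-size calculation (both on the log-ratio or mean-difference
   scale):

   BF = exp(−θ̂² / 2SE²) / exp(−(θ̂ − θ_A)² / 2SE²)

   the likelihood ratio of the point null to the point alternative.
   BF < 0.1 (ten-fold support for the alternative) is the conventional
   threshold; BF = 1 exactly when θ̂ = θ_A/2. When the design alternative
   is not based on a systematic review, an additional *sceptical* BF is
   computed with the ratio half way between 1.0 and the design ratio.
3. **Sequential adjustment.** If the planned sample size was not reached
   or interim analyses were performed, the significance threshold and the
   confidence level are adjusted with O'Brien–Fleming-type boundaries
   (classic equally-spaced form and a Lan–DeMets-type alpha-spending
   function for arbitrary stopping fractions).
4. **Multiplicity adjustment** across outcome comparisons with strong
   familywise-error control: Bonferroni, Hommel (closed testing/Simes),
   fixed-sequence and weighted fallback procedures.
5. **Clinical significance**, assessed only when steps 1–4 all passed and
   BF < 0.1: risk difference, number-needed-to-treat/harm, and comparison
   against the minimal relevant clinical difference (MCID).

A simulation module generates synthetic two-arm binary trials and
Monte-Carlo oracles for calibrating type-I error, power, familywise error
and Bayes-factor operating characteristics; no external data are needed
anywhere.

## Worked example

The repository ships three fully specified example trials
(`src/trialsig/examples/example{1,2,3}.json`). Example 2 is a large trauma
trial of tranexamic acid: all-cause mortality OR 0.89 (P = 0.0035),
design alternative RR 0.90 at 20% control-group mortality (≡ OR 0.88,
log OR −0.13), 20,211 of 20,000 planned participants randomised:

```sh
trialsig assess --spec src/trialsig/examples/example2.json --format markdown
```

prints, step by step (abridged):

```
## Step 1: Confidence intervals and exact P-values
Verdict: **pass**
- all_cause_mortality: OR scale, log effect -0.12 (SE 0.040), CI 0.823 to 0.962, P = 0.0035

## Step 2: Bayes factor for the primary outcome
Verdict: **pass**
- all_cause_mortality vs sample_size_calculation: Bayes factor = 0.01 (supports_alternative)
- all_cause_mortality vs sceptical: Bayes factor = 0.03 (supports_alternative)

## Step 3: Adjustment for early stopping / interim analyses
Verdict: **pass**
- information fraction 1.000, required threshold 0.05

## Step 4: Adjustment for multiplicity
Verdict: **pass**

## Step 5: Clinical significance
Verdict: **pass**
```

The Bayes factor of 0.01 means the observed mortality reduction is about a
hundred times more likely under the hypothesised 10% relative risk
reduction than under no effect — so the trial supports the effect it was
designed to find, and clinical significance may be assessed. Example 3 (a
starch resuscitation fluid, anticipated benefit but observed harm) shows
the opposite pattern: BF ≈ 3.6 × 10⁴ in favour of the null, step 2 fails,
and the report carries the number-needed-to-harm of 13 descriptively.

The pieces are available individually, as a library
(`trialsig.bayes_factor`, `trialsig.boundaries`,
`trialsig.sample_size_two_proportions`, …) and as CLI subcommands:

```
$ trialsig bf --theta-obs -0.12 --se 0.04 --theta-alt -0.11
bf=0.011461633942261852 log_bf=-4.46875 classification=supports_alternative
$ trialsig boundaries --alpha 0.05 --fractions 0.5,1.0
fraction,z_boundary,nominal_p_two_sided,cumulative_alpha_spent
0.5,2.771808,0.0055746,0.0055746
1,1.979311,0.047781,0.05
$ trialsig samplesize --p0 0.5 --p1 0.4
n_per_group=385 n_total=770
```

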