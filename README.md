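# eoscompare

Matched comparison of two management strategies for neonates at risk of
early-onset sepsis (EOS): the Bayesian **neonatal sepsis risk calculator
(NSC)** and an updated **serial clinical observation (SCO)** protocol.

The package is for neonatologists, antibiotic-stewardship teams and
methodologists who want to study how the two strategies would decide on the
same infants — which babies get a "rule out sepsis" laboratory workup, which
get empiric antibiotics — and how large the paired difference between the
strategies is. Because per-infant cohorts of this kind are not publicly
deposited, a seeded synthetic cohort generator reproduces the structure of a
single-centre cohort of ~3,445 live births at ≥ 34 weeks' gestation
(risk-factor prevalences, 7.66% symptomatic rate with a 68/19/13% onset
split at birth / 1–6 h / > 6 h, and minor/major symptom trajectories), so
the whole pipeline runs end to end with no external data.

## The two decision engines

**NSC.** Every infant carries a prior probability of EOS per 1,000 live
births (default: the local incidence, 0.6/1,000; a per-record override or
configurable maternal odds multipliers stand in for the unpublished
regression prior). The infant's presentation over the first 4 h of life is
classified as *well appearing*, *equivocal* or *clinical illness* from
temporal criteria (persistent abnormality > 4 h; ≥ 2 abnormalities each
> 2 h; need for nCPAP/HFNC/ventilation outside the delivery room;
supplemental O₂ > 2 h; vasoactive drugs; seizures or 5-min Apgar < 5).
The posterior follows a likelihood-ratio update on the odds scale,

```
posterior odds = prior odds × LR,   LR ∈ {0.41, 5.0, 21.2},
```

is stratified at 0.65 and 1.54 per 1,000, and mapped to one of five
management recommendations with decision thresholds at 1 and 3 per 1,000
(routine vitals → enhanced vitals → culture + vitals → strongly consider
antibiotics → empiric antibiotics).

**SCO.** Structured examinations at ages 1, 3, 6, 12, 18, 24, 36 and 48 h
grade each assessment *none* / *minor* / *major* (e.g. tachypnea > 60/min
without support need is minor; fever ≥ 38 °C, poor perfusion, or distress
requiring respiratory support are major). Minor symptoms trigger 2-h
re-evaluations but no testing; a major symptom, worsening minor symptoms,
or minor symptoms persisting 12–24 h trigger laboratory evaluation, with
the antibiotic decision modelled as an explicit policy (default: treat only
when a major finding is present).

**Comparison.** Since both strategies decide on the same infants, decisions
form a paired 2×2 table; only the discordant cells *b* (SCO no / NSC yes)
and *c* (SCO yes / NSC no) inform the difference. The package computes the
exact-binomial McNemar test (χ² variants optional), the paired marginal
difference (b − c)/n with Wald or Newcombe square-and-add 95% CIs, and
stratified rate summaries (late preterm, term, maternal fever ≥ 37.5 °C).

## Worked example

```python
from eoscompare import PairedTable, mcnemar_test, paired_difference

# published whole-cohort antibiotic decisions (SCO rows x NSC columns)
t = PairedTable(3254, 126, 5, 60)
d, m = paired_difference(t), mcnemar_test(t)
print(f"SCO {t.sco_rate_pct():.1f}%  NSC {t.nsc_rate_pct():.1f}%  "
      f"diff {d.diff_pct:.2f}% [{d.ci_low_pct:.2f}, {d.ci_high_pct:.2f}]  "
      f"p = {m.p_value:.3g}")
```

prints

```
SCO 1.9%  NSC 5.4%  diff 3.51% [2.87, 4.15]  p = 2.28e-31
```

i.e. serial observation treated 1.9% of the cohort while the calculator
would have recommended antibiotics for 5.4% — a paired difference of 3.51
percentage points, decisively non-zero by the exact McNemar test.

The same analysis over a synthetic cohort, end to end:

```python
from eoscompare import CohortParams, StrategyComparison, generate_cohort

records = generate_cohort(CohortParams(n=20_000, seed=1))
results = StrategyComparison(records).fit()
print(results.summary())
```

which begins

```
Antibiotic use -- stratum: all (n = 20000)
                  NSC no   NSC yes       total (%)
        SCO no     18767       830     19597 ( 98.0)
       SCO yes       129       274       403 (  2.0)
     total (%)     18896      1104     20000 (100.0)
  NSC marginal 5.5%  vs  SCO marginal 2.0%
  difference (NSC - SCO) 3.50%  95% CI [3.21, 3.80]  (wald_paired); McNemar exact_binomial p = 5.324e-126
```

— the calculator recommends antibiotics to roughly three times as many
infants as serial observation treats, and the discordance sits almost
entirely in the SCO-no/NSC-yes cell, the direction reported for the real
cohort.

The same stages are available from a shell:

```bash
eoscompare simulate --n 20000 --seed 1 --out cohort.csv
eoscompare compare --cohort cohort.csv --stratum late_preterm
eoscompare run --config pipeline.yaml --seed 1 --out run/
```

`run` writes a full bundle: cohort CSVs, per-strategy decision CSVs, paired
tables TSV, the text report, and a `manifest.json` with the seed, config
hash and every decision threshold. Identical config + seed give
byte-identical bundles.

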