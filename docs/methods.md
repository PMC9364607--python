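# Methods

## Problem setting

Neonates at risk of early-onset sepsis (EOS) can be managed by two broad
strategies. A *risk-calculator* approach (NSC) converts maternal risk
factors and the infant's early clinical presentation into a posterior
probability of EOS and recommends testing/antibiotics above probability
thresholds. A *serial clinical observation* approach (SCO) withholds tests
and antibiotics while symptoms are absent or mild and non-progressive, and
escalates on major or worsening findings. Because both strategies can be
evaluated on the same infants, the natural comparison is matched: a paired
2×2 table per decision (antibiotics; "rule out sepsis" evaluation), McNemar's
test on the discordant cells, and the paired difference of marginal rates.

This package implements both engines as deterministic, fully configurable
rule systems, a calibrated synthetic cohort generator, and the paired
statistics, organised as a model/results pair (`StrategyComparison.fit()` →
`StrategyComparisonResults`).

## NSC engine

*Prior.* Risks are handled per 1,000 live births. The default prior is the
local EOS incidence (0.6/1,000) for every infant. The original published
regression that maps maternal covariates (gestational age, highest
intrapartum temperature, membrane-rupture duration, GBS status, IAP) to a
prior is proprietary in the sense that its coefficients are not printed in
the sources available here; rather than invent numbers, `compute_prior` is
a pluggable interface: a per-record override column, or a configured map
of maternal covariates to odds multipliers applied multiplicatively on the
odds scale. With neither configured, the prior is the incidence.

*Presentation.* Classification uses observations inside a 4-h assessment
window. An abnormality (HR > 160, RR > 60, temperature > 38.0 °C or
< 36.4 °C — the Fahrenheit instability bounds canonicalised to Celsius —
or respiratory distress without supplemental O₂) runs from the observation
at which it is measured until the next observation at which that vital is
re-measured; if never re-measured it ends at the last charted observation,
since persistence beyond the chart cannot be confirmed. Durations of
intermittent abnormalities accumulate over the union of abnormal intervals,
so the classification is invariant to splitting an interval into contiguous
sub-intervals. Intervals must *start* inside the window but accrue their
full confirmed duration (an abnormality charted at 3 h and still present at
4.5 h counts 4.5 h even though 4.5 h lies outside the window). One
abnormality > 4 h, or two or more each > 2 h, give *equivocal*. *Clinical
illness* is any of: nCPAP/HFNC/mechanical ventilation outside the delivery
room (a record-level flag marks delivery-room-only support), vasoactive
drugs, seizures, 5-min Apgar < 5, or cumulative supplemental O₂ > 2 h.
Absent vitals are "not measured" and never abnormal; an empty timeline with
a normal birth context is *well appearing*.

*Update and decision.* The posterior is the odds-scale likelihood-ratio
update (LRs 0.41 / 5.0 / 21.2). Naive probability-scale multiplication is
available as a config switch; at risks of a few per 1,000 the two differ by
well under 3% relative, which the test suite asserts. Risk strata break at
0.65 and 1.54 per 1,000 (lower edge inclusive for each upper bin). The
decision table (thresholds 1 and 3 per 1,000) is: empiric antibiotics when
posterior > 3 or clinical illness; strongly consider antibiotics for any
other equivocal presentation; culture + vitals for well-appearing infants
with posterior in [1, 3]; enhanced vitals when posterior < 1 but prior > 1;
routine vitals otherwise. The printed source text gives the
strongly-consider band as "posterior < 3", which collides with the
culture band; resolving it as *equivocal with posterior ≤ 3* reproduces the
published split of 131 strongly-consider vs 55 empiric recommendations
without guessing beyond the text, and the whole table is overridable in
config. "Strongly consider" is counted as an antibiotic recommendation:
the published marginal of 186 antibiotic recommendations equals 131 + 55
only under that reading. The two antibiotic-implying recommendations carry
NICU-level monitoring; the decision time is the end of the assessment
window.

## SCO engine

Grading is a pure function of one observation: major findings are
respiratory distress requiring support (nCPAP/ventilation, or tachypnea
plus increased effort on any support), hypoxia (SpO₂ < 90% while
unsupported), capillary refill ≥ 3 s or shock, temperature ≥ 38 °C,
abnormal skin colour, worsening wellbeing, apnoea, lethargy, irritability,
seizures; minor findings are tachypnea > 60/min without support need,
tachycardia > 160 bpm, base excess ≤ −10 mmol/L, and temperature < 36 °C or
in (37.5, 38) °C. Note the deliberate asymmetry with the NSC: tachycardia
is minor here but an equivocal-qualifying abnormality there; the two
frameworks are kept independent, each following its own table literally
(≥ 38.0 °C for the SCO fever bound, strict > 38.0 °C for NSC temperature
instability).

Evaluation ("rule out sepsis") is triggered at the earliest of: a
major-grade observation; *worsening*, operationalised as a strictly larger
set of distinct minor findings than the previous minor assessment (the
narrower notion of intensification of a single finding, e.g. RR 62 → 90,
is not modelled — a documented limitation); or minor symptoms persisting
for 12 h (configurable up to 24 h), measured on the union of minor
intervals so the decision is subdivision-invariant. Asymptomatic infants
are never evaluated or treated, whatever their risk factors. The antibiotic
decision after evaluation is physician discretion in practice; it is
modelled as a policy enum — `major_only` (default, deterministic: treat iff
a major finding exists at or after evaluation), `always_on_eval`, or
`probabilistic(p)` with a seeded generator. Triage: NICU for
nCPAP/ventilation, vasoactive drugs or seizures; intermediate care for
supplemental O₂/HFNC and for asymptomatic infants below 35 weeks;
rooming-in otherwise. Scheduled checks run at 1, 3, 6, 12, 18, 24, 36,
48 h with 2-h re-evaluations inserted after minor assessments.

## Synthetic cohort generator

The generator emulates the observed cohort's *structure*, not EOS biology.
Record-level attributes are vectorised draws: late-preterm fraction
178/3,445; gestational age from two truncated normals matched to the
printed medians/IQRs (36.14 [35.29–36.57] on [34, 37); 39.71 [39.0–40.29]
on [37, 43] — only median and IQR are published, so the family is a
choice); vaginal delivery 77.24%; screening 95.17% with GBS positivity
21.84% among screened; bacteriuria 1.34%; prolonged rupture of membranes
with the printed GA-conditional rates (23.03% late preterm, 15.31% term);
IAP likewise (55.05% / 28.25%), adequate in 56.32% of exposed. Maternal
intrapartum temperature is a single right-skewed Gumbel distribution
calibrated by two-point quantile matching so that P(T ≥ 37.5 °C) = 110/3445
and P(T ≥ 38 °C) = 1.05% both emerge from one curve; its central location
(~36.1 °C median) is lower than typical intrapartum temperatures — the tail,
which is what the analyses stratify on, is what is calibrated.

Symptoms: 7.66% of infants are symptomatic, with onset split 68.18 /
18.56 / 13.26% between birth, 1–6 h and after 6 h. Each symptomatic infant
has a latent episode: log-normal duration with median 72 h and log-sd
ln(5)/(2·0.6745) ≈ 1.19 (so the quartile ratio matches the reported
24–120 h IQR; the printed IQR is asymmetric about its median and cannot be
matched exactly by a two-parameter family — the median is matched exactly),
a 25% probability of progressing to major grade (chosen so that, under the
`major_only` treatment policy, the treated fraction lands near the observed
64/264 treated-to-symptomatic ratio — a calibration of the generator, not
of the engines), a progression delay uniform on [0, 2] h, and a
manifestation (respiratory 70% — with support level MV 7% / nCPAP 38% /
HFNC 25% / O₂ 30% —, fever 15%, perfusion 15%; the source reports symptom
composition only graphically, so these weights are round numbers consistent
with respiratory symptoms being most common). Vitals at each charted time
(every 2 h over 0–48 h plus onset and transition times) are sampled inside
ranges that reproduce the intended grade exactly under the SCO grader
(inverse-grading consistency, asserted by tests). True-EOS infants
(incidence 0.6/1,000; settable to 0 to mirror the observed cohort, which
had no culture-proven case) are forced symptomatic with major trajectories
from birth so parameter-recovery tests have a detectable signal.

What the generator does *not* emulate: correlation between maternal risk
factors and infant symptoms (the NSC prior interface is where risk factors
would enter; with the default flat prior they do not drive decisions),
blood-culture results or contaminants, antibiotic durations, deaths, or
charting noise. Asymptomatic infants carry an empty timeline — charting
density for well babies is not reported, and "not measured" is equivalent
to "non-abnormal" for both engines. Consequently, passing tests show that
the engines and statistics behave correctly on structurally realistic
inputs, not that either strategy is clinically validated.

Determinism: all randomness descends from one seed;
record-level draws use `SeedSequence(seed, spawn_key=(0,))` and record *i*'s
timeline uses `SeedSequence(seed, spawn_key=(1, i))`, so cohorts are
byte-identical across runs and any single timeline can be regenerated.

## Statistics

McNemar's test defaults to the exact binomial form, p = min(1,
2·P(X ≤ min(b,c))), X ~ Binomial(b + c, ½), because discordant counts in
this application are as small as 0–5 where the χ² approximation is
unreliable; χ² with and without continuity correction are provided (the
continuity-corrected form tracks the exact p within ~10% at b + c ≥ 50; the
uncorrected form is systematically more liberal than the doubled exact
two-sided p). b + c = 0 yields p = 1. The paired difference is
(b − c)/n × 100 with a Wald interval diff ± 1.96·√(b + c − (b − c)²/n)/n, or
a Newcombe square-and-add interval built from the Wilson limits of the two
marginals (implemented without the pairing-correlation correction, hence
conservative; the published CIs for these data were produced by unstated
software and are slightly asymmetric, so no CI method is treated as an
exact reproduction target — point differences are). Report-layer rounding
supports both direct rounding of (b − c)/n and the difference of
one-decimal-rounded marginals, because published tables mix both
presentations (18.6 = 27.0 − 8.4 in the late-preterm antibiotic table,
versus 3.51 direct in the whole-cohort table).

## Problem sizes and numerical choices

The test suite uses cohorts of 300–600 records for pipeline tests, 10,000
records × 100 seeds for generator parameter recovery (each Bernoulli
marginal within 3 binomial SE, with up to 3/100 excursions allowed — the
3-SE coverage of a perfectly calibrated generator is 99.73%, so requiring
100/100 or 99/100 rejects a correct generator a few percent of the time,
while 97/100 has type-I error below 10⁻⁴ and still fails decisively on
miscalibration), and one 100,000-record end-to-end run for the qualitative
direction of the comparison. The acceptance script runs the 100-record
tables instantly and one seeded 100,000-record synthetic run. Brute-force
enumeration of all 2^(b+c) discordant assignments validates the exact
McNemar p for b + c ≤ 12. Boundary conventions follow the clinical tables:
strict inequalities where printed strict (> 160, > 60, > 4 h, > 2 h),
inclusive where printed inclusive (≥ 38 °C, ≥ 3 s, base excess ≤ −10).
Symptomatic-rate recovery is checked against the generator's true marginal
p + (1 − p)·incidence/1000, since true-EOS infants are forced symptomatic.

## Known limitations

- The maternal-risk prior defaults to a flat incidence; with it, NSC
  decisions are driven entirely by presentation. Configured odds
  multipliers restore risk-factor dependence but are user-supplied.
- "Worsening" of minor symptoms is count-based only.
- Symptom-type composition and several trajectory hazards are round-number
  choices, constrained only by onset timing, duration and the
  treated-to-symptomatic ratio.
- The Newcombe interval omits the pairing-correlation correction.
- The SCO schedule module reports assessment times; decisions are computed
  from the charted timeline directly, so sparse charts defer escalation to
  the next charted observation.
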