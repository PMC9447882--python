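# Methods

## Scope

The package answers one methodological question: given a tabular prognostic
model for out-of-hospital cardiac arrest trained on Utstein-style EMS
activity records, what does the model predict if one or two prehospital
time factors had been different — and do two simultaneous modifications
interact?  Everything else (cohort synthesis, encoding, splitting,
training, metrics) exists to make that question answerable and testable.

## Synthetic cohort

### What it emulates

A single-region registry profile: ~1,000 arrests/year over nine years
(11,504 recorded, ~72% surviving the adult/cardiogenic inclusion filter),
4% CPC 1/2 prevalence among included cases, 12% defibrillated, 36% given
adrenaline, 89% advanced airway, 40% witnessed, 52% bystander CPR, rhythm
mix dominated by asystole (~65%) with ~9% VF.  Time variables are
log-normal with (mu, sigma) moment-fitted to published median/IQR profiles:
call-to-contact 8 [7, 10] min, contact-to-hospital 28 [22, 36] min,
contact-to-shock 4 [3, 12] min, contact-to-adrenaline 16 [12, 21] min.
Times are rounded to whole minutes, matching how such registries record
them.

### Outcome model

`P(CPC 1/2) = logistic(eta)` with

    eta = c + b_age*age + b_t*transport + b_defib*defib_delay
        + b_drug*drug_delay + b_shock*shockable + b_wit*witnessed
        + b_cpr*cpr
        + g_td*(transport - 28)(defib_delay - 4)     [if defibrillated]
        + g_tg*(transport - 28)(drug_delay - 16)     [if drug given]

Defaults (log-odds units): age −0.08/y, transport −0.06/min, defib delay
−0.20/min, drug delay −0.10/min, shockable +4.0, witnessed +1.6, bystander
CPR +1.0, g_td −0.008, g_tg −0.004 /min².  The magnitudes are stylized: they
were chosen so that the *Bayes-optimal* discrimination of the synthetic
world (the generative score plus the ROSC likelihood ratio, see below)
reaches AUROC ≈ 0.94 at n = 20,000 — the discriminability a real
single-region registry model of this kind reports.  Weaker coefficients
produce a world in which no classifier, and therefore no class weighting,
can reach an 80% minority-sensitivity operating point at threshold 0.5.
Interaction terms are centered at the marginal time medians so that a
nonzero interaction modifies effects without collapsing the base rates;
centering does not change the interaction's difference-in-differences
signature (below).

Prehospital ROSC is drawn *conditionally on the outcome* (60% given
CPC 1/2, 8% otherwise): it is a consequence, not a cause, of physiology,
and it gives the network the kind of strongly prognostic downstream marker
real registries contain.

The intercept is calibrated by bisection so the included-subgroup
prevalence matches the 4% target regardless of the coefficient values
(80 iterations on [−40, 15]; monotone, so convergence is guaranteed if the
target is reachable).

### What it does not emulate

No temporal or geographic structure, no dispatch-protocol changes across
guideline eras (the era flag is an independent coin), no correlation
between missingness and severity (missingness is MCAR per categorical
field, default 2%), no secondary-rhythm dynamics beyond a constant
probability of defibrillation in non-shockable-initial cases.  A green
test therefore establishes that the *pipeline machinery* recovers known
structure — not that any clinical conclusion transfers to a real registry.

## Preprocessing

* Inclusion: age ≥ 18 and cardiogenic cause; the boundary case (exactly 18)
  is included.  The filter reports a tally per exclusion reason.
* Categoricals: one-hot with an explicit `missing` level; an unseen level at
  transform time maps to `missing` with a logged warning.
* Always-observed continuous items (age, defibrillation count, adrenaline
  count): z-scored with *population* mean/sd computed from the records
  passed to `fit_encode` — in the pipeline, the non-test records — and
  reused verbatim by `transform` (no re-fitting, no leakage).  Zero
  variance falls back to sd = 1 with a warning.
* Adjustable response/transport times: raw, unstandardized minutes, so
  counterfactual deltas act in natural units.  (A standardized alternative
  would only rescale the same information; raw was chosen for
  interpretability of the sweep axes.)
* Interventions (defibrillation, adrenaline): one-hot over
  {not_performed, minute 0, 1, …, cap} with caps 38 and 48 min; values
  above the cap share the top bin.  The default schema totals exactly 145
  columns (50 categorical + 3 standardized + 2 raw channels + 40 + 50).
  A flag-plus-raw-time encoder (`intervention_flag_time`, width 2, time 0
  when not performed) is available for custom schemas.

## Split

Positives and negatives are each distributed as evenly as possible over
k = 5 seeded groups (per-class counts differ by ≤ 1).  Remainders of both
classes are handed out along one shared seeded group order, so spare
positives land in groups that also receive spare negatives; at the
reference scale (8,274 records, 286 positives) this yields group sizes
{1654, 1654, 1655, 1655, 1656} and positives {57, 57, 57, 57, 58}.  The
last group in the seeded order never receives a remainder and is the
held-out test group (always a smallest group).  The four non-test groups
give four train/validation fold pairs.

## Network and training

Three hidden blocks (affine → batch norm → activation → inverted dropout)
plus a final affine and sigmoid output.  Defaults: widths 180/80/40 on 145
inputs (~44k multiply-accumulates per forward sample), sigmoid activations
(a rectifier is a config switch), dropout 0.2, batch 100, 50 epochs, Adam
lr 1e-3 (β 0.9/0.999).  Batch-norm uses batch statistics in training and
exponential running statistics (momentum 0.9) in inference; inference
disables dropout, so prediction is deterministic and invariant to batch
partitioning.  All gradients are hand-derived and tested against central
finite differences (relative error < 1e-4 on every parameter class,
batch norm included).  Initialization and shuffling are seeded; each CV
fold derives its own seed from the master seed.  Model selection is the
final epoch — no early stopping.

### Class-weight calibration

The loss weights minority (CPC 1/2) terms by w₊ (majority weight fixed
at 1).  Calibration searches the ascending geometric grid
{1, 2, 4, …, 64}, training one model per candidate, and stops at the first
weight whose validation minority sensitivity ≥ target − tolerance
(default 0.80 − 0.02); the bracket to the last failing weight is then
refined by geometric bisection to a 5% relative weight tolerance.  Because
minority sensitivity increases (stochastically) with w₊ while majority
sensitivity decreases, the smallest qualifying weight maximizes majority
sensitivity among qualifying weights.  If nothing in range qualifies, the
best-achieving weight is returned with a failure flag.  Every evaluation
is recorded in a trace.  Folds are calibrated independently.

### Metrics

Per-class sensitivities at threshold 0.5 (the count-controlling operating
point class weighting is calibrated for), their unweighted mean, and AUROC
as the Mann–Whitney rank statistic with midrank tie handling.  The 95% CI
uses DeLong's structural-component variance (deterministic Wald interval,
clipped to [0, 1]).

## Counterfactual sweeps

Adjustments operate on *raw records* and re-encode through the stored
transform — never on the encoded matrix — so adjusted data is guaranteed
to be encoded exactly as training data was.  Eligibility masks: transport
and response times and age apply to everyone; defibrillation time only to
cases with shockable initial rhythm that were defibrillated; drug time
only to cases given adrenaline whose arrest was not witnessed by EMS
personnel.  Adjusted times are floored at 0 (clamping, not dropping;
records never leave the cohort).  Ineligible records pass through
bit-identically and dilute the averaged change — the baseline is defined
over the full test set.

The summary is the grand mean of the four models' predicted probabilities
over all test records (`mean_probability`); a thresholded
predicted-positive count is available (`predicted_positive_count`) since
"average predicted CPC 1/2" admits both readings.  Cells report
100 × (adjusted − baseline)/baseline — *relative* percent change; an
absolute (percentage-point) reading is a trivial transformation the caller
can apply, the relative form is what the grid stores.  The (0, 0) cell is
set to exactly 0 rather than recomputed, making the baseline identity
structural.  Intervention counts are held fixed when their times are
adjusted.

Default axes: transport −10…+10 min, intervention times −5…+5 min (config
values; the published figures do not state their ranges).  Grids record
the number of eligible records per factor and, when training records are
supplied, the fraction of training values inside each delta's adjusted
range — cells outside the trained region are extrapolations and should be
read as direction-only.

### Interaction diagnostic

The percent-change grid cannot by itself attribute non-additivity to a
true interaction: two purely additive log-odds effects still combine
multiplicatively on the probability scale, so the grid's
difference-in-differences (DiD) is positive whenever the two main effects
share a sign, interaction or not — the ground-truth model reproduces this.
`interaction_logit_residual` therefore computes the mean per-record DiD of
the *log-odds* of the (model-averaged) prediction over jointly eligible
records.  Under the generative model this equals exactly
g · Δt_a · Δt_b — zero without interaction, sign and scale of the
interaction with it.  Model noise attenuates the magnitude heavily (a
trained ensemble recovers a few percent of the true value), so the
supported use is sign and qualitative size, not point estimation.

## Known limitations

* The network's recovered interaction residual is strongly attenuated and,
  at the default 50-epoch sigmoid configuration, often not resolvable at
  n = 8,000 with 4% prevalence; the rectifier activation with more epochs
  resolves the sign reliably (used by the recovery tests).  Real-data
  claims about interactions at this cohort scale warrant skepticism.
* DeLong's interval is asymptotic; with very few positives (< ~30) it is
  optimistic.
* Class-weighted probabilities are not calibrated probabilities; only
  relative changes and threshold counts are meaningful.
* The generator's effect sizes are stylized (chosen for realistic
  discriminability, not estimated from any registry).
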