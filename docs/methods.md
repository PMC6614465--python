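# Methods

## Data model and code taxonomy

A registry row is one outpatient visit: patient identifier, ISO-8601 date,
and up to two ICD-10 diagnosis codes, either of which may be absent. Codes
are full categories (`F20.5`), bare chapters (`F3` — registries genuinely
record chapter-level diagnoses), or chapter combinations (`F1-F3`) used to
render comorbid visits. The taxonomy gives three views of a code: its
chapter set (a combination expands to both chapters), its 3-character
category (`F20.5 → F20`; bare chapters map to themselves), and a rendered
table label. Rendering keeps the psychotic-spectrum categories
(F20–F25, F28, F29) at 3-character level and collapses everything else to
its chapter; the stability module adds F31, F34 and F60 to the detailed
set because those are the clinically salient alternatives after onset.
Schizophrenia means category F20 exactly: any `F20.x` qualifies, the bare
chapter `F2` and the neighbouring categories F21–F29 do not.

Legacy ICD-9 rows pass through a user-supplied two-column crosswalk,
validated at load time; unmapped codes pass through flagged rather than
erroring, so the caller decides whether to drop or inspect them. The
bundled default crosswalk is deliberately minimal (chapter-level mapping of
the common psychiatric ICD-9 ranges 290–319) and is not a substitute for a
complete mapping in production use.

## Cohort and descriptives

Inclusion requires one F20 visit (either diagnosis slot) and at least three
*visits* carrying at least one diagnosis; undiagnosed visits do not count.
Onset is the earliest F20 visit; dates tie-break by input order, which the
stable sort preserves. Three counting levels feed the frequency tables:

* *patient first visit* — each code of the first ever visit contributes its
  rendered label; denominator = patients.
* *per visit* (pre-onset) — each diagnosed pre-onset visit counts once. A
  two-code visit whose chapters differ counts under a chapter-pair
  combination row (`F3-F6`) rather than under both singles: combination
  rows sit alongside single rows in the published table style, and counting
  a comorbid visit twice would double-count against a per-visit
  denominator. Two codes in the same rendered label count once.
  Denominator = diagnosed pre-onset visits.
* *patient any* — the fraction of patients whose pre-onset codes, expanded
  with the comorbidity rule (a combination counts under both chapters, a
  category code counts under its category and its chapter), include the
  label.

Percentages are stored as exact integer count / denominator pairs and
rounded half-up to one decimal only when rendered, so recomputing a
percentage from its printed count and denominator is exact by construction.

## Stability curves

Months are fixed 30-day windows after the onset date: month *m* covers days
(30·(m−1), 30·m]; the onset day itself is month 0 and seeds the fill. Fixed
windows rather than calendar months keep the binning free of month-length
artefacts. Every diagnosed visit contributes all its rendered labels to its
month; a month with no diagnosed visit inherits the previous month's labels
(last observation carried forward). By default the fill continues to the
horizon even after the last observed visit — the substitution rule is
applied uniformly, with no censoring — and a
`censor_after_last_visit` option stops the fill at the last observed month
for the alternative reading. Each month's pooled labels across patients are
normalised to a distribution; with the default fill, every patient
contributes at least one label to every month, so the distributions always
sum to one.

Two summaries of diagnostic maintenance are reported, because they answer
different questions: the mean share of F20 across months 1–48 (a
visit-mass average) and the fraction of patients whose modal post-onset
label is F20 (a patient-level prospective-consistency reading).

## The CT-HMM

States are diagnosis labels; the hidden state evolves as a time-homogeneous
Markov jump process with off-diagonal intensities `q_ij` (per year) and
exit rates `q_i = Σ_j q_ij`. Assumptions: patients are exchangeable
realisations of one process; the process is stationary (intensities do not
depend on age or calendar time); the future depends only on the present
state; and — under the default *exact-times* semantics — the state changes
only at claim times. Observations are the first recorded code of each
visit, rendered to the state alphabet; a missing diagnosis is an uncertain
observation contributing a unit likelihood factor. Second codes are used by
the descriptive and stability modules but not by the CT-HMM, which emits
one diagnosis per claim.

Two interval kernels:

* *exact-times* (default): interval factor `q_ij·exp(−q_i·Δt)` on a state
  change, `exp(−q_i·Δt)` otherwise. These are sojourn densities, not
  probabilities — rows do not sum to one, and the likelihood of an
  uninformative sequence can exceed one. The payoff is a closed-form EM.
* *panel*: `expm(G·Δt)` with `G` the generator; proper transition
  probabilities allowing unobserved intermediate jumps. Provided for
  likelihood evaluation and cross-checks; EM under panel semantics (which
  needs end-point-conditioned expected sojourns) is out of scope and the
  E-step refuses it explicitly.

Inference is a scaled forward–backward pass, vectorised across all
sequences at once (sequences padded to a common length with identity
kernels and unit emissions, so padding cannot change any result). The
E-step accumulates expected jump counts `n_ij` (pair marginals summed over
intervals), expected sojourn `T_i` (each interval's full length attributed
to its start state, so `Σ_i T_i` equals total follow-up exactly), emission
counts over non-missing visits, and initial-state counts. The M-step is the
closed-form MLE. With identity emissions and fully observed paths one EM
iteration therefore reproduces `q̂_ij = jumps/sojourn` exactly, which the
tests exploit as an oracle.

Numerical choices: times in years (days/365.25); two same-day visits are
pushed apart by half a day so sojourn densities stay defined;
per-step scaling prevents underflow; a zero-probability sequence yields
−∞ log-likelihood with a warning and is excluded from the E-step (all
sequences zero-probability is an error suggesting emission smoothing); an
additive floor of 1e-8 on expected emission counts keeps EM away from
absorbing zeros, and an emission row never visited keeps its previous
values. Initialisation anchors state labels to diagnosis labels: emission
diagonal 0.8 with the remainder uniform, intensities 0.1 + U(0, 0.05) per
seeded RNG, uniform initial distribution; by default three seeded restarts
keep the best final log-likelihood, and an explicit start point disables
restarts. Convergence is declared when the relative log-likelihood
improvement drops below 1e-6 (at most 500 iterations).

Graph extraction keeps states observed in the sample (node weight =
observed diagnosis count), edges with `q_ij` at or above a threshold
(default 0.05/year — the threshold is a required analysis choice and is
echoed in the graph metadata), and then only nodes with a directed path to
the target (F20). Because no single convention fixes what "edge strength"
should mean, every edge carries both the intensity `q_ij` and the embedded
jump probability `q_ij / q_i`.

## Synthetic registry generator

The generator realises exactly the model the CT-HMM assumes, plus the two
nuisance processes a real registry adds. Competing exponential clocks drive
visits: the jump clock (rate `q_i`) moves the state and records a claim;
the repeat-visit clock (rate ρ, default 1/year) records a claim without a
state change. Repeat visits are what make consecutive same-state
observations — and hence the emission matrix — identifiable. Each claim's
diagnosis is missing with probability μ (default 0.1), otherwise drawn
from the emission row of the current state, with probability κ (default 0)
of a second code from the same row. Dates are a fixed origin (1990-01-01)
plus the event time rounded to days, so same-day duplicates occur and
exercise the half-day gap adjustment. Each patient has a counter-derived
RNG substream, making patient *k* reproducible independently of cohort
size.

The default truth is a three-state progression chain — F23 → F22 → F20
with `q_12 = 0.4`/year, `q_23 = 0.6`/year, emission diagonal 0.85, initial
distribution (0.5, 0.3, 0.2) over (F23, F22, F20) — over a 10-year horizon.
The rates put the typical sojourn in each transient state at 1.5–2.5 years,
the emission diagonal models realistic diagnostic noise while keeping
states identifiable, and the initial distribution ensures all transient
states are visited.

What the generator does *not* emulate: age or calendar-time effects on
intensities, care-pathway structure beyond the Markov chain (referral
patterns, episode clustering of visits), state-dependent missingness, and
ICD-9-era coding. Passing recovery tests therefore shows the estimator is
correct *under the model's own assumptions*, not that a real registry
satisfies them.

One small bias is accepted knowingly: the likelihood uses only inter-visit
intervals, ignoring the censored interval between each patient's last visit
and the end of follow-up. With the default rates the expected information
loss is well under 1% of total sojourn time, far inside the recovery
tolerance.

## Problem sizes

The test suite and the acceptance script use cohorts of 500 patients for
the end-to-end pipeline and 2,000 patients (≈ 30,000 visits) for parameter
recovery; the enumeration oracle checks every CT-HMM quantity on 2–3-state,
2–5-visit instances, where exhaustive path summation is exact. EM
monotonicity is checked across 100 random initialisations on a 12-patient
fixture. These sizes keep a full run in the low minutes on one CPU while
leaving every statistical check well-powered.

## Known limitations

* The exact-times semantics is an approximation whenever disorders truly
  change between visits; the panel kernel quantifies (via likelihood
  comparison) but does not correct it.
* One observation channel: the second diagnosis code is ignored by the
  CT-HMM.
* The EM objective is multimodal; restarts mitigate but cannot guarantee
  the global optimum.
* No covariates on intensities (stationarity is assumed, not tested) and
  no model selection over the state-space granularity.
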