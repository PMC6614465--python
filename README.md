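# dxtraj

Diagnostic-trajectory analysis around the onset of a schizophrenia (ICD-10
F20) diagnosis in longitudinal psychiatric-registry data.

Large case registries record, for every outpatient visit, the date and up to
two ICD-10 diagnosis codes. Two questions matter clinically: *which
diagnoses precede the first diagnosis of schizophrenia*, and *how stable is
that diagnosis once made*. `dxtraj` answers both for registry-format data:

* **Cohort selection** — patients with an F20 diagnosis in at least one
  visit and at least three diagnosed visits; the first F20 visit defines
  onset and splits each history into pre- and post-onset segments.
* **Descriptive tables** — frequencies of diagnoses at the first
  assessment, per-visit frequencies before onset (with chapter-pair
  comorbidity rows such as `F3-F6`), and patient-level rates with
  comorbidity expansion.
* **Stability curves** — post-onset visits binned into 30-day months over a
  48-month horizon, empty months filled by last observation carried forward,
  each month's pooled diagnoses normalised into a probability of maintaining
  F20 versus shifting to each alternative.
* **A continuous-time hidden Markov model (CT-HMM)** of transitions between
  diagnoses, fitted by EM, from which a directed graph of diagnoses
  converging into F20 is extracted.
* **A synthetic registry generator** that samples visit histories from a
  known CT-HMM, so every stage — including parameter recovery — is testable
  without access to any confidential registry.

## The model

The patient's underlying disorder is a continuous-time Markov jump process
on a set of diagnostic states. Its intensity matrix entry `q_ij` (events per
year, `i ≠ j`) measures the strength of the transition from disorder *i* to
disorder *j*; the exit rate `q_i = Σ_j q_ij` is high when the average time
from *i* to the next clinical event is short. At each visit the clinician
records a diagnosis `k` with emission probability `b_i(k)` given true state
*i*, or records nothing — a missing diagnosis enters the likelihood as an
uncertain observation with unit factor.

Under the working assumption that state changes coincide with claims
(*exact-times semantics*), the interval between consecutive visits
contributes `q_ij · exp(−q_i·Δt)` when the state changes and `exp(−q_i·Δt)`
when it does not, and EM has closed-form updates from expected jump counts
`n_ij`, sojourn times `T_i`, and emission counts: `q̂_ij = n_ij / T_i`,
`b̂_i(k) = m_ik / Σ_k m_ik`. A *panel* kernel `expm(G·Δt)` (state can jump
anywhere inside the interval) is provided for likelihood evaluation and
cross-checks.

## Worked example

```python
from dxtraj import GeneratorConfig, generate_trajectories, build_cohort, \
    prior_diagnosis_fraction
from dxtraj.stability import SHIFT_DETAIL, stability_curve, mean_share
from dxtraj.registry_model import CodeTaxonomy
from dxtraj.synthetic_data import recovery_experiment

# simulate 500 patients from a three-state truth: acute psychosis (F23)
# -> persistent delusional disorder (F22) -> schizophrenia (F20)
cfg = GeneratorConfig.default(n_patients=500, seed=1)
trajectories, manifest = generate_trajectories(cfg)
cohort = build_cohort(trajectories)
print(f"eligible patients: {len(cohort)} / {cfg.n_patients}")
print(f"prior non-F20 diagnosis: {100 * prior_diagnosis_fraction(cohort):.1f}%")

tax = CodeTaxonomy(detail=SHIFT_DETAIL)
curve = stability_curve(cohort, horizon=48, taxonomy=tax)
print(f"mean 48-month share of F20: {mean_share(curve, 'F20'):.1f}%")

report = recovery_experiment(n=2000, seed=1)
print(f"mean relative error of nonzero q_ij: {100 * report['mean_rel_q_error']:.1f}%")
```

prints

```
eligible patients: 496 / 500
prior non-F20 diagnosis: 74.4%
mean 48-month share of F20: 81.4%
mean relative error of nonzero q_ij: 0.7%
```

496 of 500 simulated patients meet the inclusion criteria (the rest never
reach F20 or have too few diagnosed visits); 74.4% carry another diagnosis
before onset; the schizophrenia label holds 81.4% of the month-by-month
diagnostic mass over the four years after onset; and refitting a
2,000-patient registry recovers the generating intensities to within 0.7%
on average.

The same pipeline runs from the shell:

```sh
dxtraj simulate --out sim/ --n-patients 500 --seed 1
dxtraj all --input sim/visits.csv --out run/
```

writing the cohort list, both frequency tables, the stability curve
(`stability.csv`), fitted parameters (`params.json`), the transition graph
(DOT, GraphML, edge CSV) and a run manifest.

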