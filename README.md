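# riskscreen

Patient-level simulation of **time-dependent risk-based screening**: how
many screening examinations can be saved — at the same population-level
detection benefit — by scheduling examinations where and *when* individual
risk predictions say they matter, instead of allocating them uninformedly.

The package is aimed at methodologists and screening planners who want to
compare allocation rules for follow-up programmes (e.g. cancer-recurrence
surveillance with five annual examination slots) driven by conditional
annual risk predictions p_{k,i}(D).

## Model in brief

Disease onset in interval i sits at the midpoint t_occ = i − 0.5; an
examination at year t_i ≥ i detects it with curability dp^(t_i − t_occ),
where dp ∈ (0, 1] encodes progression speed.  With perfect predictions each
annual risk is expected occurrence mass, so detection under a schedule is
an exact expectation.  A schedule's quality is its target detection rate

    tdr = n_actual(D_curable) / n_max(D_curable),

the fraction retained of the curable detections that full screening would
achieve.  Four allocation rules are compared at equal tdr:

* **CA** — screen every year iff the 5-year cumulative risk passes a threshold;
* **CAIR** — accumulate annual risks, screen and reset each time the
  threshold is reached;
* **ISA** — screen after each year whose own annual risk passes the threshold;
* **RA** — random slot allocation until the tdr is reached (the reference).

Thresholds are calibrated to the target tdr by bisection; efficiency is the
percentage of examinations avoided versus RA.  Populations are simulated
with controlled mean-risk variation over time (`cvmr`), within-patient risk
correlation (`r`), and progression speed (`dp`); a cohort mode applies the
same machinery to tables of per-patient predictions with observed events
and imperfect examination sensitivity, including a synthetic generator
shaped like published breast-cancer-recurrence nomogram output.

## Worked example

Generate a synthetic nomogram-like cohort and evaluate all strategies at a
90% target detection rate, dp = 0.3, 80% examination sensitivity:

```bash
riskscreen synth-cohort --n 6520 --seed 1 --out cohort.csv
riskscreen cohort --in cohort.csv --dp 0.3 --tdr 0.9 --sens 0.8 --seed 1
```

prints (abridged):

```
strategy  threshold    exams  ...  saving_vs_RA  expected_detected_events
      CA        0.0  21592.5  ...          24.4                      61.3
    CAIR        0.0  19623.6  ...          31.3                      58.7
     ISA        0.0  19069.4  ...          33.2                      60.5
      RA             28562.8  ...           0.0                      59.1
    FULL        0.0  32600.0  ...         -14.1                      65.9
```

Reading: random allocation needs ≈ 28,563 of the 32,600 possible follow-ups
to keep 90% of the achievable curable detections, while the
interval-specific rule needs ≈ 19,069 — a 33% saving at the same detection
benefit — and still catches 60.5 of the 65.9 events that even *full*
screening would be expected to detect in a curable state with an 80%
sensitive examination.  The same machinery runs in pure simulation mode:

```bash
riskscreen grid --tdr 0.9 --n 5000 --reps 100 --seed 1 --out results/grid
```

writes the 27-scenario table (`grid_results.csv`), marginal summaries per
dp / cvmr / r, and a `manifest.json` recording the seed, scenario mapping,
RA convention and spread scale.

In Python, the strategies are scikit-learn style policies:

```python
import numpy as np
from riskscreen import ScenarioParams, simulate_population, ThresholdScreeningPolicy
from riskscreen._rng import substream

params = ScenarioParams(dp=0.6, cvmr=0.5, r=0.2, seed=1)
rm = simulate_population(params, substream(1, "trajectory"), substream(1, "matrix"))
policy = ThresholdScreeningPolicy(rule="CAIR", tdr_target=0.9, dp=0.6).fit(rm.risks)
print(policy.threshold_, policy.exams_at_target_)
schedule = policy.transform(rm.risks)   # N x 5 examination indicators
```

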