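# bmrs

Longitudinal brain-metastases treatment-response assessment.

`bmrs` classifies per-assessment treatment response for patients with
brain metastases using the standard five-component CR/PR/SD/PD grid
(target lesions, non-target lesions, new lesions, corticosteroids,
clinical status), and extends it with:

- **Pluggable target/non-target designation policies** — `a1` (fixed
  baseline target set, at most five measurable lesions), `a2` (new
  measurable lesions are added or replace the smallest current target),
  and `arx` (every treated lesion is a target from its pre-treatment
  imaging, with no size threshold or cap). Baseline and nadir diameter
  sums are reset whenever the target-set composition changes.
- **Per-lesion and mixed-response reporting** — each lesion is
  classified with the same thresholds applied to its own longest
  diameter; reports include the fraction of lesions per category and a
  discrepancy flag when the sum-based overall category conceals
  individual lesion progression (or successful control).
- **Distant-brain-failure (DBF) metrics** — per-assessment new-lesion
  events with count and volume, DBF latency (mean inter-event interval),
  and brain-metastasis velocity in lesions/year (BMV) and mm³/year
  (vBMV).
- **Clinical status** — KPS deterioration rules plus a 0–5
  brain-specific-symptoms (BSS) scale, with declines attributable to
  non-CNS causes excluded.
- **Scenario fixtures and a simulator** — twelve programmatic fixture
  courses exercising the edge cases above, and a seeded stochastic
  course simulator (exponential lesion growth, treatment response with
  delayed regrowth, Poisson new-lesion arrivals).

## CLI

```sh
# emit a fixture course
bmrs scenario fig8 --out fig8.json

# assess it under a designation policy; writes report.json,
# timepoints.csv, dbf.csv and audit.log into --out
bmrs assess --course fig8.json --policy arx --out report_dir

# thresholds/switches from YAML (flags override)
bmrs assess --course fig8.json --config cfg.yaml --pd-rule absolute_2p5mm \
    --status-metric both --dbf-reference treatment:SYS

# simulate a random course (seed-deterministic)
bmrs simulate --params params.yaml --seed 42 --out course.json

# run all three policies on one course and tabulate disagreements
bmrs compare-policies --course fig8.json --out compare.csv
```

Courses are read from canonical JSON or from a directory of CSV tables
(`assessments.csv`, `lesions.csv`, `measurements.csv`,
`treatments.csv`, `clinical.csv`). All diameters are millimetres and
all times integer day offsets from baseline; months are reported as
days/30.44.

## Python API

```python
from bmrs import AssessmentConfig, Policy, assess_course, build_scenario

course = build_scenario("fig3_p2")
report = assess_course(course, AssessmentConfig(policy=Policy.A1))
print(report.timepoints[-1].overall)        # Category.PD
print(report.mixed_response_fractions)      # {'CR': 0.2, 'PR': 0.6, 'PD': 0.2}
```

`windowed_assessment(course, window_start_day)` re-baselines a course at
a chosen assessment (e.g. a systemic-therapy start) so response and DBF
metrics are attributed to the window.

## Layout

- `src/bmrs/course_model.py` — domain types, validation, geometry
- `src/bmrs/designation.py` — A1/A2/A-Rx policies, SLD baseline/nadir
- `src/bmrs/response_engine.py` — response grid, per-lesion and course-level reports, windowing
- `src/bmrs/clinical_status.py` — KPS/BSS deterioration rules
- `src/bmrs/dbf_metrics.py` — DBF events, extent, latency, BMV/vBMV
- `src/bmrs/scenarios.py` — fixture courses and the simulator
- `src/bmrs/io.py`, `src/bmrs/cli.py` — formats and command line
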