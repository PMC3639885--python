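# cardiolift

Unit-aware clinical patient records, algorithmic derivations (BMI,
Friedewald LDL, the men's general-CVD point score), declarative guideline
risk models — both official and clinician-personalized — and tooling for
measuring and recovering an expert's personal classification behavior.

The package "lifts" raw cardiovascular measurements through increasingly
abstract layers: semantically-typed quantities with convertible units →
derived attributes → binary/staged guideline classifications → concordance
against expert labels and recovery of personalized cutoffs. Cohorts with
the legacy spreadsheet's structure can be simulated, labeled by a
configurable rule-following (optionally deviating) expert, and round-tripped
through CSV and Turtle RDF.

## Modules

| module | what it does |
| --- | --- |
| `cardiolift.units` | compositional unit registry (base / prefixed / complex derived units), analyte-aware mg/dl ↔ mmol/L bridging, mmHg ↔ kPa |
| `cardiolift.records` | `PatientRecord` model, legacy CSV dialect reader/writer, Turtle RDF writer/parser |
| `cardiolift.derivations` | BMI, Friedewald LDL (unit-dependent constant k = 0.20 / 0.45), point score → 10-year-risk % → low/medium/high |
| `cardiolift.guidelines` | declarative band models, binary and joint blood-pressure-stage classification, dependency-resolving `lift`, gap/overlap `validate_model` |
| `cardiolift.personalization` | TP/FP concordance vs expert flags, single-threshold recovery from labeled values |
| `cardiolift.synthetic_cohort` | reproducible cohort simulation with a simulated expert labeler |
| `cardiolift.cli` | `cardiolift` command: simulate / classify / derive / convert / evaluate / recover / validate-model |

## CLI

Subcommands compose via stdin/stdout:

```sh
# simulate a labeled cohort and classify it with the personalized rules
cardiolift simulate -n 636 --seed 1 | cardiolift classify - --model-set modified

# Table-9-shaped concordance report (JSON)
cardiolift simulate -n 500 --seed 1 | cardiolift evaluate - --model-set original

# recover the expert's personal HDL cutoff from labeled records
cardiolift simulate -n 500 --seed 1 | cardiolift recover - --attribute hdl --direction le

# unit conversion and model validation
cardiolift convert --value 140 --from mmHg --to kPa
cardiolift validate-model aha_chol_mmol     # reports the 5.0-5.2 gap
```

Model sets: `original` (official binary cutoffs), `modified` (the
clinician-personalized cutoffs: cholesterol ≥ 5.2 mmol/L, HDL ≤ 0.89,
triglycerides ≥ 2.63, BMI ≥ 26), `aha` (multi-band staged models), or a
YAML file in the format emitted by
`cardiolift.guidelines.models_to_config`.

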