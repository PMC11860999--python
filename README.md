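# evband

Population-pharmacokinetic simulation of weight-band, whole-vial dosing for
enfortumab vedotin, with exposure-equivalence testing and drug-cost accounting.

Enfortumab vedotin is dosed by body weight (1.25 mg/kg, capped at 100 kg, with
reduction steps 1.0 / 0.75 / 0.5 mg/kg) but supplied in 20 mg and 30 mg
single-use vials, so almost every prescribed dose discards part of a vial.
`evband` simulates a virtual patient cohort under a two-compartment
population-PK model and asks: can a small table of fixed doses — one per body
weight band, each an exact sum of vial sizes — deliver equivalent exposure
while eliminating spillage?  Equivalence is judged on the geometric mean ratio
(GMR) of four exposure metrics (first-cycle and steady-state AUC and trough)
between the band regimen and the label regimen, using the conservative
90–111% window.  Drug use and costs are then projected per treatment course
for monotherapy (days 1/8/15 of 28-day cycles, 5 cycles) and combination
therapy with pembrolizumab (days 1/8 of 21-day cycles, 12 cycles).

## Quick start (CLI)

```text
$ evband simulate --seed 1 --out evband-out
level 1.25 mg/kg: GMR 0.912 [PASS], savings 14.7%
level 1.0 mg/kg: GMR 0.913 [PASS], savings 15.9%
level 0.75 mg/kg: GMR 0.907 [PASS], savings 18.8%
level 0.5 mg/kg: GMR 0.911 [PASS], savings 19.9%
outputs written to evband-out

$ evband report --seed 1 --out evband-out
level 1.25 mg/kg monotherapy: EUR 46,947.48 -> EUR 40,037.28 (15% saved)
level 1.0 mg/kg monotherapy: EUR 38,016.57 -> EUR 31,954.44 (16% saved)
level 0.75 mg/kg monotherapy: EUR 29,326.47 -> EUR 23,808.78 (19% saved)
level 0.5 mg/kg monotherapy: EUR 20,269.92 -> EUR 16,228.50 (20% saved)
average savings across levels: 17.4%

$ evband design --seed 1 --n-subjects 500 --level 1.25 --out evband-out
level 1.25 mg/kg: doses [60.0, 70.0, 70.0, 80.0, 100.0, 110.0] mg, GMR 0.975, feasible=True
designed tables written to evband-out/designed_band_tables.csv
```

`simulate` evaluates the packaged band tables on a fresh 500-subject cohort;
`report` prints the per-course cost comparison; `design` derives a band table
from scratch under the equivalence constraints (its minimal-cost solution is
close to, but not identical with, the packaged table — see
`docs/methods.md`).  All subcommands accept `--config run.yaml` (schema
documented in `evband.config.load_config`), `--seed`, `--n-subjects`,
repeatable `--level`, and `--out`.

Output files: `band_tables.csv`, `equivalence.csv` (per endpoint GM, %CV,
GMR, pass/fail), `accounting.csv` (per-band mg used/saved under both
accounting conventions), `costs.csv`, `quartile_summary.csv` (steady-state
AUC by weight quartile), `summary.json` and `run.log`.

## Quick start (library)

```python
from evband import (default_config, run_pipeline)

bundle = run_pipeline(default_config(seed=1))
level = bundle["summary"]["levels"]["1.25"]
print(round(level["gmr"], 3), round(level["savings_pct"], 1))
# 0.912 14.7
print(round(bundle["summary"]["average_savings_pct"], 1))
# 17.4
```

The module layout mirrors the pipeline: `cohort` (virtual patients),
`pkmodel` (closed-form two-compartment engine, NONMEM control-stream
transcription), `regimens` (dose rules, band tables, vial decomposition,
drug accounting), `equivalence` (GMR/%CV statistics), `band_designer`
(constraint-based table derivation), `costs_report` (costs and the pipeline).

## Parameter provenance

The default two-compartment parameters and weight distribution are
*calibrated placeholders*: they were fitted once so that the default cohort
reproduces published population summaries of exposure and drug use (see
`docs/methods.md` for the targets and rationale), not transcribed from a
registrational model.  Reports are watermarked accordingly.  To use estimated
parameters, transcribe a NONMEM control stream with
`evband.pkmodel.parse_nonmem_control` and pass the result through the config.

## Testing

```bash
python -m pytest -q tests/
```

The suite contains unit and property-based tests per module (including an
independent ODE oracle for the closed-form PK engine and an exhaustive-search
oracle for vial decomposition) plus an acceptance suite covering the
end-to-end claims.
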