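# glycosurv

Analysis of infection-induced deviations in self-recorded type 1 diabetes
data, and a prototype per-individual infection detector built on them.

## The problem

People with type 1 diabetes continuously self-record blood glucose (SMBG
finger-pricks and CGM sensors, mg/dL), insulin doses (bolus and basal, U)
and carbohydrate intake (g). On ordinary days these patient-controllable
inputs obey a stable norm: more insulin and less carbohydrate lower blood
glucose, and the **bolus-to-carbohydrate ratio** — units of meal insulin per
gram of carbohydrate — sits in a narrow personal operating band, typically
0.05–0.2 U/g. An acute infection breaks that norm: counterregulatory stress
hormones raise hepatic glucose output and reduce insulin sensitivity (the
factor φ in BG = f(CH, IN, PA, CRH; φ)), so glucose stays elevated for days
*despite* larger boluses and reduced appetite, and the ratio climbs toward
0.3–0.6. That signature is visible in self-management logs before any
diagnosis, which makes these patients' data a candidate signal for digital
infectious-disease surveillance — and the basis for personal "sick day"
decision support.

`glycosurv` implements the full analysis chain for one patient-year:

- **data_model** — typed event log (glucose / insulin / carbs / infection
  episodes) with validating CSV import/export;
- **preprocessing** — uniform hourly or daily bins (glucose averaged,
  insulin and carbs summed), cubic-spline imputation of missing glucose,
  trailing 48 h moving average, and the ratio computed *after* smoothing so
  carb-free bins cannot blow it up;
- **weekly_deviation** — per-week means/SDs on raw daily aggregates and the
  infection-vs-flanking-week percentage changes, with cross-case
  aggregation;
- **density_estimation** — adaptive Gaussian KDE (Abramson square-root
  local bandwidths) with a diffusion plug-in bandwidth in 1D and a
  rule-of-thumb selector in 2D, plus a full-vs-infection-excluded
  distribution comparison;
- **synthetic_data** — a seeded behavioural glucose–insulin simulator that
  emulates the study conditions (meals, dosing, φ drop, hepatic boost,
  appetite loss) with per-day ground truth, plus the published five-case
  week summaries as worked-example inputs;
- **detection** — anomaly scores against a personalized baseline density,
  a three-state status (normal 0 / suspicious −1 / infected 1) with a
  two-day persistence rule, and ground-truth evaluation;
- **cli** — `glycosurv simulate|preprocess|weekly|density|detect|report`.

## Worked example

The five published infection cases ship with the package as week summaries
(mean/SD of daily glucose, bolus insulin and carbohydrate for the
preinfection, infection and postinfection weeks). `glycosurv report`
pushes them through the deviation operations:

```text
$ glycosurv report
 case_id     parameter direction  pct_vs_pre  pct_vs_post
  case-1            bg  increase        8.57        19.13
  case-1         bolus  increase       50.92        65.57
  case-1         carbs reduction       25.84        25.86
  ...
aggregates (mean of per-case percentages):
             bg: vs pre   5.64%  vs post  15.99%  (n=5)
          bolus: vs pre  41.75%  vs post  39.25%  (n=5)
          carbs: vs pre  18.95%  vs post  25.73%  (n=4)
```

Reading: in the first case, infection-week glucose ran 8.57% above the
preinfection week while bolus insulin was up 50.92% and carbohydrate intake
down 25.84% — the infection signature. Averaged over cases, glucose was
up ~16% on the postinfection side, bolus up ~42% vs preinfection, carbs
down ~19% vs preinfection (four cases logged carbs).

An end-to-end simulated run:

```bash
glycosurv simulate --seed 3 --days 365 --episode-onset 180 --out run/
glycosurv weekly  --data run/ --out run/weekly/
glycosurv detect  --data run/ --out run/detect/
```

`detect` prints, for that seed, per-day detection metrics against the
simulator's ground truth — with seed 3: sensitivity 0.8, false-positive
rate 0.0, latency 1 day at the default thresholds.

## Known caveats

Two published per-case figures are internally inconsistent with the
published week means (third case glucose-vs-pre, fourth case
carbs-vs-post, the latter consistent with an infection-week denominator);
the package reproduces the arithmetic of the week means and surfaces both
as flagged discrepancies (`weekly_deviation.flag_discrepancies`) rather
than matching them. See `docs/methods.md` for the model, parameter
defaults and the simulator's limitations.
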