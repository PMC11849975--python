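# blastdose

Dosimetry and dose-response analysis for syringe weight-drop blast TBI in
larval zebrafish.

A widely used low-cost TBI model drops a calibration weight down a guide
tube onto the plunger of a closed, media-filled syringe holding larvae; the
impact (and the weight's subsequent bounces) drives blast-like pressure
waves through the media. A fuel-line pressure transducer sampled by a
10-bit Arduino ADC records each drop. `blastdose` is the analysis side of
that rig, for experimentalists running it and for anyone re-analysing its
exports:

- **trace_io** — read/validate raw ADC captures and convert them to kPa
  through the transducer calibration chain
  `kPa = 6.895 · 37.5 · (5·output/1023 − 0.5)`, flagging below-offset
  samples instead of clipping them.
- **dosimetry** — segment traces into baseline-to-baseline pressure waves;
  report maximal pressure (the dose metric), per-wave peaks/means,
  inter-wave intervals, replicate mean ± SEM and RSD = 100·SD/mean;
  static Pascal's-law calibration checks and drop potential energy.
- **behavior** — per-larva metrics from plate-tracking activity exports:
  mean activity, high-activity bouts above 64% of the uninjured group's
  maximum, ≥ 1 min inactivity bouts and total inactive time, candidate-dead
  flags, manual seizure-stage tallies, fin-poke response rates.
- **dose_response** — OLS activity-vs-dose fits; maximum-likelihood
  logistic fits of binary phenotypes on maximal pressure (kPa) and drop
  count with per-unit odds ratios OR = exp(β), Wald 95% CIs, ROC AUC, and
  per-k-unit scaling ORᵏ (OR 1.005/kPa ⇒ +64.7% odds per 100 kPa);
  one-way ANOVA with Dunnett comparisons against the shared control.
- **synthetic_data** — seeded generators for bouncing-weight pressure
  traces (restitution-decayed impulse train pushed back through the ADC),
  dose-structured activity traces (biphasic: seizure band ~90–300 kPa,
  suppression above), and Bernoulli phenotype tables from a stated
  logistic model — the whole pipeline runs with no animals.
- **pipeline / CLI** — manifest-driven end-to-end runs
  (`blastdose {convert,dose,behavior,doseresponse,simulate,run}`) with
  validation findings, wave tables, metric tables, fit reports and a run
  log.

## Worked example

Simulate three replicate drops of a 100 g weight from 108 cm (20 ml
syringe, clamp holder), convert and segment them, then fit the logistic
dose-response model to a synthetic phenotype table drawn from OR
1.005 per kPa:

```python
import numpy as np
from blastdose import (
    ImpactSimConfig, simulate_drop_trace, convert_trace,
    summarize_drop, summarize_replicates,
    PhenotypeSimConfig, simulate_phenotypes, fit_logistic, scale_odds_ratio,
)

drops = []
for rep in range(3):
    cfg = ImpactSimConfig(noise_sd_kpa=2.0, seed=10 + rep)
    drops.append(summarize_drop(convert_trace(simulate_drop_trace(cfg))))
for d in drops:
    print(f"drop max {d.maximal_pressure_kpa:7.2f} kPa, {d.n_waves} waves, "
          f"first interval {d.inter_wave_intervals_ms[0]:.1f} ms")
rep = summarize_replicates(drops)
print(f"replicates: {rep.mean_max_pressure_kpa:.2f} +/- "
      f"{rep.sem_max_pressure_kpa:.2f} kPa (SEM), RSD {rep.rsd_percent:.2f}%")

pcfg = PhenotypeSimConfig(
    b0=-2.0, b1_per_kpa=np.log(1.005),
    doses=tuple((d, 1) for d in (33, 150, 300, 600, 1105)),
    n_per_dose=100, seed=42,
)
fit = fit_logistic(simulate_phenotypes(pcfg))
eff = fit.effects["max_pressure_kpa"]
_, pct = scale_odds_ratio(eff.odds_ratio, 100)
print(f"OR per kPa {eff.odds_ratio:.4f} "
      f"(95% CI {eff.ci_low:.4f}-{eff.ci_high:.4f}), "
      f"AUC {fit.auc:.2f}, +{pct:.1f}% per 100 kPa")
```

Output:

```
drop max  275.12 kPa, 4 waves, first interval 469.6 ms
drop max  278.91 kPa, 4 waves, first interval 469.4 ms
drop max  276.38 kPa, 4 waves, first interval 469.4 ms
replicates: 276.80 +/- 1.11 kPa (SEM), RSD 0.70%
OR per kPa 1.0048 (95% CI 1.0039-1.0057), AUC 0.85, +61.4% per 100 kPa
```

Each drop shows the primary wave plus three bounce waves (restitution 0.5
cuts each rebound's amplitude in half; the fifth would fall below the 10%
cutoff). The maximal pressure is the per-drop dose metric; the RSD
summarizes rig consistency across replicates. The logistic fit recovers
the generative odds ratio — its 95% CI contains 1.005 — and the per-100-kPa
scaling restates it on the scale effects are usually discussed.

The same chain runs from the shell:

```bash
blastdose simulate --out demo --seed 3 --kind trace
blastdose dose --in demo/trace.csv --out demo/waves.csv
# drop 1: max 276.38 kPa, 4 wave(s)
```

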