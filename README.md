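# circadia

Behavioural chronobiology and morphometry toolkit for rodent
sleep/circadian phenotyping studies. It implements, as tested reusable
code, the quantification pipeline that such studies typically spread
across several closed tools (video-tracking sleep scores, ClockLab-style
actigraphy, El Temps periodograms, ImageJ densitometry):

- **immobility-defined sleep scoring** — behavioural sleep is called when
  ≥ 95 % of the tracked body is immobile for **more than 40 s**; scored
  seconds are binned per minute and summarised as day (ZT0–12) / night
  (ZT12–24) totals, bout counts and durations (21-min gap rule), onsets
  and hourly profiles;
- **actigraphy** — activity bouts and fragmentation (bouts/day), per-cycle
  onsets, onset precision about a regression line, alpha (active-phase
  length), nocturnality, activity amount (rev/h), phase angle of
  entrainment, and phase shifts from pre/post onset regression lines;
- **χ² periodogram** — Sokolove–Bushell rhythm detection over 20–31 h in
  3-min steps, with the χ² *P* = 0.05 significance line and power
  normalised to percentage of variance (Qp × 100/N);
- **Sholl morphometry** — circle crossings at 25-µm intervals and
  branch-order statistics (counts, lengths, branching points for
  primary/secondary/tertiary dendrites) on SWC reconstructions;
- **intensity-image quantification** — ROI column profiles, fourth-order
  polynomial peak estimation, peak-aligned profile averaging, mean ROI
  densitometry, and isodata-threshold particle counting with a ≥ 25 µm²
  area filter;
- **behavioural scores** — novel-object discrimination index, zone
  entries with 85 %-in / 75 %-out body-fraction hysteresis, relative
  occupancy heat maps;
- **statistics** — mean ± SEM summaries, Student's *t* from printed
  summaries, screen-then-test group comparison (Shapiro–Wilk,
  Brown–Forsythe, *t*/rank-sum/ANOVA, Holm–Šidák or Bonferroni post hoc).

Because real recordings of this kind are rarely deposited, the package
ships a first-class **synthetic-data module**: seeded generators for
circadian-gated bout-process activity (with onset jitter, LD masking and
imposed phase-shift events), immobility traces with placed sleep
episodes, order-structured dendritic trees and Gaussian-ridge intensity
images. Every estimator is validated by recovering the generator's
ground-truth parameters.

## Core definitions

For an activity series folded at trial period *P* into *K* phase columns,

    Qp = N · Σ_h n_h (x̄_h − x̄)² / Σ_i (x_i − x̄)²

with column means x̄\_h, column counts n\_h and N data points; under the
white-noise null Qp ≈ χ²(K−1), and the dominant period is the
supra-significance argmax. Rhythm power is %V = Qp·100/N (100 % for a
noiseless rhythm). Phase shifts are reported as phase differences:
a **delayed** onset is **negative** (so a light pulse at CT16 yields, e.g.,
−100.3 min). Onset precision is the negated mean |residual| about the
best-fit onset line, matching the convention of printing worse precision
as more negative.

## Worked example

```python
from circadia import (ActivitySimConfig, LightSchedule, Regime, gen_activity,
                      detect_bouts, fragmentation, daily_onsets, precision,
                      nocturnality, activity_amount, alpha, phase_angle,
                      chi2_periodogram, estimate_period, normalized_power)

cfg = ActivitySimConfig(tau=24.0, n_days=10, onset_jitter_sd=12.0,
                        nocturnality_target=0.9, seed=1)
ld = LightSchedule(regime=Regime.LD)
series = gen_activity(cfg, ld)            # 10 days of 3-min binned counts

bouts = detect_bouts(series)              # 21-min gap rule
onsets = daily_onsets(series)             # first bout after >= 6 h quiet
pg = chi2_periodogram(series)             # 20-31 h, 3-min steps
print(f"period        : {estimate_period(pg):.2f} h")
print(f"power         : {normalized_power(pg):.1f} %V")
print(f"fragmentation : {fragmentation(bouts, series.n_days):.1f} bouts/day")
print(f"nocturnality  : {nocturnality(series):.1f} %")
print(f"precision     : {precision(onsets):.1f} min")
print(f"phase angle   : {phase_angle(onsets, ld):.1f} min")
```

prints

```
period        : 24.00 h
power         : 62.6 %V
fragmentation : 2.1 bouts/day
nocturnality  : 90.2 %
precision     : -5.2 min
phase angle   : -27.6 min
```

The entrained 24-h period is recovered exactly on the 3-min grid; the
measured nocturnality sits at the generator's 90 % target; the onset
precision magnitude (5.2 min) reflects the 12-min Gaussian onset jitter
after the regression fit; and the negative phase angle says onsets
anticipate lights-off (the generator's default onset is ZT11.5).

A command-line interface mirrors the library
(`circadia simulate|sleep|actogram|periodogram|morph|image|stats|run`),
e.g. `circadia periodogram --in activity.csv --out pgram.csv`.

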