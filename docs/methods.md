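# Methods

This note documents the models, conventions and numerical choices behind
`circadia`, and what the synthetic-data validation does and does not
establish about real recordings.

## Conventions

All times are minutes since recording start; Zeitgeber time ZT is hours
with ZT0 = lights-on (ZT12 = lights-off under 12:12 LD). Bins are
half-open `[t, t + Δ)`. Under constant darkness the day/night split uses
the projected ZT carried over from the prior entrained phase (logged).

## Sleep scoring

A maximal run of samples with body-immobility fraction ≥ 0.95 is sleep
iff its duration **strictly exceeds** 40 s ("more than 40 s"); both the
threshold and the minimum duration are parameters. The per-sample
immobility fraction interpretation of "95 % of the animal remained
immobile" follows video-tracking-software convention. Whether the rule
is a maximal-run or sliding-window criterion is not standardised;
maximal-run is the default and a sliding-window variant (runs qualify at
≥ 40 s) is available via `method="sliding-window"`.

Qualifying runs contribute their overlap seconds to each 1-min bin, so
`Σ bins` equals total qualifying immobile time to sampling resolution.
Sleep bouts merge sleep-containing minutes separated by gaps < 21 min; a
gap of ≥ 21 min splits. A **sleep** bout's duration is the summed sleep
minutes it contains (fractional minutes count fractionally), which is
what minute-binned exports support; an **activity** bout's duration is
`end − start`. The onset is the first bout preceded by ≥ 6 h without a
bout of the same kind ("inactivity" is read as absence of bouts of the
scored kind, since the same rule is stated for activity and sleep).

## Actigraphy

Activity bouts use supra-threshold bins (default ≥ 1 count/bin, exposed
as a parameter) under the same 21-min gap rule; fragmentation is
bouts/day. Per-cycle onsets take the first qualifying bout per cycle;
the cycle length defaults to 24 h and should be set to the running
period estimate in DD so drifting onsets stay within their cycles.

Precision is the negated mean absolute residual about a least-squares
line through the onsets (reported negative so larger magnitudes mean
worse precision, matching how such values are printed). "Eye-fitted"
onset lines are replaced by least-squares fits throughout —
reproducibility over subjectivity.

Phase shifts fit one line per side (absolute cycle indices) and evaluate
the **phase difference pre − post at the first post-event cycle**; a
delayed onset (later clock time than the pre-event line predicts) is a
negative shift. The evaluation abscissa is a convention; for a pure step
change with equal slopes the estimate is abscissa-independent. The
sign convention deserves emphasis: the difference of onset *clock times*
(post − pre) is positive for a delay, so the phase shift is its negative.

Alpha groups bouts into daily episodes separated by ≥ 6 h of bout-free
time and averages onset-to-offset spans. Nocturnality is
100 × (dark-phase counts)/(total counts); amount is total counts/(24 ·
n_days); the phase angle of entrainment is the mean signed offset of
onsets from lights-off (negative = anticipation). `rolling_peak` returns
the centre of the maximal-mean window (default 2-h windows, 1-h lags;
ties → earliest), the standard way to locate the time-of-peak of a
windowed firing-rate profile.

## χ² periodogram

For trial period `P` (20–31 h by default, 3-min grid) the series is
folded into `K = round(P/bin)` phase columns; bin `i` with start time
`t` goes to column `floor((t mod P)·K/P + ε)`. The `ε = 1e-9` guards a
genuine float-precision failure mode: at trial periods that are exact
bin multiples, the unguarded expression lands just below integers and
scatters bins into wrong columns (which empties/doubles columns and
visibly deflates the null rejection rate).

The statistic is the between-column sum of squares over the overall
variance estimate,

    Qp = N · Σ_h n_h (x̄_h − x̄)² / Σ_i (x_i − x̄)²,

the classical Sokolove–Bushell form: a perfectly periodic series gives
Qp = N, and under a white-noise null Qp ≈ χ²(K−1), which supplies the
P = 0.05 significance line (df = K−1). An unweighted variant (dropping
`n_h`) is sometimes written down but is not usable here: it is bounded
by K, which is *below* the χ² quantile, and would cap the variance
percentage at K/N. Monte-Carlo checks in the test suite confirm a ~5 %
fraction of supra-significance trial periods on white noise.

Power (%V) is Qp·100/N at the dominant (supra-significance argmax)
period; a significance-referenced variant (Qp − sig)·100/N is available
behind a flag, since the phrase "normalised … according to the
significance level" is ambiguous; the plain form is primary and both are
logged. Trailing partial cycles are included in column means by default
(`include_partial=False` uses whole cycles only); which behaviour the
original desktop tools use is not documented, and the choice only
perturbs Qp at order 1/n_cycles. Ties in the argmax resolve to the
shorter period. A constant series yields Qp ≡ 0 with a warning.

## Synthetic activity generator

Each cycle `d` has onset `onset_phase + d·τ` hours plus Gaussian jitter
(`onset_jitter_sd`, minutes) and the cumulative effect of phase-shift
events (step changes applied to all later cycles; negative shift = delay
= later onsets, consistent with the estimator's sign). The active phase
lasts `alpha_min` minutes and is filled with alternating active bouts
and rest gaps whose durations are gamma distributed with shape 2 and the
stated means — a positive, unimodal convention; no distributional
information about real mouse activity underlies it. Counts in active
bins are Poisson with mean `count_rate_active` (non-negative integers by
construction); `square_wave=True` renders the noiseless mode used by the
period-recovery checks (fully active phase, constant counts).

Under LD, light-phase rates are multiplied by a masking factor `m` =
D(1−g)/(L·g) chosen so the **expected** nocturnality equals the target
`g`, where D and L are the unmasked dark/light expected totals of the
realised bout pattern. A target below 100 % therefore requires an active
phase that overlaps the light phase; the default onset of ZT11.5
(anticipating lights-off, as entrained nocturnal rodents do) provides
that overlap and yields a realistic negative phase angle. `alpha_min`
defaults to 420 min (a typical active-phase length for entrained mice).

Expected fragmentation after 21-min-gap merging has no convenient
closed form for this renewal process (and is non-monotone in the gap
mean: short gaps rarely split, very long gaps leave room for few bouts),
so `calibrate_fragmentation` scans and then bisects on the rising limb
using internally seeded Monte-Carlo evaluations of the full
generate-and-segment pipeline; common fixed seeds keep the objective
smooth and the result deterministic, and they are independent of any
evaluation seeds. Validation then measures the across-seed mean with
fresh seeds.

The other generators are constructive: immobility traces place episodes
exactly on a sub-threshold baseline (stochastic mode keeps the baseline
strictly below 0.95); dendritic trees realise exact per-order branch
counts (daughter cohorts attach in groups of ≥ 2 per branch point, so a
non-zero count of 1 is infeasible and rejected) with randomised angles
and per-order mean lengths; images are a horizontal Gaussian intensity
ridge plus particle disks plus Gaussian noise.

## Morphometry

Analysis is 2-D (camera-lucida projections); SWC z-coordinates are
ignored with a warning. Sholl crossings count transversal intersections
of each segment with each circle (quadratic roots strictly inside the
segment; tangential touches count zero), so a tortuous dendrite
re-crossing a circle counts each transversal — the classical definition.
Branch order: soma-emanating branches are order 1 and order increments
at branch points (≥ 2 children); a single-child node continues its
branch. Orders beyond tertiary are tallied under their own keys; table
summaries conventionally stop at 3.

## Imaging

Column profiles average pixel columns inside a rectangular ROI (the
fixed 358 × 617 µm box convention for whole-nucleus quantification).
The peak is the in-range argmax of a fourth-order least-squares
polynomial; restricting to the observed x-range suppresses the spurious
boundary maxima a quartic develops outside the data, ties go leftmost,
and a constant profile returns the range centre with a warning. Known
limitation: a global quartic is a biased peak estimator when the bump is
much narrower than the profile support; for SCN-scale bumps spanning a
substantial fraction of the ROI the bias is well below one pixel.
Alignment shifts profiles by whole samples so the sample nearest each
fitted peak coincides, then averages over the common support (flanks
dropped); the returned axis is micrometres relative to the peak.
No background subtraction is applied before fitting by default.

Particle counting binarises at the isodata iterative-intermeans
threshold (the documented ImageJ "default"), labels 8-connected
components (flag for 4-connectivity) and keeps those with area ≥ 25 µm²,
with no circularity restriction. The threshold is data-relative, so
counts are invariant to positive intensity rescaling.

## Behavioural scores

DI = t_novel/(t_novel + t_familiar); undefined (error) when both are
zero, as no minimum-exploration criterion is imposed. Zone entry uses an
asymmetric hysteresis band: enter at in-fraction ≥ 0.85, exit at
in-fraction ≤ 0.25 (the literal reading of "75 % of the body out"); the
frame-0 state is IN when already above the entry threshold and is not
counted as an entry. Heat maps are normalised to the comparative maximum
across a stated group of animals, so they are comparable only within a
group; raw counts are available via a flag.

## Statistics

`t_from_summary` combines printed SEMs, t = Δmean/√(sem_a² + sem_b²),
with pooled df = n_a + n_b − 2 (the df printed alongside such t values;
a Welch–Satterthwaite df is also returned). With equal group sizes this
equals the pooled-variance t on raw data. Note that day-wise and
night-wise group t values printed in the source tables of studies like
this are often not recomputable from the printed summaries; only
quantities that are arithmetically recomputable are used for validation.
`compare_groups` screens with Shapiro–Wilk and Brown–Forsythe
(median-centred Levene) and then applies Student's t / rank-sum /
one- or two-way ANOVA with Holm–Šidák (default) or Bonferroni post hocs,
logging every decision.

## Problem sizes and what the tests show

Validation uses desk-scale simulations chosen to keep Monte-Carlo error
well inside the assertion bands: 14 noiseless days for period recovery,
10 days × 20 seeds for fragmentation and nocturnality recovery, 200
white-noise series for the periodogram null, 100–200 randomised inputs
per brute-force oracle. The generators emulate the statistical skeleton
of real recordings (circadian gating, bout structure, onset jitter,
masking, episode structure) but not ultradian spectra, torpor,
individual heterogeneity or tracking artefacts; passing recovery tests
therefore establishes correctness of the estimators under the stated
generative assumptions, not robustness to every pathology of real data.
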