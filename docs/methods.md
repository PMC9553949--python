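# Methods

## Model and assumptions

The package treats a heartbeat recording as a point process: strictly
increasing pulse times (seconds), reduced to RR intervals (milliseconds).
All inference happens on interval statistics; no waveform morphology is
used. Three summary statistics are computed per window:

- Cv = ΔI/Ī with the **population** standard deviation (divide by n). This
  convention makes the strictly alternating long/short construction come
  out exactly: a sequence [τ+δ, τ−δ] repeated has mean τ and SD δ for even
  length, hence Cv = δ/τ and Lg = 3 exactly. At the window sizes used in
  practice (hundreds of beats) the population/sample difference is far
  below every other source of variation.
- Lv = 3/(n−1) Σ ((Iᵢ−Iᵢ₊₁)/(Iᵢ+Iᵢ₊₁))². The factor 3 normalises a
  Poisson train to Lv = 1. Within a window, Lv averages over interval
  pairs whose shared heartbeat falls in the window, so a pair straddling a
  window edge is counted once, in the earlier window.
- Lg = Lv/Cv², undefined (flagged, never 0 or −∞) when Cv = 0.

Scale invariance (all three unchanged under I → cI, c > 0) is enforced by
property tests; it is what makes the metrics comparable across subjects
with different mean heart rates.

## Windowing and aggregation

Defaults: 10-minute windows after a 10-minute transient, spanning up to
18 h. An interval belongs to the window containing its terminal beat.
Windows with fewer than 2 intervals, or with Cv = 0 or Lv = 0 (log
undefined), are dropped from aggregation with a logged warning; dropping a
window removes it from the Cv, Lv **and** Hr means so every summary refers
to the same window set.

Per-subject summaries are the mean over windows of log₁₀(per-window value)
— mean of logs, not log of means — and the Lg summary is derived as
summary(log₁₀Lv) − 2·summary(log₁₀Cv). Duration modes: `18h` averages all
windows; `1h` the first six; `10min` and `1min` use a single window of
that length taken immediately after the transient (the natural reading of
the one-shot short-recording protocol). Recordings shorter than a mode's
nominal span are analysed in full. Hr is summarised as the mean of
per-window rates; the classifier never consumes Hr, so this choice is
inconsequential.

## Classification and optimisation

Zone membership uses strict inequalities; boundary points are negative.
Subjects with undefined Lg (perfectly regular windows) classify negative
with a logged flag. The grid search covers the observed metric range
padded by 0.05 at resolution 0.01 (zone thresholds are meaningful to about
two decimals in log₁₀ units; both are configurable), for both inequality
directions, and is implemented with boolean matrix products so the full
grid is scored exactly, not heuristically. Ties are broken
deterministically: smaller a, then smaller |b|, then direction "greater".
MCC is defined as 0 when any confusion-matrix marginal is empty. No
cross-validation is applied by default: with one or two selected
parameters and cohorts of dozens to thousands of subjects the optimism is
negligible; callers can replicate with fresh seeds for an honesty check
(the `evaluate` workflows do exactly that).

## Synthetic data: what it emulates, and what it does not

The generators produce the three interval arrangements with known closed
forms (gamma renewal; long/short Markov chains; slow sinusoidal rate
modulation of a locally regular train) plus a labelled cohort emulating a
screening population:

- **negative** subjects: locally regular trains (beat-to-beat jitter 2.5%)
  with slow rate modulation (depth 0.08, period 300 s) and a 0.002
  background premature-beat rate — this places them near log₁₀Lv ≈ −3
  with Cv dominated by the modulation, the geometry a healthy cluster
  shows;
- **PVC-like / PAC-like** subjects: the same base train with premature
  motifs — one short interval (0.55 / 0.70 of the local mean) followed by
  a compensatory long interval preserving the two-interval sum — inserted
  at per-beat rates 0.20 / 0.15. The motif forces short/long adjacency,
  pushing Lg above 3/2; the two classes differ in depth and rate so they
  occupy distinct Lv bands;
- **AF-like** subjects: gamma-renewal intervals with shape z = 1.5 around
  the modulated mean for the whole recording (persistent fibrillation),
  giving high Lv with Lg below 3/2 (random arrangement);
- per-subject mean intervals are drawn from U(700, 950) ms; each subject's
  generative anomaly fraction is recorded as its disorder ratio and
  dichotomised at 0.1.

Default cohort: 30 negative / 8 PVC / 6 PAC / 8 AF subjects with 4200-s
recordings (a 600-s transient plus six 10-minute windows). These sizes
keep a full multi-replicate noise sweep to seconds while leaving the
class geometry unambiguous; they are the conditions under which the
pipeline tests and trends are stated.

What the cohort does **not** emulate: respiratory sinus arrhythmia and
circadian structure, ectopy bursts and bigeminy runs, paroxysmal (partial
-record) AF, detector artefacts other than Gaussian timing jitter, and the
class imbalance of a real screening population. Passing tests therefore
show that the metrics and the optimiser behave as the theory predicts on
trains with these signatures — not that the selected zone parameters
transfer to clinical data.

The jitter observation model adds i.i.d. Gaussian noise (SD 10–500 ms) to
pulse times, then re-sorts and collapses exact ties by an epsilon shift;
re-sorting (rather than discarding inverted pairs) keeps the beat count
unchanged and is logged. In the noise and duration sweeps the zone and
threshold parameters are re-selected on each perturbed dataset, so the
reported MCC measures the method's robustness, not a fixed rule's.

## Numerical choices

- Gamma variates use the properly normalised gamma distribution (mean zτ);
  draws are clipped away from zero (underflow guard at very small shapes).
- Rate-modulated intervals are generated sequentially so the modulation
  phase follows actual elapsed time; intervals are floored at 5% of the
  local mean.
- Long/short chains start in the long state (irrelevant asymptotically).
- MCC grids are compared after rounding to 12 decimals so float noise
  cannot reorder exact ties.
- All generators are deterministic given (config, seed) via
  `numpy.random.default_rng`.

## Known limitations

- The AF label is a time fraction while PVC/PAC are beat fractions; the
  subject record stores a single fraction per disorder and leaves the
  semantics to the data supplier.
- The beat-export reader handles plain-text annotation exports only;
  waveform files and R-peak detection are out of scope.
- The evaluate workflow assumes every subject yields at least one valid
  window; an all-regular recording raises rather than being silently
  skipped.
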