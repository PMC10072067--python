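# Methods

This note documents the models, scoring rules, numerical conventions and
design choices implemented in `flychrono`, and what the synthetic-data
generator does and does not emulate.

## Data model

The raw material is a per-fly series of non-negative integer beam-break
counts in contiguous, uniform time bins (5 minutes by default), annotated
with a light schedule. Zeitgeber time (ZT) is minutes since lights-on:
ZT0 is lights-on and, under the default 12:12 cycle, ZT12 (minute 720) is
dark onset. The lights-on clock time is a required configuration field with
no default: ZT anchoring is meaningless if guessed, and monitor files do not
record it. Timestamps are validated for strict monotonicity and uniform
spacing but otherwise only order matters; time zones and DST are ignored,
as incubator recordings are wall-clock monotone.

Monitor files are the common 42-column TriKinetics dialect (10 metadata
columns — row index, date, time, status code and six acquisition fields —
followed by 32 channel counts). The column count is validated per row and
is configurable for other dialects; the parser fails loudly rather than
guessing. Rows whose status code is not OK are retained but **masked**:
they keep the bins contiguous while being excluded from every scoring
denominator. Masking rather than dropping is conservative and testable.

## Sleep, bouts and death

* A bin is **asleep** iff its count is zero, it is unmasked, and it precedes
  the fly's death. The canonical fly-sleep threshold (≥ 5 min of
  inactivity) is exactly one 5-minute bin; for other bin widths the
  threshold is configurable in whole bins, and a k-bin threshold marks only
  zero-runs of length ≥ k (so sleep is monotone non-increasing in the
  threshold). No sub-bin interpolation is attempted: sleep is scored at the
  resolution the hardware acquires.
* A **rest bout** is a maximal run of consecutive asleep bins. Whether
  "bouts" should mean runs or bins is ambiguous in common usage; the run
  interpretation is adopted, and the bin count is recoverable as the sum of
  run lengths. In the per-day summaries, a bout spanning the ZT12 boundary
  is split at the boundary and counts one bout on each side, keeping
  day + night bout counts consistent with the two 12-h windows (the same
  necessarily happens at the ZT0 day boundary).
* **Death** is a terminal run of zero-count bins strictly longer than 24 h;
  exactly 24 h of terminal silence is not death. The death bin is the first
  bin of the run — i.e. lifespan ends at the last movement, the standard
  DAM convention — so the silent tail is excluded from all behavioural
  denominators. Flies alive at the 30-day analysis horizon are
  right-censored there, and deaths located past the horizon are reported as
  censored at the horizon. Dead-on-arrival flies (death within day 1) are
  excluded from behavioural summaries but retained in survival curves, with
  their lifespan floored at one bin width so lifespans stay positive.
  Both thresholds must be whole numbers of bins; fractional configurations
  are configuration errors, not silent roundings.

Daily summaries run ZT0→ZT0; a leading partial day, the (partial) death
day, and days past the horizon are excluded. The young/old age strata split
after day 13 (young = days 1–13, old = 14–30), configurable.

## Profiles, anticipation, actograms

Population profiles average **within fly across days first, then across
flies**, so long-lived flies do not dominate; the fly is the biological
replicate, and the reported sem uses n = flies with the n−1 sample standard
deviation. Pooling all fly-days, and a "percent of flies asleep per bin"
aggregation (fraction of living flies asleep at each bin, averaged across
days), are available as switches.

The anticipation index for a light transition is the activity in the final
3 h before the transition divided by the activity in the full 6 h before
it, averaged over cycles with a nonzero 6-h denominator and no masked or
post-death bins in the window. Flat activity gives 0.5; activity packed
entirely into the last 3 h gives 1.0; the index is invariant to rescaling
all counts. The 3 h/6 h windows are the conventional morning/evening
anticipation choice and are configurable; no published formula is being
reproduced, so the qualitative contrast (a rising pre-transition ramp gives
an index above 0.5) is the contract.

Actograms are double-plotted: row d is day d's 288 bins followed by day
d+1's, so the left half of each row equals the right half of the previous
one. Recordings shorter than two complete days fall back to a single-plot
matrix with a warning. Rendering is left to the caller; the matrix is the
deliverable.

## Survival and count statistics

The Kaplan–Meier estimator and the two-group log-rank test are implemented
from their defining formulas (product-limit; hypergeometric expectation and
tie-corrected variance per distinct event time, χ² with df = 1). The name
"Mantel–Haenszel test", as used by Prism for survival curves, denotes
exactly this log-rank (Mantel–Cox) computation. `lifelines` is used in the
test suite as an independent oracle, never in the implementation.

The median is the smallest t with S(t) ≤ 0.5. When S hits 0.5 exactly —
routine for even cohorts such as n = 24 — a midpoint convention (mean of
the plateau's endpoints) is provided and used by the pipeline's summary,
since it is what the field's usual software reports and it produces the
familiar fractional medians (e.g. 22.5 d); the step convention remains the
library default.

Group comparisons (eclosion percentages per replicate vial, haemocytes/mL
per larva, glia per brain, behavioural metrics per fly) use the unpaired
two-tailed Student t-test with pooled variance; Welch is behind a flag.
When both groups have zero variance the t statistic is undefined and a
label-permutation test is substituted, bounding p below by 1/(n_perm + 1).
Groups with fewer than two units report missing statistics rather than
erroring. Haemocyte concentrations are derived from haemocytometer chamber
counts via the chamber volume factor (10⁴/mL for a standard 0.1 µL square)
times a dilution factor of 2 for the equal-volume trypan-blue bleed
protocol. No multiple-testing correction is applied across genotype pairs;
raw pairwise p-values are reported.

## DEG bookkeeping

The differential-expression model fit itself (e.g. DESeq2) is out of scope;
the module consumes result tables (gene id, log2 fold-change, adjusted p,
total read sum). The prefilter removes genes with a read sum strictly
below 10; the DEG rule is |log2FC| ≥ 1 and padj ≤ 0.05 with both boundaries
inclusive. Genes with missing padj (removed by independent filtering
upstream) are excluded from both sets and reported in an "untested" tally.
Venn region counts are exact set algebra for two or three comparisons, up
and down separately; region totals satisfy inclusion–exclusion by
construction.

## The synthetic generator

Each simulated fly is a two-state (wake/sleep) Markov chain at bin
resolution whose transition probabilities may vary with ZT, gating an
inhomogeneous Poisson count process: awake bins draw Poisson counts from a
circadian mean template attenuated by a per-day multiplicative age-decline
factor; asleep and post-death bins emit exactly zero (a hard assertion).
An optional noise rate adds false beam breaks during sleep to stress-test
the scorer; it defaults to 0 so that programmed sleep is cleanly
recoverable.

Defaults, chosen once as values a fly lab would call realistic:

* template: Gaussian bumps (σ = 60 min) at ZT0 and ZT12 of amplitude 12
  counts/bin over a baseline of 4 counts/bin by day and 30 % of that by
  night — a bimodal profile with a midday siesta trough;
* sleep chain: wake→sleep 0.08 per bin by day, 0.25 in a ZT5–ZT10 siesta
  window, 0.35 at night; sleep→wake 0.45 / 0.20 / 0.12 respectively —
  yielding roughly 700–900 min of sleep per day, night-dominant;
* lifespans: Weibull with shape k = 4 and scale set from the programmed
  median. Real fly cohorts die in an age-dependent (Gompertz-like) pattern
  with sigmoidal KM curves, which the Weibull shape captures; an
  exponential option (shape = None) exists for memoryless scenarios and is
  the prescribed configuration for null-calibration checks;
* age decline: activity × 0.995 per day.

Each fly draws from its own RNG stream derived from (cohort seed, fly
index), in a fixed order, so cohorts are bit-reproducible and extensible
without reshuffling existing flies.

What the generator does **not** emulate: false beam breaks by default (real
DAM data have occasional detector noise), position-dependent beam
sensitivity, temperature or light-intensity effects, social or feeding
artefacts, and any coupling between activity level and lifespan. Passing
recovery tests therefore demonstrates the correctness of the scoring and
statistics under the generator's assumptions, not robustness to every
failure mode of real recordings.

Two recovery checks deserve explicit framing:

* **Sleep recovery** is validated against the closed-form stationary
  probability p_ws/(p_ws + p_sw) of a homogeneous chain, using templates
  with means ≥ 8 counts/bin. In beam-break data an awake bin that happens
  to emit a Poisson zero is indistinguishable from sleep; at mean λ the
  scorer's expected overshoot is P(wake)·e^(−λ), so low-activity templates
  bound how well *any* scorer can recover programmed sleep. This is a
  property of the data model, not of the implementation.
* **Death recovery** is validated on wake-forced flies (no sleep chain).
  A fly asleep at its programmed death instant fuses its final sleep bout
  with the post-death silence, so the last movement — the only observable —
  precedes programmed death by the length of that bout; no scorer can do
  better from counts alone. The wake-forced configuration isolates the
  death caller, which is what the check is about.

The DE fixture generator simulates negative-binomial counts (gamma–Poisson)
with programmed fold-changes and computes per-gene Welch t statistics on
log2 counts with BH adjustment. This per-gene test is far less powerful at
n = 3 replicates than a shrinkage-based DE fit, so recovery checks use five
replicates; the deterministic `make_overlap_tables` constructor provides
exact fixtures for overlap accounting. Per-unit count tables (haemocytes,
glia) are lognormal with a specified coefficient of variation.

## Pipeline and problem sizes

`run_pipeline` is deterministic given (inputs, config, seed): the summary
JSON is byte-identical across runs, with provenance (versions, timestamp,
full config) written to a separate run log. Simulated inputs are written as
real monitor files and parsed back, so every run exercises the same I/O
path as real data.

Default simulated recordings span 31 days against the 30-day analysis
horizon: one spare day ensures a death near the horizon still has the
>24 h silent tail required to call it, while anything later is censored at
the horizon anyway. Validation simulations use cohorts of ~24–32 flies
(the study design's group sizes), 200-pair power sweeps and 500–2000-draw
calibration sweeps, which keep the full suite under a minute of simulation
time on one core.

## Known limitations

* Sleep latency, P(wake)/P(doze) transition metrics and sleep-architecture
  statistics beyond bout counts are not computed.
* No period estimation (periodograms) or free-running (DD) analysis; the
  design assumes entrained 12:12 LD.
* No Cox regression; survival comparisons are two-group log-rank.
* The DEG module reproduces threshold/overlap bookkeeping only; it cannot
  (and does not try to) reproduce any particular upstream DE fit.
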