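# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic-data generator does and does not emulate.

## Behavioral readouts and recovery rate

Trials come from two tests: the grid walk (one scored session per day;
total steps and foot faults counted from video) and the rotating beam (four
trials per day; time, distance and hindlimb drops). Day-level readouts are
the arithmetic mean over that day's trials: foot-fault percentage
`100·f/(f+c)`, speed `distance/duration` in cm/s, and mean hindlimb drops.
A day without usable trials is absent, never imputed; a trial with zero
steps raises an explicit error rather than reporting a deceptive 0%.

The recovery rate of a readout is the OLS slope of its value against the
day over post-stroke days 3, 7 and 14 — the window with the steepest
spontaneous improvement. When all three days exist the three-point slope is
used, otherwise the two-point (3, 14) slope, otherwise the readout is
missing (`slope_mode="three_point_preferred"`; strict two- and three-point
modes are available because either convention is defensible and the choice
can move borderline animals).

## Classification

Per readout, the cohort median of the non-missing slopes is the reference;
an animal votes *good* when its slope lies on the improving side (below the
median for foot faults and hindlimb drops — fewer faults/drops over time —
above it for speed). The final label needs at least two concordant votes;
everything else, including a 1–1 split with a missing readout, is
*neutral*. A slope exactly equal to the median votes *poor* by default
(`tie_vote`), a conservative convention that only matters for discrete or
duplicated data. The labels partition the cohort by construction and are
invariant to animal relabelling.

A median split presumes the two latent groups are of roughly equal size: if
they are not, the median falls inside the larger group's slope cluster and
border animals of that group are necessarily mislabelled, however clean the
data. This is a property of the method, not of the implementation, and it
is why the generator's default cohort is balanced.

## Recovery scores and decay model

Scores normalize each readout trajectory to 0% at day 3 (the maximal
deficit; the pre-stroke baseline is deliberately ignored) and 100% at the
time-matched sham mean. Only the 0% anchor is forced by convention; the
100% anchor and the composite (the unweighted mean of the available
per-readout scores) are this package's declared choices, since several
normalizations are equally defensible. A readout whose day-3 value shows no
deficit relative to sham cannot be normalized and is excluded from the
composite with a warning.

Group score curves are fitted to
`y(t) = plateau + (y0 − plateau)·exp(−k·(t−3))` by bounded least squares
(`k ∈ [0, 10]` per day) with seven multi-starts, `k0` log-spaced over
`[1e-3, 1]`, keeping the best residual sum of squares; tolerances are tight
(1e-14) so noiseless data are recovered to numerical precision. A constant
series short-circuits to the exact flat fit (`k = 0`, rss = 0). Residual
degrees of freedom are `n − 3`. The extra sum-of-squares F test compares
the pooled fit against per-group fits,
`F = ((rss_sh − rss_sep)/(df_sh − df_sep)) / (rss_sep/df_sep)`; a perfect
separate fit with a worse shared fit is reported as `p = 0` and flagged
degenerate.

Ward clustering of per-animal readout vectors (exploratory grouping) is
delegated to scipy's agglomerative linkage; reported merge heights `h` are
Euclidean Ward distances, so the within-cluster sum-of-squares increase of
a merge is `h²/2`. Rows with missing features are excluded and logged.

## qPCR model

Amplification efficiency per gene is the standard-curve estimate
`E = 10^(−1/slope)` from OLS of Cq on log10(input ng) over the non-NTC
dilution points (0.0 ng rows are no-template controls and never enter the
fit); a non-negative slope is an invalid curve and an error, and estimates
outside [1.6, 2.1] warn but are reported as estimated.

Relative expression follows the efficiency-corrected ratio
`E_t^ΔCt_t / E_r^ΔCt_r` with `ΔCt = mean Cq(control) − mean Cq(sample)`,
Gapdh as reference, and technical replicates collapsed to animal means
before any group statistic (animals, not wells, are the experimental unit).
Setting `force_e2=True` reproduces plain `2^ΔΔCt`. Control-group
convention: sham is the control wherever present; the stroke–stroke
contrast uses the well-recovered group as control, so those ratios read as
poor-relative-to-good.

The randomization test reallocates whole animals (their target+reference Cq
pair moves together) between the two groups, preserving group sizes. The
statistic is the log ratio, which makes the two-sided test symmetric under
group swap. With `C(n1+n2, n1) ≤ 20,000` (configurable) all reallocations
are enumerated and `p = #{|stat| ≥ |observed|}/N`, the observed allocation
counting itself — exact small-sample behavior, granular in multiples of
`1/N`. Otherwise `n_perm` random reallocations give the add-one-corrected
estimate `(hits + 1)/(n_perm + 1)`, which is never exactly zero. The SE of
the ratio is a nonparametric bootstrap over animals within group, reported
as the SE of the log ratio and the back-transformed range
`ratio·exp(∓SE)`. Both the permutation statistic and the bootstrap SE are
reconstructions: the published REST tool does not document its internal
statistic, and the log-ratio choice is recorded here as ours.

With the default endpoint group sizes (5/4/5, 3/2/3, 4/3/5 for
good/poor/sham at days 14/28/56), the day-28 poor-vs-good contrast
enumerates only C(5,2) = 10 reallocations, so its smallest achievable
two-sided p is 0.2 — such cells can never be significant at α = 0.05, which
the direction table then honestly reports as `ns`.

## Synthetic-data generator

The behavioral generator emulates the study design: 30 stroke and 14 sham
animals, sessions at baseline (day −3) and days 1, 3, 7, …, 56; four beam
trials and one grid session per day. Every stroke animal draws a latent
class (default balanced 15/15, by exact allocation), and for each readout a
latent one-phase trajectory: initial day-3 deficit, plateau expressed as
the fraction of the deficit recovered (good 0.82–0.92, poor 0.25–0.35), and
rate constant per day (good 0.07–0.10, poor 0.08–0.13). These ranges were
sized so the induced day-3–14 slope distributions of the two classes are
disjoint (a noiseless cohort is perfectly separable) and so the good group
sits near 50% and the poor group near 20–25% recovery score two weeks
post-stroke, with the poor group plateauing early. Sham animals hold their
per-animal baseline level throughout.

Raw measures are back-derived from the latent readout value so the derived
readouts invert the generator: beam duration = 120 cm / speed (exact);
grid steps uniform-integer in 80–200 with
`faults = round(steps·pct/100)`; drops rounded to integers. Trial noise is
Gaussian on the latent readout value (defaults 2.0% foot faults, 0.5 cm/s,
0.8 drops — the study reports no per-trial variances, so these are
calibrated to the package's own recovery properties: ≥ 90% label agreement
at default noise, ~94% measured over 200 cohorts). Integer quantization
bounds the foot-fault round trip at ≤ 100/(2·80) ≈ 0.6% and drops at ±0.5;
speed is exact. Missingness is injected per (animal, day, test) — the two
beam readouts share trials, so they vanish together — at 5% by default,
sparing days 3/7/14 unless the neutral-group path is being exercised.

The qPCR generator plants per-gene efficiencies (1.85–2.0) and group fold
changes vs. sham keyed by (gene, region, hemisphere, endpoint, group); the
default table puts the well-recovered group at the sham level and gives the
poorly recovered group the contralesional factors this study design centers
on (Adora2a 4.5×/2.3× in cl-MOp at days 14/56, Drd2 7.5×, Pde10a 2.4× in
cl-Str at day 56, Lingo1 0.6×, …), with contrasts reported significant but
without a printed factor set to modest 1.5–2-fold. Cq values follow
`base_g − log_E(R)` plus animal-level (0.2 cycles) and replicate-level
(0.3 cycles) Gaussian noise; the reference gene is unregulated everywhere.
Dilution series follow the exact standard-curve model over 2.5–200 ng with
flagged 0-ng NTC rows.

What the generator does *not* emulate: surgical mortality and attrition,
weight loss, beam-trial truncation when an animal drops, day-1 deficits
milder than day 3, floor/ceiling compression of readouts near the sham
level, region-specific baseline Cq structure, inter-plate qPCR effects, and
any correlation between behavioral class and qPCR noise. Passing tests
therefore demonstrate that the estimators invert this idealized design with
realistic noise — not that the defaults match any particular laboratory's
variance structure.

## Determinism

All generator randomness flows from one PCG64 stream per config seed, and
the pipeline derives independent child seeds per stage from the run seed;
equal configs give byte-identical CSVs. The exhaustive permutation path is
deterministic by construction; Monte-Carlo permutations and bootstraps are
seeded. Provenance sidecars carry the config hash (output path and log
level excluded), seed and package version, and deliberately no timestamps.

## Known limitations

- The 100% recovery-score anchor and the composite definition are package
  choices (see above); published per-animal scores built with a different
  anchor will differ systematically.
- The median split assumes balanced latent groups and always splits a
  cohort near 50/50; it cannot discover that one group is rare.
- Randomization p-values are granular at small n (multiples of 2/N for
  equal groups); no multiple-testing correction is applied across genes,
  regions or endpoints, matching common practice for REST-style reports —
  the direction table should be read accordingly.
- The decay model forces `k ≥ 0`; genuinely deteriorating groups would fit
  the boundary.
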