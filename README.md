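# strokerecovery

Analysis pipeline for spontaneous functional recovery after experimental
cortical stroke in mice: behavioral recovery-rate classification,
recovery-score curve modelling, and efficiency-corrected qPCR
relative-expression analysis with randomization significance testing.

## The problem

After a focal cortical stroke, some mice recover sensorimotor function well
and others poorly, and the molecular correlates of that difference are
spread across brain regions and time. Linking the two requires (1) an
objective, per-animal dichotomization of recovery from longitudinal behavior
and (2) a group-wise gene-expression comparison that is honest about small
group sizes and imperfect PCR efficiencies. This package implements both
halves as a reusable, tested pipeline, plus a synthetic-data generator that
emulates the full study design so every stage can be validated against known
ground truth without any external data.

## Methods at the core

**Recovery rate and classification.** From grid-walk and rotating-beam
trials, three readouts are derived per animal and day: foot-fault percentage
`100·f/(f+c)`, beam speed (cm/s), and hindlimb drops. Per readout, the OLS
slope *m* of value vs. day over post-stroke days 3–14 is the "recovery rate";
the cohort median of each readout's slopes is the reference, and an animal
votes *good* on a readout when its slope is on the improving side of the
median (below it for foot faults and drops, above it for speed). At least two
concordant votes give the final *good*/*poor* label; conflicting or
incomplete votes give *neutral*.

**Recovery scores and decay fits.** Each deficit trajectory is normalized to
a recovery score: 0% at day 3 (maximal deficit), 100% at the time-matched
sham mean. Group score curves are fitted by bounded least squares to a
one-phase decay `y(t) = plateau + (y0 − plateau)·e^(−k(t−3))`, and the extra
sum-of-squares F test asks whether one shared curve fits the good and poor
groups as well as separate curves do.

**qPCR relative expression (Pfaffl/REST model).** Per-gene amplification
efficiencies come from dilution-series standard curves, `E = 10^(−1/slope)`.
The expression ratio of a sample vs. a control group is

    ratio = E_target^ΔCt_target / E_ref^ΔCt_ref,   ΔCt = mean Cq(control) − mean Cq(sample)

with Gapdh as the reference gene and group means over animal-level replicate
means. With `E = 2` this is exactly the classical `2^ΔΔCt`. Significance is a
fixed-reallocation randomization test: whole animals are reallocated between
the groups (group sizes preserved), the statistic is the log ratio, and the
two-sided p counts reallocations at least as extreme — enumerated
exhaustively when feasible, Monte Carlo with add-one correction otherwise.
Ratio dispersion is a bootstrap over animals.

## Worked example

```python
import strokerecovery as sr

# behavioral cohort: 30 stroke / 14 sham animals, days BL..56
trials, truth = sr.gen_behavior_cohort(sr.BehaviorSimConfig(seed=1))
readouts = sr.daily_readouts(trials)
classes = sr.classify_cohort(readouts[readouts.cohort == "stroke"])
print(classes["label"].value_counts().to_dict())
# {'good': 16, 'poor': 14}

# qPCR: efficiencies from the dilution series, then group contrasts
ds = sr.gen_qpcr_dataset(sr.QpcrSimConfig(seed=1))
eff = sr.efficiency_table(ds.dilution)          # Gapdh: E=2.013, Adora2a: E=1.932
tab = sr.relative_expression_table(ds.cq, efficiencies=eff, n_perm=10000, seed=1)
```

The classification table carries the per-readout slopes and votes, e.g.

```
animal_id  slope_ff  slope_speed  slope_hld label
     S001 -0.262630    -0.028888  -0.072581  poor
     S003 -1.254592     0.117565  -0.177419  good
```

(S003 loses foot faults five times faster than S001 and gains speed, so it
votes good on all three readouts). The expression table reads, for the
contralesional motor cortex at day 14, poor relative to good:

```
Adora2a cl-MOp P14: ratio=3.46 p=0.0079 [3.21, 3.73] (exhaustive)
```

i.e. Adora2a is ~3.5-fold higher in poorly recovered animals, with an exact
permutation p over all C(9,4) reallocations and a bootstrap SE range.

A full run — synthesis, behavior, qPCR, and the direction-of-change summary
table — is one call (or `srp run --config run.yaml` from the shell):

```python
sr.run_pipeline(sr.RunConfig(outdir="artifacts", seed=7))
```

Every output CSV gets a JSON provenance sidecar (config hash, seed,
version); a rerun with the same config and seed is bit-identical.

## Command-line interface

```
srp run       --config run.yaml          # full pipeline
srp synth     behavior|qpcr              # synthetic tables + truth files
srp behavior  classify|score|fit-decay   # behavioral stages
srp qpcr      efficiency|ratios          # qPCR stages
```

Exit codes: 0 ok, 2 bad config, 3–6 synth/behavior/qpcr/report stage
failure. See `docs/methods.md` for the model details, defaults and known
limitations.
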