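# statedyn

Transient brain-state dynamics from resting-state MEG amplitude envelopes,
linked to sleep quality and cognition through multivariate brain–behavior
statistics.

## The problem

Resting-state MEG activity can be described as a sequence of short-lived brain
states: a group-level hidden Markov model (HMM) on parcel amplitude envelopes
assigns every sample to one of K recurring activity patterns, each a unique
P-dimensional multivariate normal (mean vector + covariance matrix over
parcels). From each subject's Viterbi-decoded state time course, four temporal
characteristics per state summarize that subject's dynamics:

- **FO** — fractional occupancy, the proportion of time the state is active;
- **MLT** — mean lifetime (s), the average visit duration;
- **NO** — number of occurrences, the count of distinct visits;
- **MIL** — mean interval length (s), the average gap between visits.

The resulting subjects × 4K matrix is related to behavioral profiles —
seven ordinal sleep-quality components (PSQI-style, 0 = no problem … 3 =
severe) and thirteen cognitive scores — with **partial least squares**: the
singular value decomposition of the cross-covariance `C = XᵀY/(n−1)` of the
z-scored blocks yields paired saliences (u, v) maximizing the covariance of
the latent scores `Xu` and `Yv`. Significance comes from a subject-shuffling
permutation test; interpretation uses structure loadings (variable–score
correlations) thresholded at |loading| > 0.2. A second-level **moderation
regression** (behavior latent ~ brain latent × age, standardized OLS) asks
whether the brain–behavior link survives, and varies with, age; finally the
brain profiles of the sleep and the cognition analyses are compared by
correlating their loading vectors and subject scores.

Because suitable cohort data cannot ship with the package, a synthetic cohort
generator with planted ground truth (known Markov dynamics, a planted rank-1
brain–behavior salience, configurable age and moderation effects) makes every
stage verifiable end to end.

## Worked example (command line)

```bash
statedyn simulate --out sim --seed 3                      # 200-subject synthetic cohort
statedyn fit-hmm --envelopes sim/envelopes.h5 --states 3 --restarts 2 --seed 3 --out model.h5
statedyn metrics --envelopes sim/envelopes.h5 --model model.h5 --out metrics.csv
statedyn pls --brain metrics.csv --behavior sim/behavior.csv \
             --columns sleep --n-perm 199 --seed 3 --out pls_sleep
statedyn moderate --scores pls_sleep --behavior sim/behavior.csv --out mod.json
```

The PLS step prints the component singular values and permutation p-values:

```
singular values: [1.2195, 0.389, 0.1836, 0.126, 0.0424, 0.0263, 0.0166]
permutation p:   [0.005, 0.055, 0.645, 0.525, 0.995, 0.88, 0.635]
```

— exactly one significant brain–sleep component (p = 0.005 with 199
permutations), as planted. The moderation step then reports standardized
coefficients:

```
       brain: beta=+0.397  t(196)=+6.30  p=1.926e-09
         age: beta=-0.244  t(196)=-3.88  p=0.0001445
 brain_x_age: beta=-0.004  t(196)=-0.06  p=0.9487
```

— the brain–sleep association holds beyond age, age itself carries a negative
effect, and there is no interaction (none was planted). Running the cognition
PLS on the same metric matrix and comparing profiles
(`statedyn compare --a pls_sleep --b pls_cog --out cmp.json`) prints

```
overall loading r = 0.941 (p = 5e-06); score r = 0.945
```

— the sleep- and cognition-related brain patterns are essentially the same,
as expected when both are generated from one planted salience.

`statedyn run-all --out run --seed 5` performs the whole chain (simulation →
group HMM → metrics → both PLS analyses → moderation → comparison) and writes
a deterministic `summary.json`.

## Layout

- `statedyn.simulate` / `statedyn.config` — synthetic cohorts with ground truth
- `statedyn.preprocess` — Hilbert envelopes, z-scoring, concatenation
- `statedyn.hmm` — Gaussian-emission HMM (EM fitting, Viterbi decoding)
- `statedyn.metrics` — FO / MLT / NO / MIL and the brain feature matrix
- `statedyn.pls` — covariance-maximizing PLS + permutation test
- `statedyn.second_level` — moderation regression, profile comparison
- `statedyn.pipeline` / `statedyn.cli` — orchestration and the `statedyn` CLI

See `docs/methods.md` for the modeling choices and their rationale.
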