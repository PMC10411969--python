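# Methods

This note documents the models, statistical procedures and numerical
choices behind `mirrorcode`, in the spirit of a package methods appendix.
The README describes what the pipeline computes; this note records how and
why.

## Trial model and relative time

A trial is a strictly increasing sequence of eight event times on a
per-trial clock (ms), with the start-button press (BPR) at 0: BPR, LED
onset, start-button release (RLS), object touch (TCH), object-movement
onset (MOV), hold onset (HLD), reward (REW), withdrawal (WDR). Seven of
these events (all but MOV) span six epochs, each divided into four
equal-duration quartile bins — 24 bins per trial. Bins are half-open
`[edge, next_edge)`, right-edge exclusive, so no spike is counted twice; a
spike exactly at WDR falls outside the trial. Discharge rate per bin is
count/width in Hz. Rates in Hz are a convention, not a claim: all rank
tests are invariant to strictly monotone common scalings, and the LDA
classifier uses the same unit in training and test.

MOV is deliberately not a grid node (six epochs match the event structure
used throughout the analysis); it is used only by the mirror-neuron screen,
which needs the two manipulation sub-phases. The screen's five windows are
baseline `[LED−750, LED−250)`, approach `[RLS, TCH)`, manipulation-I
`[TCH, MOV)`, manipulation-II `[MOV, HLD)` and hold `[HLD, HLD+150)` ms.
When `LED − 750` precedes trial start the baseline is truncated at BPR and
flagged; window rates always use the actually covered duration. The
baseline window participates only in the screen, not in any per-bin
analysis.

## Statistics

All rank statistics are implemented in-package (the permutation null reruns
them on hundreds of thousands of small problems and needs vectorised matrix
forms); scipy and statsmodels implementations serve as independent oracles
in the test suite only.

* **Kruskal–Wallis** and **Friedman** use midranks with the standard tie
  correction and the chi-square approximation (k−1 df). Exact small-sample
  tables are not used: trial counts are ≥ 8 per condition and the
  approximation is the field's default. A fully tied sample returns
  (0, p=1).
* The **rank-sum** test uses the normal approximation with midrank tie
  correction and a 0.5 continuity correction, two-sided. Tests verify
  agreement with exhaustive enumeration on small samples; the approximation
  is loosest deep in the null (p near 1), which never affects decisions.
* **Benjamini–Hochberg** is the standard step-up procedure. Family sizes
  are always passed explicitly by the caller, mirroring the analysis
  contract (e.g. all neurons × 24 bins per task for action coding;
  examined bins × 3 for the same-discharge method; × 2 for the two
  preference polarities; × 1 for cross-task classification). Bins excluded
  for empty trial groups leave the family.
* **Diagonal LDA** fits per-class means and a single pooled per-feature
  variance (within-class SSE / (n − k)) with priors from training
  frequencies. Zero pooled variances (silent bins of synthetic data) are
  floored at 1e-9 Hz². Prediction maximises the Gaussian log-density plus
  log prior; exact ties go to the lowest class index in model order. For
  one feature, equal priors and a pooled variance this reduces to
  nearest-class-mean, which the vectorised bootstrap exploits; a test
  asserts equivalence with the full model.

## Classifier bootstrap

Single-neuron accuracy per (bin, mode) comes from n = 1000 bootstrap
resamples. The trial budget T is the largest multiple of 8 not exceeding
the minimum trial count over the six conditions (neurons under 8 are
excluded from classification). Per resample, T trials per condition are
drawn with replacement and partitioned into 8 folds; the classifier is fit
on the training task's 7/8 and tested on the held-out fold of the test
task; resample accuracy is the mean of the 8 fold accuracies. Cross-task
folds are formed on the jointly resampled trial sets of both tasks so fold
sizes are identical across the four modes; a config switch
(`train_full=True`) instead trains on all T training-task trials, since the
choice between the two geometries is not dictated by the analysis contract.
The bootstrap p-value against chance is the plain fraction of resamples
with accuracy ≤ 1/3 (no +1 smoothing; the minimum achievable p is 0).
Accuracies are accumulated as integer correct counts so the comparison with
chance (count ≤ 8·T/8· … = 24m/3) is exact.

Because trials are drawn with replacement, a trial can appear in both a
training and a test fold within a resample. This is a property of the
resampling contract, not corrected here; it inflates accuracy slightly when
the trial pool is shallow (visible for ~16 trials, negligible at 64), which
the test suite accounts for.

**Determinism.** Within each condition, the per-bin rate values are sorted
canonically before index-based resampling. Every bootstrap p-value is
therefore exactly invariant to the order in which trials are stored — a
stronger property than distributional invariance, and what makes pipeline
outputs byte-reproducible under a fixed seed.

## Preference similarity index

For a candidate bin, per-task mean rates over *all* available trials (not
the T-multiple-of-8 classifier subset — the index needs no fold structure)
are reduced to indicator vectors marking the highest-rate (positive
polarity) or lowest-rate (negative polarity) action: divide by the maximum
(or subtract the maximum and divide by the signed minimum) and floor, with
a 1e-12 tolerance added before flooring to guard against 0.999… from float
division. The index is the dot product of the unit-normalised indicators: 1
iff the indicator sets coincide. Internally the comparison "index < 1" is
evaluated on integers (dot² < |A|·|B|), so no floating-point threshold is
involved. All-equal resampled means (possible with discrete counts) mark
all three actions and thus count conservatively as index < 1 against a
single-preference partner. The scalar API refuses all-equal inputs, which
the upstream Kruskal–Wallis gate excludes by contract.

## Independence permutation null

"Assigned to a different neuron" is read literally: re-pairings are
fixed-point-free permutations (derangements), sampled by rejection and
de-duplicated by hashing, with an explicit error if the requested number of
unique derangements cannot exist. Per-task coding decisions are invariant
under re-pairing, so the Kruskal–Wallis/BH stage is computed once and only
the pairing-dependent stages rerun on chimeric (execution-source,
observation-source) neuron pairs — the same code path as the observed
analysis, via a pair-based internal API. The null re-pairs pooled across
the population (no per-animal stratification; the generator has no animal
structure). Inside the null the preference and LDA bootstraps default to
n = 200 resamples instead of 1000 so that 250 full reruns stay at desk
scale; the depth is configurable back to 1000. Null summaries are central
percentile intervals over resample counts of shared bins and of neurons
with ≥ 1 shared bin.

## Accuracy-angle analysis and threshold method

Each of the neurons × 12 action-period bins contributes a point
(e2o − chance, o2o − chance) in percentage points (chance = 100/3); its
angle is atan2(e2o_rel, o2o_rel) in degrees. Points with both coordinates 0
are undefined, excluded and counted. The angle histogram uses 2° bins over
(−90°, 90°]; raw counts (not densities) are fit, and a sensitivity test
shows the boundary moves < 3° between 1° and 5° bin widths. The model is a
sum of k Gaussians a·exp(−((x−b)/c)²) fit by nonlinear least squares;
adjusted R² uses p = 3k parameters.

Initial guesses: k = 1 starts at (max count, circular-mean angle, 20°);
k = 2 centers start at the two reference lines 0° and 45° with widths 15°
and amplitudes from the local histogram heights. Two-Gaussian fits are
accepted only with two distinct modes: centers ≥ 5° apart, positive
amplitudes, and an interior trough strictly between the peaks on a 0.1°
evaluation grid (the trough is the boundary; the flanking maxima are the
peaks). Fitting uses three deterministic starts (base centers and ±5°
shifts) and keeps the lowest-SSE valid fit, with SSE rounded to 1e-6 before
comparison and the evaluated curve rounded to 1e-6 before locating
arg-extrema; both roundings exist because nonlinear least squares on noisy
bootstrap histograms is numerically borderline, and sub-ULP differences
must not flip a near-tied grid cell or basin choice between
identically-seeded runs. If all deterministic starts fail, up to 50 retries
jitter the centers by ±10° using the stage's seeded generator. Fits with
fewer than 30 points are refused.

Thresholds 5–15 pp on o2o_rel (strict inequality) filter the points; the
across-threshold mean of the per-threshold boundaries is the average
boundary. Bootstrap CIs (95%, n = 1000) resample the *full* point set with
replacement and re-apply each threshold; per-resample two-mode failures are
counted, and the analysis aborts if any threshold fails in more than 10% of
resamples. The pipeline drops thresholds retaining fewer than 45 points
(1.5× the fit floor) before this stage and records them in the manifest:
desk-scale synthetic runs produce roughly a third of the angle points of a
full recorded dataset, and the strictest thresholds can otherwise run dry.
The threshold method labels bins with o2o_rel strictly above 10 pp as
shared iff angle ≥ boundary — no per-bin statistical test.

## Segments

A segment is a maximal run of consecutive action-period bins with one code
type; observation-only bins merge into non-shared, unlabeled bins break
runs. Start positions are reported in action-period coordinates 1–12.
Histograms are (start, duration) count matrices per code type, optionally
normalised by the total bins of that type.

## Population decoding

Neurons were not recorded simultaneously, so population "trials" are
pseudo-trials: per bootstrap resample every neuron independently
contributes 8 sampled trials per condition (re-sampled anew each resample,
not fixed once), concatenated by index into a trials × neurons feature
matrix. Eight-fold CV holds out one pseudo-trial per condition per fold;
cross-task modes test on the held-out fold of the other task. The interval
reported for population accuracy is the central 90% bootstrap interval (95%
elsewhere in the package). By construction noise correlations between
neurons are absent. Subpopulation rules: neurons with ≥ 1 shared bin
(cross-task method); neurons whose threshold-method labels are all shared;
and per-bin sets of neurons shared in exactly that bin (variable size,
possibly empty — recorded as missing).

## Synthetic data generator

The generator emulates the structure the analysis needs and nothing more:

* **Event skeleton.** Seven inter-event durations drawn uniformly per task
  and action; default bounds are the tabulated central-95% duration ranges
  of the monkey (execution) and human actor (observation) per action, whose
  midpoints reproduce the published mean durations (e.g. hold→reward
  566 ms). The generating distribution behind those printed bounds is
  unknown; uniform is the simplest model matching both bounds and means and
  is a documented choice, not a claim. The tabulated data do not separate
  the two manipulation sub-phases, so MOV is placed uniformly inside
  touch→hold; a fully explicit 7-interval specification is also accepted.
* **Spikes.** Inhomogeneous Poisson with piecewise-constant rate per
  quartile bin — constant rate within each bin matches the analysis
  resolution; no within-bin rate structure is modelled.
* **Profiles.** Defaults: 10 Hz base rate; +20 Hz action-independent
  elevation over the three action-period epochs in both tasks (without it
  no simulated neuron would pass the Friedman screen); +20 Hz for the
  preferred action (3× contrast) inside a per-neuron contiguous coding
  window of 1–4 action-period bins. `shared` uses one preferred action in
  both tasks; `non_shared` cyclically permutes the preference between
  tasks, guaranteeing coding in both tasks with different preference;
  `obs_only` codes only during observation; `non_coding` never. The default
  mix is 20/50/10/20% with 64 trials per condition.
* **Why short windows.** Real recordings show time-localised action
  segments — one-bin segments are the most frequent and durations ≥ 7 bins
  are rare — and window length controls the power of the independence null:
  with long or population-wide aligned windows, chance re-pairings match
  preferences in 1/3 of overlapping bins and the null grows to the size of
  the planted signal. Short random windows are both the realistic regime
  and the one in which the permutation test can detect dependence.

What passing tests on this generator do **not** show about real data: no
rate drift or history dependence within trials, no non-Poisson dispersion,
no noise correlations between neurons, no behavioural variability beyond
uniform durations, no animal- or session-level structure, and planted
effects are step-like rather than graded. Calibration results (false-positive
control) transfer only insofar as real rates meet the rank tests'
exchangeability assumptions.

## Problem sizes and defaults

Top-level defaults are the analysis constants: α = 0.05, bootstrap
n = 1000, permutation n = 250 (in-null bootstrap 200), thresholds 5–15 pp,
chance 1/3, 24 bins with action period 9–20. The test suite runs recovery
on 60 neurons × 64 trials, calibration on 177 non-coding neurons × 16
trials, and the end-to-end determinism check on 60 neurons with bootstrap
depths 300/100/100 — sizes chosen to exercise every stage at full
statistical contracts while staying desk-scale. `scripts/acceptance.py`
uses 100 neurons so that all 11 angle thresholds retain enough points at
any seed. Every stochastic stage consumes a child generator spawned
deterministically from one master seed.

## Known limitations

* The three shared-code criteria disagree by design (strictness ordering
  discharge ⊂ preference/LDA is data-dependent); no combined decision is
  offered.
* The bootstrap's train/test trial duplication (above) biases single-neuron
  accuracy upward for shallow trial pools.
* Two-Gaussian fits on sparse histograms can fail legitimately; failures
  are counted and surfaced rather than silently retried forever.
* The permutation null holds per-task coding fixed by construction; it
  tests only the independence of the execution/observation pairing, not the
  correctness of the coding stage itself.
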