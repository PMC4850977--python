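# Methods

This note records the models, conventions and numerical choices behind
`skimu`, in the order the pipeline applies them.

## Signal model and preprocessing

All analyses operate on uniformly sampled scalar series: roll angle per
body location at 100 Hz and two 13-cell insole pressure streams at 50 Hz.
The roll sign convention is fixed throughout: positive roll = leaning
right = a right turn.

**Foot pressure ratio.**  The left/right loading contrast is
`r = (F_L - F_R) / (F_L + F_R)` with `F_L`, `F_R` the per-sample sums over
each insole's 13 cells.  The literature this analysis follows never writes
the ratio formula, which makes the sign the single most consequential free
choice in the package: we pick the signed contrast, positive when the left
foot carries more load.  Because the outer foot of a right turn is the left
foot, this makes the ratio co-vary *positively* with roll, so pattern
correlations come out positive for faithful locations.  An outer-foot
fraction `(1 ± r)/2` is derived from the same quantity per segment.
Samples whose two-foot total falls below a floor (default `1e-6` N/cm²,
e.g. airborne phases) are flagged invalid as NaN and interpolated over
before correlation.

**Rate reconciliation.**  Correlating the ratio with a roll trace needs one
grid; the ratio is upsampled 50 → 100 Hz by linear interpolation (no
extrapolation past the endpoints), preserving the denser signal.  The
common length is the shorter of the two series.

**Smoothing and normalization.**  A centered five-point moving average with
truncated edge windows (output length = input length) precedes
standard-score normalization `z = (x - μ̂)/σ̂`.  The sample (n−1) standard
deviation is used everywhere, matching the `N_t - 1` denominator of the
pattern correlation.  Constant traces are rejected by name rather than
silently zeroed.

## Placement selection

**Pattern correlation** is the Pearson product-moment correlation computed
as the explicit normalized cross-product sum; each location is summarized
by the *median* over trials (robust to single-trial dropouts; missing
traces leave NaN cells that the median skips).

**Clustering** is agglomerative with centroid linkage
`d(r, s) = |x̄_r - x̄_s|` on correlation distance.  Two readings of
"clustering on correlation distance" are supported:

- `reference` (default): each location sits at the scalar coordinate
  `1 - R_l`, its distance to the foot-pressure reference, which is itself a
  leaf at 0.  This follows from `R_l` being defined per location against
  the foot-pressure pattern.  In one dimension, Euclidean centroid linkage
  (scipy's `method="centroid"`) is exactly `|mean - mean|`.
- `pairwise`: the full matrix of `1 - median pairwise correlation` among
  the 16 roll signals plus the ratio.

**Turn segmentation.**  A turn is a maximal run of constant roll sign.
Zero samples close the preceding run (deterministic, boundary-exact);
leading zeros attach to the first signed run.  Runs shorter than
`min_duration_s` are merged into the following run (the last merges
backwards) and same-side neighbours coalesce.  The default is 0.5 s — about
a quarter of the shortest plausible turn — because measurement noise near a
zero-crossing otherwise produces one-to-two-sample sign blips that inflate
the turn count.  Setting 0 reproduces raw zero-crossing counting, which is
what the raw-count `detection_table` reports by default so that
spurious crossings surface as >100% cells.  The **turn-detection measure**
is `detected / actual × 100`, rounded half-away-from-zero to an integer
percent; it is 100 exactly when every actual turn and nothing else is
found.

**Ranking.**  A location passes the strong-correlation flag at median
`R_l ≥ 0.80` (the conventional strong-correlation threshold) and the
perfect-detection flag when every trial detects 100% under the default
(jitter-suppressed) segmentation.  Ranking order: both flags, then higher
median, then single midline placements (head, spine, pelvis) ahead of L/R
sensor pairs — a proxy for the practical cost and distraction of paired
sensors, which no signal can measure — with alphabetical tie-breaks.  The
selected location is the top-ranked dual-flag candidate, or none.

## Performance statistics

**Branched two-sample testing.**  Per measure (turn duration; per-turn max
outer-foot fraction), groups are left vs. right turns.  A Kolmogorov–
Smirnov test per group screens normality against a normal with that group's
estimated mean and sd; estimating the parameters from the same data makes
the screen conservative (the Lilliefors caveat), which we accept and log.
Variance equality uses a two-sided F ratio at α = 0.05 — chosen over Levene
or Bartlett as the simplest test consistent with normal groups, and
configurable in principle via `variance_f_test`.  Equal variances select
the pooled t-test (`df = n_L + n_R - 2`); unequal select Welch.  The Welch–
Satterthwaite df is kept real-valued internally (p-values use it) and
reported as its integer part, matching conventional table lookups.
Decisions compare `|t|` with the two-sided critical point
`t_{α/2}(df)`; the signed statistic (left minus right) is reported
alongside.

**Adaptation effect.**  The per-trial total duration (sum of the trial's
turn durations, exact by construction) is correlated with the attempt
index.  Attempts that were made but yielded no usable data stay on the axis
as gaps — the practice count includes them — and contribute no point.
Significance uses `t = r√(n-2)/√(1-r²)` on the non-missing count; an OLS
line accompanies the correlation.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes, with
ground truth for recovery tests.

- **Latent roll**: one half-sine per turn, sign by side, alternating and
  starting with a right turn; amplitude 30° by default.  Samples sit at
  half-integer phase so the waveform never hits an exact zero and sign runs
  map one-to-one to turns.
- **Per-location traces**: `gain × latent` plus session-level Gaussian
  noise (default sd 1°), location-specific noise, and for arm/hand
  locations a 2 Hz oscillation with random phase emulating pole swing.
  Default profiles make the ranking nontrivial and mirror the fidelity
  ordering seen in practice: trunk/leg locations gain 1.0 with noise
  0.5–7°, pelvis cleanest; head attenuated (gain 0.8) and noisy; arms and
  hands gain 0.6 with heavy noise plus the oscillation.  No field data pins
  per-location roll amplitudes, so these are free parameters chosen once.
- **Insoles**: the outer foot's share of a constant two-foot force follows
  a raised cosine from 0.5 up to the turn's peak fraction and back; cell
  pressures split the foot force over fixed cell weights plus small noise.
- **Study conditions** (defaults): 8 trials × 6 turns; side-mean durations
  2.08 s (right) / 1.68 s (left) and duration sd 0.32 s — the sample
  statistics of a real giant-slalom training session; outer-foot peak
  fractions 0.86 (left turns, sd 0.047) / 0.81 (right turns, sd 0.086),
  whose unequal spreads exercise the Welch branch; adaptation slope
  −0.05 s per turn per attempt (the session-level trend of ≈ −0.28 s per
  attempt spread over six turns).  Configs whose drift drives a mean turn
  duration to ≤ 0.2 s are rejected.
- **Randomness**: a per-attempt generator derived from `(seed, attempt)`
  makes the full-signal path and the table-level Monte-Carlo shortcut
  (`simulate_turn_table`) draw identical turn parameters; missing attempts
  are manifest-level only.

**What the generator does not emulate** — and hence what passing tests do
not show about recorded data: sensor drift and fusion artifacts, terrain
and gate-geometry variation, pitch/yaw coupling, airborne or skidding
phases, and any within-turn shape variability beyond the half-sine.  One
structural consequence worth knowing: because the roll is a half-sine and
the loading curve a raised cosine, the two waveforms are not affine images
of each other, so even a noiseless location's pattern correlation tops out
near 0.97, not 1.0.

## Statistical behavior (measured by the suite)

The test suite measures, rather than assumes: type-I error of the full
branched asymmetry cascade on null sessions ≈ 0.05 (asserted within
[0.02, 0.09] over 1000 replicates); power of the duration test at the
default left/right effect size ≈ 1.0 over 200 replicates (asserted ≥ 0.80),
both at the table level and through full signal segmentation.  The
max-pressure-ratio measure at its default effect size (0.86 vs. 0.81 with
the unequal sds above) has theoretical power only ≈ 0.7 at n = 24 per side;
the suite therefore does not assert a power floor for it — a property of
those study conditions, not of the implementation.

## Problem sizes

Defaults keep everything desk-scale: a session is ≈ 8 × 12 s × 100 Hz × 16
locations ≈ 150 k roll samples; Monte-Carlo checks use the table-level
shortcut (1000 null replicates) or a single-location config (200 power
replicates), so the full suite runs in well under a minute.

## Known limitations

- Single-athlete, single-session framing: nothing here pools across
  athletes or models between-session variance.
- The comfort/distraction dimension of placement is represented only by the
  midline-before-paired ranking rule; it is a proxy, not a measurement.
- The K-S screen with estimated parameters is conservative; swap in a
  Lilliefors-corrected test if normality decisions matter downstream.
- Centroid linkage in `pairwise` mode treats the correlation-distance
  matrix as if Euclidean; inversions are possible in principle.
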