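# Methods

This note documents the models and procedures fatiguekit implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical decisions that affect results.

## Protocol model

The fatiguing task (FT) is modelled as a cue schedule: `n_cycles` windows of
`on_s` seconds of contraction followed by `off_s` seconds of rest, window
*k* starting at *k*·(on+off). The standard protocol is 270 × (1 s + 1 s) =
9 min. Segmentation is **cue-driven**: contraction windows come from the
schedule, not from force-onset detection, because the task is visually
prompted and the cue clock and data streams share a session-relative time
origin (t0 = 0 at stream start). Each segment holds `round(rate · on_s)`
samples (48 at the 47.75 Hz force rate).

The assessment task (AT) is a 4-minute bimanual object-hit task: 480 balls
released two per second from 16 evenly spaced bins across a 76 × 44 cm
workspace, falling at 15–30 cm/s toward two 1.5 × 0.5 cm paddles; balls are
0.75 cm across. The workspace is treated as a single shared field split
into per-hand halves at the midline, with both paddles free to cross it.

## Force analysis

**MVC (FWHM-median).** A contraction profile is baseline-corrected by the
minimum over its leading and trailing 10% of samples (resting force), and
the half-maximum crossings are located by linear interpolation between the
bracketing samples. The MVC estimate is the median of the corrected samples
from the first inner sample after the first crossing to the last inner
sample before the last crossing. For three repeats the session MVC is the
highest of the three medians. Baseline handling and crossing interpolation
are implementation choices; for clean profiles with a quiet baseline they
change nothing, for noisy baselines they keep the estimate anchored to the
contraction rather than the offset.

**Per-contraction AUC.** Trapezoidal integral of the raw (uncorrected) force
over the segment's sample span, in force·s. No baseline correction is
applied to AUCs.

**Fatigue slope.** The first `discard_first` (default 10) contractions are
excluded as familiarisation; the remaining AUCs are regressed on the
original contraction index by OLS. With 270 cycles this leaves 260 points.
The slope β (AUC units per contraction) is the fatigue index; the reported
standard error is the usual OLS slope SE, and `residual_se` is
√(SS_res/(n−2)).

## EMG analysis

Raw EMG (2048 Hz) is bandpassed 10–500 Hz with a 4th-order Butterworth
filter applied forward–backward (zero phase). Zero-phase filtering keeps
contraction windows aligned with the cue clock at the cost of doubling the
effective order; that trade-off is deliberate and documented here because
segment-level statistics are window-sensitive while the analysis does not
depend on the exact roll-off slope.

The envelope is the magnitude of the analytic signal (Hilbert transform) by
default; rectification followed by a 6 Hz 2nd-order zero-phase low-pass is
available as `method="rectify_lowpass"` (tiny filter undershoot is clipped
at zero). Which envelope a given lab uses varies; the Hilbert envelope is
the default because it is parameter-free and tracks amplitude modulation
with no added lag or smoothing bandwidth to choose.

During the FT the envelope goes through the identical segmentation/AUC/OLS
pipeline as force (shared code, so the two slopes are definitionally
comparable). During the AT the envelope is summarised by its median over
the task window. The first and last 100 ms of a session are excluded from
envelope statistics to guard against filter and Hilbert edge transients;
interior windows are unaffected.

## Kinematics

Hand speed and absolute acceleration are central differences (one-sided at
the ends) of the trajectory after an optional 10 Hz 2nd-order zero-phase
low-pass on positions (default on; pass `smooth_hz=None` for raw
differentiation). "Velocity" is reported as mean speed magnitude and
"acceleration" as mean acceleration-vector magnitude.

Space covered is measured on an occupancy grid (default 1 cm cells over the
76 × 44 cm workspace): every cell **intersected by a path segment** between
consecutive samples is marked, using an exact grid traversal
(Amanatides–Woo), so fast sweeps are not undercounted relative to
sample-only marking; area = visited cells × cell². Trajectories outside
the workspace are clipped to its bounds with a warning. Grid resolution is
a choice; 1 cm is fine enough that paddle-scale motion registers and coarse
enough that the per-subject maps remain well-populated for group maps.

Hits are counted per hand and per release bin from the event log; a ball is
credited to the hand whose paddle the collision involved, with simultaneous
two-paddle contact resolved to the nearer paddle centre.

## Cluster-based permutation test

Per-cell two-sample t statistics use the pooled-variance formula with
df = n₁+n₂−2 (Welch available via `equal_var=False`). The cluster-forming
threshold is the two-sided p = 0.01 critical t for those df; positive and
negative t cells are clustered separately under 4-connectivity, and
components of fewer than 2 cells are discarded (a spatial extent threshold
of one neighbour). The cluster statistic is the **mass** (sum of member
|t|); the null distribution is the maximum surviving cluster mass over each
of `n_perm` (default 5000) row-label shufflings, and every observed cluster
gets p = (1 + #{null ≥ mass})/(n_perm + 1), so p is never exactly zero and
the test is deterministic given a seed. Cells with zero variance in both
groups are masked out. The statistic, connectivity and sidedness are
defaults of this implementation (mass and 4-connectivity being the common
choices for gridded maps), not properties forced by the test itself; a
paired design can be approximated by differencing maps upstream, but the
test shipped here is the two-sample row-shuffling form.

## Within-subject statistics

One-way repeated-measures ANOVA uses the classical decomposition with
subject as blocking factor: F = MS_condition/MS_residual with
(k−1, (n−1)(k−1)) df. The two-way fully-within ANOVA tests each effect
against its own effect × subject interaction (univariate approach, one
observation per cell). Partial η² = SS_effect/(SS_effect+SS_error) per
effect. No sphericity correction is applied by default, matching the
uncorrected-df reporting convention; tests cross-check both designs against
pingouin. Paired follow-ups use the paired t (equal to the one-sample t on
differences), Bonferroni correction with the stated family size (three
pairwise comparisons for a three-level factor), and Cohen's d =
mean(diff)/sd(diff). Tiny negative sums of squares arising from floating
cancellation (below 10⁻¹² of SS_total) are clamped to zero so F and η²
honour their sign constraints.

## Synthetic generators

**Force sessions.** Trapezoid pulses (0.15 s rise, 0.7 s plateau, 0.15 s
fall within the 1 s window) toward `target_pct`% of the configured MVC,
sampled at 47.75 Hz, plus i.i.d. Gaussian sample noise. The per-contraction
amplitude is calibrated against the same trapezoid quadrature on the same
sample grid the analysis uses, so the noiseless per-contraction AUC equals
A₀ + β·k exactly and slope recovery is an identity check rather than an
approximation (the 47.75 Hz rate makes the sample phase drift across
cycles, which would otherwise add deterministic quadrature wiggle).
Amplitudes are clipped at zero if a drift would drive them negative.

**Study-level generation** (`make_synthetic_study`) injects drift as a
*fraction* of each session's baseline per-contraction AUC (defaults 0,
−0.1%, −0.2% per contraction for the 5/50/75% conditions, subject SD
0.03%), because a fixed absolute drift that is reasonable at the 75% target
is infeasible at the 5% target. Defaults produce a deterioration ordering
that grows with force level while every session stays in its linear regime.
Post-FT MVC amplitudes shrink by 8%/28%/28% across conditions. Baseline
MVCs are drawn from N(57, 8) force-au.

**EMG sessions.** Gaussian noise bandpassed to 20–450 Hz and normalised to
unit RMS, multiplied by a smooth contraction gate (50 ms ramps) whose
per-contraction amplitude drifts linearly. This emulates amplitude
modulation and band limitation only — no motor-unit structure, no
electrode artefacts, no heartbeat or movement contamination.

**Object-hit simulator.** Releases are quota-constrained (exactly 30 per
bin) with pseudorandom bin order and uniform speeds. Paddles run a
nearest-threat pursuit: each hand targets the lowest descending unhit ball
in its half, commits to target changes only after a reaction delay
(default 150 ms), and moves under a proportional controller capped at
`max_speed` (default 60 cm/s). Collisions are rectangle–circle overlap
tests; a hit flips the ball's vertical velocity and adds a horizontal
component proportional to the contact offset, and each ball can be hit at
most once, only inside the workspace. The kinematic stream is 200 Hz (a
simulator choice; the analysis does not depend on it). Paddles do not
collide with each other. The policy's speed cap and delay are the levers
for emulating a slowed, fatigued hand; nothing in the simulator models
biomechanics, motor noise structure, or learning.

**Spatial maps.** i.i.d. standard-normal cells per subject with an optional
constant block effect added to group 2 — the minimal harness for null
calibration and power checks of the cluster test.

Because the generators are simple, passing tests demonstrate that the
*analysis chain* is correct and calibrated under known ground truth; they
do not demonstrate robustness to real-data pathologies (drifting baselines,
missed cues, EMG artefacts, marker dropout).

## Problem sizes used in the shipped checks

Slope recovery uses full 270-cycle sessions (50 noisy seeds). Cluster-test
calibration uses 30 × 30 maps, 20 subjects per group, 1000 permutations per
dataset, 400 null datasets and 100 effect replicates in the test suite
(120/60 in the acceptance script). End-to-end studies use 6 subjects ×
3 conditions × 270 cycles, with 20 null replicates in the suite (10 in the
script). These sizes were chosen to keep Monte-Carlo error well inside the
asserted bands while remaining quick on a single CPU.

## Known limitations

* No imputation: NaN samples and incomplete designs are rejected, not
  repaired.
* The FWHM logic assumes an essentially unimodal contraction profile;
  strongly multimodal profiles will span the outer crossings.
* The cluster test assumes exchangeability of rows under the null; it is a
  two-sample test, so within-subject pairing is ignored unless maps are
  differenced upstream.
* Native acquisition formats (XDF, Dexterit-E exports) are not parsed; data
  enter through the package's CSV/JSON-lines formats.
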