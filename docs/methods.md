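# Methods

## Data model

A scoring is a set of labeled half-open intervals `[onset, onset+dur)`
in seconds from recording start.  All analysis is restricted to Time In
Bed (TIB), the interval between the lights-off and lights-on markers;
events are clipped to TIB on ingestion and zero-length residues are
dropped.  Intervals are half-open so that abutting events are distinct
and epoch-overlap tests are deterministic.  Sleep stagings are
normalized to per-30 s-epoch form (the hypnogram), anchored at
lights-off; consolidated stage records in input files are expanded.
The EDF+ dialect implements only the annotation (TAL) track — onset,
optional duration, text, with 0x14/0x15 separators — because the
analysis consumes scorings, not waveforms.  Free-text labels map to a
controlled vocabulary through a user-extensible alias table, since
label strings differ between labs and scoring software.  Numbers are
serialized with shortest round-tripping decimals, so write→read is an
exact identity (property-tested, and cross-checked against
`mne.read_annotations` on the EDF+ side).

## Discretization

Sleep staging uses the native 30 s epochs (5-symbol alphabet); event
tasks use 0.5 s mini-epochs with a binary present/absent value.  A
mini-epoch is "present" iff some event of interest intersects it with
strictly positive length; an event ending exactly at an epoch boundary
does not mark the next epoch.  A trailing partial epoch (TIB not
divisible by the step) is dropped; all scorers of a recording share the
TIB, so no pair is ever misaligned by this.  Wake/sleep context masks
classify each mini-epoch by the stage of its containing 30 s epoch in
the *shared clinical* hypnogram — the pre-filled one all scorers see —
never a rescored hypnogram, because it is the only hypnogram common to
all scorers of a non-staging task.

## Agreement statistics

*Cohen's kappa* is computed unweighted from the k×k pair contingency
table.  The degenerate case p_e = 1 (both raters constant, e.g. an
event absent throughout a quiet recording) is assigned κ = 1 for
perfect agreement and 0 otherwise, with a flag on the result.  For leg
movements the left and right channels are discretized separately and
the two per-channel kappas averaged per scorer pair; the epoch count
attached to the averaged result is the sum over channels.

*ICC(A,1)* follows McGraw & Wong's two-way absolute-agreement
single-measures formulation: mean squares from the recording × scorer
two-way ANOVA, the case-A,1 confidence interval, and an F
approximation with Satterthwaite degrees of freedom for H0: ICC = r0.
The implementation is verified to 1e-10 against a brute-force ANOVA
oracle and against `pingouin.intraclass_corr` (estimate, CI and
p-value at r0 = 0).  The r0 test is one-sided (alternative ICC > r0):
r0 is the manual baseline that the semi-automatic condition is
expected to exceed, and each comparison reports a single p-value.  A
constant matrix raises an explicit degenerate-data error rather than
returning a value.

## Diagnostic indices

Hypnogram-derived: TST = 30 s × #epochs in {N1, N2, N3, R}; sleep onset
is the first non-W epoch (AASM convention); stage-R latency counts from
sleep onset; WASO is defined by the identity TIB = SOL + TST + WASO;
SE = 100·TST/TIB.  With no scored sleep, SOL/REM latency/WASO are
flagged undefined and SE is 0.

Event-derived indices are counts per hour of TST.  RERAs are scored
with the respiratory events (and participate in the all-respiratory
kappa context) but never count toward the AHI.  Leg movements follow
WASM2016: opposite-leg movements with an end-to-onset gap < 0.5 s merge
into bilateral movements; after combination, movements shorter than
0.5 s are discarded, as are monolateral movements over 10 s and
bilateral ones over 15 s (all caps configurable).  Periodic LMs are
maximal runs of ≥ 4 movements whose onset-to-onset intervals all lie in
[10, 90] s.  An LM is respiratory-related if its onset falls within
−2.0 s to +10.25 s around the end of a scored apnea/hypopnea (window
configurable).  By default the PLMI *includes* respiratory-related LMs
in its counts — a compatibility flag preserves this reporting
convention; switching it off removes respiratory-related movements
from the candidate train first (the conventional reading; with it off,
intervals are measured between the remaining candidates).

## Comparison battery

Distributions are summarized as median [q1, q3] with
linear-interpolation percentiles (the most common estimator; fixed so
results are bit-reproducible).  Matched samples — 330 kappas or 60
scoring times per task — are compared with the two-sided paired
Wilcoxon signed-rank test: zero differences dropped, exact null
distribution up to n = 25 (verified against full 2ⁿ sign enumeration),
normal approximation with continuity correction above.  Effect size is
the paired Cohen's d_z = mean(Δ)/sd(Δ) on manual − semi-automatic
differences, so positive values mean the quantity is larger manually;
a zero-variance difference vector yields NaN rather than an arbitrary
number.  Variance comparisons use the Brown-Forsythe test (Levene with
median centering, via `scipy.stats.levene`) after dividing each group
by its own mean; divide-by-mean (not subtract-mean) is used because
the goal is removing location differences from a spread comparison,
and it makes the test invariant to rescaling either group.  Gain
factors are ratios of median times, reported to two decimals.  All
tests are reported at per-test α = 0.05 with no multiple-testing
correction, and the rendered report header says so.

## Recording selection

Per candidate recording, K_ac is the kappa between the automatic and
the clinical scoring under the exact task discretization used
downstream.  The five target percentiles (12.5, 37.5, 50, 62.5, 87.5 —
the middles of the four inter-quartile quarters plus the median) are
evaluated on the K_ac distribution with linear interpolation; for each
target, ascending, the not-yet-selected recording with the nearest
K_ac is chosen, ties breaking toward the lower recording id.
Nearest-value matching (rather than rank position) and
without-replacement selection are this package's documented choices;
they make the selection deterministic, and on ≥ 9 candidates the
extreme recordings are provably never selected (asserted in tests).

## Synthetic study generator

The generator's defaults are the study conditions the analysis is
exercised under; they were fixed once and are not tuning knobs.

*Ground truth.*  Hypnograms are first-order Markov chains on 30 s
epochs starting in W, with a transition matrix giving sleep efficiency
in the high 80s.  Per-task TIB defaults are 7.5/7.3/6.5/8.1 h (staging
/ leg movements / respiratory / arousals).  Events arrive as Poisson
processes parameterized per hour of TST at clinically typical rates
(arousals 13.5/h, apneas 2.2/h, hypopneas 4.5/h, RERAs 1/h).  Periodic
LM trains are generated explicitly (runs of 5–14 movements, IMIs
uniform on 15–45 s, ~13.6 periodic LMs per TST hour) plus isolated
LMs; leg movements are placed during sleep with probability 0.85,
which is what makes wake-context agreement lower than sleep-context
agreement downstream.  Desaturations follow 60 % of respiratory events
after a ~20 s delay, plus an uncoupled background rate.  Recordings
differ from each other like patients do: every event rate is scaled by
an independent log-normal factor (log-sd 0.7) and wake persistence is
perturbed per recording — this between-recording heterogeneity is what
gives the diagnostic indices high ICC ceilings.

*Scorers.*  A scorer is a corruption channel: staging epochs are
resampled from (1−e)·δ_truth + e·kernel (uniform off-diagonal kernel
by default); events are kept with a sensitivity, boundaries jittered
with Gaussian noise, and false positives added as a Poisson process
with source-like durations.  Per-label overrides let apneas be
delineated more reliably than hypopneas, reproducing the
apnea-vs-hypopnea agreement gap.  The manual condition corrupts the
truth independently per scorer; the semi-automatic condition first
draws one shared automatic draft and then applies each scorer's
(small) edit noise to that draft.  The shared draft induces the
positive between-scorer correlation that raises kappa — the mechanism,
not a fitted dependence structure.  Noise levels are set so that
median pairwise kappas land near 0.76/0.80 (staging), 0.72/0.91 (leg
movements), 0.55/0.66 (respiratory), 0.58/0.65 (arousals) for
manual/semi-automatic.

*Timing.*  Active scoring times are log-normal around per-(task,
method) medians of 32.62/24.54, 44.53/18.50, 23.81/14.58 and
27.50/21.78 minutes, with a per-scorer speed factor (log-sd 0.35)
shared across tasks and methods — this is what makes the paired
comparison informative — plus exercise noise (log-sd 0.40).

All randomness flows from one master seed through named per-cell
`SeedSequence` substreams, so a study (and its written directory) is
byte-reproducible.

*What the generator does not emulate:* waveforms of any kind,
intra-scorer drift over time, systematic per-scorer bias styles
(over-/under-scorers), label confusion between event subtypes, and
non-stationary event rates across the night.  Passing tests therefore
demonstrate the correctness of the measurement pipeline under a
controlled dependence structure, not the clinical levels any
particular lab would observe.

## Problem sizes and numerics

The default study is the full cross-classification (12 scorers × 2
methods × 4 tasks × 5 recordings = 480 scorings); analysis of a
complete study takes a few seconds on one core, and the test suite
runs it once and shares it across tests.  Monte-Carlo checks use 10⁵
epochs for the staging noise closed form (tolerance 0.015), 5-seed
batches for monotonicity assertions, 100-seed batches for index-band
coverage, and n = 5000 for timing-median recovery at 5 %.  Floating
tolerances: interval/epoch arithmetic uses 1e-9 slack before floor or
ceil; ICC oracle agreement is asserted at 1e-10; exact Wilcoxon
agreement at 1e-12.

## Known limitations

The exact formula behind a published paired effect size is not always
identifiable from summary tables; d_z is used and documented here, so
absolute effect-size values are comparable within this package but not
necessarily across publications.  Kappa on rare events over long quiet
stretches is dominated by the absent-absent cell; the degenerate-case
convention makes this explicit rather than hiding it.  The
respiratory-related LM window and the LM duration caps are
lab-configurable in the wild; defaults follow WASM2016.
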