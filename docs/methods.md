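# Methods

## Signal model and preprocessing

A recording is a muscles×samples matrix (14 canonical lower-limb
channels, default 2000 Hz) with per-muscle MVC amplitudes and three
event annotations (touchdown, ball contact, swing end) delimiting the
touch-ball (TC) and swing (SW) phases.  The linear envelope is built
per channel as zero-phase high-pass (default 50 Hz) → full-wave
rectification → zero-phase low-pass (default 20 Hz).  The filter family
and order are not dictated by the envelope definition itself; we use
4th-order Butterworth sections applied forward-backward (zero phase
preserves event alignment), with both cutoffs and the order exposed as
configuration.  The 50/20 Hz pair is an unusual combination — a
band-pass of the raw signal followed by a low-pass of the rectified
signal is the more common chain — so the cutoffs are deliberately
config keys rather than constants.  The first and last 0.25 s of a
filtered record are treated as edge-transient guard bands in analytic
tests.  Envelopes are divided by MVC per channel (values above 1 are
kept) and each phase is linearly resampled to `n_points` (default 100)
equidistant relative times, so every cycle shares a 0–200 column,
two-phase 0–100 % time base.  Multiple trials per subject are averaged
after time normalization; recordings flagged `signal_kind="envelope"`
(synthetic cohorts) skip the filtering stage, which would otherwise
destroy an already-enveloped signal.

Degenerate inputs fail loudly with the offending field named:
non-positive MVC, missing canonical channels, non-increasing events,
zero-duration phases.

## Spinal segmental mapping

The segmental output is the weighted mean
S_j(t) = Σᵢ wⱼᵢ·EMGᵢ(t) / Σᵢ wⱼᵢ over the muscles segment j innervates.
Two weightings are implemented and switchable: `printed`
(wⱼᵢ = kⱼᵢ·nᵢ, the default) and `literature` (wⱼᵢ = kⱼᵢ/nᵢ, which
down-weights muscles spread over many segments and is the formulation
the mapping methodology is usually cited with).  The printed variant
multiplies by nᵢ, which is plausibly a typographical inversion; since
this cannot be resolved from the definition alone, both are first-class
and the report records which was used.  Rows are optionally multiplied
by segmental motoneuron counts MNⱼ.  The shipped myotome chart
(L2–S3; quadriceps L2–L4, hamstrings L5–S2, TA L4–S1, GL L5–S3 with
major/minor weights 1.0/0.5) and MN counts are literature-derived
package data files, explicitly replaceable — they are inputs, not
measurements.  A segment with zero total weight yields a zero row and a
warning, not an error, so partial charts degrade gracefully.

Being a weighted mean, the output is bounded by the per-time min and
max of the contributing envelopes and is invariant to consistent
muscle permutations; both properties are tested.

## Synergy extraction

NMF minimizes ‖V − MP‖² by the classical multiplicative update pair,
P first, then M, with all entries floored at 1e-12 so zero-locked
entries cannot trap a division by zero.  Convergence follows an
R²-plateau rule: stop when R²·100 between V and MP varies by less than
`tol` = 0.01 over a window of 20 consecutive iterations (both config
keys), capped at `max_iter` = 5000; non-convergence sets a flag and
warns rather than raising.  Initialization is uniform random
nonnegative, scaled to √(mean(V)/r); `n_restarts` = 20 restarts are run
and the solution with the lowest final error kept, which in practice
keeps the spread of final R² across restarts well under half a
percentage point on well-separated data.  The per-iteration error
history of the kept restart is stored; monotone non-increase is
asserted in tests, and reconstruction quality is cross-checked against
scikit-learn's independent coordinate-descent NMF solver.

VAF uses the centered denominator Σ(V − V̄)² with V̄ the global mean (an
uncentered ‖V‖² variant is available).  Order selection fits, for each
interior candidate k on the VAF curve over r = 1..12, one least-squares
line to r ≤ k and one to r ≥ k, and picks the k minimizing the total
squared residual — a concrete estimator of the "greatest change in
slope" elbow; ties (e.g. an exactly straight curve) break toward
smaller k, and the per-candidate residuals are kept for audit.
Extraction runs per subject × condition on the concatenated TC+SW
envelope (per-phase extraction is a config choice away, by feeding
single-phase matrices).  Module columns are normalized to unit
Euclidean norm with the inverse scaling absorbed into the primitives,
leaving M·P unchanged — required for cross-subject comparability.

## Clustering, matching, combined synergies

Pooled unit modules are clustered with K-means (K-means++, best of 10
inits by inertia).  K can be fixed or chosen by maximal mean silhouette
over K ∈ [2, max selected r + 2], ties toward smaller K — a documented
stand-in for a choice the underlying methodology leaves unstated.
Clusters with fewer than one third of subjects contributing (strict
inequality on the exact fraction) are flagged subject-specific and
excluded from cross-condition matching.  Matching is the Hungarian
assignment maximizing the total scalar product of unit-normalized
centers; pairs with C ≤ 0.8 (strict ">" retained) are dropped to the
unmatched lists.  A module is a combined synergy when its cosine to the
best re-normalized sum of two unit centers exceeds both its best
single-center cosine and the 0.8 threshold; this pairwise-sum rule is
our operationalization of "composed of two or more unit synergies",
sharing the matching threshold as its similarity currency.

## Metrics and statistics

The co-activation index of an antagonist pair (thigh RF–BF, shank
GL–TA, per leg; only the lateral gastrocnemius head is instrumented)
is evaluated on exactly 200 equidistant points of the full TC+SW cycle:
CI = mean of ((H+L)/2)·(L/H), zero where both muscles are silent.  The
default `ratio_lh` uses L/H (lower over higher); the `printed` variant
keeps the degenerate L/L = 1 form, which collapses the CI to the mean
pair average and contradicts the index's stated purpose of reflecting
relative activation balance — it is retained strictly for audit.
CI is symmetric and positively scale-equivariant.

FWHM subtracts the primitive's minimum, finds the global peak, and
measures the contiguous region around the peak at ≥ half the
peak-to-min range, interpolating linearly at the crossings; each sample
spans 100/n % of the cycle.  It is invariant to offset and positive
rescaling.  For Gaussian primitives of width σ the analytic value
2√(2 ln 2)·σ anchors the tests.

Paired pre/post comparisons apply Shapiro–Wilk to the paired
differences (that is the assumption the paired t-test needs, so the
gate sits on the differences, not the margins): p > 0.05 → paired t
with Cohen's d = mean(diff)/sd(diff); otherwise Wilcoxon signed-rank
with r = Z/√n, where Z comes from the tie-corrected normal
approximation (zeros dropped, no continuity correction) computed
in-package so that p and r are mutually consistent; scipy's
implementation is the cross-check.  All-zero differences return a
flagged degenerate result (p = 1, effect 0).  Raw p-values are
reported; no multiplicity correction is applied by default, with
Benjamini–Hochberg available downstream via statsmodels if desired.

## Synthetic cohort generator

The generator defines the study conditions: 20 subjects, 14 muscles,
two conditions, three trials each, envelope noise sd 0.05 of the clean
global peak.  Signals are composed at envelope level as V = M*·P* plus
additive Gaussian noise truncated at zero (matching envelope
nonnegativity); MVC is the per-channel signal maximum, so analyses see
fraction-of-MVC data whose effective ground-truth modules are the
clean-envelope-normalized columns (`effective_modules`).  Modules are
sparse-ish — each synergy dominated by 2–4 muscles drawn from
near-disjoint pools — and primitives are Gaussian bumps with
non-overlapping centers assigned alternately to TC and SW; Gaussian
bumps make FWHM analytically known.  Per-subject variability is
multiplicative weight noise (sd 0.1), center jitter (sd 2 points) and
width jitter (sd 5 %) — values chosen once as realistic inter-subject
spread for lower-limb synergy weightings; trial durations jitter ±10 %
(removed by time normalization).  The identical jitter stream is used
for a subject's pre and post models, so a null effect leaves conditions
differing only by noise draws.  Injected effects: primitive center
shift (earlier activation), width scaling (FWHM change), weight gain,
or added synergies — additions respect the generator's invariants
(widest-gap placement, preference for not-yet-dominant muscles) so the
post ground truth remains a valid instance of the same model family.

What the generator does **not** emulate: motor-unit physiology,
crosstalk between channels, electrode lift-off or movement artifact,
non-Gaussian or heteroscedastic noise, within-phase tempo variation,
and non-Gaussian primitive shapes.  Passing recovery tests therefore
demonstrates correctness of the pipeline under the stated generative
model, not robustness to every pathology of real surface EMG.

## Calibration and power

Type-I error and power of the paired FWHM comparison are estimated by
Monte Carlo at the envelope level: per simulated cohort, each subject's
primitives are estimated by least-squares projection of the noisy
envelope onto the subject's known modules (clipped at zero), mean FWHM
is measured, and the Shapiro-gated paired test applied.  This bypasses
NMF deliberately — it calibrates the generator → metric → statistics
chain at a cost permitting hundreds of replicates (500 null cohorts run
in a few seconds), which a full factorization per replicate would not.
Observed null rejection sits within two binomial standard errors of
α = 0.05, and a 20 % FWHM narrowing at n = 20 is detected essentially
always.

## Determinism and problem sizes

A single seed drives every random draw via spawned `SeedSequence`
streams (cohort, per-subject NMF restarts, K-means), so identical
configurations produce bit-identical reports (floats serialized at
fixed precision, keys sorted; wall time excluded from the written
artifact).  The shipped validation suite exercises the full study
geometry — 20 subjects × 2 conditions × 3 trials, r = 1..12 curves with
20 restarts — in about a minute of CPU; the bundled demo uses 4
subjects and r ≤ 6 so it completes in seconds.

## Known limitations

- The elbow estimator is global (two straight segments); VAF curves
  with two comparable knees resolve to the earlier one by the
  tie-break, which may under-select on strongly hierarchical data.
- Auto-K by silhouette assumes reasonably balanced, roughly spherical
  clusters in module space; strongly nested synergy families may merge.
- The combined-synergy rule considers pairs only, not triples.
- The shipped myotome chart and MN counts are coarse literature
  defaults; segment-level conclusions inherit their uncertainty and
  study-specific charts should be substituted where available.
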