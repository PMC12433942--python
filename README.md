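# emgsyn

Muscle-synergy and spinal motor-output analysis of multi-channel surface
EMG, built for pre/post-intervention studies of ballistic lower-limb
movements such as the soccer penalty kick.

Given 14-channel surface-EMG recordings (2000 Hz, seven muscles per leg:
VL, RF, VM, BF, ST, TA, GL) with per-muscle MVC references and the three
movement events — support-foot touchdown, ball contact, swing-foot
landing — the package:

1. builds linear envelopes (zero-phase 50 Hz high-pass → full-wave
   rectification → zero-phase 20 Hz low-pass), normalizes to MVC, and
   time-normalizes the touch-ball (TC) and swing (SW) phases to 100
   points each;
2. maps envelopes onto spinal α-motoneuron pools through a myotome
   chart: S_j(t) = Σᵢ wⱼᵢ·EMGᵢ(t) / Σᵢ wⱼᵢ over the muscles segment j
   innervates, optionally scaled by the segmental motoneuron count MNⱼ;
3. extracts muscle synergies by non-negative matrix factorization,
   V ≈ V_r = M·P, with multiplicative updates
   P ← P∘(MᵀV)/(MᵀMP), M ← M∘(VPᵀ)/(MPPᵀ), stopping when R²(V, V_r)
   fluctuates < 0.01 percentage points over 20 consecutive iterations;
   the synergy count r is chosen on the VAF-vs-r curve (r = 1..12),
   VAF = (1 − ‖V−V_r‖²/‖V−V̄‖²)·100, at the two-segment least-squares
   elbow;
4. pools unit-normalized modules across subjects, clusters them with
   K-means, flags subject-specific clusters (< ⅓ of subjects
   contributing), pairs pre/post cluster centers by the Hungarian
   assignment maximizing the scalar product C, retaining pairs with
   C > 0.8, and classifies combined synergies (modules closer to a
   normalized sum of two unit centers than to any single center);
5. computes the antagonist co-activation index over 200 cycle points,
   CI = mean over j of ((EMG_H + EMG_L)/2)·(EMG_L/EMG_H), the FWHM and
   peak time of each motor primitive, and Shapiro-gated paired
   statistics (paired t + Cohen's d, or Wilcoxon signed-rank +
   r = Z/√n).

Because raw penalty-kick datasets of this kind are generally not
deposited, the package includes a first-class synthetic cohort
generator (`emgsyn.synth`) that produces envelope-level recordings from
known modules and Gaussian primitives — with per-subject variability,
trial noise, and configurable pre→post effects — so every stage can be
validated against ground truth.

## Worked example

```bash
emgsyn demo --seed 0 --outdir demo0
emgsyn report demo0/out/report.json
```

prints

```
schema v1  seed=0
post: modal r = 3 (mean 3.00)
pre: modal r = 3 (mean 3.00)
min matched C = 0.9988476433
ci_L-shank: paired-t p=0.1798 cohen_d=-0.871
ci_L-thigh: paired-t p=0.5178 cohen_d=0.365
ci_R-shank: paired-t p=0.9954 cohen_d=-0.0031
ci_R-thigh: paired-t p=0.7352 cohen_d=-0.186
fwhm_mean: paired-t p=0.4512 cohen_d=-0.432
peak_time: paired-t p=0.3534 cohen_d=-0.548
```

The demo writes a 4-subject synthetic cohort generated from a 3-synergy
ground truth with no injected pre→post effect, runs the full pipeline
on the files, and summarizes the report: both conditions select r = 3
synergies, the pre and post cluster centers match almost perfectly
(minimum scalar product C ≈ 0.999, far above the 0.8 criterion), and —
as expected under a null effect — no paired comparison is significant.
With only four subjects, individual p-values scatter widely; the
package's calibration machinery (`emgsyn.calibration`) quantifies the
type-I error and power of these comparisons at study scale.

The same pipeline runs on real data by pointing a YAML config at a
directory of `sub<NN>_<pre|post>_trial<T>.csv` channel×time tables with
JSON sidecars (`fs`, per-muscle `mvc`, event sample indices):

```bash
emgsyn run --config study.yaml --seed 1
```

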