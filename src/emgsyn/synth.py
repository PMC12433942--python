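"""Synthetic EMG cohort generator with known ground-truth synergies.

Envelope-level signals are composed as ``V = M* · P*`` — a sparse
nonnegative module matrix (each synergy dominated by 2–4 muscles) times
Gaussian-bump temporal primitives assigned to the TC or SW phase — plus
additive Gaussian noise truncated at zero.  A cohort mirrors the study
design: 20 subjects, 14 muscles, two conditions (pre/post intervention),
three kick trials each.  The post condition can carry an injected effect
(primitive timing shift, width/FWHM scaling, module-weight gain, or an
added synergy), enabling parameter-recovery and power studies with the
truth in hand.

Gaussian primitives make the FWHM analytically known: 2·√(2 ln 2)·σ.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import EmgRecording
from .muscles import CANONICAL_MUSCLES

CONDITIONS = ("pre", "post")


@dataclass
class Primitive:
    """One Gaussian temporal primitive, parameterized in % of its phase."""

    center: float        # % of phase, in [0, 100]
    width: float         # Gaussian σ, % of phase, > 0
    amplitude: float     # peak value
    phase: str           # "TC" or "SW"

    def __post_init__(self) -> None:
        if not 0.0 <= self.center <= 100.0:
            raise ValueError(f"center must lie in [0, 100], got {self.center}")
        if self.width <= 0:
            raise ValueError(f"width must be positive, got {self.width}")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Evaluate at phase-relative positions ``x`` (in %)."""
        return self.amplitude * np.exp(-0.5 * ((x - self.center) / self.width) ** 2)


@dataclass
class GroundTruthModel:
    """Known generative synergy structure: modules M* and primitives."""

    M_star: np.ndarray                    # muscles×r, col max = 1
    primitives: list[Primitive]
    muscle_labels: tuple[str, ...] = CANONICAL_MUSCLES

    def __post_init__(self) -> None:
        self.M_star = np.asarray(self.M_star, dtype=float)
        if np.any(self.M_star < 0):
            raise ValueError("M_star must be nonnegative")
        if self.M_star.shape[1] != len(self.primitives):
            raise ValueError("one primitive per module column required")

    @property
    def r(self) -> int:
        return self.M_star.shape[1]

    @property
    def n_muscles(self) -> int:
        return self.M_star.shape[0]

    def primitive_matrix(self, n_points_per_phase: int = 100) -> np.ndarray:
        """P* evaluated on the normalized two-phase grid (r × 2·n)."""
        n = n_points_per_phase
        x = 100.0 * np.arange(n) / (n - 1)
        P = np.zeros((self.r, 2 * n))
        for k, prim in enumerate(self.primitives):
            block = slice(0, n) if prim.phase == "TC" else slice(n, 2 * n)
            P[k, block] = prim.evaluate(x)
        return P

    def clean_envelope(self, n_points_per_phase: int = 100) -> np.ndarray:
        """Noiseless envelope V = M*·P* on the normalized grid."""
        return self.M_star @ self.primitive_matrix(n_points_per_phase)

    def effective_modules(self, n_points_per_phase: int = 100) -> np.ndarray:
        """Module matrix in fraction-of-MVC units (after per-channel max
        normalization of the clean envelope); the ground truth a recovery
        analysis of normalized envelopes should be scored against."""
        V = self.clean_envelope(n_points_per_phase)
        d = np.maximum(V.max(axis=1), 1e-12)
        return self.M_star / d[:, None]

    def to_dict(self) -> dict:
        return {
            "M_star": self.M_star.tolist(),
            "primitives": [asdict(p) for p in self.primitives],
            "muscle_labels": list(self.muscle_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthModel":
        return cls(
            M_star=np.asarray(d["M_star"], dtype=float),
            primitives=[Primitive(**p) for p in d["primitives"]],
            muscle_labels=tuple(d["muscle_labels"]),
        )


@dataclass
class EffectSpec:
    """Pre→post perturbation applied to the ground truth.

    ``center_shift`` moves every primitive center by the given number of
    normalized-phase percentage points (negative = activated earlier);
    ``fwhm_scale`` multiplies primitive widths (0.8 narrows FWHM by 20 %);
    ``weight_gain`` multiplies module weights; ``extra_synergies`` appends
    new synergies to the post ground truth.  The default is a null effect.
    """

    center_shift: float = 0.0
    fwhm_scale: float = 1.0
    weight_gain: float = 1.0
    extra_synergies: int = 0

    def is_null(self) -> bool:
        return (self.center_shift == 0.0 and self.fwhm_scale == 1.0
                and self.weight_gain == 1.0 and self.extra_synergies == 0)


def make_ground_truth(r: int, m: int = 14, seed: int = 0,
                      muscle_labels: tuple[str, ...] | None = None) -> GroundTruthModel:
    """Draw a ground-truth model with ``r`` synergies over ``m`` muscles.

    Modules are sparse-ish (each synergy dominated by 2–4 muscles drawn
    from disjoint pools where possible); primitives are Gaussian bumps
    with non-overlapping centers, assigned to TC and SW alternately.
    """
    if not 1 <= r <= m:
        raise ValueError(f"need 1 <= r <= m, got r={r}, m={m}")
    rng = np.random.default_rng(seed)
    # dominant-muscle pools: a random permutation chopped into chunks, so
    # synergies prefer distinct muscles (well-separated modules)
    perm = rng.permutation(m)
    M = np.zeros((m, r))
    cursor = 0
    for j in range(r):
        k = min(int(rng.integers(2, 5)), m)
        if cursor + k > m:
            cursor = 0
        dom = perm[cursor:cursor + k]
        cursor += k
        col = rng.uniform(0.0, 0.15, size=m)
        col[dom] = rng.uniform(0.7, 1.0, size=k)
        M[:, j] = col / col.max()
    phases = ["TC" if j % 2 == 0 else "SW" for j in range(r)]
    prims: list[Primitive] = []
    for ph in ("TC", "SW"):
        idx = [j for j, p in enumerate(phases) if p == ph]
        slots = 100.0 * (np.arange(len(idx)) + 1) / (len(idx) + 1)
        for j, slot in zip(idx, slots):
            prims.append(Primitive(
                center=float(np.clip(slot + rng.uniform(-5, 5), 5, 95)),
                width=float(rng.uniform(6.0, 10.0)),
                amplitude=float(rng.uniform(0.6, 1.0)),
                phase=ph,
            ))
    # restore synergy order (TC/SW interleaved as assigned)
    prims_by_synergy: list[Primitive] = [None] * r  # type: ignore[list-item]
    tc_iter = iter([p for p in prims if p.phase == "TC"])
    sw_iter = iter([p for p in prims if p.phase == "SW"])
    for j, ph in enumerate(phases):
        prims_by_synergy[j] = next(tc_iter if ph == "TC" else sw_iter)
    labels = tuple(muscle_labels) if muscle_labels else tuple(CANONICAL_MUSCLES[:m])
    if len(labels) != m:
        labels = tuple(f"M{i:02d}" for i in range(m))
    return GroundTruthModel(M_star=M, primitives=prims_by_synergy, muscle_labels=labels)


def apply_effect(model: GroundTruthModel, effect: EffectSpec,
                 rng: np.random.Generator | None = None) -> GroundTruthModel:
    """Return the post-condition ground truth with the effect injected."""
    if effect.is_null():
        return model
    prims = [Primitive(
        center=float(np.clip(p.center + effect.center_shift, 0.0, 100.0)),
        width=p.width * effect.fwhm_scale,
        amplitude=p.amplitude,
        phase=p.phase,
    ) for p in model.primitives]
    M = model.M_star * effect.weight_gain
    if effect.extra_synergies:
        if rng is None:
            rng = np.random.default_rng(0)
        m = model.n_muscles
        for _ in range(effect.extra_synergies):
            # keep the generator's invariants: the new primitive lands in the
            # widest temporal gap of the less-crowded phase, and its dominant
            # muscles prefer ones no existing synergy dominates
            counts = {ph: sum(p.phase == ph for p in prims) for ph in ("TC", "SW")}
            ph = min(counts, key=lambda key: (counts[key], key))
            edges = [0.0] + sorted(p.center for p in prims if p.phase == ph) + [100.0]
            gaps = [(edges[i + 1] - edges[i], (edges[i] + edges[i + 1]) / 2.0)
                    for i in range(len(edges) - 1)]
            _, center = max(gaps)
            prims.append(Primitive(
                center=float(np.clip(center + rng.uniform(-3, 3), 5, 95)),
                width=float(rng.uniform(6.0, 10.0)),
                amplitude=float(rng.uniform(0.6, 1.0)),
                phase=ph,
            ))
            k = min(int(rng.integers(2, 5)), m)
            free = np.flatnonzero((M >= 0.7).sum(axis=1) == 0)
            dom = (rng.choice(free, size=k, replace=False) if free.size >= k
                   else rng.choice(m, size=k, replace=False))
            col = rng.uniform(0.0, 0.15, size=m)
            col[dom] = rng.uniform(0.7, 1.0, size=k)
            M = np.hstack([M, (col / col.max())[:, None]])
    return GroundTruthModel(M_star=M, primitives=prims, muscle_labels=model.muscle_labels)


def jitter_model(model: GroundTruthModel, rng: np.random.Generator,
                 weight_jitter: float = 0.1, center_jitter: float = 2.0,
                 width_jitter: float = 0.05) -> GroundTruthModel:
    """Per-subject variability: multiplicative module-weight noise plus
    small primitive timing/width perturbations."""
    M = model.M_star * np.clip(1.0 + rng.normal(0.0, weight_jitter, model.M_star.shape), 0.0, None)
    M = M / np.maximum(M.max(axis=0, keepdims=True), 1e-12)
    prims = [Primitive(
        center=float(np.clip(p.center + rng.normal(0.0, center_jitter), 0.0, 100.0)),
        width=float(max(p.width * (1.0 + rng.normal(0.0, width_jitter)), 1.0)),
        amplitude=float(max(p.amplitude * (1.0 + rng.normal(0.0, 0.05)), 0.05)),
        phase=p.phase,
    ) for p in model.primitives]
    return GroundTruthModel(M_star=M, primitives=prims, muscle_labels=model.muscle_labels)


def _grid_primitive_matrix(model: GroundTruthModel, n_tc: int, n_sw: int) -> np.ndarray:
    """P* on a sample-resolution grid: TC spans samples 0..n_tc, SW spans
    n_tc..n_tc+n_sw (ball contact shared)."""
    n_total = n_tc + n_sw + 1
    P = np.zeros((model.r, n_total))
    x_tc = 100.0 * np.arange(n_tc + 1) / n_tc
    x_sw = 100.0 * np.arange(n_sw + 1) / n_sw
    for k, prim in enumerate(model.primitives):
        if prim.phase == "TC":
            P[k, :n_tc + 1] += prim.evaluate(x_tc)
        else:
            P[k, n_tc:] += prim.evaluate(x_sw)
    return P


def synthesize_subject(model: GroundTruthModel, noise_sd: float = 0.05,
                       seed: int | np.random.Generator = 0, fs: float = 2000.0,
                       tc_duration: float = 0.5, sw_duration: float = 0.35,
                       ) -> EmgRecording:
    """One synthetic kick trial as an envelope-level recording.

    The signal is V = M*·P* evaluated at sample resolution plus additive
    Gaussian noise (sd expressed as a fraction of the clean global peak)
    truncated at zero.  MVC is set to the per-channel signal maximum, and
    the touchdown / ball-contact / swing-end events delimit the phases.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_tc = max(int(round(fs * tc_duration)), 2)
    n_sw = max(int(round(fs * sw_duration)), 2)
    clean = model.M_star @ _grid_primitive_matrix(model, n_tc, n_sw)
    peak = clean.max()
    signal = clean
    if noise_sd > 0:
        signal = np.clip(clean + rng.normal(0.0, noise_sd * peak, clean.shape), 0.0, None)
    mvc = np.maximum(signal.max(axis=1), 1e-9)
    return EmgRecording(
        signal=signal, fs=fs, muscle_labels=model.muscle_labels, mvc=mvc,
        events={"touchdown": 0, "ball_contact": n_tc, "swing_end": n_tc + n_sw},
        signal_kind="envelope",
    )


def synthesize_envelope(model: GroundTruthModel, noise_sd: float,
                        rng: np.random.Generator,
                        n_points_per_phase: int = 100) -> np.ndarray:
    """Noisy MVC-normalized envelope directly on the normalized grid
    (muscles × 2·n); fast path for simulation studies."""
    clean = model.clean_envelope(n_points_per_phase)
    peak = clean.max()
    noisy = clean
    if noise_sd > 0:
        noisy = np.clip(clean + rng.normal(0.0, noise_sd * peak, clean.shape), 0.0, None)
    mvc = np.maximum(noisy.max(axis=1), 1e-12)
    return noisy / mvc[:, None]


@dataclass
class SyntheticCohort:
    """A generated pre/post cohort with its ground truth attached."""

    base_model: GroundTruthModel
    effect: EffectSpec
    n_subjects: int
    n_trials: int
    noise_sd: float
    seed: int
    subject_models: dict  # condition -> list[GroundTruthModel]
    recordings: dict      # condition -> list[list[EmgRecording]] (subject -> trials)
    meta: dict = field(default_factory=dict)

    @property
    def conditions(self) -> tuple[str, ...]:
        return CONDITIONS


def make_cohort(model: GroundTruthModel, n_subjects: int = 20,
                effect: EffectSpec | None = None, noise_sd: float = 0.05,
                n_trials: int = 3, seed: int = 0, fs: float = 2000.0,
                tc_duration: float = 0.5, sw_duration: float = 0.35,
                weight_jitter: float = 0.1, center_jitter: float = 2.0,
                width_jitter: float = 0.05,
                duration_jitter: float = 0.1) -> SyntheticCohort:
    """Generate a deterministic pre/post cohort from one ground truth.

    Each subject receives a single jittered copy of the base model; the
    post condition applies ``effect`` to that same copy (so a null effect
    leaves pre and post differing only by trial noise draws).  Trials get
    independent noise and mildly jittered phase durations, which the
    time-normalization stage later removes.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be at least 2")
    effect = effect or EffectSpec()
    root = np.random.SeedSequence(seed)
    effect_rng = np.random.default_rng(root.spawn(1)[0])
    post_base = apply_effect(model, effect, effect_rng)
    subject_models: dict[str, list[GroundTruthModel]] = {c: [] for c in CONDITIONS}
    recordings: dict[str, list[list[EmgRecording]]] = {c: [] for c in CONDITIONS}
    for s in range(n_subjects):
        subj_ss = np.random.SeedSequence(seed, spawn_key=(1, s))
        jitter_seed, *trial_seeds = subj_ss.spawn(1 + 2 * n_trials)
        for c_idx, (cond, base) in enumerate((("pre", model), ("post", post_base))):
            # identical jitter stream for both conditions: with a null
            # effect the subject's pre and post models coincide exactly
            subj_model = jitter_model(base, np.random.default_rng(jitter_seed),
                                      weight_jitter=weight_jitter,
                                      center_jitter=center_jitter,
                                      width_jitter=width_jitter)
            subject_models[cond].append(subj_model)
            trials = []
            for t in range(n_trials):
                trng = np.random.default_rng(trial_seeds[c_idx * n_trials + t])
                tc = tc_duration * (1.0 + trng.uniform(-duration_jitter, duration_jitter))
                sw = sw_duration * (1.0 + trng.uniform(-duration_jitter, duration_jitter))
                trials.append(synthesize_subject(
                    subj_model, noise_sd=noise_sd, seed=trng, fs=fs,
                    tc_duration=tc, sw_duration=sw))
            recordings[cond].append(trials)
    return SyntheticCohort(
        base_model=model, effect=effect, n_subjects=n_subjects,
        n_trials=n_trials, noise_sd=noise_sd, seed=seed,
        subject_models=subject_models, recordings=recordings,
        meta={"fs": fs, "tc_duration": tc_duration, "sw_duration": sw_duration,
              "weight_jitter": weight_jitter, "center_jitter": center_jitter,
              "width_jitter": width_jitter},
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write the cohort in the exact file formats the front-end reads,
    plus a ground-truth sidecar for recovery scoring."""
    import json
    from pathlib import Path

    from .io import write_recording

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for cond in cohort.conditions:
        for s, trials in enumerate(cohort.recordings[cond]):
            for t, rec in enumerate(trials):
                stem = out / f"sub{s:02d}_{cond}_trial{t}"
                write_recording(rec, f"{stem}.csv", f"{stem}.json")
    truth = {
        "base_model": cohort.base_model.to_dict(),
        "effect": asdict(cohort.effect),
        "n_subjects": cohort.n_subjects,
        "n_trials": cohort.n_trials,
        "noise_sd": cohort.noise_sd,
        "seed": cohort.seed,
        "subject_models": {
            cond: [m.to_dict() for m in models]
            for cond, models in cohort.subject_models.items()
        },
        "meta": cohort.meta,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
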