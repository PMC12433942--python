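"""End-to-end orchestration: cohort → envelopes → spinal map → synergies
→ clustering/matching → metrics → paired statistics → JSON report.

One :class:`RunConfig` governs every stage; every default that has a
printed counterpart in the underlying methodology (50/20 Hz cutoffs,
100 points per phase, R² tolerance 0.01 over 20 iterations, r = 1..12,
C > 0.8) uses that value.  A single seed drives all randomness, and the
report is serialized deterministically (sorted keys, fixed float
precision), so identical seeds give bit-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import SynergyClusterer, combined_proportion, match_centers
from .io import read_recording
from .metrics import (CI_N_POINTS, compute_ci, compute_fwhm, peak_time,
                      run_paired_stats)
from .muscles import ANTAGONIST_PAIRS, CANONICAL_MUSCLES
from .preprocess import average_trials, preprocess_recording, resample_phase
from .spinal import SpinalMapper, load_myotome_chart
from .synergy import SynergyExtractor
from .synth import CONDITIONS, EffectSpec, make_cohort, make_ground_truth, write_cohort

SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """A stage failed validation; carries the stage name."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage
        self.cause = err


@dataclass
class RunConfig:
    """All pipeline parameters with methodology-faithful defaults."""

    # input
    input_mode: str = "synthetic"          # "synthetic" | "files"
    data_dir: str | None = None            # for input_mode="files"
    # synthetic cohort
    n_subjects: int = 20
    r_true: int = 4
    noise_sd: float = 0.05
    n_trials: int = 3
    ground_truth_seed: int = 42
    effect: dict = field(default_factory=dict)   # EffectSpec fields
    # preprocessing
    hp_cut: float = 50.0
    lp_cut: float = 20.0
    filter_order: int = 4
    n_points: int = 100
    # spinal map
    eq1_variant: str = "printed"
    scale_by_mn: bool = True
    # synergy extraction
    r_max: int = 12
    nmf_max_iter: int = 5000
    nmf_tol: float = 0.01
    nmf_window: int = 20
    nmf_restarts: int = 20
    # clustering / matching
    k: object = "auto"
    match_threshold: float = 0.8
    # metrics / stats
    ci_variant: str = "ratio_lh"
    alpha: float = 0.05
    # run control
    seed: int = 0
    outdir: str = "emgsyn_out"

    def effect_spec(self) -> EffectSpec:
        return EffectSpec(**self.effect)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _jsonify(obj):
    """Deterministic JSON-safe conversion with fixed float precision."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def load_cohort_dir(data_dir: str | Path) -> dict:
    """Read a directory of ``sub<NN>_<cond>_trial<T>.csv/.json`` pairs."""
    data_dir = Path(data_dir)
    pattern = re.compile(r"sub(\d+)_(pre|post)_trial(\d+)\.csv$")
    recs: dict[str, dict[int, dict[int, object]]] = {c: {} for c in CONDITIONS}
    for csv in sorted(data_dir.glob("sub*_trial*.csv")):
        mobj = pattern.match(csv.name)
        if not mobj:
            continue
        s, cond, t = int(mobj.group(1)), mobj.group(2), int(mobj.group(3))
        recs[cond].setdefault(s, {})[t] = read_recording(csv, csv.with_suffix(".json"))
    out = {}
    for cond in CONDITIONS:
        subjects = sorted(recs[cond])
        out[cond] = [[recs[cond][s][t] for t in sorted(recs[cond][s])] for s in subjects]
    if not out["pre"] or not out["post"]:
        raise ValueError(f"no pre/post recordings found under {data_dir}")
    return out


def _ci_envelope(env_matrix) -> np.ndarray:
    """Envelope resampled to the 200 equidistant cycle points the CI uses."""
    per_phase = CI_N_POINTS // 2
    if env_matrix.n_points_per_phase == per_phase:
        return env_matrix.values
    parts = [resample_phase(env_matrix.phase(name), per_phase)
             for name in env_matrix.phase_bounds]
    return np.hstack(parts)


def run_pipeline(config: RunConfig, cohort=None, write: bool = True) -> dict:
    """Execute every stage and return (and optionally write) the report."""
    t0 = time.time()
    outdir = Path(config.outdir)
    root = np.random.SeedSequence(config.seed)

    # ------------------------------------------------------------------ input
    try:
        if cohort is not None:
            recordings = cohort.recordings
        elif config.input_mode == "synthetic":
            model = make_ground_truth(config.r_true, len(CANONICAL_MUSCLES),
                                      seed=config.ground_truth_seed)
            cohort_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
            cohort = make_cohort(model, n_subjects=config.n_subjects,
                                 effect=config.effect_spec(),
                                 noise_sd=config.noise_sd,
                                 n_trials=config.n_trials, seed=cohort_seed)
            recordings = cohort.recordings
        elif config.input_mode == "files":
            recordings = load_cohort_dir(config.data_dir)
        else:
            raise ValueError(f"unknown input_mode {config.input_mode!r}")
    except Exception as e:  # noqa: BLE001
        raise StageError("input", e) from e

    conditions = [c for c in CONDITIONS if recordings.get(c)]
    n_subjects = {c: len(recordings[c]) for c in conditions}

    # ------------------------------------------------------------- preprocess
    try:
        envelopes = {c: [] for c in conditions}
        for cond in conditions:
            for trials in recordings[cond]:
                mats = [preprocess_recording(rec, hp_cut=config.hp_cut,
                                             lp_cut=config.lp_cut,
                                             order=config.filter_order,
                                             n_points=config.n_points)
                        for rec in trials]
                envelopes[cond].append(average_trials(mats))
    except Exception as e:  # noqa: BLE001
        raise StageError("preprocess", e) from e

    # ------------------------------------------------------------- spinal map
    try:
        chart = load_myotome_chart()
        mapper = SpinalMapper(chart=chart, variant=config.eq1_variant,
                              scale_by_mn=config.scale_by_mn).fit()
        spinal_section = {}
        for cond in conditions:
            mean_env = np.mean([e.values for e in envelopes[cond]], axis=0)
            out = mapper.map_output(mean_env)
            used = out.scaled if config.scale_by_mn else out.raw
            spinal_section[cond] = {
                "segments": list(chart.segments),
                "mean_output": used,
                "segment_mean_amplitude": used.mean(axis=1),
                "variant": config.eq1_variant,
            }
    except Exception as e:  # noqa: BLE001
        raise StageError("spinal_map", e) from e

    # ---------------------------------------------------------------- synergy
    try:
        synergy_section = {}
        extractors = {c: [] for c in conditions}
        for cond in conditions:
            per_subject = []
            for s, env in enumerate(envelopes[cond]):
                seed = np.random.SeedSequence(
                    config.seed, spawn_key=(3, conditions.index(cond), s))
                ext = SynergyExtractor(
                    r_max=config.r_max, max_iter=config.nmf_max_iter,
                    tol=config.nmf_tol, window=config.nmf_window,
                    n_restarts=config.nmf_restarts,
                    random_state=np.random.default_rng(seed)).fit(env.values)
                extractors[cond].append(ext)
                per_subject.append({
                    "selected_r": ext.n_synergies_,
                    "vaf_curve": ext.vaf_curve_.vaf_values,
                    "vaf_at_selected": ext.vaf_curve_.vaf_values[ext.n_synergies_ - 1],
                })
            rs = [d["selected_r"] for d in per_subject]
            synergy_section[cond] = {
                "per_subject": per_subject,
                "modal_r": int(np.bincount(rs).argmax()),
                "mean_r": float(np.mean(rs)),
            }
    except Exception as e:  # noqa: BLE001
        raise StageError("synergy", e) from e

    # ---------------------------------------------------------------- cluster
    try:
        clusterers = {}
        pooled = {}
        cluster_section = {}
        for cond in conditions:
            mods = np.vstack([ext.modules_.T for ext in extractors[cond]])
            subj_ids = np.concatenate([
                np.full(ext.n_synergies_, s)
                for s, ext in enumerate(extractors[cond])])
            pooled[cond] = (mods, subj_ids)
            max_r = max(ext.n_synergies_ for ext in extractors[cond])
            k_range = (2, min(max_r + 2, mods.shape[0] - 1))
            seed = np.random.SeedSequence(config.seed,
                                          spawn_key=(4, conditions.index(cond)))
            clu = SynergyClusterer(
                k=config.k, threshold=config.match_threshold,
                seed=int(seed.generate_state(1)[0] % (2**31 - 1)),
                k_range=k_range).fit(mods, subj_ids)
            clusterers[cond] = clu
            res = clu.result_
            unit_idx = np.flatnonzero(~res.subject_specific)
            cluster_section[cond] = {
                "k": clu.k_,
                "centers": res.centers,
                "subject_specific": res.subject_specific,
                "contributors": [sorted(map(int, c)) for c in res.contributors],
                "combined_proportion": (
                    combined_proportion(mods, res.centers[unit_idx],
                                        config.match_threshold)
                    if len(unit_idx) >= 2 else None),
            }
        match_section = None
        if len(conditions) == 2:
            pre_res, post_res = clusterers["pre"].result_, clusterers["post"].result_
            pre_keep = np.flatnonzero(~pre_res.subject_specific)
            post_keep = np.flatnonzero(~post_res.subject_specific)
            table = match_centers(pre_res.centers[pre_keep],
                                  post_res.centers[post_keep],
                                  threshold=config.match_threshold)
            pairs = [(int(pre_keep[i]), int(post_keep[j]), c)
                     for i, j, c in table.pairs]
            match_section = {
                "pairs": pairs,
                "min_C": min((c for *_, c in pairs), default=None),
                "unmatched_pre": [int(pre_keep[i]) for i in table.unmatched_pre],
                "unmatched_post": [int(post_keep[j]) for j in table.unmatched_post],
                "threshold": config.match_threshold,
            }
    except Exception as e:  # noqa: BLE001
        raise StageError("cluster", e) from e

    # ---------------------------------------------------------------- metrics
    try:
        ci_values = {c: {name: [] for name, *_ in ANTAGONIST_PAIRS} for c in conditions}
        fwhm_values = {c: [] for c in conditions}
        peak_values = {c: [] for c in conditions}
        for cond in conditions:
            for env, ext in zip(envelopes[cond], extractors[cond]):
                env200 = _ci_envelope(env)
                labels = list(env.muscle_labels or CANONICAL_MUSCLES)
                for name, mus_a, mus_b in ANTAGONIST_PAIRS:
                    ci = compute_ci(env200[labels.index(mus_a)],
                                    env200[labels.index(mus_b)],
                                    variant=config.ci_variant)
                    ci_values[cond][name].append(ci)
                fwhm_values[cond].append(
                    float(np.mean([compute_fwhm(p) for p in ext.primitives_])))
                peak_values[cond].append(
                    float(np.mean([peak_time(p) for p in ext.primitives_])))
        metrics_section = {
            "ci": {c: {k: v for k, v in ci_values[c].items()} for c in conditions},
            "fwhm_mean_per_subject": fwhm_values,
            "peak_time_per_subject": peak_values,
            "ci_variant": config.ci_variant,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("metrics", e) from e

    # ------------------------------------------------------------------ stats
    try:
        stats_section = {}
        if len(conditions) == 2 and n_subjects["pre"] == n_subjects["post"]:
            comparisons = {}
            for name, *_ in ANTAGONIST_PAIRS:
                comparisons[f"ci_{name}"] = (ci_values["pre"][name],
                                             ci_values["post"][name])
            comparisons["fwhm_mean"] = (fwhm_values["pre"], fwhm_values["post"])
            comparisons["peak_time"] = (peak_values["pre"], peak_values["post"])
            for key, (a, b) in comparisons.items():
                res = run_paired_stats(np.asarray(a), np.asarray(b),
                                       alpha=config.alpha)
                stats_section[key] = dataclasses.asdict(res)
    except Exception as e:  # noqa: BLE001
        raise StageError("stats", e) from e

    # ----------------------------------------------------------------- report
    config_dict = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True).encode()).hexdigest()[:16]
    report = _jsonify({
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "package": "emgsyn",
            "version": __version__,
            "config": config_dict,
            "config_hash": config_hash,
            "seed": config.seed,
        },
        "preprocess": {
            "n_subjects": n_subjects,
            "n_points_per_phase": config.n_points,
            "phases": ["TC", "SW"],
        },
        "spinal_map": spinal_section,
        "synergy": synergy_section,
        "cluster": {"per_condition": cluster_section, "match": match_section},
        "metrics": metrics_section,
        "stats": stats_section,
        "wall_time_s": round(time.time() - t0, 3),
    })
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        # wall time is informational and excluded from the deterministic artifact
        stable = {k: v for k, v in report.items() if k != "wall_time_s"}
        (outdir / "report.json").write_text(
            json.dumps(stable, indent=1, sort_keys=True))
        for cond in conditions:
            pd.DataFrame(cluster_section[cond]["centers"],
                         columns=list(CANONICAL_MUSCLES)).to_csv(
                outdir / f"cluster_centers_{cond}.csv", index=False,
                float_format="%.10g")
        if match_section:
            pd.DataFrame(match_section["pairs"],
                         columns=["pre_cluster", "post_cluster", "C"]).to_csv(
                outdir / "match_table.csv", index=False, float_format="%.10g")
    return report


def make_demo(seed: int = 0, outdir: str | Path = "emgsyn_demo") -> Path:
    """Write a small 4-subject synthetic dataset plus a fast config."""
    outdir = Path(outdir)
    data_dir = outdir / "data"
    model = make_ground_truth(3, len(CANONICAL_MUSCLES), seed=seed)
    cohort = make_cohort(model, n_subjects=4, effect=EffectSpec(),
                         noise_sd=0.05, n_trials=2, seed=seed)
    write_cohort(cohort, data_dir)
    cfg = RunConfig(input_mode="files", data_dir=str(data_dir), n_subjects=4,
                    r_true=3, n_trials=2, r_max=6, nmf_restarts=5,
                    seed=seed, outdir=str(outdir / "out"))
    cfg.to_yaml(outdir / "config.yaml")
    return outdir
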