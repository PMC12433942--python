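"""Cross-subject synergy clustering and pre/post matching.

Unit-normalized motor modules pooled across subjects are clustered with
K-means (K fixed, or chosen by mean silhouette).  Pre- and
post-condition cluster centers are paired by the Hungarian assignment
that maximizes the total scalar product of unit-normalized centers;
pairs are retained only when the scalar product exceeds C = 0.8, the
standard matching criterion.  Clusters contributed by fewer than one
third of the subjects are flagged as subject-specific, and individual
modules can be classified as unit synergies, combined synergies (closer
to the normalized sum of two unit centers than to any single center),
or unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


def _unit_rows(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    return X / np.maximum(norms, 1e-12)


@dataclass
class ClusterResult:
    """K-means partition of pooled modules with subject bookkeeping."""

    centers: np.ndarray                 # K×muscles, nonnegative
    assignments: np.ndarray             # module index -> cluster id
    subject_ids: np.ndarray             # module index -> subject id
    contributors: list[set] = field(default_factory=list)
    subject_specific: np.ndarray | None = None
    inertia: float = 0.0
    k: int = 0
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    @property
    def unit_centers(self) -> np.ndarray:
        return _unit_rows(self.centers)


@dataclass
class MatchTable:
    """One-to-one pre/post cluster pairing by maximal scalar product."""

    pairs: list[tuple[int, int, float]]     # (pre id, post id, C)
    unmatched_pre: list[int]
    unmatched_post: list[int]
    threshold: float = 0.8


def cluster_modules(modules: np.ndarray, subject_ids, k="auto",
                    seed=None, k_range: tuple[int, int] | None = None,
                    n_init: int = 10) -> ClusterResult:
    """Cluster pooled module vectors with K-means (K-means++ seeding,
    best of ``n_init`` by inertia).

    ``k="auto"`` picks K by maximal mean silhouette over ``k_range``
    (default 2 … min(8, n_modules−1)), ties toward smaller K.
    """
    X = _unit_rows(modules)
    subject_ids = np.asarray(subject_ids)
    n = X.shape[0]
    if subject_ids.shape[0] != n:
        raise ValueError("one subject id per module required")
    rs = (seed if isinstance(seed, (int, np.integer)) or seed is None
          else int(np.random.default_rng(seed).integers(2**31 - 1)))
    sil_by_k: dict[int, float] = {}
    if k == "auto":
        lo, hi = k_range if k_range else (2, min(8, n - 1))
        hi = min(hi, n - 1)
        if lo > hi:
            raise ValueError("no feasible K in the requested range")
        for kk in range(lo, hi + 1):
            km = KMeans(n_clusters=kk, n_init=n_init, random_state=rs).fit(X)
            sil_by_k[kk] = float(silhouette_score(X, km.labels_))
        k = min(sil_by_k, key=lambda kk: (-round(sil_by_k[kk], 12), kk))
    k = int(k)
    if k > n:
        raise ValueError(f"K={k} exceeds the {n} available modules")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=rs).fit(X)
    contributors = [set(subject_ids[km.labels_ == c].tolist()) for c in range(k)]
    return ClusterResult(
        centers=np.clip(km.cluster_centers_, 0.0, None),
        assignments=km.labels_.copy(), subject_ids=subject_ids,
        contributors=contributors, inertia=float(km.inertia_), k=k,
        silhouette_by_k=sil_by_k)


def flag_subject_specific(result: ClusterResult, n_subjects: int) -> ClusterResult:
    """Mark clusters contributed by fewer than one third of subjects
    (strict inequality on the exact fraction n_subjects/3)."""
    result.subject_specific = np.array(
        [len(c) < n_subjects / 3.0 for c in result.contributors])
    return result


def match_centers(pre: ClusterResult | np.ndarray, post: ClusterResult | np.ndarray,
                  threshold: float = 0.8) -> MatchTable:
    """Hungarian pairing of pre and post centers by scalar product.

    Centers are unit-normalized; the assignment maximizes the total
    scalar product, and pairs with C ≤ ``threshold`` are dropped to the
    unmatched lists.
    """
    A = pre.unit_centers if isinstance(pre, ClusterResult) else _unit_rows(pre)
    B = post.unit_centers if isinstance(post, ClusterResult) else _unit_rows(post)
    S = A @ B.T
    rows, cols = linear_sum_assignment(-S)
    pairs, matched_pre, matched_post = [], set(), set()
    for i, j in zip(rows, cols):
        c = float(S[i, j])
        if c > threshold:
            pairs.append((int(i), int(j), c))
            matched_pre.add(int(i))
            matched_post.add(int(j))
    return MatchTable(
        pairs=sorted(pairs),
        unmatched_pre=[i for i in range(A.shape[0]) if i not in matched_pre],
        unmatched_post=[j for j in range(B.shape[0]) if j not in matched_post],
        threshold=threshold)


def detect_combined(module: np.ndarray, unit_centers: np.ndarray,
                    threshold: float = 0.8) -> dict:
    """Classify one module as ``unit``, ``combined`` or ``unclassified``.

    ``c1`` is the best cosine against a single unit center; ``c2`` the
    best cosine against the re-normalized sum of any unordered pair of
    centers.  Combined requires c2 > c1 and c2 > threshold; unit requires
    c1 ≥ c2 and c1 > threshold.
    """
    v = np.asarray(module, dtype=float).ravel()
    v = v / max(np.linalg.norm(v), 1e-12)
    C = _unit_rows(unit_centers)
    sims1 = C @ v
    i1 = int(np.argmax(sims1))
    c1 = float(sims1[i1])
    c2, pair = -np.inf, None
    for a, b in combinations(range(C.shape[0]), 2):
        s = C[a] + C[b]
        s = s / max(np.linalg.norm(s), 1e-12)
        val = float(s @ v)
        if val > c2:
            c2, pair = val, (a, b)
    if pair is not None and c2 > c1 and c2 > threshold:
        label = "combined"
    elif c1 >= c2 and c1 > threshold:
        label = "unit"
    else:
        label = "unclassified"
    return {"label": label, "c1": c1, "best_center": i1,
            "c2": (c2 if pair is not None else None), "best_pair": pair}


def combined_proportion(modules: np.ndarray, unit_centers: np.ndarray,
                        threshold: float = 0.8) -> float:
    """Fraction of modules classified as combined synergies."""
    labels = [detect_combined(m, unit_centers, threshold)["label"]
              for m in np.atleast_2d(modules)]
    return labels.count("combined") / len(labels)


class SynergyClusterer(BaseEstimator):
    """Estimator wrapper: fit pools modules, clusters, flags
    subject-specific clusters; ``match`` pairs against another fitted
    clusterer's centers."""

    def __init__(self, k="auto", threshold: float = 0.8, seed=None,
                 k_range: tuple[int, int] | None = None, n_init: int = 10):
        self.k = k
        self.threshold = threshold
        self.seed = seed
        self.k_range = k_range
        self.n_init = n_init

    def fit(self, X: np.ndarray, subject_ids=None) -> "SynergyClusterer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if subject_ids is None:
            subject_ids = np.arange(X.shape[0])
        res = cluster_modules(X, subject_ids, k=self.k, seed=self.seed,
                              k_range=self.k_range, n_init=self.n_init)
        n_subjects = len(set(np.asarray(subject_ids).tolist()))
        self.result_ = flag_subject_specific(res, n_subjects)
        self.centers_ = self.result_.centers
        self.labels_ = self.result_.assignments
        self.k_ = self.result_.k
        return self

    def match(self, other: "SynergyClusterer") -> MatchTable:
        return match_centers(self.result_, other.result_, threshold=self.threshold)
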