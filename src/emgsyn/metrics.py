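"""Co-activation index, primitive FWHM, and paired pre/post statistics.

The co-activation index (CI) of an antagonist pair is evaluated on 200
equidistant points of the normalized movement cycle.  At each point the
higher (H) and lower (L) of the two MVC-normalized envelopes contribute

    ((H + L) / 2) · (L / H),

i.e. the mean activation level damped by the balance ratio of the pair;
the CI is the average over the 200 points.  (The alternative
``variant="printed"`` uses a ratio of L to itself, which is identically
1 and reduces the CI to the mean of the pairwise averages; it is kept
for auditability.)

FWHM of a motor primitive is the width, in percent of the normalized
cycle, of the contiguous region around the global peak where the
min-subtracted waveform stays at or above half its peak value, with
linear interpolation at the half-height crossings.

Pre/post comparisons are paired by subject: Shapiro–Wilk on the
differences gates between the paired t-test (effect size Cohen's
d = mean(diff)/sd(diff)) and the Wilcoxon signed-rank test (effect size
r = Z/√n from the tie-corrected normal approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

CI_N_POINTS = 200


def compute_ci(env_a: np.ndarray, env_b: np.ndarray,
               variant: str = "ratio_lh") -> float:
    """Co-activation index of two 200-point MVC-normalized envelopes."""
    a = np.asarray(env_a, dtype=float).ravel()
    b = np.asarray(env_b, dtype=float).ravel()
    if a.shape != (CI_N_POINTS,) or b.shape != (CI_N_POINTS,):
        raise ValueError(f"both envelopes must have exactly {CI_N_POINTS} points")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("envelopes must be nonnegative")
    H = np.maximum(a, b)
    L = np.minimum(a, b)
    base = (H + L) / 2.0
    if variant == "ratio_lh":
        ratio = np.divide(L, H, out=np.zeros_like(L), where=H > 0)
    elif variant == "printed":
        ratio = np.where(H > 0, 1.0, 0.0)   # L/L as printed, guarded at H=0
    else:
        raise ValueError(f"variant must be 'ratio_lh' or 'printed', got {variant!r}")
    return float(np.mean(base * ratio))


def compute_fwhm(primitive: np.ndarray) -> float:
    """Full width at half maximum of a primitive, in % of the cycle.

    The waveform is min-subtracted; the width of the contiguous
    half-height region around the global maximum is measured with linear
    interpolation at the crossings.  Each sample spans 100/n percent of
    the cycle.
    """
    y = np.asarray(primitive, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("primitive too short for FWHM")
    y = y - y.min()
    peak = int(np.argmax(y))
    half = y[peak] / 2.0
    if y[peak] <= 0:
        raise ValueError("constant primitive has no FWHM")
    # walk left
    i = peak
    while i > 0 and y[i - 1] >= half:
        i -= 1
    if i == 0:
        left = 0.0
    else:
        left = (i - 1) + (half - y[i - 1]) / (y[i] - y[i - 1])
    # walk right
    j = peak
    while j < n - 1 and y[j + 1] >= half:
        j += 1
    if j == n - 1:
        right = float(n - 1)
    else:
        right = j + (y[j] - half) / (y[j] - y[j + 1])
    return (right - left) * 100.0 / n


def peak_time(primitive: np.ndarray) -> float:
    """Location of the global maximum, in % of the normalized cycle."""
    y = np.asarray(primitive, dtype=float).ravel()
    return float(np.argmax(y)) * 100.0 / y.size


@dataclass
class StatsResult:
    """Outcome of one paired pre/post comparison."""

    test_used: str            # "paired-t" | "wilcoxon" | "degenerate"
    p_value: float
    effect_size: float
    effect_name: str          # "cohen_d" | "r"
    normality_p: float
    n: int
    mean_diff: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < 0.05


def _wilcoxon_z(diff: np.ndarray) -> tuple[float, float]:
    """Signed-rank Z and two-sided p from the tie-corrected normal
    approximation (zeros dropped, no continuity correction)."""
    d = diff[diff != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        return 0.0, 1.0
    z = (w_plus - mu) / np.sqrt(var)
    return z, float(2.0 * stats.norm.sf(abs(z)))


def run_paired_stats(pre, post, alpha: float = 0.05) -> StatsResult:
    """Paired comparison with a Shapiro–Wilk normality gate on differences.

    Normal differences (Shapiro p > 0.05): paired t-test, Cohen's d.
    Otherwise: Wilcoxon signed-rank, r = Z/√n.  All-zero differences
    return a flagged degenerate result (p = 1, effect 0).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size < 3:
        raise ValueError("pre and post must be equal-length 1-D arrays with n >= 3")
    diff = post - pre
    n = diff.size
    if np.allclose(diff, 0.0):
        return StatsResult(test_used="degenerate", p_value=1.0, effect_size=0.0,
                           effect_name="cohen_d", normality_p=1.0, n=n,
                           mean_diff=0.0, degenerate=True)
    sw_p = float(stats.shapiro(diff).pvalue)
    if sw_p > alpha:
        t_res = stats.ttest_rel(post, pre)
        d = float(diff.mean() / diff.std(ddof=1))
        return StatsResult(test_used="paired-t", p_value=float(t_res.pvalue),
                           effect_size=d, effect_name="cohen_d",
                           normality_p=sw_p, n=n, mean_diff=float(diff.mean()))
    z, p = _wilcoxon_z(diff)
    return StatsResult(test_used="wilcoxon", p_value=p,
                       effect_size=float(abs(z) / np.sqrt(n)), effect_name="r",
                       normality_p=sw_p, n=n, mean_diff=float(diff.mean()))
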