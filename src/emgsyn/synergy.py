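"""Muscle-synergy extraction by Gaussian (Frobenius) NMF.

The nonnegative envelope matrix V (muscles×time) is factorized as
V ≈ V_r = M·P, where M (muscles×r) holds the motor modules (spatial
muscle weightings) and P (r×time) the motor primitives (temporal
activation waveforms).  Fitting uses the classical multiplicative
update pair

    P ← P ∘ (MᵀV) / (MᵀMP),      M ← M ∘ (VPᵀ) / (MPPᵀ),

which never increases the Frobenius reconstruction error.  Iteration
stops when the coefficient of determination R² between V and V_r
fluctuates by less than 0.01 percentage points over 20 consecutive
iterations, or at ``max_iter``.  Fit quality is summarized as Variance
Accounted For,

    VAF = (1 − ‖V − V_r‖² / ‖V − V̄‖²) × 100,

with V̄ the global-mean matrix (an uncentered variant using ‖V‖² in the
denominator is available).  The number of synergies is chosen from the
VAF-vs-r curve (r = 1..12 by default) at the elbow: the interior point
where two least-squares line segments fitted to the left and right
parts of the curve leave the smallest total squared residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

_EPS = 1e-12          # floor for zero-locked entries
_DIV_EPS = 1e-12      # guard against division by zero in update ratios


def compute_vaf(V: np.ndarray, Vr: np.ndarray, centered: bool = True) -> float:
    """Variance Accounted For (percent) of reconstruction ``Vr`` for ``V``.

    Centered (default): denominator is the total squared deviation from
    the global mean of V.  Uncentered: denominator is ‖V‖².
    """
    V = np.asarray(V, dtype=float)
    Vr = np.asarray(Vr, dtype=float)
    if V.shape != Vr.shape:
        raise ValueError(f"shape mismatch: {V.shape} vs {Vr.shape}")
    sse = float(np.sum((V - Vr) ** 2))
    denom = float(np.sum((V - V.mean()) ** 2)) if centered else float(np.sum(V ** 2))
    if denom <= 0:
        raise ValueError("V has zero variance; VAF undefined")
    return (1.0 - sse / denom) * 100.0


def normalize_synergy(M: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each module column to unit Euclidean norm, compensating the
    matching primitive row so that M·P is unchanged."""
    M = np.asarray(M, dtype=float)
    P = np.asarray(P, dtype=float)
    norms = np.linalg.norm(M, axis=0)
    if np.any(norms <= 0):
        raise ValueError("cannot normalize an all-zero module column")
    return M / norms, P * norms[:, None]


@dataclass
class SynergySet:
    """One NMF solution: modules M, primitives P and fit diagnostics."""

    M: np.ndarray
    P: np.ndarray
    r: int
    vaf: float
    r2: float
    n_iter: int
    converged: bool
    restart_errors: list[float] = field(default_factory=list)
    error_history: np.ndarray | None = None

    @property
    def reconstruction(self) -> np.ndarray:
        return self.M @ self.P

    def normalized(self) -> "SynergySet":
        M, P = normalize_synergy(self.M, self.P)
        return SynergySet(M=M, P=P, r=self.r, vaf=self.vaf, r2=self.r2,
                          n_iter=self.n_iter, converged=self.converged,
                          restart_errors=list(self.restart_errors),
                          error_history=self.error_history)


class SynergyNMF(TransformerMixin, BaseEstimator):
    """NMF estimator with multiplicative updates and an R²-plateau stop.

    Parameters
    ----------
    n_components : int
        Number of synergies r.
    max_iter : int
        Iteration cap per restart.
    tol : float
        Convergence threshold on the fluctuation of R² (percentage
        points) over ``window`` consecutive iterations; default 0.01.
    window : int
        Length of the convergence window; default 20 iterations.
    n_restarts : int
        Random restarts; the solution with the highest final R² is kept.
    random_state : int or Generator or None
        Seeds the uniform nonnegative initialization.

    Attributes
    ----------
    modules_ : ndarray (muscles×r)
    primitives_ : ndarray (r×time)
    vaf_, r2_, n_iter_, converged_, restart_errors_, error_history_
    """

    def __init__(self, n_components: int = 4, max_iter: int = 5000,
                 tol: float = 0.01, window: int = 20, n_restarts: int = 20,
                 random_state=None):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.window = window
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _single_fit(self, V: np.ndarray, rng: np.random.Generator,
                    sst: float) -> tuple[np.ndarray, np.ndarray, int, bool, np.ndarray]:
        m, n = V.shape
        r = self.n_components
        scale = np.sqrt(max(V.mean(), _EPS) / r)
        M = rng.uniform(_EPS, 1.0, size=(m, r)) * scale
        P = rng.uniform(_EPS, 1.0, size=(r, n)) * scale
        r2_hist: list[float] = []
        err_hist = np.empty(self.max_iter)
        n_iter, converged = self.max_iter, False
        for it in range(self.max_iter):
            MtV = M.T @ V
            P *= MtV / (M.T @ M @ P + _DIV_EPS)
            np.maximum(P, _EPS, out=P)
            VPt = V @ P.T
            M *= VPt / (M @ (P @ P.T) + _DIV_EPS)
            np.maximum(M, _EPS, out=M)
            sse = float(np.sum((V - M @ P) ** 2))
            err_hist[it] = sse
            r2_hist.append((1.0 - sse / sst) * 100.0)
            if len(r2_hist) > self.window:
                recent = r2_hist[-(self.window + 1):]
                if max(recent) - min(recent) < self.tol:
                    n_iter, converged = it + 1, True
                    break
        return M, P, n_iter, converged, err_hist[:n_iter]

    def fit(self, X: np.ndarray, y=None) -> "SynergyNMF":
        V = np.asarray(X, dtype=float)
        if V.ndim != 2:
            raise ValueError("V must be a 2-D muscles×time matrix")
        if np.any(V < 0):
            raise ValueError("V must be nonnegative")
        if not np.any(V > 0):
            raise ValueError("V must not be all zero")
        r = self.n_components
        if not 1 <= r <= min(V.shape):
            raise ValueError(f"need 1 <= n_components <= {min(V.shape)}, got {r}")
        sst = float(np.sum((V - V.mean()) ** 2))
        if sst <= 0:
            raise ValueError("V is constant; R² undefined")
        rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        best = None
        restart_errors: list[float] = []
        for _ in range(max(self.n_restarts, 1)):
            M, P, n_iter, converged, err_hist = self._single_fit(V, rng, sst)
            final_err = err_hist[-1]
            restart_errors.append(float(final_err))
            if best is None or final_err < best[4]:
                best = (M, P, n_iter, converged, final_err, err_hist)
        M, P, n_iter, converged, final_err, err_hist = best
        if not converged:
            warnings.warn(f"NMF did not converge within {self.max_iter} iterations")
        self.modules_, self.primitives_ = M, P
        self.n_iter_ = n_iter
        self.converged_ = bool(converged)
        self.restart_errors_ = restart_errors
        self.error_history_ = err_hist
        self.r2_ = 1.0 - final_err / sst
        self.vaf_ = compute_vaf(V, M @ P)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Return the fitted primitives (r×time)."""
        return self.primitives_

    def to_synergy_set(self) -> SynergySet:
        return SynergySet(
            M=self.modules_, P=self.primitives_, r=self.n_components,
            vaf=self.vaf_, r2=self.r2_, n_iter=self.n_iter_,
            converged=self.converged_, restart_errors=self.restart_errors_,
            error_history=self.error_history_)


def nmf_factorize(V: np.ndarray, r: int, seed=None, n_restarts: int = 20,
                  max_iter: int = 5000, tol: float = 0.01,
                  window: int = 20) -> SynergySet:
    """Functional wrapper over :class:`SynergyNMF`."""
    est = SynergyNMF(n_components=r, max_iter=max_iter, tol=tol, window=window,
                     n_restarts=n_restarts, random_state=seed)
    return est.fit(V).to_synergy_set()


@dataclass
class VafCurve:
    """VAF as a function of candidate synergy count, with elbow diagnostics."""

    r_values: np.ndarray
    vaf_values: np.ndarray
    selected_r: int | None = None
    elbow_residuals: dict[int, float] = field(default_factory=dict)


def select_order(vaf_values: np.ndarray, r_values: np.ndarray | None = None,
                 ) -> tuple[int, dict[int, float]]:
    """Elbow of the VAF-vs-r curve by two-segment least squares.

    For every interior candidate k, one line is fitted to the points with
    r ≤ k and another to those with r ≥ k; the k with the smallest total
    squared residual is the elbow (ties break toward smaller k).  Returns
    the selected r and the per-candidate residuals.
    """
    vaf = np.asarray(vaf_values, dtype=float)
    r = (np.arange(1, len(vaf) + 1, dtype=float) if r_values is None
         else np.asarray(r_values, dtype=float))
    if len(vaf) < 3:
        raise ValueError("need at least 3 points to locate an elbow")
    residuals: dict[int, float] = {}
    for i in range(1, len(r) - 1):
        total = 0.0
        for sl in (slice(0, i + 1), slice(i, len(r))):
            x, y = r[sl], vaf[sl]
            coef = np.polyfit(x, y, 1)
            total += float(np.sum((y - np.polyval(coef, x)) ** 2))
        residuals[int(r[i])] = total
    best = min(residuals, key=lambda k: (round(residuals[k], 12), k))
    return best, residuals


class SynergyExtractor(BaseEstimator):
    """Full extraction: NMF across r = 1..r_max, VAF curve, elbow choice.

    After ``fit(V)``:

    - ``n_synergies_`` — elbow-selected synergy count
    - ``modules_``, ``primitives_`` — solution at the selected r
      (modules unit-normalized when ``normalize=True``)
    - ``vaf_curve_`` — :class:`VafCurve` with diagnostics
    - ``synergy_set_`` — the selected :class:`SynergySet`
    """

    def __init__(self, r_max: int = 12, max_iter: int = 5000, tol: float = 0.01,
                 window: int = 20, n_restarts: int = 20, random_state=None,
                 normalize: bool = True):
        self.r_max = r_max
        self.max_iter = max_iter
        self.tol = tol
        self.window = window
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.normalize = normalize

    def fit(self, X: np.ndarray, y=None) -> "SynergyExtractor":
        V = np.asarray(X, dtype=float)
        r_hi = min(self.r_max, min(V.shape))
        if r_hi < 3:
            raise ValueError("r_max too small to build a VAF curve (need ≥ 3 candidates)")
        rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        sets: list[SynergySet] = []
        for r in range(1, r_hi + 1):
            sets.append(nmf_factorize(V, r, seed=rng, n_restarts=self.n_restarts,
                                      max_iter=self.max_iter, tol=self.tol,
                                      window=self.window))
        vaf = np.array([s.vaf for s in sets])
        selected, residuals = select_order(vaf, np.arange(1, r_hi + 1))
        self.vaf_curve_ = VafCurve(
            r_values=np.arange(1, r_hi + 1), vaf_values=vaf,
            selected_r=selected, elbow_residuals=residuals)
        chosen = sets[selected - 1]
        self.synergy_set_ = chosen.normalized() if self.normalize else chosen
        self.n_synergies_ = selected
        self.modules_ = self.synergy_set_.M
        self.primitives_ = self.synergy_set_.P
        self.all_sets_ = sets
        return self
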