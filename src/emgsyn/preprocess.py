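"""EMG envelope construction and phase time-normalization.

The linear envelope follows standard surface-EMG practice: a zero-phase
high-pass filter (default 50 Hz) removes motion artifact and offset,
full-wave rectification takes the absolute value, and a zero-phase
low-pass filter (default 20 Hz) smooths the rectified signal.  Envelopes
are then expressed as a fraction of each muscle's maximum voluntary
contraction (MVC) and the two movement phases — touch-ball (TC, support
touchdown → ball contact) and swing (SW, ball contact → swing-foot
landing) — are each linearly resampled to a fixed number of points so
that every cycle shares a common 0–100 % time base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .io import EmgRecording, ValidationError

#: duration (s) at each end of a filtered record affected by filter
#: transients; analytic assertions should ignore these guard bands.
EDGE_GUARD_S = 0.25


@dataclass
class PhaseDefinition:
    """One movement phase, delimited by two named events."""

    name: str
    start_event: str
    end_event: str


DEFAULT_PHASES: tuple[PhaseDefinition, ...] = (
    PhaseDefinition("TC", "touchdown", "ball_contact"),
    PhaseDefinition("SW", "ball_contact", "swing_end"),
)


@dataclass
class EnvelopeMatrix:
    """Phase-normalized, MVC-normalized activation envelopes.

    ``values`` is muscles×timepoints (dimensionless, fraction of MVC) with
    each phase occupying ``n_points_per_phase`` consecutive columns;
    ``phase_bounds`` maps phase name → (start, stop) column range.
    """

    values: np.ndarray
    phase_bounds: dict[str, tuple[int, int]]
    n_points_per_phase: int
    muscle_labels: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValidationError("envelope values must be nonnegative")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("envelope values must be finite")
        for name, (a, b) in self.phase_bounds.items():
            if b - a != self.n_points_per_phase:
                raise ValidationError(
                    f"phase {name} spans {b - a} points, expected {self.n_points_per_phase}"
                )

    def phase(self, name: str) -> np.ndarray:
        a, b = self.phase_bounds[name]
        return self.values[:, a:b]


class EnvelopeExtractor(TransformerMixin, BaseEstimator):
    """Linear-envelope transformer: high-pass → rectify → low-pass.

    Parameters
    ----------
    fs : float
        Sampling rate of the input signal, Hz.
    hp_cut, lp_cut : float
        High-pass and low-pass cutoff frequencies, Hz.  Defaults 50 and 20.
    order : int
        Butterworth order (applied forward-backward, so the effective
        attenuation is doubled and the phase response is zero).
    """

    def __init__(self, fs: float = 2000.0, hp_cut: float = 50.0,
                 lp_cut: float = 20.0, order: int = 4):
        self.fs = fs
        self.hp_cut = hp_cut
        self.lp_cut = lp_cut
        self.order = order

    def fit(self, X=None, y=None):
        nyq = self.fs / 2.0
        for name, cut in (("hp_cut", self.hp_cut), ("lp_cut", self.lp_cut)):
            if not 0 < cut < nyq:
                raise ValueError(
                    f"{name}={cut} Hz must lie in (0, Nyquist={nyq} Hz)"
                )
        self.sos_hp_ = sps.butter(self.order, self.hp_cut, "highpass", fs=self.fs, output="sos")
        self.sos_lp_ = sps.butter(self.order, self.lp_cut, "lowpass", fs=self.fs, output="sos")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Return the nonnegative envelope of a muscles×samples signal."""
        if not hasattr(self, "sos_hp_"):
            self.fit()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        hp = sps.sosfiltfilt(self.sos_hp_, X, axis=1)
        env = sps.sosfiltfilt(self.sos_lp_, np.abs(hp), axis=1)
        return np.clip(env, 0.0, None)  # clip numerical undershoot


def build_envelope(recording: EmgRecording, hp_cut: float = 50.0,
                   lp_cut: float = 20.0, order: int = 4) -> np.ndarray:
    """Linear envelope of a raw recording (muscles×samples, nonnegative)."""
    ext = EnvelopeExtractor(fs=recording.fs, hp_cut=hp_cut, lp_cut=lp_cut, order=order)
    return ext.fit().transform(recording.signal)


def normalize_mvc(envelope: np.ndarray, mvc: np.ndarray,
                  labels: tuple[str, ...] | None = None) -> np.ndarray:
    """Divide each envelope row by its MVC amplitude.

    Values may exceed 1 — task activation above the MVC reference is kept.
    """
    envelope = np.asarray(envelope, dtype=float)
    mvc = np.asarray(mvc, dtype=float)
    bad = np.flatnonzero(~(mvc > 0))
    if bad.size:
        names = [labels[i] if labels else f"channel {i}" for i in bad]
        raise ValidationError(f"non-positive MVC for {', '.join(map(str, names))}")
    return envelope / mvc[:, None]


def resample_phase(segment: np.ndarray, n_points: int) -> np.ndarray:
    """Linearly resample a muscles×samples segment to ``n_points`` columns.

    Sampling positions are the ``n_points`` equidistant relative times
    spanning the closed interval [0, 1] of the phase.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    n_in = segment.shape[1]
    if n_in < 2:
        raise ValidationError("phase of zero duration cannot be resampled")
    x_new = np.linspace(0.0, n_in - 1.0, n_points)
    x_old = np.arange(n_in, dtype=float)
    return np.vstack([np.interp(x_new, x_old, row) for row in segment])


def segment_phases(envelope: np.ndarray, events: dict[str, int],
                   phases: tuple[PhaseDefinition, ...] = DEFAULT_PHASES,
                   n_points: int = 100,
                   muscle_labels: tuple[str, ...] = ()) -> EnvelopeMatrix:
    """Cut the envelope into phases and time-normalize each to ``n_points``.

    Each phase (start event inclusive, end event inclusive) is linearly
    resampled to ``n_points`` columns; phases are concatenated in order.
    """
    if n_points < 2:
        raise ValidationError("n_points must be at least 2")
    envelope = np.atleast_2d(np.asarray(envelope, dtype=float))
    pieces, bounds, cursor = [], {}, 0
    for ph in phases:
        a, b = int(events[ph.start_event]), int(events[ph.end_event])
        if b <= a:
            raise ValidationError(f"phase {ph.name} has zero or negative duration")
        pieces.append(resample_phase(envelope[:, a:b + 1], n_points))
        bounds[ph.name] = (cursor, cursor + n_points)
        cursor += n_points
    return EnvelopeMatrix(
        values=np.clip(np.hstack(pieces), 0.0, None),
        phase_bounds=bounds,
        n_points_per_phase=n_points,
        muscle_labels=muscle_labels,
    )


def preprocess_recording(recording: EmgRecording, hp_cut: float = 50.0,
                         lp_cut: float = 20.0, order: int = 4,
                         n_points: int = 100,
                         phases: tuple[PhaseDefinition, ...] = DEFAULT_PHASES,
                         ) -> EnvelopeMatrix:
    """Full front-end: envelope → MVC normalization → phase normalization.

    Recordings flagged ``signal_kind="envelope"`` (e.g. synthetic cohorts,
    which are generated at envelope level) skip the filter/rectify stage.
    """
    if recording.signal_kind == "envelope":
        env = np.clip(recording.signal, 0.0, None)
    else:
        env = build_envelope(recording, hp_cut=hp_cut, lp_cut=lp_cut, order=order)
    norm = normalize_mvc(env, recording.mvc, recording.muscle_labels)
    return segment_phases(norm, recording.events, phases=phases, n_points=n_points,
                          muscle_labels=recording.muscle_labels)


def average_trials(mats: list[EnvelopeMatrix]) -> EnvelopeMatrix:
    """Average time-normalized envelopes across trials of one subject."""
    if not mats:
        raise ValidationError("no trials to average")
    first = mats[0]
    for m in mats[1:]:
        if m.values.shape != first.values.shape or m.phase_bounds != first.phase_bounds:
            raise ValidationError("trials must share shape and phase layout")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean = np.mean([m.values for m in mats], axis=0)
    return EnvelopeMatrix(
        values=mean,
        phase_bounds=dict(first.phase_bounds),
        n_points_per_phase=first.n_points_per_phase,
        muscle_labels=first.muscle_labels,
        meta={"n_trials": len(mats)},
    )
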