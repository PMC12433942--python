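"""Reading and writing EMG recordings.

A recording is a pair of files: a delimited channel-by-time table whose
header row holds the canonical muscle labels (one column per muscle, one
row per sample), and a JSON or YAML sidecar holding the sampling rate,
per-muscle MVC amplitudes and the movement-event sample indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .muscles import CANONICAL_MUSCLES, EVENT_ORDER


class ValidationError(ValueError):
    """Raised when an input file or object violates a structural contract."""


@dataclass
class EmgRecording:
    """Multi-channel surface-EMG recording with MVC and event annotations.

    Parameters
    ----------
    signal : ndarray of shape (n_muscles, n_samples)
        Channel-by-time signal in millivolts (``signal_kind="raw"``) or an
        already-enveloped nonnegative signal (``signal_kind="envelope"``).
    fs : float
        Sampling rate in Hz.
    muscle_labels : tuple of str
        Ordered channel labels; must match the canonical 14-muscle set.
    mvc : ndarray of shape (n_muscles,)
        Per-muscle maximum-voluntary-contraction amplitude, strictly positive.
    events : dict
        Sample indices for ``touchdown``, ``ball_contact`` and ``swing_end``,
        strictly increasing in that order.
    """

    signal: np.ndarray
    fs: float
    muscle_labels: tuple[str, ...]
    mvc: np.ndarray
    events: dict[str, int]
    signal_kind: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.mvc = np.asarray(self.mvc, dtype=float)
        self.muscle_labels = tuple(self.muscle_labels)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be a 2-D muscles×samples matrix")
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if len(self.muscle_labels) != self.signal.shape[0]:
            raise ValidationError(
                f"{len(self.muscle_labels)} labels for {self.signal.shape[0]} channels"
            )
        if len(set(self.muscle_labels)) != len(self.muscle_labels):
            raise ValidationError("duplicate muscle labels")
        missing = [m for m in CANONICAL_MUSCLES if m not in self.muscle_labels]
        if missing:
            raise ValidationError(f"missing canonical channel(s): {', '.join(missing)}")
        if self.mvc.shape != (self.signal.shape[0],):
            raise ValidationError("mvc must hold one value per channel")
        bad = [self.muscle_labels[i] for i in np.flatnonzero(~(self.mvc > 0))]
        if bad:
            raise ValidationError(f"non-positive MVC for channel(s): {', '.join(bad)}")
        missing_ev = [e for e in EVENT_ORDER if e not in self.events]
        if missing_ev:
            raise ValidationError(f"missing event(s): {', '.join(missing_ev)}")
        idx = [int(self.events[e]) for e in EVENT_ORDER]
        if not (idx[0] < idx[1] < idx[2]):
            raise ValidationError(
                "events must satisfy touchdown < ball_contact < swing_end, got "
                + ", ".join(f"{e}={i}" for e, i in zip(EVENT_ORDER, idx))
            )
        if idx[0] < 0 or idx[2] >= self.signal.shape[1]:
            raise ValidationError("event indices outside the recorded sample range")
        if self.signal_kind not in ("raw", "envelope"):
            raise ValidationError(f"signal_kind must be 'raw' or 'envelope', got {self.signal_kind!r}")

    @property
    def n_muscles(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def reorder_canonical(self) -> "EmgRecording":
        """Return a copy with channels coerced to canonical label order."""
        order = [self.muscle_labels.index(m) for m in CANONICAL_MUSCLES]
        return EmgRecording(
            signal=self.signal[order],
            fs=self.fs,
            muscle_labels=CANONICAL_MUSCLES,
            mvc=self.mvc[order],
            events=dict(self.events),
            signal_kind=self.signal_kind,
            meta=dict(self.meta),
        )


def _load_sidecar(path: Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def read_recording(path: str | Path, sidecar: str | Path) -> EmgRecording:
    """Read a channel×time table plus its sidecar into a validated recording.

    The table's header row must contain the 14 canonical muscle labels; the
    sidecar supplies ``fs``, ``mvc`` (label → millivolts) and ``events``
    (name → sample index).  Channel order is coerced to canonical order.
    """
    df = pd.read_csv(path)
    meta = _load_sidecar(Path(sidecar))
    labels = tuple(df.columns)
    missing = [m for m in CANONICAL_MUSCLES if m not in labels]
    if missing:
        raise ValidationError(f"missing canonical channel(s): {', '.join(missing)}")
    mvc_map = meta.get("mvc", {})
    absent = [m for m in labels if m not in mvc_map]
    if absent:
        raise ValidationError(f"sidecar mvc missing channel(s): {', '.join(absent)}")
    rec = EmgRecording(
        signal=df.to_numpy(dtype=float).T,
        fs=float(meta["fs"]),
        muscle_labels=labels,
        mvc=np.array([float(mvc_map[m]) for m in labels]),
        events={k: int(v) for k, v in meta["events"].items()},
        signal_kind=meta.get("signal_kind", "raw"),
        meta={k: v for k, v in meta.items() if k not in ("fs", "mvc", "events", "signal_kind")},
    )
    return rec.reorder_canonical()


def write_recording(rec: EmgRecording, path: str | Path, sidecar: str | Path) -> None:
    """Write a recording in the format :func:`read_recording` consumes."""
    df = pd.DataFrame(rec.signal.T, columns=list(rec.muscle_labels))
    df.to_csv(path, index=False, float_format="%.8g")
    meta = {
        "fs": rec.fs,
        "mvc": {m: float(v) for m, v in zip(rec.muscle_labels, rec.mvc)},
        "events": {k: int(v) for k, v in rec.events.items()},
        "signal_kind": rec.signal_kind,
        **rec.meta,
    }
    Path(sidecar).write_text(json.dumps(meta, indent=1, sort_keys=True))
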