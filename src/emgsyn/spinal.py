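"""Spinal segmental motor-output mapping.

Muscle envelopes are projected onto the α-motoneuron pools of the
lumbosacral segments (default L2–S3) through a myotome chart: a
muscles×segments matrix of innervation weights k_ji.  The segmental
output is a weighted mean of the envelopes of the muscles a segment
innervates,

    S_j(t) = Σ_i w_ji · EMG_i(t) / Σ_i w_ji,

with w_ji = k_ji·n_i (``variant="printed"``) or w_ji = k_ji/n_i
(``variant="literature"``), where n_i is the number of segments
innervating muscle i.  Rows are then optionally multiplied by the
segment's motoneuron count MN_j to express total pool output.

The shipped chart and MN counts are literature-derived defaults and are
plain data files meant to be replaced by study-specific tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ValidationError
from .muscles import CANONICAL_MUSCLES


@dataclass
class MyotomeChart:
    """Innervation weights of muscles across spinal segments.

    ``k`` is muscles×segments and nonnegative; ``n_i`` (segments per
    muscle) is derived from the nonzero pattern of ``k``.
    """

    segments: tuple[str, ...]
    muscles: tuple[str, ...]
    k: np.ndarray
    mn_counts: dict[str, float]

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.segments = tuple(self.segments)
        self.muscles = tuple(self.muscles)
        if self.k.shape != (len(self.muscles), len(self.segments)):
            raise ValidationError("k must be muscles×segments")
        if np.any(self.k < 0):
            raise ValidationError("innervation weights must be nonnegative")
        zero = [m for m, row in zip(self.muscles, self.k) if not np.any(row > 0)]
        if zero:
            raise ValidationError(f"muscle(s) with all-zero weights: {', '.join(zero)}")
        missing = [s for s in self.segments if s not in self.mn_counts]
        if missing:
            raise ValidationError(f"mn_counts missing segment(s): {', '.join(missing)}")
        if any(self.mn_counts[s] <= 0 for s in self.segments):
            raise ValidationError("mn_counts must be strictly positive")

    @property
    def n_i(self) -> np.ndarray:
        """Number of innervating segments per muscle."""
        return (self.k > 0).sum(axis=1).astype(float)

    @property
    def mn_vector(self) -> np.ndarray:
        return np.array([float(self.mn_counts[s]) for s in self.segments])

    def subset(self, muscles: tuple[str, ...]) -> "MyotomeChart":
        """Rows reordered/reduced to the given muscle list."""
        missing = [m for m in muscles if m not in self.muscles]
        if missing:
            raise ValidationError(f"chart missing muscle(s): {', '.join(missing)}")
        idx = [self.muscles.index(m) for m in muscles]
        return MyotomeChart(self.segments, tuple(muscles), self.k[idx], dict(self.mn_counts))

    def write(self, chart_path: str | Path, mn_path: str | Path) -> None:
        df = pd.DataFrame(self.k, index=list(self.muscles), columns=list(self.segments))
        df.index.name = "muscle"
        df.to_csv(chart_path)
        Path(mn_path).write_text(json.dumps(
            {s: float(self.mn_counts[s]) for s in self.segments}, indent=1))


def load_myotome_chart(chart_path: str | Path | None = None,
                       mn_path: str | Path | None = None,
                       require: tuple[str, ...] = CANONICAL_MUSCLES) -> MyotomeChart:
    """Load a chart from CSV (+ MN-count JSON), defaulting to the packaged
    literature-derived chart; validates that all required muscles appear."""
    if chart_path is None:
        pkg = resources.files("emgsyn.data")
        chart_text = (pkg / "myotome_chart.csv").read_text()
        mn_raw = json.loads((pkg / "mn_counts.json").read_text())
        import io as _io
        df = pd.read_csv(_io.StringIO(chart_text), index_col="muscle")
    else:
        df = pd.read_csv(chart_path, index_col="muscle")
        mn_raw = json.loads(Path(mn_path).read_text()) if mn_path else {}
    mn = {k: float(v) for k, v in mn_raw.items() if not k.startswith("_")}
    missing = [m for m in require if m not in df.index]
    if missing:
        raise ValidationError(f"chart missing muscle(s): {', '.join(missing)}")
    chart = MyotomeChart(
        segments=tuple(df.columns),
        muscles=tuple(df.index),
        k=df.to_numpy(dtype=float),
        mn_counts=mn,
    )
    return chart.subset(tuple(require))


def compute_segment_output(envelope: np.ndarray, chart: MyotomeChart,
                           variant: str = "printed") -> np.ndarray:
    """Weighted-mean segmental output S_j(t) (segments×time, unscaled).

    ``variant="printed"`` weights each muscle by k_ji·n_i; the
    ``"literature"`` variant divides by the per-muscle segment count
    instead (k_ji/n_i).  A segment whose weights sum to zero yields a
    zero row and a warning rather than an error.
    """
    envelope = np.atleast_2d(np.asarray(envelope, dtype=float))
    if envelope.shape[0] != len(chart.muscles):
        raise ValidationError(
            f"envelope has {envelope.shape[0]} rows for {len(chart.muscles)} chart muscles")
    if variant == "printed":
        w = chart.k * chart.n_i[:, None]
    elif variant == "literature":
        w = chart.k / chart.n_i[:, None]
    else:
        raise ValueError(f"variant must be 'printed' or 'literature', got {variant!r}")
    totals = w.sum(axis=0)
    out = np.zeros((len(chart.segments), envelope.shape[1]))
    for j, seg in enumerate(chart.segments):
        if totals[j] <= 0:
            warnings.warn(f"segment {seg} has zero total weight; output row is zero")
            continue
        out[j] = (w[:, j] @ envelope) / totals[j]
    return out


def scale_by_mn_count(raw: np.ndarray, chart: MyotomeChart) -> np.ndarray:
    """Multiply each segment row by its motoneuron count MN_j."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.shape[0] != len(chart.segments):
        raise ValidationError("row count must equal number of chart segments")
    return raw * chart.mn_vector[:, None]


@dataclass
class SpinalMotorOutput:
    """Segments×time motor output, raw (weighted mean) and MN-scaled."""

    segments: tuple[str, ...]
    raw: np.ndarray
    scaled: np.ndarray
    variant: str


class SpinalMapper(TransformerMixin, BaseEstimator):
    """Transformer from muscle envelopes to segmental motor output.

    ``transform`` returns the MN-scaled segments×time matrix by default
    (``scale_by_mn=False`` returns the plain weighted mean); ``map_output``
    returns the full :class:`SpinalMotorOutput` with both.
    """

    def __init__(self, chart: MyotomeChart | None = None,
                 variant: str = "printed", scale_by_mn: bool = True):
        self.chart = chart
        self.variant = variant
        self.scale_by_mn = scale_by_mn

    def fit(self, X=None, y=None):
        self.chart_ = self.chart if self.chart is not None else load_myotome_chart()
        return self

    def map_output(self, X: np.ndarray) -> SpinalMotorOutput:
        if not hasattr(self, "chart_"):
            self.fit()
        raw = compute_segment_output(X, self.chart_, variant=self.variant)
        return SpinalMotorOutput(
            segments=self.chart_.segments, raw=raw,
            scaled=scale_by_mn_count(raw, self.chart_), variant=self.variant)

    def transform(self, X: np.ndarray) -> np.ndarray:
        out = self.map_output(X)
        return out.scaled if self.scale_by_mn else out.raw
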