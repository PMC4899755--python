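"""Time-dependent feedback drive functions PF(t) and NF(t).

The kinase model is driven by two measured, transcriptionally induced inputs:
a positive feedback PF(t) proportional to newly synthesized IAP protein, and a
negative feedback NF(t) proportional to the averaged, per-gene-normalized
expression kinetics of the negative regulators (A20 for BCR signalling; DUSP5
and SPRY2 for CD40 signalling).  Both are built from sampled kinetics by
shape-preserving piecewise-cubic Hermite (pchip) interpolation, which hits
every knot exactly and never overshoots between monotone knots.

Outside the sampled window the interpolant is held constant at the nearest
endpoint value: the models are only ever simulated within the measured
0–120 min window, so holding is the least-assumption extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .timecourse import TimeCourse

__all__ = ["FeedbackInput", "build_positive_feedback", "build_negative_feedback", "evaluate"]


@dataclass(frozen=True)
class FeedbackInput:
    """A pchip interpolant over sampled feedback kinetics.

    ``kind`` distinguishes the positive (IAP-derived) from the negative
    (regulator-expression-derived) drive; evaluation semantics are identical.
    """

    knot_times: np.ndarray
    knot_values: np.ndarray
    kind: str = "positive"

    def __post_init__(self) -> None:
        t = np.asarray(self.knot_times, dtype=float)
        v = np.asarray(self.knot_values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ValueError("need >= 2 knots with matching times and values")
        if np.any(np.diff(t) <= 0):
            raise ValueError("knot times must be strictly increasing")
        if t[0] != 0:
            raise ValueError("first knot time must be 0")
        if np.any(v < 0):
            raise ValueError("knot values must be non-negative")
        if self.kind not in ("positive", "negative"):
            raise ValueError(f"kind must be 'positive' or 'negative', got {self.kind!r}")
        object.__setattr__(self, "knot_times", t)
        object.__setattr__(self, "knot_values", v)
        object.__setattr__(self, "_interp", PchipInterpolator(t, v, extrapolate=False))

    def __call__(self, t):
        """Evaluate at time(s) ``t``; constant hold outside the knot range.

        Evaluation at a knot time returns the knot value exactly (bitwise),
        not the last-ulp result of the local polynomial.
        """
        scalar = np.ndim(t) == 0
        tt = np.clip(np.asarray(t, dtype=float), self.knot_times[0], self.knot_times[-1])
        y = np.asarray(self._interp(tt))
        idx = np.clip(np.searchsorted(self.knot_times, tt), 0, self.knot_times.size - 1)
        on_knot = self.knot_times[idx] == tt
        y = np.where(on_knot, self.knot_values[idx], y)
        return float(y) if scalar else y

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"time_min": self.knot_times, "value": self.knot_values, "kind": self.kind}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeedbackInput":
        df = pd.read_csv(path, sep="\t")
        kinds = df["kind"].unique()
        if len(kinds) != 1:
            raise ValueError("mixed kinds in feedback-input file")
        return cls(df["time_min"].to_numpy(float), df["value"].to_numpy(float), kind=str(kinds[0]))


def build_positive_feedback(newly_synthesized_iap: TimeCourse) -> FeedbackInput:
    """PF(t): interpolate newly synthesized IAP, rescaled to its own maximum.

    The absolute protein scale is unidentifiable from relative immunoblot
    quantification and is absorbed into the positive-feedback rate constant
    k4, so the curve is normalized to unit maximum.
    """
    values = np.asarray(newly_synthesized_iap.value, dtype=float)
    if np.any(values < 0):
        raise ValueError("newly synthesized IAP values must be non-negative")
    vmax = values.max()
    if vmax <= 0:
        raise ValueError("all-zero input: positive feedback undefined (max = 0)")
    return FeedbackInput(newly_synthesized_iap.time, values / vmax, kind="positive")


def build_negative_feedback(regulator_curves: list[TimeCourse]) -> FeedbackInput:
    """NF(t): per-gene max-normalized regulator kinetics, pointwise-averaged.

    Each regulator's expression is used relative to its own maximal value;
    the average of the normalized curves is interpolated without further
    rescaling, so the averaged maximum is <= 1 with equality only when the
    regulators peak simultaneously.
    """
    if not regulator_curves:
        raise ValueError("need at least one regulator curve")
    t0 = regulator_curves[0].time
    normalized = []
    for tc in regulator_curves:
        if tc.time.shape != t0.shape or np.any(tc.time != t0):
            raise ValueError("regulator curves must share one time grid")
        vmax = tc.value.max()
        if vmax <= 0:
            raise ValueError(f"regulator {tc.observable or '<unnamed>'} has max <= 0: normalization undefined")
        normalized.append(tc.value / vmax)
    return FeedbackInput(t0, np.mean(normalized, axis=0), kind="negative")


def evaluate(fi: FeedbackInput, t) -> np.ndarray | float:
    """Functional alias for ``fi(t)`` (constant hold outside the knot range)."""
    return fi(t)
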