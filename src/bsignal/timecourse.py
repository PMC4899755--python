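"""Time-course measurement container and tidy-TSV serialization.

A :class:`TimeCourse` holds one observable (a kinase activity, a regulator
transcript, an IAP protein level) measured under one condition: times in
minutes, per-timepoint mean, sample standard deviation over replicates, and
replicate count.  This is the universal currency passed between the
synthetic-data generators, the feedback-input builders and the fitting stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

TIDY_COLUMNS = ["condition", "stimulus", "kinase_or_gene", "time_min", "value", "sd", "n"]


@dataclass(frozen=True)
class TimeCourse:
    """One observable's measured (or simulated) trajectory.

    Parameters
    ----------
    time
        Strictly increasing sample times, minutes.
    value
        Per-timepoint mean of the observable (relative units).
    sd
        Per-timepoint sample standard deviation; 0 for noiseless series.
    n
        Replicate count per timepoint (default 1).
    condition, stimulus, observable
        Free-text labels (e.g. ``"WT"``, ``"BCR"``, ``"IKK"``).
    """

    time: np.ndarray
    value: np.ndarray
    sd: np.ndarray = None  # type: ignore[assignment]
    n: np.ndarray = None  # type: ignore[assignment]
    condition: str = ""
    stimulus: str = ""
    observable: str = ""

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        value = np.asarray(self.value, dtype=float)
        sd = np.zeros_like(value) if self.sd is None else np.asarray(self.sd, dtype=float)
        n = np.ones(value.shape, dtype=int) if self.n is None else np.asarray(self.n, dtype=int)
        if time.ndim != 1 or time.shape != value.shape or sd.shape != value.shape or n.shape != value.shape:
            raise ValueError("time, value, sd and n must be 1-D arrays of equal length")
        if time.size == 0:
            raise ValueError("empty time course")
        if np.any(np.diff(time) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(sd < 0):
            raise ValueError("sd must be non-negative")
        if np.any(n < 1):
            raise ValueError("replicate count must be >= 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "value", value)
        object.__setattr__(self, "sd", sd)
        object.__setattr__(self, "n", n)

    def __len__(self) -> int:
        return self.time.size

    @property
    def is_noiseless(self) -> bool:
        return bool(np.all(self.sd == 0))

    def with_labels(self, **labels: str) -> "TimeCourse":
        return replace(self, **labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "stimulus": self.stimulus,
                "kinase_or_gene": self.observable,
                "time_min": self.time,
                "value": self.value,
                "sd": self.sd,
                "n": self.n,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimeCourse":
        missing = [c for c in TIDY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        labels = {}
        for col, attr in [("condition", "condition"), ("stimulus", "stimulus"), ("kinase_or_gene", "observable")]:
            uniq = df[col].fillna("").unique()
            if len(uniq) != 1:
                raise ValueError(f"column {col!r} must be constant within one time course, got {list(uniq)}")
            labels[attr] = str(uniq[0])
        df = df.sort_values("time_min")
        return cls(
            time=df["time_min"].to_numpy(float),
            value=df["value"].to_numpy(float),
            sd=df["sd"].to_numpy(float),
            n=df["n"].to_numpy(int),
            **labels,
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TimeCourse":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def write_timecourses(courses: list[TimeCourse], path: str | Path) -> None:
    """Write several time courses into one tidy TSV."""
    pd.concat([tc.to_frame() for tc in courses], ignore_index=True).to_csv(path, sep="\t", index=False)


def read_timecourses(path: str | Path) -> list[TimeCourse]:
    """Read a tidy TSV, splitting on the (condition, stimulus, observable) key."""
    df = pd.read_csv(path, sep="\t")
    label_cols = ["condition", "stimulus", "kinase_or_gene"]
    df[label_cols] = df[label_cols].fillna("")  # empty labels round-trip as NaN
    out = []
    for _, grp in df.groupby(label_cols, sort=False):
        out.append(TimeCourse.from_frame(grp))
    return out
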