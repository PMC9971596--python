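"""Survival-curve containers shared across the pipeline.

Three light-weight containers move between the stages: a Kaplan-Meier step
function (``KMCurve``), the coordinate list a digitizer would extract from a
published figure (``DigitizedCurve``), and the numbers-at-risk table printed
beneath such a figure (``RiskTable``). Times are in months throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["KMCurve", "DigitizedCurve", "RiskTable", "DAYS_PER_MONTH"]

#: Fixed month length used everywhere cycles (21 days) meet months.
DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class KMCurve:
    """A right-continuous Kaplan-Meier step function.

    ``times`` are the distinct event times (months, increasing) and
    ``survival`` the product-limit estimate just after each of them.
    S(t) = 1 for t before the first event time.
    """

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("times and survival must be 1-d arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any((s < -1e-12) | (s > 1 + 1e-12)):
            raise ValueError("survival values must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)

    @property
    def t_max(self) -> float:
        return float(self.times[-1]) if self.times.size else 0.0

    def evaluate(self, t) -> np.ndarray:
        """S(t) for scalar or array ``t`` (right-continuous step lookup)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("negative time")
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "survival": self.survival})


@dataclass(frozen=True)
class DigitizedCurve:
    """Coordinates read off a published KM figure: (time, survival) pairs.

    The first point is (0, 1.0); it is prepended automatically when absent.
    Times strictly increase and survival is non-increasing within [0, 1].
    """

    points: np.ndarray  # shape (k, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise ValueError("points must be a (k, 2) array")
        if not (pts[0, 0] == 0.0 and abs(pts[0, 1] - 1.0) < 1e-9):
            pts = np.vstack([[0.0, 1.0], pts])
        if np.any(np.diff(pts[:, 0]) <= 0):
            raise ValueError("digitized times must be strictly increasing")
        if np.any(np.diff(pts[:, 1]) > 1e-9):
            raise ValueError("digitized survival must be non-increasing")
        if np.any((pts[:, 1] < -1e-9) | (pts[:, 1] > 1 + 1e-9)):
            raise ValueError("digitized survival must lie in [0, 1]")
        object.__setattr__(self, "points", pts)

    @property
    def times(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def survival(self) -> np.ndarray:
        return self.points[:, 1]

    def truncate(self, t_max: float) -> "DigitizedCurve":
        """Drop coordinates after ``t_max`` (inclusive boundary).

        Mirrors the manual removal of terminal digitization artifacts: the
        retained points are untouched, later ones discarded.
        """
        if t_max <= 0:
            raise ValueError("t_max must be positive")
        keep = self.points[self.points[:, 0] <= t_max]
        if keep.shape[0] < 2:
            raise ValueError(f"t_max={t_max} leaves fewer than two points")
        return DigitizedCurve(keep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "survival": self.survival})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DigitizedCurve":
        cols = [c for c in df.columns if "time" in c.lower()], [
            c for c in df.columns if "surv" in c.lower()
        ]
        if not cols[0] or not cols[1]:
            raise ValueError("need a time column and a survival column")
        return cls(np.column_stack([df[cols[0][0]], df[cols[1][0]]]))


@dataclass(frozen=True)
class RiskTable:
    """Numbers at risk at scheduled times, as printed under a KM figure."""

    times: np.ndarray
    n_risk: np.ndarray
    total_events: int | None = field(default=None)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_risk, dtype=int)
        if t.ndim != 1 or t.shape != n.shape or t.size < 1:
            raise ValueError("times and n_risk must be equal-length 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(np.diff(n) > 0):
            raise ValueError("n_risk must be non-increasing")
        if np.any(n < 0):
            raise ValueError("n_risk must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_risk", n)

    @property
    def n_total(self) -> int:
        return int(self.n_risk[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "n_risk": self.n_risk})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, total_events: int | None = None) -> "RiskTable":
        tcol = next(c for c in df.columns if "time" in c.lower())
        ncol = next(c for c in df.columns if "risk" in c.lower())
        return cls(df[tcol].to_numpy(), df[ncol].to_numpy(), total_events)
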