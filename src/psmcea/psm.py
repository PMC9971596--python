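"""Partitioned survival model engine: curves → per-cycle state occupancy.

A three-state model (progression-free, progressed, dead) is read directly
off the two survival endpoints, with no transition probabilities:

    pfs(c)   = min(S_PFS(c), S_OS(c))
    pd(c)    = max(S_OS(c) - S_PFS(c), 0)
    death(c) = 1 - S_OS(c)

Each arm's survival series is a splice: early cycles are read from the
observed KM step function (evaluated at cycle boundaries), later cycles from
the fitted parametric model — the standard within-trial / extrapolation
split. The model cycle is 21 days; months are converted at 30.4375
days/month. Cycle 0 is model entry (t = 0, everyone progression-free) and no
half-cycle correction is applied: costs and utilities downstream accrue on
the state occupied at each cycle start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import DAYS_PER_MONTH, KMCurve
from .parametric import SurvivalModel

__all__ = [
    "CYCLE_DAYS",
    "cycle_to_months",
    "ArmCurveSet",
    "survival_series",
    "occupancy",
    "check_horizon",
]

CYCLE_DAYS = 21.0


def cycle_to_months(cycle) -> np.ndarray:
    return np.asarray(cycle, dtype=float) * CYCLE_DAYS / DAYS_PER_MONTH


@dataclass(frozen=True)
class ArmCurveSet:
    """Everything needed to build one arm's survival series.

    ``km_cutoff_cycles`` is the last cycle read from the KM curve for each
    endpoint (the within-trial period); beyond it the parametric model takes
    over. ``splice_mode='anchored'`` rescales the parametric tail to meet the
    KM value at the cutoff; ``'raw'`` (default) uses the fitted curve as is.
    """

    label: str
    pfs_km: KMCurve
    os_km: KMCurve
    pfs_model: SurvivalModel
    os_model: SurvivalModel
    pfs_cutoff_cycles: int
    os_cutoff_cycles: int
    splice_mode: str = "raw"

    def __post_init__(self) -> None:
        if self.pfs_cutoff_cycles < 0 or self.os_cutoff_cycles < 0:
            raise ValueError("cutoff cycles must be >= 0")
        if self.splice_mode not in ("raw", "anchored"):
            raise ValueError("splice_mode must be 'raw' or 'anchored'")


def survival_series(
    km: KMCurve,
    model: SurvivalModel,
    cutoff: int,
    horizon: int,
    mode: str = "raw",
) -> np.ndarray:
    """Spliced survival probabilities at cycles 0..horizon inclusive.

    Cycles 0..cutoff come from the KM step function evaluated at the cycle
    boundary; cycles cutoff+1..horizon from the parametric model, optionally
    rescaled (``mode='anchored'``) by S_km(cutoff)/S_model(cutoff) so the
    series is continuous at the splice.
    """
    if cutoff > horizon:
        raise ValueError("cutoff cannot exceed the horizon")
    if mode not in ("raw", "anchored"):
        raise ValueError("mode must be 'raw' or 'anchored'")
    cycles = np.arange(horizon + 1)
    t_months = cycle_to_months(cycles)
    if cutoff > 0 and t_months[cutoff] > km.t_max + 1e-9:
        raise ValueError(
            f"KM curve ends at {km.t_max:.2f} months, before cutoff cycle {cutoff}"
        )
    series = np.empty(horizon + 1)
    series[: cutoff + 1] = km.evaluate(t_months[: cutoff + 1])
    if cutoff < horizon:
        tail = np.asarray(model.survival_at(t_months[cutoff + 1 :]), dtype=float)
        if mode == "anchored":
            s_model_cut = float(model.survival_at(t_months[cutoff]))
            anchor = series[cutoff] / s_model_cut if s_model_cut > 0 else 0.0
            tail = np.minimum(tail * anchor, 1.0)
        series[cutoff + 1 :] = tail
    # the splice can introduce a tiny upward step; occupancy needs a
    # non-increasing series
    return np.minimum.accumulate(np.clip(series, 0.0, 1.0))


def occupancy(arm: ArmCurveSet, horizon: int = 104) -> pd.DataFrame:
    """Per-cycle state occupancy for one arm over cycles 0..horizon.

    Returns a DataFrame with columns cycle, t_days, t_months, pfs, pd,
    death; each row sums to 1. PFS > OS crossings (possible because the two
    endpoints are fitted independently) are clamped to OS.
    """
    s_pfs = survival_series(
        arm.pfs_km, arm.pfs_model, arm.pfs_cutoff_cycles, horizon, arm.splice_mode
    )
    s_os = survival_series(
        arm.os_km, arm.os_model, arm.os_cutoff_cycles, horizon, arm.splice_mode
    )
    return occupancy_from_series(s_pfs, s_os)


def occupancy_from_series(s_pfs: np.ndarray, s_os: np.ndarray) -> pd.DataFrame:
    """State occupancy from two survival series (cycle 0..H aligned)."""
    s_pfs = np.asarray(s_pfs, dtype=float)
    s_os = np.asarray(s_os, dtype=float)
    if s_pfs.shape != s_os.shape:
        raise ValueError("series must be aligned")
    pfs = np.minimum(s_pfs, s_os)
    pd_frac = np.maximum(s_os - s_pfs, 0.0)
    death = 1.0 - s_os
    cycles = np.arange(s_pfs.size)
    return pd.DataFrame(
        {
            "cycle": cycles,
            "t_days": cycles * CYCLE_DAYS,
            "t_months": cycle_to_months(cycles),
            "pfs": pfs,
            "pd": pd_frac,
            "death": death,
        }
    )


def check_horizon(occ: pd.DataFrame) -> float:
    """Fraction dead at the final cycle (horizon adequacy check).

    The model horizon is chosen so nearly the whole cohort (>= 99%) has died
    by the last cycle; the caller should warn when the returned value falls
    short of that.
    """
    return float(occ["death"].iloc[-1])
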