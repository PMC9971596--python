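"""Synthetic two-arm trial generator.

Every downstream stage of the pipeline (pseudo-IPD reconstruction, parametric
fitting, the economic model) is exercised against trials simulated here with
known ground truth, because the published trial deposits no patient-level
data. An arm draws Weibull progression-free survival (PFS) and overall
survival (OS) times, applies independent exponential dropout plus
administrative censoring at the end of follow-up, and can emit the resulting
KM step curve, numbers-at-risk table, and a "digitized" coordinate list that
emulates manual point extraction from a published figure.

PFS and OS are simulated marginally and constrained per subject by
``PFS := min(PFS, OS)``, which guarantees the ordering the partitioned
survival model assumes; the marginal PFS parameters are therefore
approximate (slightly stochastically smaller than the nominal Weibull).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .curves import DigitizedCurve, KMCurve, RiskTable

__all__ = ["ArmSimSpec", "simulate_arm", "km_estimate", "n_at_risk", "digitize"]


@dataclass(frozen=True)
class ArmSimSpec:
    """Ground-truth description of one simulated trial arm.

    Scales are in months; ``censor_rate`` is the exponential dropout hazard
    per month (0 disables dropout); ``max_followup`` administratively
    censors both endpoints.
    """

    label: str
    n_subjects: int
    pfs_shape: float
    pfs_scale: float
    os_shape: float
    os_scale: float
    censor_rate: float = 0.0
    max_followup: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for name in ("pfs_shape", "pfs_scale", "os_shape", "os_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.max_followup <= 0:
            raise ValueError("max_followup must be positive")


def simulate_arm(spec: ArmSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one arm; returns ``(pfs_ipd, os_ipd)`` DataFrames.

    Each frame has columns ``time`` (months, > 0) and ``event`` (1 = event
    observed, 0 = censored). A subject's dropout time is shared between the
    two endpoints, so the recorded PFS time never exceeds the recorded OS
    time. Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    os_t = spec.os_scale * rng.weibull(spec.os_shape, size=n)
    pfs_t = np.minimum(spec.pfs_scale * rng.weibull(spec.pfs_shape, size=n), os_t)
    if spec.censor_rate > 0:
        dropout = rng.exponential(1.0 / spec.censor_rate, size=n)
    else:
        dropout = np.full(n, np.inf)
    censor = np.minimum(dropout, spec.max_followup)

    def _records(t_event: np.ndarray) -> pd.DataFrame:
        observed = t_event <= censor
        time = np.where(observed, t_event, censor)
        # guard against exact zeros from the RNG; survival times are positive
        time = np.maximum(time, 1e-9)
        return pd.DataFrame({"time": time, "event": observed.astype(int)})

    return _records(pfs_t), _records(os_t)


def km_estimate(ipd: pd.DataFrame) -> KMCurve:
    """Product-limit estimate of an IPD frame (columns ``time``, ``event``)."""
    if len(ipd) == 0:
        raise ValueError("cannot estimate a KM curve from no records")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(ipd["time"], ipd["event"])
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0
    t, s = t[keep], s[keep]
    if t.size == 0:  # all censored at time ~0 edge case
        t, s = np.array([ipd["time"].max()]), np.array([1.0])
    return KMCurve(t, s)


def n_at_risk(ipd: pd.DataFrame, times) -> RiskTable:
    """Numbers at risk at the requested times (subjects with follow-up >= t)."""
    times = np.asarray(times, dtype=float)
    t_obs = ipd["time"].to_numpy()
    n = np.array([(t_obs >= t).sum() for t in times], dtype=int)
    return RiskTable(times, n)


def digitize(
    curve: KMCurve,
    n_points: int = 100,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> DigitizedCurve:
    """Emulate manual point extraction from a plotted KM curve.

    Samples the step function on an even time grid from 0 to the last event
    time. ``jitter_sd`` adds Gaussian reading error to the survival values,
    after which the points are clipped to [0, 1] and repaired to a
    non-increasing sequence by isotonic regression, mimicking how a careful
    digitizer resolves small inconsistencies.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.linspace(0.0, curve.t_max, n_points)
    surv = np.asarray(curve.evaluate(grid), dtype=float)
    surv[0] = 1.0
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        surv = surv + rng.normal(0.0, jitter_sd, size=surv.size)
        surv[0] = 1.0
        surv = np.clip(surv, 0.0, 1.0)
        iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
        surv = iso.fit_transform(grid, surv)
        surv[0] = 1.0
    return DigitizedCurve(np.column_stack([grid, surv]))
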