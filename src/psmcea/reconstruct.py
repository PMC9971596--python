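"""Pseudo individual-patient-data reconstruction from digitized KM curves.

Published trials usually report survival only as a plotted Kaplan-Meier
curve plus a numbers-at-risk table. The algorithm of Guyot et al. (2012)
inverts the product-limit construction: within each risk-table interval it
guesses how many subjects were censored (assumed uniform over the interval),
places events at the digitized drop points so the running KM estimate tracks
the digitized survival, and iteratively adjusts the censoring count until
the implied number at risk at the next risk time matches the printed table.
Beyond the last risk time the previous interval's censoring rate is reused,
or, when the total event count is published, censoring is tuned to match it.

The result is one (time, event) record per enrolled subject — "pseudo-IPD" —
suitable for maximum-likelihood fitting of parametric survival models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curves import DigitizedCurve, RiskTable

__all__ = ["reconstruct", "truncate_curve"]

_MAX_ITER = 1000


class InconsistentRiskTable(ValueError):
    """Digitized curve and risk table cannot be reconciled."""


def truncate_curve(curve: DigitizedCurve, t_max: float) -> DigitizedCurve:
    """Drop digitized points after ``t_max`` (inclusive).

    Used to remove terminal digitization artifacts ("extreme points") before
    fitting; retained coordinates are unchanged.
    """
    return curve.truncate(t_max)


def reconstruct(curve: DigitizedCurve, risk: RiskTable) -> pd.DataFrame:
    """Reconstruct pseudo-IPD from a digitized curve and its risk table.

    Returns a DataFrame with columns ``time`` (months) and ``event``
    (1 = event, 0 = censored), with exactly ``risk.n_risk[0]`` rows.

    Raises :class:`InconsistentRiskTable` when no non-negative censoring
    pattern can reconcile the curve with the table in some interval.
    """
    t = curve.times
    s = curve.survival
    k_total = t.size
    rt, rn = risk.times, risk.n_risk
    n_int = rt.size
    if n_int < 2 and risk.total_events is None:
        raise ValueError("need >= 2 risk-table entries (or total_events) to reconstruct")
    if rt[0] > t[0] + 1e-9:
        raise ValueError("risk table must start at (or before) the first curve point")

    # click index ranges per risk interval: lower[i] .. upper[i]
    lower = np.searchsorted(t, rt, side="left")
    upper = np.empty(n_int, dtype=int)
    upper[:-1] = np.searchsorted(t, rt[1:], side="left") - 1
    upper[-1] = k_total - 1

    d = np.zeros(k_total, dtype=int)  # events at click k
    cen = np.zeros(k_total, dtype=int)  # censorings in (t[k], t[k+1])
    cen_times: list[list[float]] = [[] for _ in range(k_total)]
    n_hat = np.zeros(k_total + 1, dtype=float)
    n_hat[0] = rn[0]

    km_last = 1.0  # running KM estimate at the last event click
    last_rate = 0.0  # censoring rate of the most recent completed interval

    def _round(x: float) -> int:
        # round half away from zero, as censor/event counts are integers
        return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0

    def _process_interval(i: int, n_censor: int, t_end: float, km_in: float):
        """Distribute ``n_censor`` censorings uniformly over interval ``i``,
        place events at the digitized drops, and return the state at the
        interval's end. Pure in everything except the d/cen/cen_times slices
        it writes, which are overwritten on every call."""
        lo, up = lower[i], upper[i]
        if n_censor > 0:
            ct = t[lo] + (np.arange(1, n_censor + 1)) * (t_end - t[lo]) / (n_censor + 1)
        else:
            ct = np.array([])
        km = km_in
        n_run = n_hat[lo]
        for k in range(lo, up + 1):
            if k == 0:
                d[k] = 0
            else:
                want = n_run * (1.0 - s[k] / km) if km > 0 else 0.0
                d[k] = min(max(_round(want), 0), int(n_run))
            if n_run > 0 and d[k] > 0:
                km = km * (1.0 - d[k] / n_run)
            in_gap = (ct >= t[k]) & (ct < (t[k + 1] if k < up else t_end + 1e-9))
            cen[k] = int(in_gap.sum())
            cen_times[k] = list(ct[in_gap])
            n_run = n_run - d[k] - cen[k]
            n_hat[k + 1] = n_run
        return n_run, km

    for i in range(n_int - 1):
        lo, nxt = lower[i], lower[i + 1]
        # initial censoring guess: uniform censoring consistent with the
        # survival drop across the interval
        guess = _round(n_hat[lo] * s[min(nxt, k_total - 1)] / max(s[lo], 1e-300)) - rn[i + 1]
        n_censor = max(guess, 0)
        for _ in range(_MAX_ITER):
            n_end, km_out = _process_interval(i, n_censor, rt[i + 1], km_last)
            if n_end < 0:
                raise InconsistentRiskTable(
                    f"interval {i} ({rt[i]:g}-{rt[i + 1]:g} months): implied "
                    f"number at risk is negative"
                )
            diff = int(round(n_end - rn[i + 1]))
            if diff == 0:
                break
            adjusted = n_censor + diff
            if adjusted < 0:
                # the digitized drops alone already take the at-risk count
                # below the table (grid discretization); accept the mismatch
                # with no censoring rather than invent negative counts
                if n_censor != 0:
                    n_end, km_out = _process_interval(i, 0, rt[i + 1], km_last)
                    n_censor = 0
                break
            if adjusted == n_censor:
                break
            n_censor = adjusted
        else:
            raise InconsistentRiskTable(
                f"interval {i} ({rt[i]:g}-{rt[i + 1]:g} months): censoring "
                f"adjustment did not converge"
            )
        km_last = km_out
        width = rt[i + 1] - rt[i]
        last_rate = n_censor / width if width > 0 else 0.0
        # carry the computed at-risk count into the next interval (it can
        # differ from the printed table by rounding)
        n_hat[lower[i + 1]] = n_end

    # tail beyond the last risk time
    i = n_int - 1
    lo = lower[i]
    t_end = max(t[-1], rt[-1]) + 1e-9
    if lo < k_total:
        tail_span = max(t[-1] - rt[i], 0.0)
        n_censor = min(_round(last_rate * tail_span), int(rn[i]))
        _process_interval(i, n_censor, t_end, km_last)
        if risk.total_events is not None:
            for _ in range(_MAX_ITER):
                total_d = int(d.sum())
                if total_d == risk.total_events:
                    break
                n_censor = int(np.clip(n_censor + (total_d - risk.total_events), 0, rn[i]))
                _process_interval(i, n_censor, t_end, km_last)
            # integer censoring cannot always hit the target; pin the last
            # event click so the published event total is honoured exactly
            total_d = int(d.sum())
            if total_d != risk.total_events:
                ev_clicks = np.nonzero(d)[0]
                k_fix = ev_clicks[-1] if ev_clicks.size else k_total - 1
                d[k_fix] = max(d[k_fix] - (total_d - risk.total_events), 0)
                _rebalance_tail(d, cen, n_hat, lo, k_total)

    # assemble records: events at drop times, censorings at distributed
    # times, survivors administratively censored at the curve end
    times: list[float] = []
    events: list[int] = []
    for k in range(k_total):
        times.extend([t[k]] * d[k])
        events.extend([1] * d[k])
        times.extend(cen_times[k][: cen[k]])
        events.extend([0] * cen[k])
    leftover = int(round(rn[0] - len(times)))
    if leftover < 0:
        raise InconsistentRiskTable("reconstructed more subjects than enrolled")
    times.extend([t[-1]] * leftover)
    events.extend([0] * leftover)
    ipd = pd.DataFrame({"time": times, "event": events}).sort_values(
        ["time", "event"], ascending=[True, False], kind="stable"
    )
    return ipd.reset_index(drop=True)


def _rebalance_tail(d, cen, n_hat, lo, k_total) -> None:
    """Recompute the running at-risk count after a manual event adjustment."""
    n_run = n_hat[lo]
    for k in range(lo, k_total):
        d[k] = min(d[k], int(max(n_run, 0)))
        n_run -= d[k]
        cen[k] = min(cen[k], int(max(n_run, 0)))
        n_run -= cen[k]
        n_hat[k + 1] = n_run
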