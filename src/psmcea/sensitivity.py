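"""Sensitivity and scenario analyses around the base-case economic model.

Three layers of robustness checking:

* one-way deterministic sensitivity analysis (DSA): each parameter is moved
  to its low and high bound in turn with everything else at base, and the
  resulting ICER swing is ranked in tornado order;
* probabilistic sensitivity analysis (PSA): all varied parameters are drawn
  jointly — costs from gamma distributions, utilities from beta
  distributions, each moment-matched to the base value with an SE of 20% of
  base — for 1,000 Monte Carlo evaluations, summarised as an incremental
  cost/effect scatter and a cost-effectiveness acceptability curve (CEAC);
* scenarios: alternative utility sets and stepwise reductions of the
  camrelizumab acquisition price.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .economics import CEResult, EconomicInputs, evaluate, with_price_cut

__all__ = [
    "ParamRange",
    "PSASpec",
    "one_way_dsa",
    "moment_match_gamma",
    "moment_match_beta",
    "run_psa",
    "ceac",
    "default_dsa_ranges",
    "apply_overrides",
    "scenario_price_reduction",
    "scenario_utilities",
    "default_wtp_grid",
]


# ---------------------------------------------------------------------------
# deterministic (one-way) sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamRange:
    """One parameter's base value and DSA bounds."""

    name: str
    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"{self.name}: need low <= base <= high")

    @classmethod
    def pct(cls, name: str, base: float, fraction: float = 0.25) -> "ParamRange":
        return cls(name, base, base * (1 - fraction), base * (1 + fraction))


def one_way_dsa(
    model: Callable[[dict], float], ranges: list[ParamRange]
) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low and high bound.

    ``model`` maps a {parameter-name: value} override dict to an ICER.
    Undefined ICERs at an endpoint are recorded as NaN rather than aborting.
    Rows are sorted by swing width, descending.
    """
    rows = []
    for r in ranges:
        out = {}
        for side, value in (("icer_at_low", r.low), ("icer_at_high", r.high)):
            try:
                out[side] = float(model({r.name: value}))
            except ZeroDivisionError:
                out[side] = float("nan")
        width = abs(out["icer_at_high"] - out["icer_at_low"])
        rows.append({"name": r.name, **out, "width": width})
    df = pd.DataFrame(rows)
    return df.sort_values("width", ascending=False, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# moment matching for PSA draws
# ---------------------------------------------------------------------------


def moment_match_gamma(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) whose mean and SD equal ``mean`` and ``se``."""
    if mean <= 0 or se <= 0:
        raise ValueError("mean and se must be positive")
    shape = (mean / se) ** 2
    return shape, se**2 / mean


def moment_match_beta(mean: float, se: float) -> tuple[float, float]:
    """Beta (a, b) whose mean and SD equal ``mean`` and ``se``."""
    if not 0 < mean < 1:
        raise ValueError("mean must lie strictly in (0, 1)")
    if se**2 >= mean * (1 - mean):
        raise ValueError("variance too large for a beta distribution")
    nu = mean * (1 - mean) / se**2 - 1
    return mean * nu, (1 - mean) * nu


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSASpec:
    """PSA configuration: draw count, seed and the SE rule (20% of base)."""

    n_draws: int = 1000
    seed: int = 0
    se_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_draws <= 0:
            raise ValueError("n_draws must be positive")
        if self.se_fraction <= 0:
            raise ValueError("se_fraction must be positive")


#: (parameter name, distribution family) pairs varied in the PSA: the eight
#: per-cycle/one-time cost parameters and the two health-state utilities.
PSA_PARAMS: tuple[tuple[str, str], ...] = (
    ("arm1.one_time", "gamma"),
    ("arm1.cost_pfs", "gamma"),
    ("arm1.cost_maintenance", "gamma"),
    ("arm1.cost_pd", "gamma"),
    ("arm0.one_time", "gamma"),
    ("arm0.cost_pfs", "gamma"),
    ("arm0.cost_maintenance", "gamma"),
    ("arm0.cost_pd", "gamma"),
    ("u_pfs", "beta"),
    ("u_pd", "beta"),
)


def _get_param(inputs: EconomicInputs, name: str) -> float:
    if "." in name:
        arm_name, attr = name.split(".", 1)
        return getattr(getattr(inputs, arm_name), attr)
    return getattr(inputs, name)


def apply_overrides(inputs: EconomicInputs, overrides: dict) -> EconomicInputs:
    """Return a copy of ``inputs`` with dotted-path parameter overrides.

    When an arm's phase costs are rescaled, the drug component line is kept
    within bounds so scenario machinery stays consistent.
    """
    arm_updates: dict[str, dict] = {}
    top_updates: dict[str, float] = {}
    for name, value in overrides.items():
        if "." in name:
            arm_name, attr = name.split(".", 1)
            arm_updates.setdefault(arm_name, {})[attr] = float(value)
        else:
            top_updates[name] = float(value)
    new = inputs
    for arm_name, upd in arm_updates.items():
        arm = getattr(new, arm_name)
        pfs = upd.get("cost_pfs", arm.cost_pfs)
        maint = upd.get("cost_maintenance", arm.cost_maintenance)
        drug = upd.get("drug_component", arm.drug_component)
        upd["drug_component"] = min(drug, pfs, maint)
        new = replace(new, **{arm_name: replace(arm, **upd)})
    if top_updates:
        new = replace(new, **top_updates)
    return new


def draw_psa_parameters(
    inputs: EconomicInputs, spec: PSASpec
) -> pd.DataFrame:
    """Moment-matched gamma/beta draws of the varied parameters.

    One row per Monte Carlo draw, one column per parameter, deterministic
    for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cols = {}
    for name, dist in PSA_PARAMS:
        base = _get_param(inputs, name)
        se = spec.se_fraction * base
        if dist == "gamma":
            shape, scale = moment_match_gamma(base, se)
            cols[name] = rng.gamma(shape, scale, size=spec.n_draws)
        else:
            a, b = moment_match_beta(base, se)
            cols[name] = rng.beta(a, b, size=spec.n_draws)
    return pd.DataFrame(cols)


def run_psa(
    model: Callable[[dict], tuple[float, float]],
    inputs: EconomicInputs,
    spec: PSASpec,
) -> pd.DataFrame:
    """Monte Carlo PSA: returns a frame of (inc_cost, inc_qalys) per draw.

    ``model`` maps a parameter-override dict to (ΔC, ΔE). The frame carries
    summary attrs: mean ΔC, mean ΔE and the ICER of the means.
    """
    params = draw_psa_parameters(inputs, spec)
    d_cost = np.empty(spec.n_draws)
    d_eff = np.empty(spec.n_draws)
    for i in range(spec.n_draws):
        d_cost[i], d_eff[i] = model(params.iloc[i].to_dict())
    out = pd.DataFrame({"inc_cost": d_cost, "inc_qalys": d_eff})
    out.attrs["mean_inc_cost"] = float(d_cost.mean())
    out.attrs["mean_inc_qalys"] = float(d_eff.mean())
    out.attrs["icer_of_means"] = float(d_cost.mean() / d_eff.mean())
    return out


def default_wtp_grid() -> np.ndarray:
    """WTP grid for the CEAC: 0 to 60,000 USD/QALY in 1,000 steps."""
    return np.arange(0, 60001, 1000, dtype=float)


def ceac(draws: pd.DataFrame, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from PSA draws.

    At each willingness-to-pay λ, the probability of cost-effectiveness is
    the fraction of draws with positive incremental net monetary benefit
    λ·ΔE − ΔC; dominated and dominant draws are retained in the count.
    """
    if draws.empty:
        raise ValueError("no PSA draws")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    dc = draws["inc_cost"].to_numpy()
    de = draws["inc_qalys"].to_numpy()
    prob = [(lam * de - dc > 0).mean() for lam in grid]
    return pd.DataFrame({"wtp_usd_per_qaly": grid, "prob_cost_effective": prob})


# ---------------------------------------------------------------------------
# DSA parameter set and scenarios
# ---------------------------------------------------------------------------


def default_dsa_ranges(inputs: EconomicInputs) -> list[ParamRange]:
    """The standard tornado parameter set.

    Cost parameters vary ±25% of base; utilities move over their published
    95% ranges (progression-free 0.603-0.840, progressed 0.050-0.473);
    the annual discount rate spans 0-8%.
    """
    ranges = [
        ParamRange.pct(name, _get_param(inputs, name))
        for name, dist in PSA_PARAMS
        if dist == "gamma"
    ]
    ranges.append(ParamRange("u_pfs", inputs.u_pfs, 0.603, 0.840))
    ranges.append(ParamRange("u_pd", inputs.u_pd, 0.050, 0.473))
    ranges.append(ParamRange("discount_rate", inputs.discount_rate, 0.0, 0.08))
    return ranges


def scenario_price_reduction(
    occ1: pd.DataFrame, occ0: pd.DataFrame, inputs: EconomicInputs, fraction: float
) -> CEResult:
    """Re-run the model with the camrelizumab price cut by ``fraction``.

    Only the arm-1 drug acquisition line changes, so incremental QALYs are
    untouched and the ICER falls affinely in the cut fraction.
    """
    return evaluate(occ1, occ0, with_price_cut(inputs, fraction))


def scenario_utilities(
    occ1: pd.DataFrame,
    occ0: pd.DataFrame,
    inputs: EconomicInputs,
    u_pfs: float = 0.71,
    u_pd: float = 0.67,
) -> CEResult:
    """Re-run the model with an alternative utility set; costs unchanged."""
    return evaluate(occ1, occ0, replace(inputs, u_pfs=u_pfs, u_pd=u_pd))
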