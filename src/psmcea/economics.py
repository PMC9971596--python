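"""Costing and health-outcome valuation over state occupancy.

The cost model follows the treatment phases of the trial regimen. Each
21-day cycle a progression-free patient accrues the induction cost (cycles
0-6, i.e. the first ~4.2 months of platinum doublet ± camrelizumab), then
the maintenance cost (cycles 7-34); progressed patients accrue the
progressed-disease cost, which folds in subsequent-line therapy. In the
camrelizumab arm the drug cannot be given beyond two years, so from cycle 35
onward every alive state accrues the progressed-disease cost. Adverse-event
management and pre-treatment workup (puncture, PD-L1 test) enter once, as an
undiscounted one-time cost in the first cycle.

QALYs weight time in state by its utility (progression-free 0.804,
progressed 0.321 in the base case) and both costs and QALYs are discounted
at 5%/year, with the cycle clock converted at 365 days/year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AdverseEvent",
    "AECostTable",
    "AtomicCostInputs",
    "ArmCosts",
    "EconomicInputs",
    "CEResult",
    "one_time_cost",
    "drug_cost_per_dose",
    "cycle_cost",
    "discount_factor",
    "total_cost",
    "total_qalys",
    "icer",
    "nmb",
    "evaluate",
    "with_price_cut",
]

DAYS_PER_YEAR = 365.0


# ---------------------------------------------------------------------------
# one-time costs: adverse events + pre-treatment workup
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdverseEvent:
    name: str
    cost_per_patient: float  # USD, management cost of one grade 3+ episode
    incidence_arm1: float  # camrelizumab + chemotherapy arm
    incidence_arm0: float  # chemotherapy-alone arm

    def __post_init__(self) -> None:
        if not (0 <= self.incidence_arm1 <= 1 and 0 <= self.incidence_arm0 <= 1):
            raise ValueError(f"{self.name}: incidences must be probabilities")


def _default_ae_rows() -> tuple[AdverseEvent, ...]:
    # grade 3+ events reported in >10% of either trial arm
    return (
        AdverseEvent("neutrophil count decreased", 455.62, 0.38, 0.30),
        AdverseEvent("white blood cell count decreased", 455.62, 0.20, 0.14),
        AdverseEvent("anemia", 88.76, 0.19, 0.11),
        AdverseEvent("platelet count decreased", 5482.40, 0.17, 0.12),
    )


@dataclass(frozen=True)
class AECostTable:
    """Adverse-event management costs plus one-off pre-treatment costs."""

    rows: tuple[AdverseEvent, ...] = field(default_factory=_default_ae_rows)
    puncture: float = 443.79
    pdl1_test: float = 295.86


def one_time_cost(ae: AECostTable, arm: int) -> float:
    """Expected one-time cost per patient for ``arm`` (1 = camrelizumab).

    Sum of incidence-weighted adverse-event management costs plus the
    pre-treatment puncture and PD-L1 test, applied once at model entry.
    """
    inc = [(r.incidence_arm1 if arm == 1 else r.incidence_arm0, r.cost_per_patient) for r in ae.rows]
    return float(sum(p * c for p, c in inc) + ae.puncture + ae.pdl1_test)


# ---------------------------------------------------------------------------
# drug acquisition atoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomicCostInputs:
    """Unit prices and dosing rules for the regimen's drugs (USD).

    Fractional-vial pricing is assumed (no vial waste): a dose costs
    dose_mg / vial_mg x vial price. Carboplatin is dosed by AUC in the
    clinic; the model carries the implied milligram dose directly.
    """

    camrelizumab_vial_price: float = 433.14  # per 200 mg, post-insurance
    camrelizumab_dose_mg: float = 200.0  # fixed dose
    pemetrexed_vial_price: float = 404.71  # per 500 mg
    pemetrexed_dose_per_m2: float = 500.0  # mg/m2
    body_surface_area: float = 1.72  # m2, Chinese population mean
    carboplatin_vial_price: float = 4.49  # per 50 mg
    carboplatin_dose_mg: float = 750.0  # AUC-5 equivalent
    outpatient_fee: float = 3.70  # per cycle
    blood_test: float = 7.40  # per cycle
    imaging: float = 73.96  # every 6 weeks to week 54, then every 12


def drug_cost_per_dose(atomic: AtomicCostInputs, drug: str) -> float:
    """Acquisition cost of one administration of ``drug``."""
    if drug == "camrelizumab":
        return atomic.camrelizumab_dose_mg / 200.0 * atomic.camrelizumab_vial_price
    if drug == "pemetrexed":
        dose = atomic.pemetrexed_dose_per_m2 * atomic.body_surface_area
        return dose / 500.0 * atomic.pemetrexed_vial_price
    if drug == "carboplatin":
        return atomic.carboplatin_dose_mg / 50.0 * atomic.carboplatin_vial_price
    raise ValueError(f"unknown drug {drug!r}")


# ---------------------------------------------------------------------------
# per-cycle cost schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArmCosts:
    """One arm's per-cycle cost parameters (USD per 21-day cycle).

    ``drug_component`` is the per-cycle acquisition cost of the arm's
    immunotherapy within ``cost_pfs``/``cost_maintenance``; price-reduction
    scenarios rescale this line item only. ``cap_cycle`` implements a
    treatment-duration cap: from that cycle on, every alive state accrues
    ``cost_pd`` (None disables the cap).
    """

    cost_pfs: float
    cost_maintenance: float
    cost_pd: float
    one_time: float
    drug_component: float = 0.0
    cap_cycle: int | None = None

    def __post_init__(self) -> None:
        for name in ("cost_pfs", "cost_maintenance", "cost_pd", "one_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.drug_component > min(self.cost_pfs, self.cost_maintenance) + 1e-9:
            raise ValueError("drug_component cannot exceed the phase costs it is part of")


@dataclass(frozen=True)
class EconomicInputs:
    """Full parameter set of the economic model (base case = trial values)."""

    arm1: ArmCosts = field(
        default_factory=lambda: ArmCosts(
            cost_pfs=904.48,
            cost_maintenance=837.13,
            cost_pd=388.96,
            one_time=1952.78,
            drug_component=433.14,
            cap_cycle=35,
        )
    )
    arm0: ArmCosts = field(
        default_factory=lambda: ArmCosts(
            cost_pfs=774.54,
            cost_maintenance=707.19,
            cost_pd=421.67,
            one_time=1607.77,
        )
    )
    u_pfs: float = 0.804
    u_pd: float = 0.321
    discount_rate: float = 0.05  # per year
    cycle_days: float = 21.0
    induction_end: int = 6  # last induction cycle; maintenance starts at 7
    wtp: float = 35936.09  # USD/QALY (3x GDP per capita, China 2021)

    def __post_init__(self) -> None:
        if not (0 <= self.u_pfs <= 1 and 0 <= self.u_pd <= 1):
            raise ValueError("utilities must lie in [0, 1]")
        if not (0 <= self.discount_rate <= 1):
            raise ValueError("discount rate must lie in [0, 1]")

    def arm(self, index: int) -> ArmCosts:
        return self.arm1 if index == 1 else self.arm0


def cycle_cost(arm: ArmCosts, cycle: int, state: str, inputs: EconomicInputs) -> float:
    """Cost accrued by one patient in ``state`` during ``cycle``."""
    if state not in ("pfs", "pd"):
        raise ValueError("state must be 'pfs' or 'pd'")
    if arm.cap_cycle is not None and cycle >= arm.cap_cycle:
        return arm.cost_pd
    if state == "pd":
        return arm.cost_pd
    return arm.cost_pfs if cycle <= inputs.induction_end else arm.cost_maintenance


def discount_factor(cycle, rate: float, cycle_days: float = 21.0) -> np.ndarray:
    """(1+r)^(-t) with t in years, evaluated at cycle starts."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    years = np.asarray(cycle, dtype=float) * cycle_days / DAYS_PER_YEAR
    out = (1.0 + rate) ** (-years)
    return out if out.ndim else float(out)


def total_cost(occ: pd.DataFrame, arm: ArmCosts, inputs: EconomicInputs) -> float:
    """Discounted lifetime cost per patient for one arm.

    One-time cost enters undiscounted at cycle 0; thereafter each cycle's
    state-occupancy fractions are costed by the phase schedule and
    discounted. Dead patients accrue nothing.
    """
    cycles = occ["cycle"].to_numpy()
    df = discount_factor(cycles, inputs.discount_rate, inputs.cycle_days)
    c_pfs = np.array([cycle_cost(arm, int(c), "pfs", inputs) for c in cycles])
    c_pd = np.array([cycle_cost(arm, int(c), "pd", inputs) for c in cycles])
    running = df * (occ["pfs"].to_numpy() * c_pfs + occ["pd"].to_numpy() * c_pd)
    return float(arm.one_time + running.sum())


def total_qalys(occ: pd.DataFrame, inputs: EconomicInputs) -> float:
    """Discounted QALYs per patient: utility-weighted, discounted cycle time."""
    cycles = occ["cycle"].to_numpy()
    df = discount_factor(cycles, inputs.discount_rate, inputs.cycle_days)
    q = df * (occ["pfs"].to_numpy() * inputs.u_pfs + occ["pd"].to_numpy() * inputs.u_pd)
    return float(q.sum() * inputs.cycle_days / DAYS_PER_YEAR)


# ---------------------------------------------------------------------------
# incremental results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CEResult:
    """Per-arm discounted totals and the incremental comparison."""

    cost1: float
    qalys1: float
    cost0: float
    qalys0: float
    wtp: float

    @property
    def inc_cost(self) -> float:
        return self.cost1 - self.cost0

    @property
    def inc_qalys(self) -> float:
        return self.qalys1 - self.qalys0

    @property
    def icer(self) -> float:
        return icer((self.cost1, self.qalys1), (self.cost0, self.qalys0))

    @property
    def icer_or_nan(self) -> float:
        """ICER, or NaN when incremental effectiveness is zero."""
        try:
            return self.icer
        except ZeroDivisionError:
            return float("nan")

    @property
    def inc_nmb(self) -> float:
        return nmb(self.inc_cost, self.inc_qalys, self.wtp)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "chemotherapy": {"cost_usd": self.cost0, "qalys": self.qalys0},
            "camrelizumab+chemotherapy": {"cost_usd": self.cost1, "qalys": self.qalys1},
            "incremental": {
                "cost_usd": self.inc_cost,
                "qalys": self.inc_qalys,
                "icer_usd_per_qaly": self.icer_or_nan,
            },
        }
        return pd.DataFrame(rows).T


def icer(result1: tuple[float, float], result0: tuple[float, float]) -> float:
    """Incremental cost-effectiveness ratio, computed on unrounded inputs.

    Raises on ΔE = 0; a negative value signals dominance (ΔC < 0 with
    ΔE > 0, or the reverse) and should be read alongside the signs.
    """
    d_cost = result1[0] - result0[0]
    d_eff = result1[1] - result0[1]
    if d_eff == 0:
        raise ZeroDivisionError("ICER undefined: incremental effectiveness is zero")
    return d_cost / d_eff


def nmb(cost: float, qalys: float, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp``: λ·E − C."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * qalys - cost


def evaluate(occ1: pd.DataFrame, occ0: pd.DataFrame, inputs: EconomicInputs) -> CEResult:
    """Run the cost and QALY accrual for both arms on fixed occupancies."""
    return CEResult(
        cost1=total_cost(occ1, inputs.arm1, inputs),
        qalys1=total_qalys(occ1, inputs),
        cost0=total_cost(occ0, inputs.arm0, inputs),
        qalys0=total_qalys(occ0, inputs),
        wtp=inputs.wtp,
    )


def with_price_cut(inputs: EconomicInputs, fraction: float) -> EconomicInputs:
    """Economic inputs with the arm-1 drug acquisition line reduced by ``fraction``."""
    if not (0 <= fraction <= 1):
        raise ValueError("price-cut fraction must lie in [0, 1]")
    a = inputs.arm1
    if a.drug_component <= 0:
        raise ValueError("arm-1 config carries no separate drug acquisition line")
    saving = a.drug_component * fraction
    new_arm = replace(
        a,
        cost_pfs=a.cost_pfs - saving,
        cost_maintenance=a.cost_maintenance - saving,
        drug_component=a.drug_component - saving,
    )
    return replace(inputs, arm1=new_arm)
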