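"""Run configuration: YAML/JSON in, validated ``RunConfig`` out.

A configuration describes the whole pipeline: where each arm's survival
data comes from (files of digitized coordinates and risk tables, or a
simulation spec with known ground truth), the KM/parametric splice cutoffs,
the parametric-family preference rule, and every economic parameter. Omitted
fields fall back to the shipped base case (``data/paper_basecase.yaml``),
whose values are the published trial analysis's inputs; unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .economics import AdverseEvent, AECostTable, ArmCosts, EconomicInputs
from .sensitivity import PSASpec
from .synthetic import ArmSimSpec

__all__ = ["RunConfig", "ArmConfig", "load_config", "paper_basecase_path"]

_DATA_DIR = Path(__file__).parent / "data"


def paper_basecase_path() -> Path:
    """Path of the shipped base-case configuration."""
    return _DATA_DIR / "paper_basecase.yaml"


@dataclass(frozen=True)
class ArmConfig:
    """One arm's survival-data source and splice cutoffs."""

    label: str
    pfs_cutoff_cycles: int
    os_cutoff_cycles: int
    simulate: ArmSimSpec | None = None
    files: dict | None = None  # pfs_curve/pfs_risk/os_curve/os_risk paths
    truncate_after_months: dict | None = None  # optional per-endpoint t_max

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.files is None):
            raise ValueError(f"arm {self.label!r}: provide exactly one of simulate/files")
        if self.files is not None:
            missing = {"pfs_curve", "pfs_risk", "os_curve", "os_risk"} - set(self.files)
            if missing:
                raise ValueError(f"arm {self.label!r}: missing file keys {sorted(missing)}")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    horizon_cycles: int = 104
    splice_mode: str = "raw"
    preferred_family: str = "weibull"
    family_tolerance: float = 0.05
    digitize_points: int = 200
    risk_interval_months: float = 3.0
    arm1: ArmConfig = None  # type: ignore[assignment]
    arm0: ArmConfig = None  # type: ignore[assignment]
    economics: EconomicInputs = field(default_factory=EconomicInputs)
    ae_table: AECostTable = field(default_factory=AECostTable)
    psa: PSASpec = field(default_factory=PSASpec)
    price_cuts: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7)
    scenario_u_pfs: float = 0.71
    scenario_u_pd: float = 0.67

    def __post_init__(self) -> None:
        if self.horizon_cycles < max(
            self.arm1.pfs_cutoff_cycles,
            self.arm1.os_cutoff_cycles,
            self.arm0.pfs_cutoff_cycles,
            self.arm0.os_cutoff_cycles,
        ):
            raise ValueError("horizon must cover every KM cutoff")
        if self.splice_mode not in ("raw", "anchored"):
            raise ValueError("splice_mode must be 'raw' or 'anchored'")


# ---------------------------------------------------------------------------
# dict <-> dataclass plumbing
# ---------------------------------------------------------------------------


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def _arm_config(d: dict, where: str) -> ArmConfig:
    _check_keys(
        d,
        {"label", "km_cutoff_cycles", "simulate", "files", "truncate_after_months"},
        where,
    )
    cut = d.get("km_cutoff_cycles", {})
    sim = None
    if "simulate" in d:
        sim = ArmSimSpec(label=d.get("label", where), **d["simulate"])
    return ArmConfig(
        label=d.get("label", where),
        pfs_cutoff_cycles=int(cut.get("pfs", 0)),
        os_cutoff_cycles=int(cut.get("os", 0)),
        simulate=sim,
        files=d.get("files"),
        truncate_after_months=d.get("truncate_after_months"),
    )


def _economics(d: dict) -> EconomicInputs:
    _check_keys(
        d,
        {"arm1", "arm0", "u_pfs", "u_pd", "discount_rate", "cycle_days",
         "induction_end", "wtp"},
        "economics",
    )
    kwargs = {k: v for k, v in d.items() if k not in ("arm1", "arm0")}
    for arm_key in ("arm1", "arm0"):
        if arm_key in d:
            arm_d = dict(d[arm_key])
            _check_keys(
                arm_d,
                {f.name for f in dataclasses.fields(ArmCosts)},
                f"economics.{arm_key}",
            )
            kwargs[arm_key] = ArmCosts(**arm_d)
    return EconomicInputs(**kwargs)


def _ae_table(d: dict) -> AECostTable:
    _check_keys(d, {"rows", "puncture", "pdl1_test"}, "ae_table")
    kwargs = {k: v for k, v in d.items() if k != "rows"}
    if "rows" in d:
        kwargs["rows"] = tuple(AdverseEvent(**row) for row in d["rows"])
    return AECostTable(**kwargs)


_TOP_KEYS = {
    "seed", "horizon_cycles", "splice_mode", "preferred_family",
    "family_tolerance", "digitize_points", "risk_interval_months",
    "arms", "economics", "ae_table", "psa", "scenarios",
}


def config_from_dict(raw: dict) -> RunConfig:
    raw = raw or {}
    _check_keys(raw, _TOP_KEYS, "config")
    base = _default_raw()
    merged = _deep_merge(base, raw)
    arms = merged.pop("arms")
    scen = merged.pop("scenarios", {})
    _check_keys(scen, {"price_cuts", "utilities"}, "scenarios")
    psa_d = merged.pop("psa", {})
    _check_keys(psa_d, {"n_draws", "seed", "se_fraction"}, "psa")
    utilities = scen.get("utilities", {})
    return RunConfig(
        seed=int(merged.pop("seed")),
        horizon_cycles=int(merged.pop("horizon_cycles")),
        splice_mode=merged.pop("splice_mode"),
        preferred_family=merged.pop("preferred_family"),
        family_tolerance=float(merged.pop("family_tolerance")),
        digitize_points=int(merged.pop("digitize_points")),
        risk_interval_months=float(merged.pop("risk_interval_months")),
        arm1=_arm_config(arms["arm1"], "arms.arm1"),
        arm0=_arm_config(arms["arm0"], "arms.arm0"),
        economics=_economics(merged.pop("economics")),
        ae_table=_ae_table(merged.pop("ae_table")),
        psa=PSASpec(**psa_d),
        price_cuts=tuple(scen.get("price_cuts", ())),
        scenario_u_pfs=float(utilities.get("u_pfs", 0.71)),
        scenario_u_pd=float(utilities.get("u_pd", 0.67)),
    )


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict) and k != "arms":
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def _default_raw() -> dict:
    with open(paper_basecase_path()) as fh:
        return yaml.safe_load(fh)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a run configuration.

    ``None`` (or an empty file) yields the shipped base case. YAML and JSON
    are both accepted.
    """
    if path is None:
        return config_from_dict({})
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    return config_from_dict(raw or {})


def config_to_dict(cfg: RunConfig) -> dict:
    """Serialize a config back to the dict form ``config_from_dict`` accepts."""

    def arm_dict(a: ArmConfig) -> dict:
        d: dict = {
            "label": a.label,
            "km_cutoff_cycles": {"pfs": a.pfs_cutoff_cycles, "os": a.os_cutoff_cycles},
        }
        if a.simulate is not None:
            sim = dataclasses.asdict(a.simulate)
            sim.pop("label")
            d["simulate"] = sim
        if a.files is not None:
            d["files"] = dict(a.files)
        if a.truncate_after_months is not None:
            d["truncate_after_months"] = dict(a.truncate_after_months)
        return d

    eco = cfg.economics
    return {
        "seed": cfg.seed,
        "horizon_cycles": cfg.horizon_cycles,
        "splice_mode": cfg.splice_mode,
        "preferred_family": cfg.preferred_family,
        "family_tolerance": cfg.family_tolerance,
        "digitize_points": cfg.digitize_points,
        "risk_interval_months": cfg.risk_interval_months,
        "arms": {"arm1": arm_dict(cfg.arm1), "arm0": arm_dict(cfg.arm0)},
        "economics": {
            "arm1": dataclasses.asdict(eco.arm1),
            "arm0": dataclasses.asdict(eco.arm0),
            "u_pfs": eco.u_pfs,
            "u_pd": eco.u_pd,
            "discount_rate": eco.discount_rate,
            "cycle_days": eco.cycle_days,
            "induction_end": eco.induction_end,
            "wtp": eco.wtp,
        },
        "ae_table": {
            "rows": [dataclasses.asdict(r) for r in cfg.ae_table.rows],
            "puncture": cfg.ae_table.puncture,
            "pdl1_test": cfg.ae_table.pdl1_test,
        },
        "psa": dataclasses.asdict(cfg.psa),
        "scenarios": {
            "price_cuts": list(cfg.price_cuts),
            "utilities": {"u_pfs": cfg.scenario_u_pfs, "u_pd": cfg.scenario_u_pd},
        },
    }
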