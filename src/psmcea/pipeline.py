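"""End-to-end pipeline: survival data → occupancy → economics → analyses.

One call chains every stage: obtain each arm's digitized curves and risk
tables (from files, or by simulating a trial, plotting its KM curves and
"digitizing" them), reconstruct pseudo-IPD, fit and select a parametric
family per endpoint, splice KM + parametric survival into three-state
occupancy, and run the base-case, deterministic, probabilistic and scenario
analyses. All artifacts are returned in memory and optionally written as
headed CSV files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import economics as eco
from . import parametric, psm, reconstruct, sensitivity, synthetic
from .config import ArmConfig, RunConfig
from .curves import DigitizedCurve, KMCurve, RiskTable

__all__ = ["ArmArtifacts", "PipelineResult", "run_pipeline", "prepare_arm"]

log = logging.getLogger(__name__)


def _substream_seed(*parts: int) -> int:
    """Deterministic child seed (< 2^31) from the top-level seed."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % 2**31)


@dataclass
class ArmArtifacts:
    """Everything produced for one arm on the way to its occupancy."""

    label: str
    pfs_ipd: pd.DataFrame
    os_ipd: pd.DataFrame
    pfs_curve: DigitizedCurve
    os_curve: DigitizedCurve
    pfs_risk: RiskTable
    os_risk: RiskTable
    pfs_km: KMCurve
    os_km: KMCurve
    pfs_fit_table: pd.DataFrame
    os_fit_table: pd.DataFrame
    pfs_model: parametric.SurvivalModel
    os_model: parametric.SurvivalModel
    occupancy: pd.DataFrame


@dataclass
class PipelineResult:
    config: RunConfig
    arm1: ArmArtifacts
    arm0: ArmArtifacts
    base_case: eco.CEResult
    tornado: pd.DataFrame
    psa_draws: pd.DataFrame
    ceac: pd.DataFrame
    scenarios: pd.DataFrame


def _risk_times(t_max: float, interval: float) -> np.ndarray:
    return np.arange(0.0, t_max, interval)


def prepare_arm(arm_cfg: ArmConfig, cfg: RunConfig) -> ArmArtifacts:
    """Produce one arm's pseudo-IPD, fitted models and occupancy."""
    if arm_cfg.simulate is not None:
        sim = dataclasses.replace(
            arm_cfg.simulate, seed=_substream_seed(cfg.seed, arm_cfg.simulate.seed)
        )
        log.info("arm %s: simulating n=%d (seed %d)", arm_cfg.label, sim.n_subjects, sim.seed)
        pfs_src, os_src = synthetic.simulate_arm(sim)
        curves, risks = {}, {}
        for name, ipd in (("pfs", pfs_src), ("os", os_src)):
            km = synthetic.km_estimate(ipd)
            risks[name] = synthetic.n_at_risk(ipd, _risk_times(km.t_max, cfg.risk_interval_months))
            curves[name] = synthetic.digitize(km, cfg.digitize_points, jitter_sd=0.0)
    else:
        curves, risks = {}, {}
        for name in ("pfs", "os"):
            cdf = pd.read_csv(arm_cfg.files[f"{name}_curve"])
            rdf = pd.read_csv(arm_cfg.files[f"{name}_risk"])
            curves[name] = DigitizedCurve.from_frame(cdf)
            risks[name] = RiskTable.from_frame(rdf)
    if arm_cfg.truncate_after_months:
        for name, t_max in arm_cfg.truncate_after_months.items():
            curves[name] = reconstruct.truncate_curve(curves[name], t_max)

    ipds, kms, tables, models = {}, {}, {}, {}
    for name in ("pfs", "os"):
        ipds[name] = reconstruct.reconstruct(curves[name], risks[name])
        kms[name] = synthetic.km_estimate(ipds[name])
        tables[name] = parametric.compare_families(ipds[name])
        family = parametric.select_family(
            tables[name], cfg.preferred_family, cfg.family_tolerance
        )
        models[name] = parametric.fit(ipds[name], family)
        log.info(
            "arm %s %s: %d subjects reconstructed, family %s (median %.2f months)",
            arm_cfg.label, name, len(ipds[name]), family, models[name].median(),
        )

    curveset = psm.ArmCurveSet(
        label=arm_cfg.label,
        pfs_km=kms["pfs"],
        os_km=kms["os"],
        pfs_model=models["pfs"],
        os_model=models["os"],
        pfs_cutoff_cycles=arm_cfg.pfs_cutoff_cycles,
        os_cutoff_cycles=arm_cfg.os_cutoff_cycles,
        splice_mode=cfg.splice_mode,
    )
    occ = psm.occupancy(curveset, cfg.horizon_cycles)
    dead = psm.check_horizon(occ)
    if dead < 0.99:
        log.warning("arm %s: only %.1f%% dead at the horizon", arm_cfg.label, 100 * dead)
    return ArmArtifacts(
        label=arm_cfg.label,
        pfs_ipd=ipds["pfs"], os_ipd=ipds["os"],
        pfs_curve=curves["pfs"], os_curve=curves["os"],
        pfs_risk=risks["pfs"], os_risk=risks["os"],
        pfs_km=kms["pfs"], os_km=kms["os"],
        pfs_fit_table=tables["pfs"], os_fit_table=tables["os"],
        pfs_model=models["pfs"], os_model=models["os"],
        occupancy=occ,
    )


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage; write artifact CSVs under ``outdir`` when given."""
    inputs = cfg.economics
    for arm_idx in (1, 0):
        arm = inputs.arm(arm_idx)
        log.info(
            "arm%d economics: pfs=%.2f maintenance=%.2f pd=%.2f one_time=%.2f USD/cycle",
            arm_idx, arm.cost_pfs, arm.cost_maintenance, arm.cost_pd, arm.one_time,
        )
    log.info("utilities u_pfs=%.3f u_pd=%.3f, discount %.1f%%/yr, WTP %.2f USD/QALY",
             inputs.u_pfs, inputs.u_pd, 100 * inputs.discount_rate, inputs.wtp)

    arm1 = prepare_arm(cfg.arm1, cfg)
    arm0 = prepare_arm(cfg.arm0, cfg)
    occ1, occ0 = arm1.occupancy, arm0.occupancy

    base = eco.evaluate(occ1, occ0, inputs)
    log.info("base case: ΔC=%.2f USD, ΔE=%.4f QALY, ICER=%.2f USD/QALY",
             base.inc_cost, base.inc_qalys, base.icer_or_nan)

    def icer_model(overrides: dict) -> float:
        return eco.evaluate(occ1, occ0, sensitivity.apply_overrides(inputs, overrides)).icer

    tornado = sensitivity.one_way_dsa(icer_model, sensitivity.default_dsa_ranges(inputs))

    def psa_model(overrides: dict) -> tuple[float, float]:
        res = eco.evaluate(occ1, occ0, sensitivity.apply_overrides(inputs, overrides))
        return res.inc_cost, res.inc_qalys

    psa_spec = dataclasses.replace(cfg.psa, seed=_substream_seed(cfg.seed, cfg.psa.seed, 97))
    draws = sensitivity.run_psa(psa_model, inputs, psa_spec)
    ceac_df = sensitivity.ceac(draws)

    scen_rows = [{
        "scenario": "base case",
        "inc_cost_usd": base.inc_cost,
        "inc_qalys": base.inc_qalys,
        "icer_usd_per_qaly": base.icer_or_nan,
    }]
    alt = sensitivity.scenario_utilities(occ1, occ0, inputs, cfg.scenario_u_pfs, cfg.scenario_u_pd)
    scen_rows.append({
        "scenario": f"utilities {cfg.scenario_u_pfs}/{cfg.scenario_u_pd}",
        "inc_cost_usd": alt.inc_cost,
        "inc_qalys": alt.inc_qalys,
        "icer_usd_per_qaly": alt.icer_or_nan,
    })
    for cut in cfg.price_cuts:
        r = sensitivity.scenario_price_reduction(occ1, occ0, inputs, cut)
        scen_rows.append({
            "scenario": f"{int(round(100 * cut))}% price reduction",
            "inc_cost_usd": r.inc_cost,
            "inc_qalys": r.inc_qalys,
            "icer_usd_per_qaly": r.icer_or_nan,
        })
    scenarios = pd.DataFrame(scen_rows)

    result = PipelineResult(
        config=cfg, arm1=arm1, arm0=arm0, base_case=base,
        tornado=tornado, psa_draws=draws, ceac=ceac_df, scenarios=scenarios,
    )
    if outdir is not None:
        write_artifacts(result, Path(outdir))
    return result


def write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for tag, arm in (("arm1", result.arm1), ("arm0", result.arm0)):
        occ = arm.occupancy.rename(columns={
            "t_days": "t_days", "t_months": "t_months",
            "pfs": "pfs_fraction", "pd": "pd_fraction", "death": "death_fraction",
        })
        occ.to_csv(outdir / f"occupancy_{tag}.csv", index=False)
        for name in ("pfs", "os"):
            getattr(arm, f"{name}_ipd").rename(
                columns={"time": "time_months", "event": "event"}
            ).to_csv(outdir / f"ipd_{tag}_{name}.csv", index=False)
            getattr(arm, f"{name}_fit_table").to_csv(
                outdir / f"fit_{tag}_{name}.csv", index=False
            )
    result.base_case.to_frame().to_csv(outdir / "base_case.csv")
    result.tornado.rename(columns={
        "icer_at_low": "icer_at_low_usd_per_qaly",
        "icer_at_high": "icer_at_high_usd_per_qaly",
        "width": "width_usd_per_qaly",
    }).to_csv(outdir / "tornado.csv", index=False)
    result.psa_draws.rename(columns={
        "inc_cost": "inc_cost_usd", "inc_qalys": "inc_qalys",
    }).to_csv(outdir / "psa_draws.csv", index=False)
    result.ceac.to_csv(outdir / "ceac.csv", index=False)
    result.scenarios.to_csv(outdir / "scenarios.csv", index=False)
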