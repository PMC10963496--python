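"""End-to-end subject workflow: model build -> calibration -> physiomarkers.

For one subject-condition the pipeline runs, in order:

1. network read / validation;
2. analytic stiffness estimate and diastolic anchoring of the tube law
   from the record's MPA pressure/area pairs;
3. nominal Windkessel parameterization (with the left-lung flow
   recomputed as Q_MPA - Q_RPA for obstructed records);
4. multi-start calibration of the global Windkessel scaling factors;
5. a final converged periodic solve at the calibrated factors;
6. wall-shear physiomarkers (TAWSS/OSI per role, phi) and the summary
   row used by the cohort statistics.

The measured inputs {mPAP, PCWP, Q_MPA(t)} drive the model; the
calibration set {P_sys, P_dia, A_sys, A_dia, Q_LPA(t), Q_RPA(t)} is only
ever compared against model output, never prescribed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationResult,
    SubjectRecord,
    calibrate,
    model_from_record,
    nominal_from_record,
)
from .network import ArterialNetwork, read_timeseries
from .shear import shear_report
from .solver import SolverConfig, solve_to_periodic
from .stats import mpap, pvr
from .windkessel import apply_scaling

__all__ = ["RunConfig", "run_subject", "load_record"]

log = logging.getLogger(__name__)

ROLES = ("MPA", "LPA", "RPA", "intralobar")


@dataclass
class RunConfig:
    """Pipeline options (solver resolution, calibration, shear cutoffs)."""

    solver: SolverConfig = field(default_factory=SolverConfig)
    n_starts: int = 10
    seed: int = 0
    weights: str = "normalized"
    tawss_cutoff: float = 5.0
    osi_cutoff: float = 0.05
    phi_scope: str = "intralobar"
    gamma: float | None = None  # None: use the network's gamma

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        solver = SolverConfig(**doc.pop("solver", {}))
        return cls(solver=solver, **doc)

    def to_json(self, path) -> None:
        doc = {
            "solver": {
                "dx": self.solver.dx,
                "dt": self.solver.dt,
                "cycle_tolerance": self.solver.cycle_tolerance,
                "max_cycles": self.solver.max_cycles,
                "cfl_number": self.solver.cfl_number,
                "dt_floor": self.solver.dt_floor,
            },
            "n_starts": self.n_starts,
            "seed": self.seed,
            "weights": self.weights,
            "tawss_cutoff": self.tawss_cutoff,
            "osi_cutoff": self.osi_cutoff,
            "phi_scope": self.phi_scope,
            "gamma": self.gamma,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def load_record(data_dir, condition: str = "baseline") -> SubjectRecord:
    """Read a subject-condition record from a directory of plain files.

    Expects ``scalars.json`` (p_sys, p_dia, p_pcw, a_sys, a_dia, optional
    t_decay) and waveform CSVs ``q_mpa.csv``, ``q_lpa.csv``, ``q_rpa.csv``
    with header time_s,value.
    """
    d = Path(data_dir)
    with open(d / "scalars.json") as fh:
        sc = json.load(fh)
    return SubjectRecord(
        p_sys=sc["p_sys"],
        p_dia=sc["p_dia"],
        p_pcw=sc["p_pcw"],
        a_sys=sc["a_sys"],
        a_dia=sc["a_dia"],
        q_mpa=read_timeseries(d / "q_mpa.csv"),
        q_lpa=read_timeseries(d / "q_lpa.csv"),
        q_rpa=read_timeseries(d / "q_rpa.csv"),
        condition=condition,
        t_decay=sc.get("t_decay"),
    )


def save_record(record: SubjectRecord, data_dir) -> None:
    """Write a subject-condition record as scalars.json + waveform CSVs."""
    from .network import write_timeseries

    d = Path(data_dir)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "scalars.json", "w") as fh:
        json.dump(
            {
                "p_sys": record.p_sys,
                "p_dia": record.p_dia,
                "p_pcw": record.p_pcw,
                "a_sys": record.a_sys,
                "a_dia": record.a_dia,
                "t_decay": record.t_decay,
                "condition": record.condition,
            },
            fh,
            indent=1,
        )
    write_timeseries(record.q_mpa, d / "q_mpa.csv")
    write_timeseries(record.q_lpa, d / "q_lpa.csv")
    write_timeseries(record.q_rpa, d / "q_rpa.csv")


def run_subject(
    net: ArterialNetwork,
    record: SubjectRecord,
    config: RunConfig = RunConfig(),
    subject: str = "subject",
) -> dict:
    """Run the full workflow for one subject-condition.

    Returns a summary dict with hemodynamic scalars, calibrated
    Windkessel totals, role-averaged shear metrics, phi, the calibrated
    scaling factors, fit diagnostics, and stage timings.
    """
    timings = {}
    t0 = time.perf_counter()

    model_net, wall = model_from_record(net, record)
    wks_nominal = nominal_from_record(model_net, record)
    timings["setup_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cal: CalibrationResult = calibrate(
        net,
        record,
        cfg=config.solver,
        n_starts=config.n_starts,
        seed=config.seed,
        weights=config.weights,
    )
    timings["calibration_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    wks = apply_scaling(wks_nominal, cal.theta_best)
    state = solve_to_periodic(
        model_net, wall, wks, record.q_mpa, config.solver
    )
    timings["final_solve_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    report = shear_report(
        model_net,
        state,
        gamma=config.gamma,
        tawss_cutoff=config.tawss_cutoff,
        osi_cutoff=config.osi_cutoff,
        scope=config.phi_scope,
    )
    timings["shear_s"] = time.perf_counter() - t0

    mean_pap = mpap(record.p_sys, record.p_dia)
    summary = {
        "subject": subject,
        "condition": record.condition,
        "mpap": mean_pap,
        "pvr": pvr(mean_pap, record.p_pcw, record.q_mpa.mean),
        "stiffness": wall.stiffness,
        "r_prox_total": wks.r_prox_total,
        "r_dist_total": wks.r_dist_total,
        "c_total": wks.c_total,
        "phi": report.phi,
        "theta_r_prox": cal.theta_best.r_prox,
        "theta_r_dist": cal.theta_best.r_dist,
        "theta_c": cal.theta_best.compliance,
        "calibration_cost": cal.cost_best,
        "calibration_all_agree": cal.all_agree,
        "cycles_used": state.cycles_used,
        "cycle_metric": state.cycle_metric,
    }
    tbl = report.table
    for role in ROLES:
        sub = tbl[tbl["role"] == role]
        summary[f"tawss_{role}"] = float(sub["tawss"].mean())
        summary[f"osi_{role}"] = float(sub["osi"].mean())
    summary.update({f"fit_{k}": v for k, v in cal.diagnostics.items()})
    summary["timings"] = timings
    log.info(
        "subject %s/%s: mPAP %.1f mmHg, phi %.1f%%, theta %s",
        subject,
        record.condition,
        mean_pap,
        report.phi,
        cal.theta_best.as_tuple(),
    )
    return summary


def summary_frame(summaries: list[dict]) -> pd.DataFrame:
    """Tabulate run_subject summaries (drops the nested timing dict)."""
    rows = [
        {k: v for k, v in s.items() if not isinstance(v, dict)}
        for s in summaries
    ]
    return pd.DataFrame(rows)
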