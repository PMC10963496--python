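#!/usr/bin/env python
"""Generate the paired virtual cohort (5 subjects, baseline + CTEPH).

Each subject is a self-consistent ground-truth model: a canine-scale
bifurcating tree, a periodic inlet flow, three-element Windkessel outlets,
and a CTEPH condition produced by raising outlet resistances (left-lung
biased), lowering compliance, stiffening the wall, and reducing stroke
volume. Writes one directory per subject under results/cohort/ with the
network file, baseline and CTEPH records, and the retained ground truth.
"""

import json
from pathlib import Path

from pulmo1d.network import write_network
from pulmo1d.pipeline import save_record
from pulmo1d.solver import SolverConfig
from pulmo1d.synthetic import default_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"

N_SUBJECTS = 5
SEED = 0
NOISE = 0.0
SOLVER = SolverConfig(dx=0.25, cycle_tolerance=1e-9)


def main() -> None:
    cohort = default_cohort(
        n_subjects=N_SUBJECTS, seed=SEED, noise=NOISE, solver_config=SOLVER
    )
    for i, vs in enumerate(cohort):
        d = OUT / f"S{i + 1}"
        d.mkdir(parents=True, exist_ok=True)
        write_network(vs.network, d / "network.json")
        save_record(vs.baseline_record, d / "baseline")
        save_record(vs.cteph_record, d / "cteph")
        with open(d / "ground_truth.json", "w") as fh:
            json.dump({
                "theta_truth_baseline": vs.theta_truth.as_tuple(),
                "theta_truth_cteph": vs.theta_truth_cteph.as_tuple(),
                "stiffness_baseline": vs.wall_truth.stiffness,
                "stiffness_cteph": vs.wall_truth_cteph.stiffness,
                "transform": vs.transform.__dict__,
                "seed": vs.seed,
            }, fh, indent=1)
        br, cr = vs.baseline_record, vs.cteph_record
        print(f"S{i + 1}: baseline mPAP {br.mpap:5.1f} mmHg, "
              f"CTEPH mPAP {cr.mpap:5.1f} mmHg, "
              f"left-lung share {br.q_lpa.mean / br.q_mpa.mean:.2f} -> "
              f"{(cr.q_mpa.mean - cr.q_rpa.mean) / cr.q_mpa.mean:.2f}")
    print(f"\ncohort written to {OUT}")


if __name__ == "__main__":
    main()
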