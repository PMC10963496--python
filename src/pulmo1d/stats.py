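"""Cohort summaries and paired statistics across subject-conditions.

Each subject contributes one baseline and one CTEPH row of model outputs
(mPAP, PVR, stiffness Eh/r0, Windkessel totals, TAWSS and OSI by vessel
role, and the low-shear/high-oscillation percentage phi). Disease effects
are assessed with paired one-sided t-tests (the direction of each
hypothesis is specified a priori from clinical understanding), and
between-subject disease progression is explored with Pearson correlations
of the relative changes (CTEPH - baseline)/baseline of each output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "mpap",
    "pvr",
    "paired_one_sided_t",
    "cohort_table",
    "paired_tests",
    "relative_change_correlations",
    "DEFAULT_DIRECTIONS",
]

log = logging.getLogger(__name__)

#: a-priori directions of change from baseline to CTEPH for each cohort
#: output ('greater' means CTEPH > baseline is the alternative)
DEFAULT_DIRECTIONS: dict[str, str] = {
    "mpap": "greater",
    "pvr": "greater",
    "stiffness": "greater",
    "r_prox_total": "greater",
    "r_dist_total": "greater",
    "c_total": "less",
    "tawss_MPA": "less",
    "tawss_LPA": "less",
    "tawss_RPA": "less",
    "tawss_intralobar": "less",
    "phi": "greater",
}

#: relative variance below which a column is dropped from the correlation
#: analysis (mirrors excluding outputs whose values are essentially zero)
VARIANCE_FLOOR = 1.0e-12


def mpap(p_sys: float, p_dia: float) -> float:
    """Weighted mean pulmonary artery pressure 1/3 P_sys + 2/3 P_dia."""
    if p_sys < p_dia:
        raise ValueError("need P_sys >= P_dia")
    return p_sys / 3.0 + 2.0 * p_dia / 3.0


def pvr(mean_pap: float, p_pcw: float, q_mean: float) -> float:
    """Pulmonary vascular resistance (mPAP - PCWP)/mean flow, mmHg*s/mL."""
    if q_mean <= 0:
        raise ValueError("mean flow must be > 0")
    return (mean_pap - p_pcw) / q_mean


def paired_one_sided_t(
    x_base: np.ndarray,
    x_cteph: np.ndarray,
    direction: str = "greater",
) -> tuple[float, float]:
    """Paired one-sided t-test on differences d = CTEPH - baseline.

    direction 'greater' tests H1: CTEPH > baseline; 'less' the reverse.
    Returns (t, p) with t = dbar/(s_d/sqrt(n)) on n-1 degrees of freedom.
    Zero-variance differences with a nonzero mean yield p = 0 (or 1) with
    a warning, as the t statistic degenerates.
    """
    x_base = np.asarray(x_base, dtype=float)
    x_cteph = np.asarray(x_cteph, dtype=float)
    if x_base.shape != x_cteph.shape:
        raise ValueError("paired samples must have equal length")
    n = x_base.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    d = x_cteph - x_base
    if direction == "less":
        d = -d
    sd = float(np.std(d, ddof=1))
    dbar = float(np.mean(d))
    if sd == 0.0:
        if dbar == 0.0:
            return 0.0, 0.5
        warnings.warn(
            "zero variance of paired differences; p degenerates",
            stacklevel=2,
        )
        return float("inf") if dbar > 0 else float("-inf"), (
            0.0 if dbar > 0 else 1.0
        )
    t = dbar / (sd / np.sqrt(n))
    p = float(sps.t.sf(t, df=n - 1))
    return float(t), p


def cohort_table(summaries: list[dict]) -> pd.DataFrame:
    """Assemble per-subject-condition summaries into a paired cohort table.

    Each summary dict must carry 'subject', 'condition', and the output
    columns; the result is indexed by (subject, condition) and validated
    to contain both conditions for every subject.
    """
    df = pd.DataFrame(summaries).set_index(["subject", "condition"])
    for subject in df.index.get_level_values("subject").unique():
        have = set(df.loc[subject].index)
        if have != {"baseline", "CTEPH"}:
            raise ValueError(
                f"subject {subject!r} has conditions {sorted(have)}; "
                "need paired baseline and CTEPH rows"
            )
    return df.sort_index()


def paired_tests(
    cohort: pd.DataFrame,
    directions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Run the paired one-sided test for every directed output column."""
    directions = DEFAULT_DIRECTIONS if directions is None else directions
    base = cohort.xs("baseline", level="condition")
    cteph = cohort.xs("CTEPH", level="condition")
    rows = []
    for col, direction in directions.items():
        if col not in cohort.columns:
            continue
        t, p = paired_one_sided_t(
            base[col].to_numpy(), cteph[col].to_numpy(), direction
        )
        rows.append(
            {
                "output": col,
                "direction": direction,
                "mean_baseline": float(base[col].mean()),
                "mean_cteph": float(cteph[col].mean()),
                "t": t,
                "p": round(p, 4),
                "significant": p < 0.05,
            }
        )
    return pd.DataFrame(rows).set_index("output")


def relative_change_correlations(
    cohort: pd.DataFrame,
    threshold: float = 0.80,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations of per-subject relative changes.

    For every output, Delta = (CTEPH - baseline)/baseline per subject;
    the correlation matrix is computed over subjects, and the highlight
    mask flags |r| > threshold. Outputs with (relative) variance of Delta
    below the floor — e.g. shear-direction metrics that are essentially
    zero in every subject — are dropped with a logged note.
    """
    base = cohort.xs("baseline", level="condition")
    cteph = cohort.xs("CTEPH", level="condition")
    if len(base) < 3:
        raise ValueError("need at least 3 paired subjects")
    cols = columns if columns is not None else list(cohort.columns)
    deltas = {}
    for col in cols:
        b = base[col].to_numpy(dtype=float)
        c = cteph[col].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(b != 0, (c - b) / b, np.nan)
        if np.any(~np.isfinite(delta)):
            log.info("dropping %r: undefined relative change", col)
            continue
        scale = max(float(np.mean(np.abs(delta))), 1.0)
        if float(np.var(delta)) < VARIANCE_FLOOR * scale**2:
            log.info("dropping %r: near-zero variance of changes", col)
            continue
        deltas[col] = delta
    dd = pd.DataFrame(deltas)
    corr = dd.corr(method="pearson")
    mask = corr.abs() > threshold
    np.fill_diagonal(mask.values, False)
    return corr, mask
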