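"""Heart-rate variability (rMSSD) change scores and behavioral synchrony.

rMSSD is computed on cleaned *beat-domain* IBIs — resampling to a uniform
grid would distort successive differences.  HRV change is block rMSSD minus
the same subject's resting-baseline rMSSD.

Behavioral synchrony per trial is the absolute difference between the two
subjects' grasp-contact times (task performance) and start-release times
(spontaneous synchrony); smaller is more synchronous.  Outliers are removed
with Tukey's 1.5 x IQR fence — pooled across the study's trials by default,
since single global retained ranges are reported for these measures — and
retained trials are averaged to one value per block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ecg import IbiSeries

__all__ = [
    "HrvChange",
    "rmssd",
    "hrv_change",
    "hrv_table",
    "trial_differences",
    "tukey_filter",
    "block_average",
    "behavioral_table",
]


@dataclass
class HrvChange:
    rmssd_block_ms: float
    rmssd_baseline_ms: float

    @property
    def change_ms(self) -> float:
        return self.rmssd_block_ms - self.rmssd_baseline_ms


def rmssd(ibi: IbiSeries | np.ndarray) -> float:
    """Root mean square of successive IBI differences, in ms."""
    x = ibi.ibi_ms if isinstance(ibi, IbiSeries) else np.asarray(ibi, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 intervals, got {len(x)}")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d**2)))


def hrv_change(block_ibi: IbiSeries, baseline_ibi: IbiSeries | None) -> HrvChange:
    """Baseline-corrected rMSSD for one subject-block."""
    if baseline_ibi is None:
        raise ValueError("baseline IBI series is required for HRV change")
    return HrvChange(rmssd_block_ms=rmssd(block_ibi),
                     rmssd_baseline_ms=rmssd(baseline_ibi))


def hrv_table(study) -> pd.DataFrame:
    """Per subject-block rMSSD and change from baseline for a whole study."""
    rows = []
    for dyad in study.dyads:
        baseline = dyad.blocks[0]
        base = {"s1": rmssd(baseline.ibi1), "s2": rmssd(baseline.ibi2)}
        for block in dyad.blocks[1:]:
            for subj, ibi in (("s1", block.ibi1), ("s2", block.ibi2)):
                r = rmssd(ibi)
                rows.append({"dyad": dyad.dyad_id, "subject": subj,
                             "block": block.block_id, "rmssd": r,
                             "rmssd_baseline": base[subj],
                             "change": r - base[subj]})
    return pd.DataFrame(rows)


def trial_differences(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial absolute between-subject differences of grasp and start times.

    Expects long format (dyad, block, trial, subject, start_time_ms,
    grasp_time_ms); trials without both subjects are skipped.
    """
    wide = trials.pivot_table(index=["dyad", "block", "trial"], columns="subject",
                              values=["start_time_ms", "grasp_time_ms"])
    complete = wide.dropna()
    n_skipped = len(wide) - len(complete)
    if n_skipped:
        import logging
        logging.getLogger(__name__).warning("skipped %d unpaired trials", n_skipped)
    out = pd.DataFrame({
        "grasp_diff_ms": (complete[("grasp_time_ms", "s1")]
                          - complete[("grasp_time_ms", "s2")]).abs(),
        "start_diff_ms": (complete[("start_time_ms", "s1")]
                          - complete[("start_time_ms", "s2")]).abs(),
    })
    return out.reset_index()


def tukey_filter(values) -> np.ndarray:
    """Drop values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (linear-interpolated
    quartiles).  Idempotent only in the usual practical sense of a single
    pass; re-application to an already-clean set changes nothing."""
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError(f"need at least 4 values, got {len(x)}")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return x[(x >= lo) & (x <= hi)]


def block_average(diffs: pd.DataFrame, column: str) -> pd.DataFrame:
    """Mean retained absolute difference per dyad-block, with trial counts."""
    grouped = diffs.groupby(["dyad", "block"])[column]
    out = grouped.agg(["mean", "count"]).reset_index()
    if (out["count"] == 0).any():
        raise ValueError("a block has no retained trials")
    return out.rename(columns={"mean": column, "count": f"{column}_n"})


def behavioral_table(trials: pd.DataFrame, pool: str = "study") -> pd.DataFrame:
    """Per-block behavioral synchrony summary.

    Computes per-trial absolute differences, removes outliers with the Tukey
    fence (pooled over the whole study by default, per block with
    ``pool="block"``), and averages retained trials to one value per
    dyad-block for each measure.
    """
    diffs = trial_differences(trials)
    out = None
    for col in ("grasp_diff_ms", "start_diff_ms"):
        if pool == "study":
            kept = tukey_filter(diffs[col].to_numpy())
            lo, hi = kept.min(), kept.max()
            mask = (diffs[col] >= lo) & (diffs[col] <= hi)
            retained = diffs[mask]
        elif pool == "block":
            parts = []
            for _, grp in diffs.groupby(["dyad", "block"]):
                kept = tukey_filter(grp[col].to_numpy())
                parts.append(grp[grp[col].isin(kept)])
            retained = pd.concat(parts)
        else:
            raise ValueError(f"unknown pooling {pool!r}")
        summary = block_average(retained, col)
        out = summary if out is None else out.merge(summary, on=["dyad", "block"])
    return out
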