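"""On-disk study layout: plain CSV signal tables plus a YAML manifest.

Layout written by :func:`write_study` and read back by :func:`read_study`::

    study_dir/
      manifest.yaml          # dyads, blocks, conditions, file paths
      subjects.csv           # dyad, subject, social_anxiety, perspective_taking
      trials.csv             # dyad, block, trial, subject, start/grasp times
      ibi/<dyad>_<block>_<subject>.csv   # beat_time_s, ibi_ms, replaced
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ecg import EcgRecording, IbiSeries

__all__ = [
    "write_ibi_csv",
    "read_ibi_csv",
    "read_signal_csv",
    "write_study",
    "read_study_manifest",
    "qc_row",
]


def write_ibi_csv(ibi: IbiSeries, path) -> None:
    pd.DataFrame({"beat_time_s": ibi.beat_times_s, "ibi_ms": ibi.ibi_ms,
                  "replaced": ibi.replaced_mask.astype(int)}).to_csv(path, index=False)


def read_ibi_csv(path, subject: str = "", block: str = "") -> IbiSeries:
    df = pd.read_csv(path)
    return IbiSeries(beat_times_s=df["beat_time_s"].to_numpy(),
                     ibi_ms=df["ibi_ms"].to_numpy(),
                     replaced_mask=df.get("replaced", pd.Series(np.zeros(len(df)))).to_numpy().astype(bool),
                     subject=subject, block=block)


def read_signal_csv(path, fs: float | None = None, subject: str = "",
                    block: str = "") -> EcgRecording:
    """Read a (time_s, voltage) table; fs is inferred from the time column
    unless given."""
    df = pd.read_csv(path)
    if fs is None:
        dt = np.diff(df["time_s"].to_numpy())
        fs = 1.0 / float(np.median(dt))
    return EcgRecording(fs=fs, samples=df["voltage"].to_numpy(),
                        subject=subject, block=block)


def fit_report_row(fit, dyad: str = "", block: str = "", subject: str = "") -> dict:
    """One row of the per-block ARIMA fit report CSV."""
    s = fit.spec
    return {"dyad": dyad, "block": block, "subject": subject,
            "p": s.p, "d": s.d, "q": s.q, "P": s.P, "D": s.D, "Q": s.Q,
            "m": s.m, "lambda": s.lam,
            "aicc": fit.ic.get("aicc"), "aic": fit.ic.get("aic"),
            "bic": fit.ic.get("bic"), "ljung_box_p": fit.ljung_box_p,
            "converged": fit.converged}


def qc_row(ibi: IbiSeries) -> dict:
    """Per-block quality-control summary for the cleaning report."""
    return {"subject": ibi.subject, "block": ibi.block, "n_beats": len(ibi),
            "replaced_fraction": ibi.replaced_fraction,
            "duration_s": float(ibi.beat_times_s[-1] - ibi.beat_times_s[0])
            if len(ibi) else 0.0}


def write_study(study, out_dir) -> Path:
    """Write a synthetic study in the on-disk layout the pipeline reads."""
    out = Path(out_dir)
    (out / "ibi").mkdir(parents=True, exist_ok=True)
    study.subjects_table().to_csv(out / "subjects.csv", index=False)
    study.trials_table().to_csv(out / "trials.csv", index=False)
    manifest = {"dyads": []}
    for dyad in study.dyads:
        rec = {"dyad": dyad.dyad_id, "blocks": []}
        for block in dyad.blocks:
            paths = {}
            for subj, ibi in (("s1", block.ibi1), ("s2", block.ibi2)):
                rel = f"ibi/{dyad.dyad_id}_{block.block_id}_{subj}.csv"
                write_ibi_csv(ibi, out / rel)
                paths[subj] = rel
            rec["blocks"].append({
                "block": block.block_id, "order": block.order,
                "block_type": block.block_type, "movement": block.movement,
                "leader": block.leader, "novelty": block.novelty,
                "session": block.session, "files": paths,
            })
        manifest["dyads"].append(rec)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out


def read_study_manifest(study_dir) -> dict:
    with open(Path(study_dir) / "manifest.yaml") as fh:
        return yaml.safe_load(fh)
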