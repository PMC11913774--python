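"""Pseudo-dyad surrogate null distribution via participant shuffling.

Synchrony measured in real dyads could simply reflect two people doing the
same task at the same point of the session.  The null controls for this by
pairing subject 1 of one dyad with subject 2 of a *different* dyad within
the same condition cell (block type, movement pattern, leader role, and
ordinal position of the block within its condition).  The identical
prewhitening -> CCF -> average -> Fisher-Z path is run on every surrogate
pair; per-subject ARIMA fits are computed once and reused across pairings.

The exhaustive pairing count obeys N_p = (N_b^2 - N_b)/2 * N_c, where N_b is
the number of blocks per condition cell across dyads and N_c the number of
cells; with 40 dyads and 17 cells this gives the study-scale 13,260 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synchrony import (SynchronyConfig, average_ccf, cross_correlation,
                        fisher_z)
from .ecg import resample_ibi
from .prewhiten import prewhiten_series

__all__ = [
    "PseudoPairing",
    "PseudoDyadSet",
    "WelchResult",
    "pseudo_pair_count",
    "enumerate_pseudo_pairs",
    "residual_cache",
    "real_synchrony_table",
    "pseudo_synchrony_distribution",
    "welch_test",
    "compare_real_pseudo",
]


@dataclass(frozen=True)
class PseudoPairing:
    """One surrogate pair: subject 1 of ``dyad_a`` with subject 2 of ``dyad_b``."""

    dyad_a: str
    block_a: str
    dyad_b: str
    block_b: str
    condition: tuple


@dataclass
class PseudoDyadSet:
    """Enumeration of surrogate pairings, optionally with synchrony values."""

    pairings: list
    n_b: int
    n_c: int
    exhaustive: bool
    synchrony: pd.DataFrame | None = field(default=None)

    @property
    def n_pairs(self) -> int:
        return len(self.pairings)


def pseudo_pair_count(n_b: int, n_c: int) -> int:
    """Closed-form exhaustive pairing count: (N_b^2 - N_b)/2 * N_c."""
    return (n_b * n_b - n_b) // 2 * n_c


def enumerate_pseudo_pairs(study, exhaustive: bool = True,
                           subsample: int | None = None,
                           seed: int | None = None,
                           include_baseline: bool = True) -> PseudoDyadSet:
    """Enumerate cross-dyad subject-1 x subject-2 pairings within condition.

    Two blocks match when their (block type, movement, leader, session
    ordinal) keys are identical; members of the same real dyad are never
    paired.  With ``subsample`` set, a seeded sample without replacement is
    drawn from the exhaustive enumeration.
    """
    cells: dict[tuple, list] = {}
    for dyad, block in study.iter_blocks():
        if block.is_baseline and not include_baseline:
            continue
        cells.setdefault(block.condition, []).append((dyad.dyad_id, block.block_id))
    if not cells:
        raise ValueError("study has no blocks to pair")
    sizes = {len(v) for v in cells.values()}
    if min(sizes) < 2:
        raise ValueError("every condition cell needs at least 2 dyads")

    pairings = []
    for cond in sorted(cells):
        members = sorted(cells[cond])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                da, ba = members[i]
                db, bb = members[j]
                if da == db:
                    continue
                pairings.append(PseudoPairing(da, ba, db, bb, cond))

    n_b = max(sizes)
    n_c = len(cells)
    if subsample is not None and subsample < len(pairings):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairings), size=subsample, replace=False)
        pairings = [pairings[k] for k in sorted(idx)]
        return PseudoDyadSet(pairings, n_b, n_c, exhaustive=False)
    return PseudoDyadSet(pairings, n_b, n_c, exhaustive=exhaustive)


def residual_cache(study, cfg: SynchronyConfig | None = None) -> dict:
    """Prewhiten every subject-block once; keyed (dyad, subject, block)."""
    cfg = cfg or SynchronyConfig()
    cache = {}
    for dyad, block in study.iter_blocks():
        for subj, ibi in (("s1", block.ibi1), ("s2", block.ibi2)):
            u = resample_ibi(ibi, rate_hz=cfg.rate_hz)
            fit = prewhiten_series(u, method=cfg.prewhiten_method,
                                   **cfg.prewhiten_kwargs)
            cache[(dyad.dyad_id, subj, block.block_id)] = fit
    return cache


def real_synchrony_table(study, cfg: SynchronyConfig | None = None,
                         cache: dict | None = None) -> pd.DataFrame:
    """Per-block synchrony of the real dyads (one row per dyad-block)."""
    cfg = cfg or SynchronyConfig()
    if cache is None:
        cache = residual_cache(study, cfg)
    rows = []
    for dyad, block in study.iter_blocks():
        f1 = cache[(dyad.dyad_id, "s1", block.block_id)]
        f2 = cache[(dyad.dyad_id, "s2", block.block_id)]
        ccf = cross_correlation(f1.residuals, f2.residuals, max_lag=cfg.max_lag)
        avg = average_ccf(ccf)
        z = fisher_z(avg)
        groups = ccf.lag_group_means
        rows.append({"dyad": dyad.dyad_id, "block": block.block_id,
                     "block_type": block.block_type, "movement": block.movement,
                     "leader": block.leader, "novelty": block.novelty,
                     "session": block.session, "is_baseline": block.is_baseline,
                     "average_ccf": avg, "fisher_z": z, "scaled": 100.0 * z,
                     "lag_group_negative": groups["negative"],
                     "lag_group_zero": groups["zero"],
                     "lag_group_positive": groups["positive"],
                     "converged1": f1.converged, "converged2": f2.converged})
    return pd.DataFrame(rows)


def pseudo_synchrony_distribution(study, pairs: PseudoDyadSet,
                                  cfg: SynchronyConfig | None = None,
                                  cache: dict | None = None) -> PseudoDyadSet:
    """Run the synchrony path on every surrogate pairing.

    Returns the same :class:`PseudoDyadSet` with its ``synchrony`` table
    filled (one row per pairing, unscaled Fisher-Z plus the x100 reporting
    scale).
    """
    cfg = cfg or SynchronyConfig()
    if cache is None:
        cache = residual_cache(study, cfg)
    rows = []
    for k, pr in enumerate(pairs.pairings):
        key_a = (pr.dyad_a, "s1", pr.block_a)
        key_b = (pr.dyad_b, "s2", pr.block_b)
        if key_a not in cache or key_b not in cache:
            raise KeyError(f"missing residuals for pairing {pr}")
        ccf = cross_correlation(cache[key_a].residuals, cache[key_b].residuals,
                                max_lag=cfg.max_lag)
        avg = average_ccf(ccf)
        z = fisher_z(avg)
        rows.append({"pair_id": k, "dyad_a": pr.dyad_a, "dyad_b": pr.dyad_b,
                     "block_a": pr.block_a, "block_b": pr.block_b,
                     "is_baseline": pr.condition[0] == "baseline",
                     "average_ccf": avg, "fisher_z": z, "scaled": 100.0 * z})
    pairs.synchrony = pd.DataFrame(rows)
    return pairs


@dataclass
class WelchResult:
    """Welch's unequal-variance t-test with Satterthwaite degrees of freedom."""

    t: float
    df: float
    p: float
    ci95: tuple[float, float]
    mean_a: float
    mean_b: float


def welch_test(a, b) -> WelchResult:
    """Two-sided Welch t-test of mean(a) - mean(b) with a 95% CI.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b); df by the
    Welch-Satterthwaite approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0, (0.0, 0.0),
                           float(a.mean()), float(b.mean()))
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both groups")
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    diff = a.mean() - b.mean()
    half = tcrit * np.sqrt(se2)
    return WelchResult(float(t), float(df), float(p),
                       (float(diff - half), float(diff + half)),
                       float(a.mean()), float(b.mean()))


def compare_real_pseudo(real: pd.DataFrame, pseudo: pd.DataFrame,
                        value: str = "fisher_z") -> dict:
    """REAL vs PSEUDO Welch comparisons, separately for task and baseline.

    Also returns the within-real task-vs-baseline comparison.  Tests run on
    unscaled Fisher-Z values by default; means are reported on both scales.
    """
    out = {}
    r_task = real.loc[~real["is_baseline"], value].to_numpy()
    r_base = real.loc[real["is_baseline"], value].to_numpy()
    p_task = pseudo.loc[~pseudo["is_baseline"], value].to_numpy()
    p_base = pseudo.loc[pseudo["is_baseline"], value].to_numpy()
    out["task_real_vs_pseudo"] = welch_test(r_task, p_task)
    if len(r_base) >= 2 and len(p_base) >= 2:
        out["baseline_real_vs_pseudo"] = welch_test(r_base, p_base)
    if len(r_base) >= 2:
        out["real_task_vs_baseline"] = welch_test(r_task, r_base)
    return out
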