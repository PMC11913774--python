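"""Synthetic dyadic study generator with known ground truth.

Every downstream stage (peak detection, prewhitening, cross-correlation,
surrogates, dyad-level models) is testable without external recordings by
generating data whose coupling structure is known exactly.

The cardiac model: each subject's inter-beat-interval fluctuation is the sum
of an AR(1) process (beat-to-beat autocorrelation), a linear trend (slow
drift over the block), a sinusoidal quasi-periodic component (respiratory
sinus arrhythmia stand-in), and a *shared* low-pass-filtered Gaussian driver
weighted by ``coupling_gain`` — the ground-truth synchrony knob.  The driver
entering subject 2 can be delayed by an integer number of samples to emulate
lagged leading/following.  Series are produced directly on the 4 Hz analysis
grid by default (fast; exercises prewhitening and CCF), with a beat-domain
mode feeding the full ECG path.

A full study mirrors the reference design: one non-interactive baseline
block plus 16 task blocks (4 conditions x 4 blocks, order counterbalanced
across dyads, 20 trials per block), per-trial behavioral times with
dyad-level coupling, and per-subject questionnaire scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .ecg import EcgRecording, IbiSeries

__all__ = [
    "CouplingConfig",
    "EcgNoiseConfig",
    "StudyConfig",
    "Block",
    "Dyad",
    "SyntheticStudy",
    "generate_dyad_ibi",
    "generate_ecg_from_rpeaks",
    "generate_simulation_study",
    "generate_study",
]

IBI_FLOOR_MS, IBI_CEIL_MS = 300.0, 2000.0


@dataclass
class CouplingConfig:
    """Ground-truth parameters of one dyad-block's coupled IBI pair.

    ``coupling_gain`` is the weight of the shared driver in units of each
    subject's own fluctuation SD (0 = fully independent subjects).
    """

    baseline_ibi_ms: tuple[float, float] = (850.0, 850.0)
    ibi_sd_ms: float = 40.0
    ar_coefficient: float = 0.85
    trend_slope_ms_per_min: float = 6.0
    seasonal_period_s: float = 4.0
    seasonal_amplitude_ms: float = 15.0
    coupling_gain: float = 0.0
    coupling_lag_samples: int = 0
    driver_bandwidth_hz: float = 0.1
    block_duration_s: float = 300.0
    rate_hz: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for v in self.baseline_ibi_ms:
            if not (300.0 <= v <= 2000.0):
                raise ValueError(f"baseline IBI {v} ms outside [300, 2000]")
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("|ar_coefficient| must be < 1")
        if self.coupling_gain < 0:
            raise ValueError("coupling_gain must be >= 0")
        for name in ("ibi_sd_ms", "seasonal_period_s", "block_duration_s",
                     "driver_bandwidth_hz", "rate_hz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not np.isfinite(self.trend_slope_ms_per_min):
            raise ValueError("trend_slope_ms_per_min must be finite")


def _ar1(rng: np.random.Generator, n: int, phi: float, marginal_sd: float) -> np.ndarray:
    e = rng.normal(0.0, marginal_sd * np.sqrt(1 - phi**2), n)
    e[0] = rng.normal(0.0, marginal_sd)  # draw x0 from the stationary marginal
    return signal.lfilter([1.0], [1.0, -phi], e)


def _lowpass_driver(rng: np.random.Generator, n: int, bandwidth_hz: float,
                    rate_hz: float) -> np.ndarray:
    """Unit-SD shared driver: white Gaussian noise low-passed at bandwidth_hz."""
    pad = max(n // 4, 64)
    w = rng.normal(0.0, 1.0, n + 2 * pad)
    sos = signal.butter(2, bandwidth_hz / (rate_hz / 2.0), btype="lowpass", output="sos")
    d = signal.sosfiltfilt(sos, w)[pad:pad + n]
    sd = d.std()
    return d / sd if sd > 0 else d


def generate_dyad_ibi(config: CouplingConfig) -> tuple[IbiSeries, IbiSeries, dict]:
    """Generate one coupled IBI pair on the uniform analysis grid.

    Each subject's series is baseline + AR(1) + trend + seasonal sinusoid +
    gain x shared driver (subject 2's copy delayed by
    ``coupling_lag_samples``).  Deterministic under a fixed seed.

    Returns the two :class:`~cardiosync.ecg.IbiSeries` (beat times on the
    uniform grid) and a ground-truth dict (driver, per-subject components,
    gain, lag).
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.block_duration_s * config.rate_hz))
    t = np.arange(n) / config.rate_hz
    lag = int(config.coupling_lag_samples)
    driver_full = _lowpass_driver(rng, n + abs(lag), config.driver_bandwidth_hz,
                                  config.rate_hz)
    if lag >= 0:
        d1 = driver_full[lag:lag + n]      # s2 sees the driver `lag` samples later
        d2 = driver_full[:n]
    else:
        d1 = driver_full[:n]
        d2 = driver_full[-lag:-lag + n]

    series = []
    for subj, drv in ((0, d1), (1, d2)):
        phase = rng.uniform(0, 2 * np.pi)
        fluct = (
            _ar1(rng, n, config.ar_coefficient, config.ibi_sd_ms)
            + config.trend_slope_ms_per_min * t / 60.0
            + config.seasonal_amplitude_ms * np.sin(2 * np.pi * t / config.seasonal_period_s + phase)
            + config.coupling_gain * config.ibi_sd_ms * drv
        )
        x = np.clip(config.baseline_ibi_ms[subj] + fluct, IBI_FLOOR_MS, IBI_CEIL_MS)
        series.append(IbiSeries(beat_times_s=t, ibi_ms=x, subject=f"s{subj + 1}"))
    truth = {"driver_s1": d1, "driver_s2": d2, "gain": config.coupling_gain,
             "lag_samples": lag, "times_s": t}
    return series[0], series[1], truth


@dataclass
class EcgNoiseConfig:
    """Amplitudes of the nuisance components added to a synthetic ECG trace."""

    qrs_amplitude: float = 1.0
    wander_amplitude: float = 0.1
    noise_amplitude: float = 0.03
    seed: int = 0


def _qrs_template(fs: float, amplitude: float) -> np.ndarray:
    # stylized QRS: sharp R wave (Gaussian, sigma 12 ms) flanked by small
    # negative Q and S dips; enough morphology for threshold peak detection
    tt = np.arange(-0.06, 0.06 + 1.0 / fs, 1.0 / fs)
    r = np.exp(-0.5 * (tt / 0.012) ** 2)
    q = -0.15 * np.exp(-0.5 * ((tt + 0.030) / 0.008) ** 2)
    s = -0.20 * np.exp(-0.5 * ((tt - 0.030) / 0.008) ** 2)
    return amplitude * (r + q + s)


def generate_ecg_from_rpeaks(r_times: np.ndarray, fs: float,
                             noise_cfg: EcgNoiseConfig | None = None,
                             ) -> tuple[EcgRecording, np.ndarray]:
    """Synthesize an ECG voltage trace with QRS-like complexes at ``r_times``.

    Adds baseline wander below 0.6 Hz and broadband noise above 20 Hz at the
    configured amplitudes, so the band-pass + detection chain is exercised on
    both nuisance types.  Returns the trace and the true R sample indices.
    """
    noise_cfg = noise_cfg or EcgNoiseConfig()
    r_times = np.asarray(r_times, dtype=float)
    if np.any(np.diff(r_times) <= 0):
        raise ValueError("r_times must be strictly increasing")
    if np.any(np.diff(r_times) < 0.25):
        raise ValueError("r_times closer than 250 ms are not physiological")
    if fs < 128:
        raise ValueError(f"fs must be >= 128 Hz, got {fs}")
    rng = np.random.default_rng(noise_cfg.seed)
    n = int(round((r_times[-1] + 0.5) * fs))
    x = np.zeros(n)
    tmpl = _qrs_template(fs, noise_cfg.qrs_amplitude)
    half = len(tmpl) // 2
    true_idx = np.round(r_times * fs).astype(int)
    for idx in true_idx:
        lo, hi = idx - half, idx - half + len(tmpl)
        s0, s1 = max(lo, 0), min(hi, n)
        x[s0:s1] += tmpl[s0 - lo:s1 - lo]
    t = np.arange(n) / fs
    if noise_cfg.wander_amplitude > 0:
        for f_hz in (0.12, 0.27, 0.45):
            x += (noise_cfg.wander_amplitude / 2.0) * np.sin(
                2 * np.pi * f_hz * t + rng.uniform(0, 2 * np.pi))
    if noise_cfg.noise_amplitude > 0:
        w = rng.normal(0.0, 1.0, n)
        sos = signal.butter(2, 20.0 / (fs / 2.0), btype="highpass", output="sos")
        hf = signal.sosfiltfilt(sos, w)
        x += noise_cfg.noise_amplitude * hf / hf.std()
    return EcgRecording(fs=fs, samples=x), true_idx


# ---------------------------------------------------------------------------
# full-study generation


@dataclass
class StudyConfig:
    """Design and ground-truth parameters of a synthetic study.

    Defaults mirror the reference design: 1 baseline (~4 min) + 16 task
    blocks (~5 min, 4 conditions x 4 blocks, 20 trials each) per dyad;
    social anxiety and perspective-taking scores drawn from truncated
    normals matching the reported questionnaire distributions (means 38.2
    and 27.8, SDs 20.7 and 3.8).

    ``task_gain`` is the shared-driver gain in all task blocks;
    ``novelty_gain_boost`` is added in novelty ("new") blocks and
    ``anxiety_gain_slope`` scales gain by the dyad's standardized social
    anxiety sum — both default to 0 (no planted effect).  Baseline blocks
    always have zero coupling.
    """

    n_dyads: int = 8
    blocks_per_condition: int = 4
    n_trials_per_block: int = 20
    block_duration_s: float = 300.0
    baseline_duration_s: float = 240.0
    task_gain: float = 0.0
    novelty_gain_boost: float = 0.0
    anxiety_gain_slope: float = 0.0
    coupling_lag_samples: int = 0
    social_anxiety_mean: float = 38.2
    social_anxiety_sd: float = 20.7
    perspective_taking_mean: float = 27.8
    perspective_taking_sd: float = 3.8
    grasp_subject_sd_ms: float = 100.0
    start_subject_sd_ms: float = 146.0
    dyad_skill_sd: float = 0.3
    seed: int = 0
    signal_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_dyads < 2:
            raise ValueError("need at least 2 dyads")
        if self.blocks_per_condition != 4:
            raise ValueError("the design has 4 blocks per condition")


@dataclass
class Block:
    """One dyad-block with its two IBI series and condition labels."""

    dyad_id: str
    block_id: str
    order: int                      # 0 = baseline, 1..16 task order
    block_type: str                 # "baseline" | "free" | "leader_follower"
    movement: str                   # "none" | "same" | "opposite"
    leader: str                     # "none" | "s1" | "s2"
    novelty: str                    # "none" | "new" | "old"
    session: int                    # ordinal within its condition (1..4)
    ibi1: IbiSeries
    ibi2: IbiSeries
    gain: float

    @property
    def is_baseline(self) -> bool:
        return self.block_type == "baseline"

    @property
    def condition(self) -> tuple:
        """Matching key for surrogate pairing: type, movement, leader, session."""
        return (self.block_type, self.movement, self.leader, self.session)


@dataclass
class Dyad:
    dyad_id: str
    blocks: list
    social_anxiety: dict            # subject -> score
    perspective_taking: dict
    trials: pd.DataFrame


@dataclass
class SyntheticStudy:
    config: StudyConfig
    dyads: list
    ground_truth: dict

    def iter_blocks(self, task_only: bool = False):
        for dyad in self.dyads:
            for block in dyad.blocks:
                if task_only and block.is_baseline:
                    continue
                yield dyad, block

    def trials_table(self) -> pd.DataFrame:
        return pd.concat([d.trials for d in self.dyads], ignore_index=True)

    def subjects_table(self) -> pd.DataFrame:
        rows = []
        for d in self.dyads:
            for subj in ("s1", "s2"):
                rows.append({"dyad": d.dyad_id, "subject": subj,
                             "social_anxiety": d.social_anxiety[subj],
                             "perspective_taking": d.perspective_taking[subj]})
        return pd.DataFrame(rows)

    def blocks_table(self) -> pd.DataFrame:
        rows = []
        for dyad, block in self.iter_blocks():
            rows.append({"dyad": dyad.dyad_id, "block": block.block_id,
                         "order": block.order, "block_type": block.block_type,
                         "movement": block.movement, "leader": block.leader,
                         "novelty": block.novelty, "session": block.session,
                         "gain": block.gain})
        return pd.DataFrame(rows)


def generate_simulation_study(n_dyads: int = 8, n_blocks: int = 4,
                              block_duration_s: float = 60.0,
                              gain: float = 0.0, lag_samples: int = 0,
                              include_baseline: bool = False,
                              seed: int = 0, **signal_kwargs) -> SyntheticStudy:
    """Reduced single-condition study for simulation experiments.

    Generates ``n_dyads`` dyads with ``n_blocks`` task blocks each (all
    free/same; the block ordinal serves as the condition cell for surrogate
    pairing) and optionally a zero-coupling baseline.  Used by calibration
    and power studies where the full 17-block design would only add cost.
    """
    if n_dyads < 2:
        raise ValueError("need at least 2 dyads")
    rng = np.random.default_rng(seed)
    dyads = []
    for i in range(n_dyads):
        dyad_id = f"d{i + 1:02d}"
        blocks = []
        if include_baseline:
            cfg = CouplingConfig(coupling_gain=0.0, block_duration_s=block_duration_s,
                                 seed=int(rng.integers(2**31)), **signal_kwargs)
            b1, b2, _ = generate_dyad_ibi(cfg)
            blocks.append(Block(dyad_id, "b00", 0, "baseline", "none", "none",
                                "none", 1, b1, b2, 0.0))
        for k in range(1, n_blocks + 1):
            cfg = CouplingConfig(coupling_gain=gain, block_duration_s=block_duration_s,
                                 coupling_lag_samples=lag_samples,
                                 seed=int(rng.integers(2**31)), **signal_kwargs)
            s1, s2, _ = generate_dyad_ibi(cfg)
            blocks.append(Block(dyad_id, f"b{k:02d}", k, "free", "same", "none",
                                "new" if k == 1 else "old", k, s1, s2, gain))
        dyads.append(Dyad(dyad_id=dyad_id, blocks=blocks,
                          social_anxiety={"s1": 0.0, "s2": 0.0},
                          perspective_taking={"s1": 0.0, "s2": 0.0},
                          trials=pd.DataFrame()))
    study_cfg = StudyConfig(n_dyads=n_dyads, block_duration_s=block_duration_s,
                            task_gain=gain, seed=seed)
    return SyntheticStudy(config=study_cfg, dyads=dyads,
                          ground_truth={"task_gain": gain})


#: the four task-condition runs (block_type, movement pattern, leader)
_CONDITION_RUNS = (
    ("free", ("same", "same", "same", "same"), "none"),
    ("free", ("opposite", "opposite", "opposite", "opposite"), "none"),
    ("leader_follower", ("same", "same", "opposite", "opposite"), "s1"),
    ("leader_follower", ("same", "same", "opposite", "opposite"), "s2"),
)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_study(cfg: StudyConfig) -> SyntheticStudy:
    """Generate a complete synthetic study.

    Condition-run order is counterbalanced by rotating the four runs across
    dyads.  Novelty follows the block-transition rule: a task block is "new"
    when its (block type, movement, leader) combination differs from the
    immediately preceding task block's, "old" otherwise.  Behavioral grasp
    and start times share a per-dyad skill factor, which induces a positive
    across-dyad correlation between the two asynchrony measures.
    """
    rng = np.random.default_rng(cfg.seed)
    dyads = []
    truth_rows = []
    sa_all = _truncnorm(rng, cfg.social_anxiety_mean, cfg.social_anxiety_sd,
                        0.0, 144.0, (cfg.n_dyads, 2))
    pt_all = _truncnorm(rng, cfg.perspective_taking_mean, cfg.perspective_taking_sd,
                        7.0, 35.0, (cfg.n_dyads, 2))
    sa_sum = sa_all.sum(axis=1)
    sa_sum_z = (sa_sum - sa_sum.mean()) / (sa_sum.std() or 1.0)

    for i in range(cfg.n_dyads):
        dyad_id = f"d{i + 1:02d}"
        run_order = [_CONDITION_RUNS[(i + k) % 4] for k in range(4)]
        blocks = []
        base_cfg = CouplingConfig(
            coupling_gain=0.0,
            block_duration_s=cfg.baseline_duration_s,
            coupling_lag_samples=0,
            seed=int(rng.integers(2**31)),
            **cfg.signal_kwargs,
        )
        b1, b2, _ = generate_dyad_ibi(base_cfg)
        blocks.append(Block(dyad_id, "b00", 0, "baseline", "none", "none",
                            "none", 1, b1, b2, 0.0))
        order = 0
        prev_combo = None
        session_counter: dict[tuple, int] = {}
        for block_type, movements, leader in run_order:
            for movement in movements:
                order += 1
                combo = (block_type, movement, leader)
                novelty = "new" if combo != prev_combo else "old"
                prev_combo = combo
                # ordinal within the full condition combination, so cells are
                # identical across dyads whatever the counterbalanced order
                session_counter[combo] = session_counter.get(combo, 0) + 1
                gain = cfg.task_gain
                if novelty == "new":
                    gain += cfg.novelty_gain_boost
                gain += cfg.anxiety_gain_slope * sa_sum_z[i]
                gain = max(gain, 0.0)
                blk_cfg = CouplingConfig(
                    coupling_gain=gain,
                    block_duration_s=cfg.block_duration_s,
                    coupling_lag_samples=cfg.coupling_lag_samples,
                    seed=int(rng.integers(2**31)),
                    **cfg.signal_kwargs,
                )
                s1, s2, _ = generate_dyad_ibi(blk_cfg)
                blocks.append(Block(dyad_id, f"b{order:02d}", order, block_type,
                                    movement, leader, novelty,
                                    session_counter[combo], s1, s2, gain))
                truth_rows.append({"dyad": dyad_id, "block": f"b{order:02d}",
                                   "gain": gain, "novelty": novelty})

        skill = np.exp(rng.normal(0.0, cfg.dyad_skill_sd))  # shared sloppiness
        trial_rows = []
        for block in blocks[1:]:
            for trial in range(1, cfg.n_trials_per_block + 1):
                start_shared = rng.normal(420.0, 60.0)
                move_shared = rng.normal(820.0, 80.0)
                for subj in ("s1", "s2"):
                    start = max(start_shared + rng.normal(0.0, cfg.start_subject_sd_ms * skill), 50.0)
                    grasp = start + max(move_shared + rng.normal(0.0, cfg.grasp_subject_sd_ms * skill), 100.0)
                    trial_rows.append({"dyad": dyad_id, "block": block.block_id,
                                       "trial": trial, "subject": subj,
                                       "start_time_ms": start,
                                       "grasp_time_ms": grasp})
        dyads.append(Dyad(
            dyad_id=dyad_id, blocks=blocks,
            social_anxiety={"s1": float(sa_all[i, 0]), "s2": float(sa_all[i, 1])},
            perspective_taking={"s1": float(pt_all[i, 0]), "s2": float(pt_all[i, 1])},
            trials=pd.DataFrame(trial_rows),
        ))

    n_task = 4 * cfg.blocks_per_condition
    for d in dyads:
        assert len(d.blocks) == n_task + 1
    truth = {"block_gains": pd.DataFrame(truth_rows),
             "task_gain": cfg.task_gain,
             "novelty_gain_boost": cfg.novelty_gain_boost,
             "anxiety_gain_slope": cfg.anxiety_gain_slope}
    return SyntheticStudy(config=cfg, dyads=dyads, ground_truth=truth)
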