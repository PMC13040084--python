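"""Seeded synthetic-data generators with attached ground truth.

Every input the analysis pipeline consumes can be generated here: sparse
GCaMP6f-like somatic fluorescence traces (and small movie stacks painted
from them), orientation-tuned responses driven by a grating schedule,
trial-organized 1/f source signals with planted γ bursts, cohort tables
(life events → mental-health scores) with exclusion flags, subject-level
predictor tables for the Bayesian regressions, and the 2×2 emotional
Flanker trial schedule.  All generators are deterministic given their seed.

Group defaults encode the direction of the empirical group differences:
nonresilient somata fire more often and with larger transients than
resilient ones, resilient neurons are more sharply orientation-tuned, and
resilient subjects show a lower γ-burst rate (hence longer inter-event
intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging import FluorescenceTrace


class InvalidConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


class LayoutError(ValueError):
    """Raised when an ROI layout does not fit the requested frame."""


#: per-group generator defaults: (event_rate /min, amplitude_mean ΔF/F,
#: von-Mises κ, burst rate /s).  Directions follow the observed group
#: effects; magnitudes are free, documented choices.
GROUP_DEFAULTS: dict[str, tuple[float, float, float, float]] = {
    "resilient": (1.0, 0.8, 2.0, 0.6),
    "nonresilient": (2.0, 1.0, 1.0, 1.0),
    "nonstressed": (1.2, 0.9, 1.0, 0.8),
}

GROUPS = tuple(GROUP_DEFAULTS)


@dataclass
class SimConfig:
    """Configuration for all generators.

    Imaging parameters default to the recording geometry of the mouse arm
    (30.8 Hz frames); signal parameters to the standard EEG-like setting
    (1 kHz).  ``event_rate`` is in transients per minute, ``burst_rate`` in
    bursts per second.  ``burst_snr`` is the planted burst's peak amplitude
    expressed in SDs of the unit-variance 1/f background.
    """

    seed: int = 0
    fs: float = 30.8
    duration: float = 600.0
    n_neurons: int = 66
    group: str = "nonstressed"
    event_rate: float = 1.2
    amplitude_mean: float = 0.9
    amplitude_sd: float = 0.2
    decay_tau: float = 0.5
    noise_sd: float = 0.1
    baseline_f0: float = 100.0
    drift_amplitude: float = 0.0
    tuning_kappa: float = 1.0
    preferred_direction: float | None = None
    burst_rate: float = 0.8
    burst_freq: float = 60.0
    burst_cycles: int = 6
    burst_snr: float = 3.0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise InvalidConfigError("fs and duration must be positive")
        if min(self.event_rate, self.burst_rate) < 0:
            raise InvalidConfigError("rates must be nonnegative")
        if self.noise_sd < 0 or self.amplitude_sd < 0:
            raise InvalidConfigError("noise/amplitude SDs must be nonnegative")
        if self.n_neurons < 0:
            raise InvalidConfigError("n_neurons must be nonnegative")
        if self.group not in GROUP_DEFAULTS:
            raise InvalidConfigError(f"unknown group {self.group!r}")
        if not 0 < self.burst_freq < self.fs / 2 and self.fs > 120:
            raise InvalidConfigError("burst_freq must lie below Nyquist")

    @classmethod
    def for_group(cls, group: str, **overrides) -> "SimConfig":
        """Config preset with the documented per-group effect directions."""
        if group not in GROUP_DEFAULTS:
            raise InvalidConfigError(f"unknown group {group!r}")
        rate, amp, kappa, brate = GROUP_DEFAULTS[group]
        base = dict(
            group=group,
            event_rate=rate,
            amplitude_mean=amp,
            tuning_kappa=kappa,
            burst_rate=brate,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """Planted truth attached to each generated dataset."""

    event_times: list[np.ndarray] = field(default_factory=list)
    amplitudes: list[np.ndarray] = field(default_factory=list)
    burst_times: list[np.ndarray] = field(default_factory=list)
    preferred_directions: np.ndarray | None = None
    coefficients: np.ndarray | None = None

    def __post_init__(self) -> None:
        for times in list(self.event_times) + list(self.burst_times):
            if np.any(np.diff(times) < 0):
                raise ValueError("ground-truth times must be sorted")


# ---------------------------------------------------------------------------
# calcium traces and movies


def gen_event_times(
    cfg: SimConfig, n_neurons: int | None = None, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Poisson event times (s) per neuron at ``cfg.event_rate`` per minute."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_neurons if n_neurons is None else n_neurons
    lam = cfg.event_rate / 60.0 * cfg.duration
    return [np.sort(rng.uniform(0.0, cfg.duration, rng.poisson(lam))) for _ in range(n)]


def gen_calcium_traces(
    cfg: SimConfig,
) -> tuple[list[FluorescenceTrace], GroundTruth]:
    """Sparse spontaneous calcium transients on a noisy baseline.

    Each neuron's fluorescence is ``baseline_f0 · (1 + s(t))`` with signal
    ``s(t) = Σ A·exp(−(t−t0)/τ)`` over Poisson-timed events (instantaneous
    rise), Gaussian noise of SD ``noise_sd`` (ΔF/F units) and an optional
    slow sinusoidal drift.  Ground truth records event times and planted
    ΔF/F amplitudes.
    """
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.duration * cfg.fs))
    if n_frames < 2:
        raise InvalidConfigError("duration too short for the sampling rate")
    t = np.arange(n_frames) / cfg.fs
    traces, all_times, all_amps = [], [], []
    for i in range(cfg.n_neurons):
        times = gen_event_times(cfg, 1, rng)[0]
        amps = np.clip(
            rng.normal(cfg.amplitude_mean, cfg.amplitude_sd, times.size), 0.05, None
        )
        s = np.zeros(n_frames)
        for t0, a in zip(times, amps):
            i0 = int(np.ceil(t0 * cfg.fs))
            if i0 >= n_frames:
                continue
            s[i0:] += a * np.exp(-(t[i0:] - t0) / cfg.decay_tau)
        if cfg.drift_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            s += cfg.drift_amplitude * np.sin(
                2 * np.pi * t / (2 * cfg.duration) + phase
            )
        if cfg.noise_sd > 0:
            s += rng.normal(0.0, cfg.noise_sd, n_frames)
        traces.append(
            FluorescenceTrace(roi_id=i, samples=cfg.baseline_f0 * (1.0 + s), fs=cfg.fs)
        )
        all_times.append(times)
        all_amps.append(amps)
    return traces, GroundTruth(event_times=all_times, amplitudes=all_amps)


def make_layout(
    n: int,
    shape: tuple[int, int] = (512, 512),
    radius: float = 5.0,
    min_separation: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Random non-overlapping disc centers inside a frame.

    Returns (centers (n, 2) in pixels, radius).  Dart-throwing placement;
    raises :class:`LayoutError` when the requested density cannot be met.
    """
    rng = np.random.default_rng(seed)
    if min_separation is None:
        min_separation = 2.5 * radius
    centers: list[np.ndarray] = []
    margin = radius + 1
    for _ in range(20000):
        if len(centers) == n:
            break
        c = rng.uniform([margin, margin], [shape[0] - margin, shape[1] - margin])
        if all(np.hypot(*(c - o)) >= min_separation for o in centers):
            centers.append(c)
    if len(centers) < n:
        raise LayoutError("could not place all ROIs without overlap")
    return np.array(centers), radius


def gen_movie(
    traces: Sequence[FluorescenceTrace],
    centers: np.ndarray,
    radius: float,
    shape: tuple[int, int] = (512, 512),
    background: float = 10.0,
    shot_noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Paint disc-shaped somata into an image stack, frame by frame.

    Pixel intensity inside each disc follows that neuron's fluorescence
    trace; shot-like noise (Gaussian with SD ∝ sqrt(intensity)) is added
    when ``shot_noise_sd`` > 0.  Returns a float32 (frames, rows, cols)
    stack suitable for multi-page TIFF export.
    """
    centers = np.asarray(centers, dtype=float)
    if len(centers) != len(traces):
        raise LayoutError("one center per trace required")
    margin_ok = (
        (centers[:, 0] >= radius)
        & (centers[:, 0] <= shape[0] - radius)
        & (centers[:, 1] >= radius)
        & (centers[:, 1] <= shape[1] - radius)
    )
    if not margin_ok.all():
        raise LayoutError("ROI disc extends outside the frame")
    rng = np.random.default_rng(seed)
    n_frames = traces[0].n_frames
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    masks = [
        (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2 for r0, c0 in centers
    ]
    stack = np.full((n_frames, *shape), background, dtype=np.float32)
    for mask, tr in zip(masks, traces):
        stack[:, mask] = tr.samples[:, None].astype(np.float32)
    if shot_noise_sd > 0:
        stack += rng.normal(
            0.0, shot_noise_sd * np.sqrt(np.maximum(stack, 0.0))
        ).astype(np.float32)
    return stack


# ---------------------------------------------------------------------------
# orientation-tuned responses


def gen_tuned_responses(
    cfg: SimConfig,
    schedule,
) -> tuple[list[FluorescenceTrace], GroundTruth]:
    """Event trains whose rate during drifting gratings is orientation-tuned.

    During the drifting window of direction θ the event rate scales with a
    von-Mises profile on the doubled angle (orientation symmetry),
    exp(κ·cos(2(θ−θ_pref))), normalized to preserve the mean rate across
    the 8 directions.  Outside drifting windows the baseline rate applies.
    ``schedule`` is a :class:`resilnet.tuning.GratingSchedule`.
    """
    rng = np.random.default_rng(cfg.seed)
    duration = float(schedule.total_duration)
    if duration <= 0:
        raise InvalidConfigError("schedule covers no time")
    n_frames = int(round(duration * cfg.fs))
    t = np.arange(n_frames) / cfg.fs
    drift = schedule.trials[schedule.trials.phase == "drifting"]
    dirs = np.sort(schedule.trials.direction_deg.unique())
    base = cfg.event_rate / 60.0

    traces, all_times, all_amps = [], [], []
    prefs = np.empty(cfg.n_neurons)
    for i in range(cfg.n_neurons):
        pref = (
            rng.uniform(0, 180.0)
            if cfg.preferred_direction is None
            else float(cfg.preferred_direction)
        )
        prefs[i] = pref
        w = np.exp(
            cfg.tuning_kappa * np.cos(2 * np.deg2rad(dirs - pref))
        )
        w = w / w.mean()  # mean rate over directions preserved
        gain = dict(zip(dirs, w))
        times = []
        # baseline Poisson train over the whole recording
        n_base = rng.poisson(base * duration)
        times.append(rng.uniform(0, duration, n_base))
        # extra drive during drifting windows, direction-dependent
        for _, row in drift.iterrows():
            extra = base * max(gain[row.direction_deg] - 1.0, 0.0)
            span = row.offset_s - row.onset_s
            n_ev = rng.poisson(extra * span)
            times.append(rng.uniform(row.onset_s, row.offset_s, n_ev))
        times = np.sort(np.concatenate(times))
        amps = np.clip(
            rng.normal(cfg.amplitude_mean, cfg.amplitude_sd, times.size), 0.05, None
        )
        s = np.zeros(n_frames)
        for t0, a in zip(times, amps):
            i0 = int(np.ceil(t0 * cfg.fs))
            if i0 >= n_frames:
                continue
            s[i0:] += a * np.exp(-(t[i0:] - t0) / cfg.decay_tau)
        if cfg.noise_sd > 0:
            s += rng.normal(0.0, cfg.noise_sd, n_frames)
        traces.append(
            FluorescenceTrace(roi_id=i, samples=cfg.baseline_f0 * (1.0 + s), fs=cfg.fs)
        )
        all_times.append(times)
        all_amps.append(amps)
    return traces, GroundTruth(
        event_times=all_times, amplitudes=all_amps, preferred_directions=prefs
    )


# ---------------------------------------------------------------------------
# burst signals


def _pink_noise(n: int, fs: float, rng: np.random.Generator, exponent: float = 1.0):
    """Spectrally shaped Gaussian noise with 1/f^exponent power, unit SD."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    f[0] = f[1]
    spec /= f ** (exponent / 2.0)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_burst_signal(
    cfg: SimConfig,
    n_trials: int,
    trial_len: float,
) -> tuple[np.ndarray, GroundTruth]:
    """Trial-organized 1/f background with planted oscillatory bursts.

    Each trial is unit-variance 1/f Gaussian background plus Poisson-timed
    Hann-windowed sinusoids at ``burst_freq`` lasting ``burst_cycles``
    cycles, scaled so the burst peak equals ``burst_snr`` background SDs.
    Planted bursts keep a refractory gap of two burst durations so each
    ground-truth peak is an identifiable event.  Returns
    (trials × samples array, ground truth with per-trial peak times).
    """
    fs = 1000.0 if cfg.fs < 200 else cfg.fs  # imaging-rate configs use EEG default
    if not 0 < cfg.burst_freq < fs / 2:
        raise InvalidConfigError("burst_freq must lie in (0, Nyquist)")
    rng = np.random.default_rng(cfg.seed)
    ns = int(round(trial_len * fs))
    blen = int(round(cfg.burst_cycles / cfg.burst_freq * fs))
    burst_dur = blen / fs
    margin = burst_dur
    trials = np.empty((n_trials, ns))
    peak_times: list[np.ndarray] = []
    for j in range(n_trials):
        x = _pink_noise(ns, fs, rng)
        n_cand = rng.poisson(cfg.burst_rate * trial_len)
        cand = np.sort(rng.uniform(margin, trial_len - margin, n_cand))
        kept: list[float] = []
        for c in cand:
            if not kept or c - kept[-1] >= 2 * burst_dur:
                kept.append(float(c))
        for c in kept:
            i0 = int(round(c * fs)) - blen // 2
            phase = rng.uniform(0, 2 * np.pi)
            w = np.hanning(blen) * np.sin(
                2 * np.pi * cfg.burst_freq * np.arange(blen) / fs + phase
            )
            x[i0 : i0 + blen] += cfg.burst_snr * w / np.abs(w).max()
        trials[j] = x
        peak_times.append(np.asarray(kept))
    return trials, GroundTruth(burst_times=peak_times)


# ---------------------------------------------------------------------------
# cohort / predictor / task tables


def gen_cohort(
    n: int,
    slope: float = 0.2,
    intercept: float = 2.0,
    resid_sd: float = 1.9,
    le_mean: float = 4.0,
    n_technical_failure: int = 0,
    n_mri_incomplete: int = 0,
    n_eeg_noise: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort table: life-event counts, GHQ scores, exclusion flags.

    LE ~ Poisson(``le_mean``); GHQ = intercept + slope·LE + N(0, resid_sd).
    The default residual SD puts the LE–GHQ association in the weak
    regime these cohorts show (population r ≈ 0.2).  Exclusion flags are
    assigned to disjoint random subject subsets, mirroring the study
    ledger categories.
    """
    if n < 3:
        raise InvalidConfigError("need at least 3 subjects")
    if resid_sd < 0:
        raise InvalidConfigError("resid_sd must be nonnegative")
    n_flagged = n_technical_failure + n_mri_incomplete + n_eeg_noise
    if n_flagged > n:
        raise InvalidConfigError("more exclusion flags than subjects")
    rng = np.random.default_rng(seed)
    le = rng.poisson(le_mean, n)
    ghq = intercept + slope * le + rng.normal(0.0, resid_sd, n)
    df = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "LE": le,
            "GHQ": ghq,
            "technical_failure": False,
            "mri_incomplete": False,
            "eeg_noise": False,
        }
    )
    flagged = rng.choice(n, size=n_flagged, replace=False)
    a = n_technical_failure
    b = a + n_mri_incomplete
    df.loc[flagged[:a], "technical_failure"] = True
    df.loc[flagged[a:b], "mri_incomplete"] = True
    df.loc[flagged[b:], "eeg_noise"] = True
    return df


def gen_predictor_table(
    n: int,
    true_lambdas: Sequence[float],
    resid_sd: float = 0.5,
    names: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Subject-level predictors with a linear stressor-reactivity outcome.

    Predictors are standard normal; the outcome column ``sr_proxy`` is
    Σ λᵢ·xᵢ + N(0, resid_sd).  Ground truth retains λ.
    """
    lam = np.asarray(true_lambdas, dtype=float)
    if lam.size < 1:
        raise InvalidConfigError("need at least one predictor")
    if resid_sd < 0:
        raise InvalidConfigError("resid_sd must be nonnegative")
    if names is None:
        names = [f"x{i+1}" for i in range(lam.size)]
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, lam.size))
    y = X @ lam + (rng.normal(0.0, resid_sd, n) if resid_sd > 0 else 0.0)
    df = pd.DataFrame(X, columns=list(names))
    df.insert(0, "subject_id", np.arange(n))
    df["sr_proxy"] = y
    return df, GroundTruth(coefficients=lam)


FLANKER_CONDITIONS = (
    ("Neutral", "Congruent"),
    ("Neutral", "Incongruent"),
    ("Negative", "Congruent"),
    ("Negative", "Incongruent"),
)


def gen_flanker_schedule(
    seed: int = 0,
    rt_base: float = 450.0,
    rt_emotion: float = 10.0,
    rt_congruency: float = 40.0,
    rt_interaction: float = 0.0,
    rt_sd: float = 80.0,
    accuracy: float = 0.96,
    simulate_behavior: bool = True,
) -> pd.DataFrame:
    """The 2×2 emotional Flanker design: 1,120 trials in 5 blocks of 224.

    Each condition (valence × congruency) has 280 trials with left/right
    target directions balanced 140/140.  With ``simulate_behavior`` a
    linear RT model (main effects + interaction, Gaussian noise, in ms)
    and Bernoulli correctness are added, so behavioral contrasts can be
    recovered against the injected effects.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for valence, congruency in FLANKER_CONDITIONS:
        for direction in ("left", "right"):
            rows.extend(
                {"valence": valence, "congruency": congruency, "target": direction}
                for _ in range(140)
            )
    df = pd.DataFrame(rows)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "trial", np.arange(1, len(df) + 1))
    df["block"] = 1 + (df.trial - 1) // 224
    if simulate_behavior:
        neg = (df.valence == "Negative").to_numpy(dtype=float)
        inc = (df.congruency == "Incongruent").to_numpy(dtype=float)
        rt = (
            rt_base
            + rt_emotion * neg
            + rt_congruency * inc
            + rt_interaction * neg * inc
            + rng.normal(0.0, rt_sd, len(df))
        )
        df["rt_ms"] = np.clip(rt, 100.0, None)
        df["correct"] = rng.random(len(df)) < accuracy
    return df


def gen_si_table(
    n_per_group: dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Mouse social-interaction dwell-time table with known group labels.

    Resilient animals dwell longer near the caged aggressor than near the
    empty enclosure (ratio > 1), nonresilient the reverse; nonstressed
    animals are generated like resilient ones (no avoidance).
    """
    rng = np.random.default_rng(seed)
    rows = []
    aid = 0
    for group, n in n_per_group.items():
        for _ in range(n):
            empty = rng.uniform(40.0, 80.0)
            if group == "nonresilient":
                ratio = rng.uniform(0.15, 0.95)
            else:
                ratio = rng.uniform(1.05, 1.65)
            rows.append(
                {
                    "animal_id": aid,
                    "dwell_target_s": empty * ratio,
                    "dwell_empty_s": empty,
                    "true_group": group,
                }
            )
            aid += 1
    return pd.DataFrame(rows)
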