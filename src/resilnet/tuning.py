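"""Grating schedules, direction response functions, and circular variance.

The visual-stimulation paradigm is 5 s of gray screen followed by 8 grating
directions (0°, 45°, …, 315°), each shown 5 s static then 5 s drifting, the
whole sequence repeated 10 times with a fresh randomization.  Orientation
selectivity is summarized by the circular variance

    CV = 1 − |Σ_k r_k · exp(i·2θ_k)| / Σ_k r_k

on the doubled angle (orientation symmetry): CV = 0 for a neuron responding
to a single orientation, CV = 1 for a uniform responder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DIRECTIONS_DEG = (0, 45, 90, 135, 180, 225, 270, 315)


class AlignmentError(ValueError):
    """Raised when a schedule does not fit the trace it is applied to."""


@dataclass
class GratingSchedule:
    """Stimulus timing table plus gray-screen periods.

    ``trials`` has one row per (direction, phase) block with columns
    ``trial, direction_deg, phase, onset_s, offset_s, rep``; ``gray``
    lists (onset_s, offset_s) gray periods.
    """

    trials: pd.DataFrame
    gray: list[tuple[float, float]]

    def __post_init__(self) -> None:
        t = self.trials
        if np.any(t.offset_s <= t.onset_s):
            raise ValueError("trials must have positive duration")
        if np.any(np.diff(t.onset_s) < 0):
            raise ValueError("trials must be time-sorted")

    @property
    def total_duration(self) -> float:
        ends = [self.trials.offset_s.max()] + [b for _, b in self.gray]
        return float(max(ends))


@dataclass
class TuningResult:
    """Per-neuron direction responses and circular variance."""

    roi_id: int
    directions_deg: np.ndarray
    responses: np.ndarray
    cv: float = np.nan


def build_schedule(
    directions=DIRECTIONS_DEG,
    gray_s: float = 5.0,
    static_s: float = 5.0,
    drift_s: float = 5.0,
    reps: int = 10,
    seed: int = 0,
) -> GratingSchedule:
    """Build the randomized grating paradigm.

    Each repetition opens with a gray period, then presents all directions
    in a fresh seeded permutation, each as a static block followed by a
    drifting block.
    """
    rng = np.random.default_rng(seed)
    rows = []
    gray = []
    t = 0.0
    trial = 0
    for rep in range(reps):
        gray.append((t, t + gray_s))
        t += gray_s
        for d in rng.permutation(directions):
            for phase, dur in (("static", static_s), ("drifting", drift_s)):
                rows.append(
                    {
                        "trial": trial,
                        "direction_deg": int(d),
                        "phase": phase,
                        "onset_s": t,
                        "offset_s": t + dur,
                        "rep": rep,
                    }
                )
                t += dur
                trial += 1
    return GratingSchedule(trials=pd.DataFrame(rows), gray=gray)


def response_function(dff, schedule: GratingSchedule, include_static: bool = False):
    """Mean ΔF/F per direction during drifting windows, gray-corrected.

    r_k = mean ΔF/F over direction-k drifting windows (averaged over
    repetitions) minus the mean over gray periods, clipped at zero so the
    circular variance stays well-defined.  Returns a
    :class:`TuningResult` without the CV filled in.
    """
    y = np.asarray(dff.dff)
    fs = dff.fs
    n = y.size
    if schedule.total_duration > n / fs + 1.0 / fs:
        raise AlignmentError("schedule extends past the end of the trace")

    def window_mean(a: float, b: float) -> float:
        i0, i1 = int(round(a * fs)), min(int(round(b * fs)), n)
        if i1 <= i0:
            raise AlignmentError("empty stimulus window")
        return float(y[i0:i1].mean())

    gray_mean = float(np.mean([window_mean(a, b) for a, b in schedule.gray]))
    phases = ("drifting", "static") if include_static else ("drifting",)
    sel = schedule.trials[schedule.trials.phase.isin(phases)]
    dirs = np.sort(sel.direction_deg.unique())
    r = np.empty(dirs.size)
    for k, d in enumerate(dirs):
        blocks = sel[sel.direction_deg == d]
        r[k] = np.mean([window_mean(a, b) for a, b in zip(blocks.onset_s, blocks.offset_s)])
    r = np.clip(r - gray_mean, 0.0, None)
    return TuningResult(roi_id=dff.roi_id, directions_deg=dirs, responses=r)


def circular_variance(r, theta) -> float:
    """CV = 1 − |Σ r_k e^{i2θ_k}| / Σ r_k (θ in radians).

    Returns NaN when all responses are zero (undefined tuning).
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if r.shape != theta.shape:
        raise ValueError("r and theta must have equal length")
    if np.any(r < 0):
        raise ValueError("responses must be nonnegative")
    total = r.sum()
    if total == 0:
        return float("nan")
    return float(1.0 - np.abs(np.sum(r * np.exp(2j * theta))) / total)


def tune_neurons(results: list[TuningResult]) -> list[TuningResult]:
    """Fill the circular variance of each tuning result in place."""
    for res in results:
        res.cv = circular_variance(res.responses, np.deg2rad(res.directions_deg))
    return results


def tuning_compare(
    groups: dict[str, np.ndarray],
    cv_cutoff: float | None = None,
) -> pd.DataFrame:
    """Pairwise two-sided KS tests on pooled CV distributions per group.

    Optionally reports, per group, the fraction of neurons with CV below
    ``cv_cutoff`` ("well-tuned" fraction).  Returns a tidy table with one
    row per group pair.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(np.asarray(vals)) == 0:
            raise ValueError(f"group {name!r} is empty")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va = np.asarray(groups[a], dtype=float)
            vb = np.asarray(groups[b], dtype=float)
            res = stats.ks_2samp(va, vb, method="asymp")
            row = {
                "group_a": a,
                "group_b": b,
                "ks_D": float(res.statistic),
                "p_value": float(res.pvalue),
            }
            if cv_cutoff is not None:
                row["tuned_frac_a"] = float(np.mean(va <= cv_cutoff))
                row["tuned_frac_b"] = float(np.mean(vb <= cv_cutoff))
            rows.append(row)
    return pd.DataFrame(rows)
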