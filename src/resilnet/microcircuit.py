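"""Neuron- and group-level microcircuit statistics.

Activity frequency, transient amplitudes, inter-event intervals (IEIs),
empirical CDFs with two-sided Kolmogorov–Smirnov group comparisons, neuron
density t tests, and pairwise-correlation connectivity maps built from the
binarized activity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import BinaryRaster


@dataclass
class NeuronSummary:
    """Pooled per-soma statistics carrying the animal's group label."""

    animal_id: int
    roi_id: int
    group: str
    frequency: float  # events per minute
    amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    ieis: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise ValueError("frequency must be nonnegative")
        if np.any(np.asarray(self.ieis) <= 0):
            raise ValueError("IEIs must be positive")


@dataclass
class ConnectivityMap:
    """Ensemble connectivity: node positions/frequencies + correlation edges."""

    positions: np.ndarray
    frequencies: np.ndarray
    weights: np.ndarray
    constant_rows: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = self.weights
        if w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T, equal_nan=True):
            raise ValueError("weight matrix must be symmetric")

    @property
    def mean_edge_weight(self) -> float:
        iu = np.triu_indices_from(self.weights, k=1)
        return float(np.mean(self.weights[iu])) if iu[0].size else float("nan")

    @property
    def weighted_degree(self) -> np.ndarray:
        return self.weights.sum(axis=1) - np.diag(self.weights)


def event_frequency(event_times_or_count, duration_s: float) -> float:
    """Events per minute over a recording of ``duration_s`` seconds."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = (
        event_times_or_count
        if np.isscalar(event_times_or_count)
        else len(event_times_or_count)
    )
    return 60.0 * n / duration_s


def compute_iei(event_times_s) -> np.ndarray:
    """Successive peak-to-peak differences (s); empty below 2 events."""
    t = np.asarray(event_times_s, dtype=float)
    if t.size < 2:
        return np.empty(0)
    if np.any(np.diff(t) < 0):
        raise ValueError("event times must be sorted")
    return np.diff(t)


class ecdf:
    """Right-continuous empirical CDF, evaluable at arbitrary points."""

    def __init__(self, sample):
        x = np.asarray(sample, dtype=float)
        if x.size == 0:
            raise ValueError("empty sample")
        self.x = np.sort(x)
        self.n = x.size

    def __call__(self, q):
        return np.searchsorted(self.x, np.asarray(q, dtype=float), side="right") / self.n


def ks_compare(a, b) -> tuple[float, float]:
    """Two-sided KS test: D = sup|ECDF_a − ECDF_b| and asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def density_compare(counts_a, counts_b) -> tuple[float, float]:
    """Two-sided two-sample t test on per-micrograph neuron counts."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0  # identical constant groups: no evidence
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def connectivity_map(
    raster: BinaryRaster,
    positions: np.ndarray,
    frequencies: np.ndarray,
) -> ConnectivityMap:
    """Pairwise Pearson correlation of binarized rows on co-active frames.

    Frames where no neuron is active are discarded first; correlations on
    binary rows over the remaining frames are the φ coefficients of the
    ensemble.  Rows constant on the restricted frames get zero correlation
    and are flagged.
    """
    mat = raster.matrix.astype(float)
    if mat.size == 0:
        raise ValueError("empty raster")
    active = mat.sum(axis=0) > 0
    sub = mat[:, active]
    n = mat.shape[0]
    if sub.shape[1] < 2:
        raise ValueError("fewer than 2 co-active frames; correlations undefined")
    sd = sub.std(axis=1)
    constant = sd == 0
    weights = np.zeros((n, n))
    ok = ~constant
    if ok.sum() >= 2:
        weights[np.ix_(ok, ok)] = np.corrcoef(sub[ok])
    np.fill_diagonal(weights, 1.0)
    return ConnectivityMap(
        positions=np.asarray(positions, dtype=float),
        frequencies=np.asarray(frequencies, dtype=float),
        weights=weights,
        constant_rows=constant,
    )


def pool_groups(
    summaries: list[NeuronSummary] | pd.DataFrame,
    si_table: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Pool somata into groups by their animal's SI classification.

    ``si_table`` must map every ``animal_id`` to a ``group`` column.
    Returns one tidy DataFrame of somata per group (empty groups allowed).
    """
    if isinstance(summaries, list):
        df = pd.DataFrame(
            {
                "animal_id": [s.animal_id for s in summaries],
                "roi_id": [s.roi_id for s in summaries],
                "frequency": [s.frequency for s in summaries],
                "amplitudes": [np.asarray(s.amplitudes) for s in summaries],
                "ieis": [np.asarray(s.ieis) for s in summaries],
            }
        )
    else:
        df = summaries.copy()
    lookup = si_table.set_index("animal_id")["group"]
    missing = set(df.animal_id.unique()) - set(lookup.index)
    if missing:
        raise KeyError(f"animals without SI classification: {sorted(missing)}")
    df = df.assign(group=df.animal_id.map(lookup))
    pools = {g: sub.reset_index(drop=True) for g, sub in df.groupby("group")}
    for g in pd.unique(lookup):
        if g not in pools:
            warnings.warn(f"group {g!r} has no somata", stacklevel=2)
            pools[g] = df.iloc[0:0].copy()
    return pools
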