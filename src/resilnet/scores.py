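"""Outcome-based resilience scores and behavioral contrasts.

Human arm: the stressor-reactivity (SR) proxy is the residual of an
ordinary least-squares regression of mental-health problems (GHQ) on
life-event (LE) exposure — a positive residual means worse-than-expected
mental health given the stressors experienced, i.e. lower resilience.
Mouse arm: the social-interaction (SI) score after chronic social defeat,
100 × dwell(aggressor present)/dwell(empty enclosure), classifies animals
as resilient (> 100) or nonresilient.  Flanker reaction-time contrasts and
the participant exclusion ledger complete the behavioral layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class DegenerateDataError(ValueError):
    """Raised when a score is undefined on the given data."""


def sr_proxy(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append the SR proxy (GHQ-on-LE OLS residual) to a cohort table.

    Positive residuals indicate worse-than-expected mental health for the
    experienced stressor load (higher stressor reactivity, lower
    resilience).  Requires ≥ 3 subjects and non-constant LE.
    """
    if len(cohort) < 3:
        raise DegenerateDataError("need at least 3 subjects")
    le = cohort["LE"].to_numpy(dtype=float)
    if np.ptp(le) == 0:
        raise DegenerateDataError("life-event counts are all equal")
    model = sm.OLS(cohort["GHQ"].to_numpy(dtype=float), sm.add_constant(le)).fit()
    out = cohort.copy()
    out["sr_proxy"] = model.resid
    out.attrs["ghq_on_le"] = {
        "intercept": float(model.params[0]),
        "slope": float(model.params[1]),
    }
    return out


def le_ghq_correlation(cohort: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between LE and GHQ with two-sided t-based p."""
    if len(cohort) < 3:
        raise DegenerateDataError("need at least 3 subjects")
    le = cohort["LE"].to_numpy(dtype=float)
    ghq = cohort["GHQ"].to_numpy(dtype=float)
    if le.std() == 0 or ghq.std() == 0:
        raise DegenerateDataError("zero variance in LE or GHQ")
    r, p = stats.pearsonr(le, ghq)
    return float(r), float(p)


def si_score(
    dwell_target_s: float,
    dwell_empty_s: float,
    boundary_group: str = "nonresilient",
) -> tuple[float, str]:
    """Social-interaction score and resilience classification.

    SI = 100 × dwell(aggressor)/dwell(empty); > 100 ⇒ resilient,
    < 100 ⇒ nonresilient.  The boundary SI = 100 is assigned to
    ``boundary_group`` (conservatively nonresilient by default).
    """
    if min(dwell_target_s, dwell_empty_s) < 0:
        raise ValueError("dwell times must be nonnegative")
    if dwell_empty_s == 0:
        raise DegenerateDataError("SI undefined: no time near the empty enclosure")
    si = 100.0 * dwell_target_s / dwell_empty_s
    if si > 100.0:
        group = "resilient"
    elif si < 100.0:
        group = "nonresilient"
    else:
        group = boundary_group
    return si, group


def score_si_table(si_table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Vectorized :func:`si_score` over a dwell-time table."""
    scored = si_table.copy()
    res = [
        si_score(t, e, **kwargs)
        for t, e in zip(si_table.dwell_target_s, si_table.dwell_empty_s)
    ]
    scored["si_score"] = [s for s, _ in res]
    scored["group"] = [g for _, g in res]
    return scored


@dataclass
class FlankerContrasts:
    """Per-subject reaction-time and accuracy contrasts of the 2×2 design."""

    rt_emotion: float
    rt_cognition: float
    rt_interaction: float
    acc_emotion: float
    acc_cognition: float
    acc_interaction: float
    n_trials_used: int
    cell_means_rt: dict[tuple[str, str], float] | None = None


def flanker_contrasts(
    trials: pd.DataFrame,
    rt_max_ms: float = 1000.0,
    exclude_errors: bool = True,
) -> FlankerContrasts:
    """Condition-mean contrasts from a Flanker trial table.

    RT contrasts use correct trials with RT ≤ ``rt_max_ms`` (slow responses
    are excluded as in the task's feedback rule):
    ΔRT_emotion = Negative − Neutral, ΔRT_cognition = Incongruent −
    Congruent, and ΔRT_interaction = (Incong.Neg − Incong.Neut) −
    (Cong.Neg − Cong.Neut).  Accuracy contrasts are analogous on
    proportions correct over in-window trials.
    """
    required = {"valence", "congruency", "rt_ms", "correct"}
    if not required <= set(trials.columns):
        raise KeyError(f"trial table needs columns {sorted(required)}")
    in_window = trials[trials.rt_ms <= rt_max_ms]
    rt_pool = in_window[in_window.correct] if exclude_errors else in_window

    def cell(df: pd.DataFrame, val: str, cong: str) -> pd.DataFrame:
        sub = df[(df.valence == val) & (df.congruency == cong)]
        if len(sub) == 0:
            raise DegenerateDataError(f"no usable trials in cell ({val}, {cong})")
        return sub

    rt = {
        (v, c): float(cell(rt_pool, v, c).rt_ms.mean())
        for v in ("Neutral", "Negative")
        for c in ("Congruent", "Incongruent")
    }
    acc = {
        (v, c): float(cell(in_window, v, c).correct.mean())
        for v in ("Neutral", "Negative")
        for c in ("Congruent", "Incongruent")
    }

    def contrasts(m: dict) -> tuple[float, float, float]:
        emotion = (
            m[("Negative", "Congruent")] + m[("Negative", "Incongruent")]
        ) / 2 - (m[("Neutral", "Congruent")] + m[("Neutral", "Incongruent")]) / 2
        cognition = (
            m[("Neutral", "Incongruent")] + m[("Negative", "Incongruent")]
        ) / 2 - (m[("Neutral", "Congruent")] + m[("Negative", "Congruent")]) / 2
        interaction = (
            m[("Negative", "Incongruent")] - m[("Neutral", "Incongruent")]
        ) - (m[("Negative", "Congruent")] - m[("Neutral", "Congruent")])
        return emotion, cognition, interaction

    rt_e, rt_c, rt_i = contrasts(rt)
    ac_e, ac_c, ac_i = contrasts(acc)
    return FlankerContrasts(
        rt_emotion=rt_e,
        rt_cognition=rt_c,
        rt_interaction=rt_i,
        acc_emotion=ac_e,
        acc_cognition=ac_c,
        acc_interaction=ac_i,
        n_trials_used=len(rt_pool),
        cell_means_rt=rt,
    )


def roster_filter(cohort: pd.DataFrame) -> dict:
    """Participant counts per analysis stage from the exclusion flags.

    Behavioral n = total − technical failures; electrophysiological n =
    behavioral − MRI-related − EEG-noise exclusions.  Subjects carrying
    multiple flags are counted once, at the earliest applicable stage, and
    reported.
    """
    flags = ("technical_failure", "mri_incomplete", "eeg_noise")
    for f in flags:
        if f not in cohort.columns:
            raise KeyError(f"missing exclusion flag column {f!r}")
    total = len(cohort)
    tech = cohort.technical_failure.astype(bool)
    mri = cohort.mri_incomplete.astype(bool) & ~tech
    noise = cohort.eeg_noise.astype(bool) & ~tech & ~cohort.mri_incomplete.astype(bool)
    overlap = int((cohort[list(flags)].astype(bool).sum(axis=1) > 1).sum())
    behavioral = total - int(tech.sum())
    electrophys = behavioral - int(mri.sum()) - int(noise.sum())
    return {
        "total": total,
        "excluded_technical": int(tech.sum()),
        "behavioral_n": behavioral,
        "excluded_mri": int(mri.sum()),
        "excluded_eeg_noise": int(noise.sum()),
        "electrophys_n": electrophys,
        "multi_flagged": overlap,
    }


def split_by_sr_sign(scored: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Dichotomize subjects: negative SR proxy ⇒ resilient, positive ⇒ not."""
    if "sr_proxy" not in scored.columns:
        raise KeyError("run sr_proxy() first")
    return {
        "resilient": scored[scored.sr_proxy < 0].reset_index(drop=True),
        "nonresilient": scored[scored.sr_proxy >= 0].reset_index(drop=True),
    }
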