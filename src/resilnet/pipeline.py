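"""End-to-end orchestration of the mouse and human analysis arms.

Both pipelines run entirely on generated data with ground truth attached,
propagate a single master seed to every stage, and emit a machine-readable
JSON report (plus tidy CSVs when an output directory is given).  Reports
embed the configuration hash and per-stage seeds, so a fixed seed
reproduces the report exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes, imaging, microcircuit, scores, spectral, synthdata, tuning


@dataclass
class PipelineConfig:
    """Top-level configuration; stage parameters scale the problem size."""

    arm: str = "both"
    seed: int = 0
    output_dir: str | None = None
    # mouse arm
    animals_per_group: int = 3
    neurons_per_animal: int = 30
    recording_s: float = 300.0
    threshold_sd: float = 2.5
    smoothing_passes: int = 25
    cutoff_hz: float = 0.12
    # human arm
    n_subjects: int = 121
    n_technical_failure: int = 4
    n_mri_incomplete: int = 13
    n_eeg_noise: int = 1
    cohort_slope: float = 0.2
    cohort_resid_sd: float = 1.9
    n_burst_trials: int = 60
    n_train_trials: int = 100
    trial_len_s: float = 4.0  # long enough for within-trial IEI statistics
    bayes_tune: int = 1000
    bayes_draws: int = 2000

    def __post_init__(self) -> None:
        if self.arm not in ("mouse", "human", "both"):
            raise ValueError("arm must be mouse, human or both")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _detect_events(traces, cfg: PipelineConfig):
    """ΔF/F → smooth/filter → transient detection for a list of traces."""
    events_per_roi = []
    dffs = []
    for tr in traces:
        dff = imaging.compute_dff(tr)
        smoothed = imaging.smooth_and_filter(
            dff, passes=cfg.smoothing_passes, cutoff_hz=cfg.cutoff_hz
        )
        events_per_roi.append(
            imaging.detect_transients(
                smoothed, threshold_sd=cfg.threshold_sd, raw=dff
            )
        )
        dffs.append(smoothed)
    return dffs, events_per_roi


def run_mouse_pipeline(cfg: PipelineConfig) -> dict:
    """Simulate → detect → binarize → statistics → group comparisons."""
    report: dict = {
        "arm": "mouse",
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stage_seeds": {},
    }
    groups = ("resilient", "nonresilient", "nonstressed")
    per_group_freq: dict[str, list[float]] = {g: [] for g in groups}
    per_group_amp: dict[str, list[float]] = {g: [] for g in groups}
    per_group_iei: dict[str, list[float]] = {g: [] for g in groups}
    counts = {g: 0 for g in groups}
    try:
        animal_id = 0
        connectivity_summary = []
        for group in groups:
            for _ in range(cfg.animals_per_group):
                sseed = _stage_seed(cfg.seed, f"mouse:{group}:{animal_id}")
                report["stage_seeds"][f"animal_{animal_id}"] = sseed
                sim = synthdata.SimConfig.for_group(
                    group,
                    seed=sseed,
                    duration=cfg.recording_s,
                    n_neurons=cfg.neurons_per_animal,
                )
                traces, _truth = synthdata.gen_calcium_traces(sim)
                _, events = _detect_events(traces, cfg)
                n_frames = traces[0].n_frames
                raster = imaging.binarize(events, n_frames, sim.fs)
                for evs in events:
                    peaks_s = np.array([e.peak for e in evs]) / sim.fs
                    per_group_freq[group].append(
                        microcircuit.event_frequency(peaks_s, cfg.recording_s)
                    )
                    per_group_amp[group].extend(e.amplitude for e in evs)
                    per_group_iei[group].extend(microcircuit.compute_iei(peaks_s))
                    counts[group] += 1
                if raster.matrix.sum() > 0:
                    freqs = raster.matrix.sum(axis=1)
                    pos = np.zeros((len(traces), 2))
                    try:
                        cmap = microcircuit.connectivity_map(raster, pos, freqs)
                        connectivity_summary.append(cmap.mean_edge_weight)
                    except ValueError:
                        pass
                animal_id += 1
    except Exception as exc:  # noqa: BLE001
        raise StageError("mouse:simulate+detect", exc) from exc

    try:
        stats_out = {}
        for a, b in (("resilient", "nonresilient"),):
            for name, pool in (
                ("frequency", per_group_freq),
                ("amplitude", per_group_amp),
                ("iei", per_group_iei),
            ):
                d, p = microcircuit.ks_compare(pool[a], pool[b])
                stats_out[f"ks_{name}_{a}_vs_{b}"] = {"D": d, "p": p}
        report["somata_per_group"] = counts
        report["median_frequency_per_min"] = {
            g: float(np.median(v)) if v else None for g, v in per_group_freq.items()
        }
        report["mean_amplitude"] = {
            g: float(np.mean(v)) if v else None for g, v in per_group_amp.items()
        }
        report["group_tests"] = stats_out
        report["mean_edge_weight"] = (
            float(np.mean(connectivity_summary)) if connectivity_summary else None
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("mouse:stats", exc) from exc

    try:
        tseed = _stage_seed(cfg.seed, "mouse:tuning")
        report["stage_seeds"]["tuning"] = tseed
        schedule = tuning.build_schedule(reps=3, seed=tseed)
        cv_groups = {}
        for group in ("resilient", "nonresilient"):
            sim = synthdata.SimConfig.for_group(
                group,
                seed=tseed + (0 if group == "resilient" else 1),
                duration=schedule.total_duration,
                n_neurons=cfg.neurons_per_animal,
                noise_sd=0.05,
            )
            traces, _ = synthdata.gen_tuned_responses(sim, schedule)
            cvs = []
            for tr in traces:
                dff = imaging.compute_dff(tr)
                res = tuning.response_function(dff, schedule)
                cv = tuning.circular_variance(
                    res.responses, np.deg2rad(res.directions_deg)
                )
                if np.isfinite(cv):
                    cvs.append(cv)
            cv_groups[group] = np.array(cvs)
        comp = tuning.tuning_compare(cv_groups, cv_cutoff=0.5)
        report["tuning"] = {
            "median_cv": {g: float(np.median(v)) for g, v in cv_groups.items()},
            "ks": comp.to_dict(orient="records"),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("mouse:tuning", exc) from exc
    return report


def run_human_pipeline(cfg: PipelineConfig) -> dict:
    """Cohort scoring → contrasts → TFR extremes → bursts → Bayesian fits."""
    report: dict = {
        "arm": "human",
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stage_seeds": {},
    }
    try:
        cseed = _stage_seed(cfg.seed, "human:cohort")
        report["stage_seeds"]["cohort"] = cseed
        cohort = synthdata.gen_cohort(
            cfg.n_subjects,
            slope=cfg.cohort_slope,
            resid_sd=cfg.cohort_resid_sd,
            n_technical_failure=cfg.n_technical_failure,
            n_mri_incomplete=cfg.n_mri_incomplete,
            n_eeg_noise=cfg.n_eeg_noise,
            seed=cseed,
        )
        report["roster"] = scores.roster_filter(cohort)
        behavioral = cohort[~cohort.technical_failure].reset_index(drop=True)
        scored = scores.sr_proxy(behavioral)
        r, p = scores.le_ghq_correlation(behavioral)
        report["le_ghq"] = {"r": r, "p": p}
        report["sr_proxy_sd"] = float(scored.sr_proxy.std())
    except Exception as exc:  # noqa: BLE001
        raise StageError("human:cohort", exc) from exc

    try:
        fseed = _stage_seed(cfg.seed, "human:flanker")
        report["stage_seeds"]["flanker"] = fseed
        sched = synthdata.gen_flanker_schedule(seed=fseed, rt_interaction=-20.0)
        fc = scores.flanker_contrasts(sched)
        report["flanker"] = {
            "n_trials": len(sched),
            "rt_emotion": fc.rt_emotion,
            "rt_cognition": fc.rt_cognition,
            "rt_interaction": fc.rt_interaction,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("human:flanker", exc) from exc

    try:
        bseed = _stage_seed(cfg.seed, "human:bursts")
        report["stage_seeds"]["bursts"] = bseed
        iei_pool = {}
        for group, rate in (("resilient", 0.6), ("nonresilient", 1.0)):
            sim = synthdata.SimConfig(
                seed=bseed + (0 if group == "resilient" else 1),
                fs=1000.0,
                duration=cfg.trial_len_s,
                burst_rate=rate,
                burst_snr=3.0,
            )
            trials, _ = synthdata.gen_burst_signal(
                sim, cfg.n_train_trials + cfg.n_burst_trials, cfg.trial_len_s
            )
            dico = spectral.learn_dictionary(
                trials[: cfg.n_train_trials], fs=1000.0, seed=bseed
            )
            bursts = spectral.detect_bursts(trials[cfg.n_train_trials :], dico)
            iei_pool[group] = spectral.burst_iei(bursts)
        d, p = microcircuit.ks_compare(
            iei_pool["resilient"], iei_pool["nonresilient"]
        )
        report["burst_iei"] = {
            "median_iei_s": {
                g: float(np.median(v)) if v.size else None for g, v in iei_pool.items()
            },
            "ks_D": d,
            "ks_p": p,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("human:bursts", exc) from exc

    try:
        mseed = _stage_seed(cfg.seed, "human:bayes")
        report["stage_seeds"]["bayes"] = mseed
        n_eeg = report["roster"]["electrophys_n"]
        predictors = ["ifg_tri_min", "ifg_tri_max", "v2_min", "v2_max"]
        table, truth = synthdata.gen_predictor_table(
            n_eeg,
            true_lambdas=[-0.5, 0.0, 0.0, 0.4],
            resid_sd=0.7,
            names=predictors,
            seed=mseed,
        )
        model_defs = {
            "m1": ["ifg_tri_min"],
            "m2": ["ifg_tri_max"],
            "m3": ["v2_min"],
            "m4": ["v2_max"],
            "m5": ["ifg_tri_min", "v2_max"],
            "m6": predictors,
        }
        fits = {}
        for name, preds in model_defs.items():
            summary, _ = bayes.fit_model(
                bayes.RegressionSpec.power_model(preds),
                table,
                chains=2,
                tune=cfg.bayes_tune,
                draws=cfg.bayes_draws,
                seed=mseed,
            )
            fits[name] = summary
        ranking = bayes.loo_compare(fits)
        report["bayes"] = {
            "true_lambdas": dict(zip(predictors, truth.coefficients.tolist())),
            "loo_ranking": ranking.to_dict(orient="records"),
            "winning_model": str(ranking.model.iloc[0]),
            "m5_coefficients": {
                k: float(fits["m5"].params.loc[k, "mean"])
                for k in ("ifg_tri_min", "v2_max")
            },
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("human:bayes", exc) from exc
    return report


def run(cfg: PipelineConfig) -> dict:
    """Run the requested arm(s) and optionally write the JSON report."""
    report = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    if cfg.arm in ("mouse", "both"):
        report["mouse"] = run_mouse_pipeline(cfg)
    if cfg.arm in ("human", "both"):
        report["human"] = run_human_pipeline(cfg)
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
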