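import numpy as np
import pytest

from resilnet import synthdata, tuning


@pytest.fixture(scope="session")
def short_schedule():
    """Three-repetition grating schedule (fast tests)."""
    return tuning.build_schedule(reps=3, seed=7)


@pytest.fixture(scope="session")
def quiet_traces():
    """Small noiseless trace set with known events."""
    cfg = synthdata.SimConfig.for_group(
        "nonstressed", seed=11, duration=120.0, n_neurons=4, noise_sd=0.0
    )
    return synthdata.gen_calcium_traces(cfg)


@pytest.fixture(scope="session")
def noisy_traces():
    """Trace set at SNR 5 (amplitude 1.0, noise 0.2) with ground truth."""
    cfg = synthdata.SimConfig(
        seed=5,
        duration=300.0,
        n_neurons=10,
        event_rate=2.0,
        amplitude_mean=1.0,
        amplitude_sd=0.2,
        noise_sd=0.2,
    )
    return synthdata.gen_calcium_traces(cfg), cfg


def match_events(detected_s, true_s, tol_s=0.3):
    """Greedy one-to-one matching; returns (tp, fp, fn)."""
    detected_s = np.asarray(detected_s, dtype=float)
    true_s = np.asarray(true_s, dtype=float)
    used = np.zeros(true_s.size, dtype=bool)
    tp = 0
    for d in detected_s:
        if true_s.size == 0:
            break
        dist = np.abs(true_s - d) + used * 1e9
        j = int(np.argmin(dist))
        if dist[j] <= tol_s:
            used[j] = True
            tp += 1
    return tp, detected_s.size - tp, true_s.size - tp
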