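import numpy as np
import pytest
from hypothesis import settings

from baepstd.config import SimulationConfig

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def small_config():
    """A 20-patient cohort, quick enough for per-test regeneration."""
    return SimulationConfig(n_patients=20, seed=1234)


@pytest.fixture
def quiet_config():
    """All stochastic corruption switched off: no injury, no drift, no noise."""
    return SimulationConfig(
        n_patients=6, seed=7,
        injury_effect_latency=0.0, injury_effect_amplitude=0.0,
        common_mode_sd=0.0, common_mode_latency_sd=0.0,
        measurement_noise_sd=0.0, epoch_dropout=0.0,
        audiometry_noise_sd=0.0,
    )


def brute_force_auc(scores, y):
    """Exhaustive concordant-pair AUC: ties half-counted."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(scores, y):
    """Best J = sens + spec - 1 over all observed thresholds (rule: score >= c)."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    best = -np.inf
    for c in np.unique(scores):
        pred = scores >= c
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        best = max(best, sens + spec - 1.0)
    return best
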