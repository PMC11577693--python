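import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prosim import TrialDataset, grid_from_label

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def build_trial(y0, y1, rep_index: int = 0) -> TrialDataset:
    """Assemble a trial directly from per-arm observed score vectors."""
    y0 = np.asarray(y0, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y = np.concatenate([y0, y1])
    return TrialDataset(
        arm=np.concatenate([np.zeros(y0.size, int), np.ones(y1.size, int)]),
        latent=y.copy(),
        clamped=np.clip(y, 0.0, 100.0),
        observed=y,
        rep_index=rep_index,
    )


@pytest.fixture
def trial_factory():
    return build_trial


@pytest.fixture(params=["RE4", "BP10", "MH26"])
def builtin_grid(request):
    return grid_from_label(request.param)
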