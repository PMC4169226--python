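import numpy as np
import pytest

from masweep import PhantomSpec, analyze_study, generate_phantom


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    """Rendered three-view study plus analytic truth (noiseless defaults)."""
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def default_result(default_phantom):
    """Full pipeline run on the default phantom, seeded at true pixels."""
    study, truth = default_phantom
    return analyze_study(study, truth.seeds())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_ncc(template: np.ndarray, search: np.ndarray) -> np.ndarray:
    """Naive Pearson-correlation scan over every full placement (oracle)."""
    th, tw = template.shape
    hh = search.shape[0] - th + 1
    ww = search.shape[1] - tw + 1
    out = np.full((hh, ww), -np.inf)
    t = template.ravel()
    for i in range(hh):
        for j in range(ww):
            w = search[i:i + th, j:j + tw].ravel()
            if w.std() == 0:
                continue
            out[i, j] = np.corrcoef(t, w)[0, 1]
    return out
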