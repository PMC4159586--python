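import numpy as np
import pytest

import scnmap as sm
from scnmap.pipeline import RunConfig, run_pipeline


def superpixel_truth(truth, factor: int = 2) -> np.ndarray:
    """Ground-truth region id per superpixel, flattened row-major."""
    h, w = truth.label_image.shape
    coarse = truth.label_image.reshape(
        h // factor, factor, w // factor, factor
    ).max(axis=(1, 3))
    return coarse.reshape(-1)


def preprocessed(stack):
    """Despike -> coarsen -> mask chain used throughout the tests."""
    clean = sm.despike(stack)
    series = sm.coarsen(clean)
    return sm.preprocess.apply_mask(series, sm.auto_mask(clean))


@pytest.fixture(scope="session")
def wt_movie():
    config = sm.preset("wt", seed=1)
    stack, truth = sm.generate_movie(config)
    return config, stack, truth


@pytest.fixture(scope="session")
def wt_series(wt_movie):
    _, stack, truth = wt_movie
    return preprocessed(stack), superpixel_truth(truth)


@pytest.fixture(scope="session")
def preset_runs():
    """Full-pipeline summaries for every preset at seeds 1-3.

    Computed once and shared: several tests assert different facets of
    the same runs (phenotype flags, clock-hand statistics, coherence,
    notch stability).
    """
    out = {}
    for name in sm.simulate.PRESET_NAMES:
        for seed in (1, 2, 3):
            stack, _ = sm.generate_movie(sm.preset(name, seed=seed))
            config = RunConfig(k_policy="fixed", k_fixed=5, top_n=5,
                               seed=seed)
            res = run_pipeline(config, stack=stack, write=False)
            out[(name, seed)] = res.summary
    return out
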