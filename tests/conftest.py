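"""Shared fixtures: phantom cases and the two end-to-end experiments.

The heavy objects are session-scoped so the cohort and the refinement /
recovery experiments are computed once and reused by unit, property and
acceptance tests alike.
"""

import numpy as np
import pytest

from papkit import phantom
from papkit.experiments import cohort_recovery, refinement_experiment
from papkit.volio import LabelMap, Volume


@pytest.fixture(scope="session")
def cohort200():
    """Measured 200-phantom cohort at the default 96³ / 1.5 mm grid."""
    return phantom.synth_cohort(200, seed=0)


@pytest.fixture(scope="session")
def recovery(cohort200):
    """CV parameter-recovery on the 200-phantom cohort (5 repeats)."""
    return cohort_recovery(n=200, seed=0, repeats=5, null_repeats=2,
                           cohort=cohort200)


@pytest.fixture(scope="session")
def refinement():
    """20-case degraded-mask refinement suite with a trained classifier."""
    return refinement_experiment(n_train=10, n_test=20, seed=1)


@pytest.fixture(scope="session")
def one_phantom():
    """One rendered phantom (volume, labels) at default settings."""
    hemo = phantom.synth_hemodynamics(1, seed=11)[0]
    geom = phantom.synth_geometry(hemo, seed=11)
    return phantom.render_phantom(geom, seed=11)


def make_ball_case(radius_vox: int = 8, size: int = 32, blur: float = 1.0,
                   inside: float = 350.0, outside: float = 40.0):
    """Tiny synthetic (Volume, truth mask): a blurred bright ball."""
    ax = np.arange(size) - size / 2 + 0.5
    r2 = (ax[:, None, None] ** 2 + ax[None, :, None] ** 2
          + ax[None, None, :] ** 2)
    mask = r2 <= radius_vox ** 2
    img = np.where(mask, inside, outside).astype(float)
    if blur > 0:
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, blur)
    return Volume(data=img), mask


def make_label_map(mask: np.ndarray, code: int,
                   spacing=(1.0, 1.0, 1.0)) -> LabelMap:
    """Wrap one binary mask as a label map with the given code."""
    data = np.zeros(mask.shape, dtype=np.int16)
    data[mask] = code
    return LabelMap(data=data, spacing=spacing)
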