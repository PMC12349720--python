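import logging

import numpy as np
import pytest

from cectfidelity.core import Phase, PhaseImage, StudySet
from cectfidelity.phantom import CohortConfig, PhantomSpec, render_phantom, simulate_cohort
from cectfidelity.pipeline import extract_cohort_features

logging.getLogger("cectfidelity").setLevel(logging.ERROR)


def make_image(pixels, phase=Phase.NEPHROGRAPHIC, spacing=1.0, **kw) -> PhaseImage:
    return PhaseImage(pixels=np.asarray(pixels, dtype=float), phase=phase,
                      pixel_spacing=spacing, **kw)


def make_study(values_by_phase, roi=None, spacing=1.0, **kw) -> StudySet:
    """Four uniform (or array-valued) phases sharing one grid."""
    images = {}
    for phase, v in values_by_phase.items():
        arr = np.asarray(v, dtype=float)
        if arr.ndim == 0:
            arr = np.full((16, 16), float(v))
        images[Phase(phase)] = make_image(arr, Phase(phase), spacing)
    shape = next(iter(images.values())).shape
    if roi is None:
        roi = np.zeros(shape, bool)
        roi[4:12, 4:12] = True
    return StudySet(images=images, tumor_roi=roi, **kw)


@pytest.fixture(scope="session")
def base_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def base_study(base_spec) -> StudySet:
    """Noiseless homogeneous solid phantom, phase curve (30, 80, 110, 90)."""
    return render_phantom(base_spec, seed=7)


@pytest.fixture(scope="session")
def identity_cohort():
    """37-study cohort whose surrogates are pixel-identical to GT."""
    return simulate_cohort(37, CohortConfig.zero_degradation(), seed=11)


@pytest.fixture(scope="session")
def identity_features(identity_cohort):
    pairs, _ = identity_cohort
    return extract_cohort_features(pairs)
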