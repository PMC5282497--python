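import warnings

import numpy as np
import pytest

from spermtopo import SyntheticSpec, make_nucleus
from spermtopo.pipeline import RunConfig, analyze_cohort
from spermtopo.types import NucleusModel


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def treated_nucleus(default_spec):
    """Noise-free treated nucleus (image + analytic model)."""
    spec = SyntheticSpec(noise_sd=0.0)
    return make_nucleus(spec, treated=True)


@pytest.fixture(scope="session")
def sphere_nucleus():
    """Analytic sphere mask of radius 3 um at 0.1 um isotropic voxels."""
    h = 0.1
    n = int(2 * (3.0 + 0.4) / h) + 1  # odd: sphere centre on a voxel centre
    c = (np.arange(n) + 0.5) * h - n * h / 2
    Z, Y, X = np.meshgrid(c, c, c, indexing="ij")
    mask = X**2 + Y**2 + Z**2 <= 9.0
    center = n * h / 2
    return NucleusModel(
        mask=mask,
        voxel_size=(h, h, h),
        tail_point=np.array([center - 3.0, center, center]),
        head_point=np.array([center + 3.0, center, center]),
        length_L=6.0,
        widest_diameter_D=6.0,
        volume=4 / 3 * np.pi * 27,
    )


@pytest.fixture(scope="session")
def cohort_result(default_spec):
    """Full streaming 10 x 30 cohort analysis, shared by the slow checks.

    This is the study-sized synthetic cohort (300 cells, all channels) run
    through the complete image -> segmentation -> distance transform ->
    assignment -> cluster -> statistics chain.
    """
    cfg = RunConfig(
        spec=default_spec,
        null_kind="both",
        mc_null_points=50_000,
        compare_2d=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_cohort(cfg)
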