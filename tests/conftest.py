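"""Shared fixtures: small synthetic cohorts and hand-constructed models.

The constructed models have analytically designed filters (a darkness
detector and a center-surround contrast detector in layer 1, identity
pass-throughs above) so that traceback and statistics tests can reason
about what a filter responds to without training anything.
"""

from __future__ import annotations

import numpy as np
import pytest

from enteronet import presets
from enteronet.probes import blank_image_with_blob, make_probe_model  # noqa: F401
from enteronet.synthgen import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """2 cases/class x 2 images of 120x160 pixels; fast to generate."""
    spec = SyntheticCohortSpec(
        n_cases_per_class=2,
        images_per_case=2,
        image_height=120,
        image_width=160,
        seed=42,
    )
    out = tmp_path_factory.mktemp("small_cohort")
    return generate_cohort(spec, out)


@pytest.fixture(scope="session")
def desk_cohort(tmp_path_factory):
    """The desk-scale study cohort: 30 cases, 5 images each, 200x200."""
    out = tmp_path_factory.mktemp("desk_cohort")
    return generate_cohort(presets.desk_scale_cohort_spec(seed=7), out)


@pytest.fixture(scope="session")
def probe_model():
    return make_probe_model(input_size=200)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
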