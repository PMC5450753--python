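"""Shared fixtures: a small but fully realistic forward-model context.

Session-scoped so the lead field is computed once; tests must not mutate
these objects.
"""

import numpy as np
import pytest

from denserp.headmodel import (DEFAULT_CONDUCTIVITIES, DEFAULT_RADII_MM,
                               build_head_model, build_regularizer,
                               build_source_space, compute_lead_field,
                               place_sensors)


@pytest.fixture(scope="session")
def head():
    return build_head_model(DEFAULT_RADII_MM, DEFAULT_CONDUCTIVITIES)


@pytest.fixture(scope="session")
def sensors(head):
    return place_sensors(64, head.scalp_radius, 0.75)


@pytest.fixture(scope="session")
def src(head):
    # coarse grid keeps the session fast; geometry contracts are identical
    return build_source_space(head, spacing=14.0, margin=7.0)


@pytest.fixture(scope="session")
def lead_field(head, src, sensors):
    return compute_lead_field(head, src, sensors, series_terms=60)


@pytest.fixture(scope="session")
def regularizer(lead_field, src):
    return build_regularizer(lead_field, src)


@pytest.fixture(scope="session")
def sensors128(head):
    return place_sensors(128, head.scalp_radius, 0.75)
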