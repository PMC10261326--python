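"""Shared fixtures: the default synthetic study and a small fast one
(generated once per session; several suites reuse them)."""

from __future__ import annotations

import pytest

from cfrlp.report import run_study
from cfrlp.synthetic import SyntheticSpec, make_study


@pytest.fixture(scope="session")
def default_study():
    """Default synthetic study: 9 target groups x 95 children, seed 0."""
    return make_study(SyntheticSpec())


@pytest.fixture(scope="session")
def default_report(default_study):
    """Full pipeline run on the default study (shared across suites)."""
    s = default_study
    return run_study(s.composition, s.recalls, s.config, seed=0)


@pytest.fixture(scope="session")
def small_study():
    """Small, fast study: one livelihood, 20 children per band."""
    spec = SyntheticSpec(seed=11, n_children=20, livelihoods=("settled",))
    return make_study(spec)
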