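"""Shared fixtures.

The expensive model families are session-scoped so the acceptance tests
that need them (family selection, modulation sweeps) build them once.
All sizes here are the reduced-scale defaults (n = 30 members) so the
whole suite stays desk-scale; the full-scale runs go through the CLI.
"""

from __future__ import annotations

import numpy as np
import pytest

from modvar import family as fam
from modvar.lp_model import LPParameters


@pytest.fixture(scope="session")
def rebound_family():
    """Rebound-selected LP family, n=30, fixed seed."""
    res = fam.build_family(
        fam.rebound_prior(), kind="rebound", n_target=30, budget=250, seed=1
    )
    assert len(res.members) >= 30, "rebound family shortfall"
    return res


@pytest.fixture(scope="session")
def rebound_sweep(rebound_family):
    """Fixed-increment modulation sweep of the rebound family."""
    per_member, per_level = fam.modulation_variability_sweep(
        rebound_family.members, kind="rebound",
        levels=(0.0, 0.01, 0.025, 0.05, 0.1), mode="fixed", seed=7,
    )
    return per_member, per_level


@pytest.fixture(scope="session")
def fi_family():
    """f–I-selected LP family, n=30, fixed seed."""
    res = fam.build_family(
        fam.fi_prior(), kind="fi", n_target=30, budget=200, seed=2,
        block_check_delta=0.1,
    )
    assert len(res.members) >= 30, "f-I family shortfall"
    return res


@pytest.fixture
def reference_params():
    return LPParameters()
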