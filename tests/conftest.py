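"""Shared fixtures.

The expensive full-resolution runs (401 radial nodes, dt = 1e-3) are
session-scoped and shared: the default parameter sweep covers every
combination the individual tests need, so each combination is simulated
exactly once per session.
"""

from __future__ import annotations

import pytest

from kroghsim.driver import Numerics, SweepSpec, run_sweep

#: The default sweep grid: growth rate x vascularization x vessel radius.
SWEEP_ALPHAS = (0.0, 0.3, 0.7)
SWEEP_BVFS = (0.01, 0.05)
SWEEP_RBS = (0.05, 0.102)


@pytest.fixture(scope="session")
def default_sweep():
    """Summary table and full results of the default parameter sweep."""
    spec = SweepSpec(alphas=SWEEP_ALPHAS, bvfs=SWEEP_BVFS, rb_over_Ls=SWEEP_RBS,
                     numerics=Numerics())
    summary, results = run_sweep(spec)
    assert (summary["status"] == "ok").all()
    return summary, results


@pytest.fixture(scope="session")
def headline_result(default_sweep):
    """Full-resolution run at alpha = 0.3, BVF = 0.01, rb/L = 0.102."""
    _, results = default_sweep
    return results[(0.3, 0.01, 0.102)]


@pytest.fixture(scope="session")
def no_growth_result(default_sweep):
    """Same geometry as the headline run but with proliferation switched off."""
    _, results = default_sweep
    return results[(0.0, 0.01, 0.102)]
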