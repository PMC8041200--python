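import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import chemosurf as cs

settings.register_profile(
    "package",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def fig2():
    return cs.load_scenario("fig2_arbacia")


@pytest.fixture(scope="session")
def fig2_src(fig2):
    return fig2.source()


@pytest.fixture(scope="session")
def fig2_params(fig2):
    return fig2.chemotaxis()


@pytest.fixture(scope="session")
def fig2_field_01(fig2_src):
    """Tabulated chemoattractant field of the sea-urchin scenario at
    alpha = 0.1 1/s (shared across tests; ~10 s to build)."""
    flow = cs.ShearFlow(alpha=0.1)
    return cs.tabulate_field(fig2_src, flow, fig2_src.t_release)


@pytest.fixture(scope="session")
def fig2_sweep(fig2):
    """Scaled-down Monte-Carlo sweep of the sea-urchin scenario over eight
    shear rates (the optimal-shear-rate study; several minutes)."""
    cfg = fig2.domain(n_sperm=20000, seed=42)
    tab = cs.sweep_alpha(
        cfg,
        [0.0, 0.03, 0.06, 0.1, 0.15, 0.2, 0.45, 0.9],
        fig2.chemotaxis(),
        src=fig2.source(),
        sphere=fig2.sphere(),
    )
    return tab


@pytest.fixture(scope="session")
def corotation_toggle(fig2, fig2_field_01):
    """Encounter statistics at alpha = 0.1 with and without co-rotation,
    identical seeds and ensemble size."""
    flow = cs.ShearFlow(alpha=0.1)
    out = {}
    for coro in (True, False):
        params = cs.ChemotaxisParams(
            v_h=fig2.values["chemotaxis.v_h"],
            v_phi=fig2.values["chemotaxis.v_phi"],
            c_b=fig2.values["chemotaxis.c_b"],
            r0=fig2.values["chemotaxis.r0"],
            g=fig2.values["chemotaxis.g"],
            chemotaxis_on=True,
            corotation_on=coro,
        )
        cfg = fig2.domain(n_sperm=20000, seed=7)
        out[coro] = cs.run_ensemble(
            cfg, flow, fig2.sphere(), fig2_field_01, params,
            rng=np.random.default_rng(7),
        )
    return out
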