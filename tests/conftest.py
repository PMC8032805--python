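import numpy as np
import pytest

from saxsmw import ParticleModel, fit_form_factor
from saxsmw.simulate import TWO_PHASE_SYSTEMS, simulate_system


@pytest.fixture(scope="session")
def ps_h2o_curve():
    """Polystyrene-in-water hard-sphere suspension: R = 90 A spheres,
    Gaussian sigma/mean = 0.05, PY structure factor at phi = 0.2."""
    return simulate_system(TWO_PHASE_SYSTEMS["ps_h2o"])


@pytest.fixture(scope="session")
def ps_h2o_fit(ps_h2o_curve):
    """Sphere + Schulz-Zimm fit of the PS/H2O curve above the interaction
    region (q > 0.05 1/A)."""
    return fit_form_factor(ps_h2o_curve, "sphere", q_lo=0.05)


@pytest.fixture(scope="session")
def ps_h2o_spheroid_misfit(ps_h2o_curve):
    """Deliberately wrong family: monodisperse spheroid forced on sphere data."""
    return fit_form_factor(
        ps_h2o_curve, "spheroid", q_lo=0.05,
        init=ParticleModel("spheroid", 90.0, axis_ratio=1.05),
        vary_pd=False, vary_axis_ratio=False,
    )
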