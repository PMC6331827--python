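import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("repro", derandomize=True, deadline=None)
hypothesis_settings.load_profile("repro")

from cpc_photokin.config import DEFAULT_CONFIG, build_field, build_reactor_spec, merge_config
from cpc_photokin.kinetics import KineticParameters, fit_lh_linearized
from cpc_photokin.optics import SlurryState, aeroxide_p25, derive_sfm
from cpc_photokin.radiation import vrpa_per_length, vrpa_total


@pytest.fixture(scope="session")
def p25():
    return aeroxide_p25()


@pytest.fixture(scope="session")
def slurry06(p25):
    """0.6 g/L slurry across the 33 mm tube diameter."""
    return SlurryState(props=p25, c_cat=0.6, delta=0.033)


@pytest.fixture(scope="session")
def sfm06(slurry06):
    return derive_sfm(slurry06)


@pytest.fixture(scope="session")
def paper_cfg():
    return merge_config({})


@pytest.fixture(scope="session")
def paper_setup(paper_cfg):
    """Full paper-mode reactor: spec + VRPA-calibrated field (4.86 W)."""
    from dataclasses import replace

    spec = build_reactor_spec(paper_cfg)
    field, geometry = build_field(paper_cfg)
    return replace(spec, geometry=geometry), field


@pytest.fixture(scope="session")
def coarse_cfg():
    return merge_config({"simulation": {"n_r": 20, "n_theta": 24, "n_subreactors": 25}})


@pytest.fixture(scope="session")
def coarse_setup(coarse_cfg):
    """Coarse-grid reactor for Monte-Carlo work (converged to ~0.1%)."""
    from dataclasses import replace

    spec = build_reactor_spec(coarse_cfg)
    field, geometry = build_field(coarse_cfg)
    return replace(spec, geometry=geometry), field


@pytest.fixture(scope="session")
def params_paper(paper_setup):
    """Kinetic constants from the published regression slope/intercept."""
    spec, field = paper_setup
    vrpa = vrpa_total(vrpa_per_length(field), spec.geometry.total_length)
    fit = fit_lh_linearized(
        [(100.0, 1.0 / (25773.0 + 348947.0 / 100.0)),
         (400.0, 1.0 / (25773.0 + 348947.0 / 400.0))],
        vrpa=vrpa,
    )
    return fit.params


@pytest.fixture(scope="session")
def kt_calibrated(coarse_setup, params_paper):
    """Lumped k_T calibrated so the forward model reproduces the observed
    31.1% mineralisation at 213.6 ppm / 42 min."""
    from cpc_photokin.workbench import calibrate_kt_to_removal

    spec, field = coarse_setup
    return calibrate_kt_to_removal(
        spec, field, params_paper.k_r, 0.311, 213.6, 42.0
    )


@pytest.fixture(scope="session")
def zero_field(paper_setup):
    """A zero LVRPA field (dark reactor) on the default grid."""
    spec, field = paper_setup
    return field.copy_with(np.zeros_like(field.values))
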