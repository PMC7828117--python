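import numpy as np
import pytest

from nanomsc_pkpd.params import paper_2021

#: published PD truth used across estimation tests (Table-2-style vector in
#: the package's internal naming)
PD_TRUTH = dict(
    Kg0_CTR=0.00339, Kg0_PTX=0.00372, Kg0_PTXNP=0.00417, Kg0_MSC=0.00588,
    TVBL_CTR=0.360, TVBL_PTX=0.376, TVBL_PTXNP=0.539, TVBL_MSC=0.227,
    Kmax_PTX=0.00343, Kmax_NP=0.000427, K_MSC=4.35e-6, eta_TVBL=0.964,
    eps_CTR=0.493, eps_PTXsol=0.668, eps_PTXNP=0.624, eps_nanoMSC=0.622,
)


@pytest.fixture(scope="session")
def params():
    """Canonical published parameter set, static tumor geometry."""
    return paper_2021()


@pytest.fixture(scope="session")
def params_dyn():
    """Canonical published parameter set with dynamic tumor geometry."""
    return paper_2021(dynamic_geometry=True)


@pytest.fixture(scope="session")
def pd_truth():
    return dict(PD_TRUTH)


@pytest.fixture(scope="session")
def pk_study(params):
    from nanomsc_pkpd.synthetic import generate_pk_study
    return generate_pk_study(params, seed=1)


@pytest.fixture(scope="session")
def pd_study(params_dyn):
    """One four-arm efficacy study at the default design (8 animals/arm),
    with its latent trajectories."""
    from nanomsc_pkpd.synthetic import generate_pd_study
    return generate_pd_study(params_dyn, seed=3)


@pytest.fixture(autouse=True)
def _quiet_numeric_warnings():
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        yield
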