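import numpy as np
import pytest

from rcdkit.demography import DemographicModel


@pytest.fixture
def nm_model():
    """A deep-split no-migration scenario at the scale of the study system."""
    return DemographicModel(
        "NM", t_sp=5e5, t_reg_c=1.25e5, t_reg_f=2.5e5,
        n_now=1e6, n_anc=1e5, m_intra=0.01,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
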