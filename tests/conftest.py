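import pytest

from ciliaflow import FlowParameters


@pytest.fixture
def table_params():
    """Parameter set of the published velocity/stream-function tables."""
    return FlowParameters(zeta=0.01, alpha=0.2, eps=0.15, delta=0.01, F=0.1)


@pytest.fixture
def thermal_params():
    """Parameter set of the published concentration/temperature profiles."""
    return FlowParameters(zeta=0.01, alpha=1.0, eps=0.2, delta=0.1, F=0.5,
                          Pr=2.0, Nb=0.8, Nt=1.0, Ec=1.0)


# small, varied catalogue for parametrised property checks; all sets keep the
# required wall shear inside the pseudoplastic branch fold |psi_yy| < 1/sqrt(3*zeta)
PRESETS = [
    dict(zeta=0.0, eps=0.15, alpha=0.2, delta=0.01, F=0.1),
    dict(zeta=0.01, eps=0.15, alpha=0.2, delta=0.01, F=0.1),
    dict(zeta=0.01, eps=0.2, alpha=1.0, delta=0.05, F=0.2),
    dict(zeta=0.005, eps=0.1, alpha=0.5, delta=0.1, F=-0.3),
    dict(zeta=0.01, eps=0.05, alpha=0.8, delta=0.1, F=-0.2),
]
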