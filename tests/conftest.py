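import pytest

from leafphong import PhongParameters, eval_bridf
from leafphong.preprocess import design_grid


@pytest.fixture
def table2_surface() -> PhongParameters:
    """The directional-sweep benchmark surface: d=0.2, s=0.04, g=0.6."""
    return PhongParameters(0.2, 0.04, 0.6)


@pytest.fixture
def leafy_surface() -> PhongParameters:
    """A surface with the benchmark 0.3 specular proportion."""
    return PhongParameters(0.14, 0.06, 0.6)


def make_curve(params: PhongParameters, theta_i: float, wavelength: float = 630.0):
    """Analytic URIDF on the instrument design grid for one incidence angle."""
    return eval_bridf(params, theta_i, design_grid(theta_i), wavelength)


@pytest.fixture
def curve_factory():
    return make_curve
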