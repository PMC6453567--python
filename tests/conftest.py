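import numpy as np
import pytest
from dataclasses import replace

from biofilm_mech import LayerStack


@pytest.fixture
def trilayer():
    """Reference trilayer: G_r = 0.1 G_f, h_r = 0.3 h_f, normalised units."""
    return LayerStack.from_ratios(1.0, gr_over_gf=0.1, hr_over_hf=0.3)


@pytest.fixture
def bilayer_template():
    """Template whose residual layer is identical to the substrate."""
    t = LayerStack.from_ratios(1.0, gr_over_gf=1.0, hr_over_hf=0.3)
    return replace(t, residual=replace(t.residual, G=t.substrate.G))


def make_bilayer(gf_over_gs: float, hf: float = 1.0) -> LayerStack:
    t = LayerStack.from_ratios(gf_over_gs, gr_over_gf=1.0, hr_over_hf=0.3, hf=hf)
    return replace(t, residual=replace(t.residual, G=t.substrate.G))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
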