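import numpy as np
import pytest

from idrscope import cgsim


@pytest.fixture(scope="session")
def neutral_params():
    """HPS parameter set with all stickiness switched off (athermal chain)."""
    p = cgsim.HPSParameterSet.default()
    p.lam = {k: 0.0 for k in p.lam}
    return p


@pytest.fixture(scope="session")
def default_params():
    return cgsim.HPSParameterSet.default()


def neutral_homopolymer(n, aa="G"):
    """Uncharged homopolymer topology of n beads."""
    top = cgsim.build_topology(
        cgsim.FRETConstruct(aa * n, 0, n - 1), with_dyes=False)
    top.bead_charges[:] = 0.0
    return top


@pytest.fixture(scope="session")
def gauss_frames():
    """Shared Gaussian-chain ensemble (1e4 frames, 60 beads, b=0.38 nm)."""
    from idrscope import synthdata

    frames, truth = synthdata.gen_gaussian_chain(10_000, 60, seed=1234)
    return frames, truth
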