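import numpy as np
import pytest

from quadbind import (
    MeltDesign,
    TitrationDesign,
    gen_melt,
    gen_titration,
    statistical_from_micro,
)


@pytest.fixture()
def noiseless_titration():
    """One noiseless statistical-2:1 titration plus its generating truth."""
    design = TitrationDesign(noise_sd=0.0, n_replicates=1)
    series, truth = gen_titration(design)
    return series[0], truth


@pytest.fixture()
def noisy_titration():
    design = TitrationDesign(noise_sd=0.002, seed=11, n_replicates=1)
    series, truth = gen_titration(design)
    return series[0], truth


@pytest.fixture()
def noiseless_melt():
    design = MeltDesign(Tm=40.0, width=3.0, s=1.0, noise_sd=0.0)
    return gen_melt(design), design


def bisection_oracle(r_tot, l_tot, k1, k2, iters=200):
    """Independent interval bisection on the monotone ligand mass balance."""

    def h(p):
        denom = 1.0 + k1 * p + k1 * k2 * p * p
        return p + r_tot * (k1 * p + 2.0 * k1 * k2 * p * p) / denom - l_tot

    lo, hi = 0.0, l_tot
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if h(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
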