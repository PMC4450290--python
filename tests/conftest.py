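import numpy as np
import pytest

import asymseg as a


@pytest.fixture(scope="session")
def noisefree_phantom():
    """Default 64-cubed phantom, no noise, no bias: the clean study condition."""
    spec = a.PhantomSpec(seed=1)
    vol, lab = a.generate_phantom(spec)
    return spec, vol, lab


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom at 5% Rician noise."""
    spec = a.PhantomSpec(seed=7, noise_sigma=0.05)
    vol, lab = a.generate_phantom(spec)
    return spec, vol, lab


@pytest.fixture(scope="session")
def noisy_pipeline_result(noisy_phantom):
    """Full pipeline run on the 5%-noise phantom, shared across tests."""
    _, vol, lab = noisy_phantom
    res = a.run_pipeline(vol, a.PipelineConfig(seed=11), truth=lab)
    return vol, lab, res


def asym_cdf(z, params):
    """Closed-form mixture CDF of asymmetric Gaussians (test oracle).

    Left lobe mass r/(1+r) is half-normal with scale rσ; right lobe mass
    1/(1+r) is half-normal with scale σ.
    """
    from scipy.stats import norm
    z = np.asarray(z, dtype=float)
    out = np.zeros_like(z)
    for p in params:
        left = 2.0 * norm.cdf((z - p.mean) / (p.ratio * p.sigma_first))
        right = 2.0 * norm.cdf((z - p.mean) / p.sigma_first) - 1.0
        fi = np.where(z <= p.mean,
                      (p.ratio / (1 + p.ratio)) * left,
                      p.ratio / (1 + p.ratio) + right / (1 + p.ratio))
        out += p.weight * fi
    return out
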