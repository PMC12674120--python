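"""Truncated normal on [0, ∞): the surrogate posterior family.

Reparameterized sampling goes through the inverse-CDF transform of a uniform,
so samples are differentiable in (μ, σ). Moments are evaluated in closed form
with ``log_ndtr`` for stability at extreme μ/σ.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

from . import autodiff as ad

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
_TINY = 1e-12


def sample_core(mu, sigma, u):
    """Inverse-CDF reparameterized draw; ``u`` ~ U(0,1) is a constant array.

    F = μ + σ·Φ⁻¹(Φ(−μ/σ) + u·(1 − Φ(−μ/σ))), clipped away from the
    endpoints so Φ⁻¹ stays finite.
    """
    alpha = -mu / sigma
    t = ad.ndtr(alpha)
    p = t + u * (1.0 - t)
    p = ad.clip(p, _TINY, 1.0 - _TINY)
    return mu + sigma * ad.ndtri(p)


def logpdf_core(x, mu, sigma):
    """log q(x) for x ≥ 0; normalizer is log Φ(μ/σ), evaluated stably."""
    z = (x - mu) / sigma
    return (-0.5 * ad.square(z) - ad.log(sigma) - _LOG_SQRT_2PI
            - ad.log_ndtr(mu / sigma))


def moments(mu, sigma):
    """Mean and SD of TruncNormal(μ, σ; [0, ∞)), vectorized and stable.

    Uses the hazard ratio λ = φ(α)/(1−Φ(α)) with α = −μ/σ, computed in log
    space so both deep-in-support (μ ≫ σ) and far-out (μ ≪ −σ) regimes work.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    alpha = -mu / sigma
    lam = np.exp(-0.5 * alpha ** 2 - _LOG_SQRT_2PI - _sp.log_ndtr(mu / sigma))
    mean = mu + sigma * lam
    var = sigma ** 2 * (1.0 + alpha * lam - lam ** 2)
    sd = np.sqrt(np.maximum(var, _TINY ** 2))
    return mean, sd
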