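"""Wilson, folded-normal and Rice log-densities and samplers.

These are the structure-factor amplitude laws of the double-Wilson model. A
crystal's structure factor F_h is a sum of many atomic phasors, so by the
central limit theorem its components are Gaussian: amplitudes of acentric
reflections follow a Rayleigh-type (Wilson) law with E[F²] = ε, centric ones a
half-normal law. When two datasets are related — the same protein with a
ligand bound, a later time point, a Bijvoet mate — corresponding real (and
imaginary) components are correlated with coefficient r, and the amplitude of
the child reflection conditional on its parent follows a Rice distribution
(acentric) or a folded normal (centric). All densities are evaluated in log
space; the Rice density uses an exponentially scaled Bessel I₀ so that large
ν·x/σ² cannot overflow.

The ``*_core`` functions carry no validation and accept either NumPy arrays or
:class:`dwmerge.autodiff.Tensor` values, so the exact same expressions serve
the public API and the differentiable variational objective.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad

__all__ = [
    "wilson_logpdf", "folded_normal_logpdf", "rice_logpdf",
    "conditional_prior_logpdf", "sample_wilson", "sample_double_wilson",
    "conditional_scale_centric", "conditional_scale_acentric",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# cores (array-or-Tensor, no validation)
# ---------------------------------------------------------------------------

def normal_logpdf_core(x, mu, sigma):
    z = (x - mu) / sigma
    return -0.5 * ad.square(z) - ad.log(sigma) - _LOG_SQRT_2PI


def wilson_centric_core(F, epsilon):
    # half-normal with variance ε: √(2/(πε))·exp(−F²/(2ε))
    return 0.5 * (np.log(2.0 / np.pi) - ad.log(epsilon)) - ad.square(F) / (2.0 * epsilon)


def wilson_acentric_core(F, epsilon):
    # Rayleigh with E[F²] = ε: (2F/ε)·exp(−F²/ε)
    return np.log(2.0) + ad.log(F) - ad.log(epsilon) - ad.square(F) / epsilon


def folded_normal_core(x, mu, sigma):
    return ad.logaddexp(normal_logpdf_core(x, mu, sigma),
                        normal_logpdf_core(x, -mu, sigma))


def rice_core(x, nu, sigma):
    s2 = ad.square(sigma)
    return (ad.log(x) - ad.log(s2)
            - (ad.square(x) + ad.square(nu)) / (2.0 * s2)
            + ad.log_i0(x * nu / s2))


def conditional_scale_centric(r, epsilon):
    """σ of the centric (folded-normal) conditional prior: √(ε(1−r²))."""
    return ad.sqrt(epsilon * (1.0 - ad.square(r)))


def conditional_scale_acentric(r, epsilon):
    """σ of the acentric (Rice) conditional prior: √(ε(1−r²)/2)."""
    return ad.sqrt(epsilon * (1.0 - ad.square(r)) / 2.0)


# ---------------------------------------------------------------------------
# public API (NumPy in, NumPy out, validated)
# ---------------------------------------------------------------------------

def _check_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0):
        raise ValueError(f"{name} must be > 0")
    return arr


def wilson_logpdf(F, epsilon, centric):
    """Log-density of the univariate Wilson prior.

    Parameters
    ----------
    F : array-like, amplitudes (≥ 0; > 0 required for acentrics)
    epsilon : array-like, symmetry multiplicity ε ≥ 1
    centric : bool array-like
    """
    F = np.asarray(F, dtype=float)
    epsilon = _check_positive("epsilon", epsilon)
    centric = np.asarray(centric, dtype=bool)
    if np.any(F < 0):
        raise ValueError("amplitude F must be >= 0")
    F, epsilon, centric = np.broadcast_arrays(F, epsilon, centric)
    out = np.empty(F.shape, dtype=float)
    c = centric
    if c.any():
        out[c] = wilson_centric_core(F[c], epsilon[c])
    if (~c).any():
        with np.errstate(divide="ignore"):
            out[~c] = wilson_acentric_core(F[~c], epsilon[~c])
    return out if out.ndim else float(out)


def folded_normal_logpdf(x, mu, sigma):
    """Log-density of FoldedNormal(x | μ, σ) = N(x|μ,σ) + N(x|−μ,σ), x ≥ 0."""
    x = np.asarray(x, dtype=float)
    sigma = _check_positive("sigma", sigma)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    res = folded_normal_core(x, np.asarray(mu, dtype=float), sigma)
    return res if np.ndim(res) else float(res)


def rice_logpdf(x, nu, sigma):
    """Log-density of Rice(x | ν, σ) = (x/σ²)·exp(−(x²+ν²)/(2σ²))·I₀(xν/σ²)."""
    x = np.asarray(x, dtype=float)
    sigma = _check_positive("sigma", sigma)
    nu = np.asarray(nu, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be > 0")
    if np.any(nu < 0):
        raise ValueError("nu must be >= 0")
    res = rice_core(x, nu, sigma)
    return res if np.ndim(res) else float(res)


def conditional_prior_logpdf(F, F_parent, r, epsilon, centric):
    """Log-density of the child amplitude given its parent amplitude.

    Centric reflections: FoldedNormal(F | r·F_parent, √(ε(1−r²)));
    acentric: Rice(F | r·F_parent, √(ε(1−r²)/2)). At r = 0 (or F_parent = 0,
    the systematically-absent-parent convention) both reduce exactly to the
    univariate Wilson law.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr >= 1):
        raise ValueError("r must lie in [0, 1)")
    F = np.asarray(F, dtype=float)
    F_parent = np.asarray(F_parent, dtype=float)
    if np.any(F_parent < 0):
        raise ValueError("F_parent must be >= 0")
    epsilon = _check_positive("epsilon", epsilon)
    centric = np.asarray(centric, dtype=bool)
    F, F_parent, r_arr, epsilon, centric = np.broadcast_arrays(
        F, F_parent, r_arr, epsilon, centric)
    out = np.empty(F.shape, dtype=float)
    c = centric
    if c.any():
        out[c] = folded_normal_core(
            F[c], r_arr[c] * F_parent[c],
            conditional_scale_centric(r_arr[c], epsilon[c]))
    if (~c).any():
        a = ~c
        with np.errstate(divide="ignore"):
            out[a] = rice_core(
                F[a], r_arr[a] * F_parent[a],
                conditional_scale_acentric(r_arr[a], epsilon[a]))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _components(n, epsilon, centric, rng):
    """Draw the real/imaginary Gaussian components of a Wilson-law F."""
    epsilon = np.broadcast_to(np.asarray(epsilon, dtype=float), (n,))
    if centric:
        A = rng.normal(0.0, np.sqrt(epsilon))
        B = np.zeros(n)
    else:
        A = rng.normal(0.0, np.sqrt(epsilon / 2.0))
        B = rng.normal(0.0, np.sqrt(epsilon / 2.0))
    return A, B


def sample_wilson(n, epsilon, centric, seed=None):
    """Draw ``n`` amplitudes from the univariate Wilson distribution."""
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = _rng(seed)
    A, B = _components(n, epsilon, bool(centric), rng)
    return np.hypot(A, B)


def sample_double_wilson(n, r, epsilon, centric, seed=None):
    """Draw ``n`` (parent, child) amplitude pairs from the double-Wilson model.

    Child components are r·parent + √(1−r²)·fresh noise of the same marginal
    variance, so the child marginal is exactly Wilson and the amplitude
    correlation obeys CC(F_parent, F_child) ≈ r².
    """
    if not (0.0 <= r < 1.0):
        raise ValueError("r must lie in [0, 1)")
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = _rng(seed)
    centric = bool(centric)
    A_p, B_p = _components(n, epsilon, centric, rng)
    A_f, B_f = _components(n, epsilon, centric, rng)
    t = np.sqrt(1.0 - r * r)
    A_c = r * A_p + t * A_f
    B_c = r * B_p + t * B_f
    return np.hypot(A_p, B_p), np.hypot(A_c, B_c)
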