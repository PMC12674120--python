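"""Density and sampler correctness for the Wilson / folded-normal / Rice laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special, stats

from dwmerge import priors

RNG = np.random.default_rng(2024)


# ---------------------------------------------------------------------------
# closed-form spot values
# ---------------------------------------------------------------------------

def test_wilson_logpdf_closed_form_values():
    # centric ε=1 at F=0: √(2/π); acentric ε=1 at F=1: 2e⁻¹
    assert priors.wilson_logpdf(0.0, 1, True) == pytest.approx(
        np.log(np.sqrt(2.0 / np.pi)), abs=1e-12)
    assert priors.wilson_logpdf(1.0, 1, False) == pytest.approx(
        np.log(2.0) - 1.0, abs=1e-12)


def test_folded_normal_at_origin_and_symmetry_in_mu():
    assert priors.folded_normal_logpdf(0.0, 0.0, 1.0) == pytest.approx(
        np.log(2.0 / np.sqrt(2.0 * np.pi)), abs=1e-12)
    x = RNG.uniform(0, 3, 20)
    mu = RNG.normal(0, 2, 20)
    sg = RNG.uniform(0.2, 2, 20)
    np.testing.assert_allclose(priors.folded_normal_logpdf(x, mu, sg),
                               priors.folded_normal_logpdf(x, -mu, sg),
                               rtol=0, atol=1e-12)


def test_rice_reduces_to_rayleigh_and_folded_to_halfnormal():
    x = np.linspace(0.05, 6.0, 40)
    np.testing.assert_allclose(
        priors.rice_logpdf(x, 0.0, 1.3),
        stats.rayleigh.logpdf(x, scale=1.3), atol=1e-12)
    np.testing.assert_allclose(
        priors.folded_normal_logpdf(x, 0.0, 0.7),
        stats.halfnorm.logpdf(x, scale=0.7), atol=1e-12)


def test_rice_matches_scipy_at_moderate_and_extreme_snr():
    # scipy.stats.rice is the independent reference implementation
    for nu, sg in [(1.0, 1.0), (3.0, 0.5), (50.0, 1.0)]:
        x = np.linspace(max(nu - 4, 0.01), nu + 4, 30)
        np.testing.assert_allclose(
            priors.rice_logpdf(x, nu, sg),
            stats.rice.logpdf(x, nu / sg, scale=sg), rtol=1e-10, atol=1e-10)


# ---------------------------------------------------------------------------
# normalization (quadrature oracle)
# ---------------------------------------------------------------------------

def _quad_mass(logpdf, upper):
    val, _ = integrate.quad(lambda x: np.exp(logpdf(x)), 1e-12, upper, limit=300)
    return val


@pytest.mark.parametrize("epsilon,centric", [(1, True), (1, False),
                                             (2, True), (4, False)])
def test_wilson_pdf_integrates_to_one(epsilon, centric):
    mass = _quad_mass(lambda F: priors.wilson_logpdf(F, epsilon, centric),
                      40.0 * np.sqrt(epsilon))
    assert mass == pytest.approx(1.0, abs=1e-8)


def test_folded_and_rice_pdfs_integrate_to_one_over_random_parameters():
    rng = np.random.default_rng(7)
    for _ in range(20):
        mu, sg = rng.normal(0, 3), rng.uniform(0.1, 2.5)
        mass = _quad_mass(lambda x: priors.folded_normal_logpdf(x, mu, sg),
                          abs(mu) + 12 * sg)
        assert mass == pytest.approx(1.0, abs=1e-8)
        nu, sg = rng.uniform(0, 5), rng.uniform(0.1, 2.0)
        mass = _quad_mass(lambda x: priors.rice_logpdf(x, nu, sg), nu + 14 * sg)
        assert mass == pytest.approx(1.0, abs=1e-8)
    # extreme ν/σ = 50: the log-scaled Bessel must not overflow
    mass = _quad_mass(lambda x: priors.rice_logpdf(x, 50.0, 1.0), 70.0)
    assert mass == pytest.approx(1.0, abs=1e-8)


# ---------------------------------------------------------------------------
# conditional prior
# ---------------------------------------------------------------------------

@given(st.floats(0.01, 5.0), st.floats(0.0, 4.0), st.booleans(),
       st.integers(1, 4))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_conditional_prior_reduces_to_wilson_at_r0_or_absent_parent(
        F, F_parent, centric, epsilon):
    assert priors.conditional_prior_logpdf(F, F_parent, 0.0, epsilon, centric) \
        == pytest.approx(priors.wilson_logpdf(F, epsilon, centric), abs=1e-12)
    # systematically-absent parent: evaluate the conditional at F_Pa = 0,
    # which is Wilson with the reduced effective multiplicity ε(1−r²)
    r = 0.9
    assert priors.conditional_prior_logpdf(F, 0.0, r, epsilon, centric) \
        == pytest.approx(
            priors.wilson_logpdf(F, epsilon * (1 - r * r), centric), abs=1e-12)


def test_conditional_prior_rejects_bad_r():
    with pytest.raises(ValueError):
        priors.conditional_prior_logpdf(1.0, 1.0, 1.0, 1, False)
    with pytest.raises(ValueError):
        priors.conditional_prior_logpdf(1.0, 1.0, -0.1, 1, False)


def test_conditional_mean_approaches_parent_as_r_to_one():
    # r = 0.99: Rice mean ≈ r·F_parent for F_parent well above σ
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 6, 400_000)  # importance-free MC via rejection-ish grid
    # direct sampling: Rice(ν, σ) = |ν + σ(Z1 + iZ2)|
    nu, sg = 0.99 * 1.3, np.sqrt((1 - 0.99 ** 2) / 2.0)
    z = nu + sg * (rng.standard_normal(1_000_000)
                   + 1j * rng.standard_normal(1_000_000))
    assert np.mean(np.abs(z)) == pytest.approx(1.3, abs=0.02)


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def test_sample_wilson_second_moment_and_determinism():
    for centric, tol in ((False, 0.005), (True, 0.01)):
        F = priors.sample_wilson(10 ** 6, 1, centric, seed=3)
        assert np.mean(F ** 2) == pytest.approx(1.0, abs=tol * 3)
    a = priors.sample_wilson(1000, 2, False, seed=9)
    b = priors.sample_wilson(1000, 2, False, seed=9)
    np.testing.assert_array_equal(a, b)


def _exact_amplitude_cc(r: float) -> float:
    """Closed-form Pearson CC of bivariate-Rayleigh amplitudes."""
    e = special.hyp2f1(-0.5, -0.5, 1.0, r * r)
    return (np.pi / 2.0 * e - np.pi / 2.0) / (2.0 - np.pi / 2.0)


@pytest.mark.parametrize("r", [0.0, 0.5, 0.85, 0.99])
def test_double_wilson_amplitude_correlation_matches_closed_form(r):
    Fp, Fc = priors.sample_double_wilson(10 ** 5, r, 1, False, seed=17)
    cc = np.corrcoef(Fp, Fc)[0, 1]
    assert cc == pytest.approx(_exact_amplitude_cc(r), abs=0.01)


def test_double_wilson_intensity_correlation_is_exactly_r_squared():
    r = 0.85
    Fp, Fc = priors.sample_double_wilson(4 * 10 ** 5, r, 1, False, seed=21)
    cc = np.corrcoef(Fp ** 2, Fc ** 2)[0, 1]
    assert cc == pytest.approx(r ** 2, abs=0.01)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("centric", [False, True])
def test_double_wilson_child_marginal_is_wilson(seed, centric):
    _, Fc = priors.sample_double_wilson(10 ** 5, 0.9, 1, centric, seed=seed)
    ref = priors.sample_wilson(10 ** 5, 1, centric, seed=seed + 100)
    assert stats.ks_2samp(Fc, ref).pvalue > 0.01
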