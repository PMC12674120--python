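"""Variational engine: likelihood contract, ELBO properties, training."""

import numpy as np
import pytest
from scipy import integrate, stats

from dwmerge.exceptions import ConfigError
from dwmerge.postmerge import merge_posterior
from dwmerge.refl_io import DatasetGraph
from dwmerge.scaling import MLPConfig
from dwmerge.simulate import SimulationConfig, simulate_dataset
from dwmerge.vi import (TrainingConfig, elbo_estimate, likelihood_logpdf,
                        optimize_r, train)

FAST_MLP = MLPConfig(n_layers=2, width=8)


def _small_sim(seed=0, **kw):
    base = dict(n_reflections=120, n_images=10, multiplicity=4,
                noise_floor=0.05, nodes=("only",), edges=(), seed=seed)
    base.update(kw)
    return simulate_dataset(SimulationConfig(**base))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_normal_likelihood_peak_and_normalization():
    sigI = 0.37
    peak = likelihood_logpdf(I=2.0, sigI=sigI, F=np.sqrt(2.0), Sigma=1.0)
    assert peak == pytest.approx(-np.log(np.sqrt(2 * np.pi) * sigI), abs=1e-12)
    mass, _ = integrate.quad(
        lambda I: np.exp(likelihood_logpdf(I, sigI, 1.3, 0.8)), -10, 10)
    assert mass == pytest.approx(1.0, abs=1e-8)


def test_student_t_likelihood_approaches_normal_at_large_dof():
    # agreement to 1e-4 holds in the bulk (|z| ≲ 4); tails differ as z⁴/(4·dof)
    I = np.linspace(-1, 3, 30)
    ll_t = likelihood_logpdf(I, 0.5, 1.0, 1.0, family="student-t", dof=1e6)
    ll_n = likelihood_logpdf(I, 0.5, 1.0, 1.0, family="normal")
    np.testing.assert_allclose(ll_t, ll_n, atol=1e-4)


def test_likelihood_rejects_bad_inputs():
    with pytest.raises(ValueError):
        likelihood_logpdf(1.0, 0.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        likelihood_logpdf(1.0, 1.0, 1.0, -1.0)
    with pytest.raises(ValueError):
        likelihood_logpdf(1.0, 1.0, 1.0, 1.0, family="cauchy")


# ---------------------------------------------------------------------------
# ELBO
# ---------------------------------------------------------------------------

def test_elbo_estimate_is_deterministic(toy_table, toy_graph):
    cfg = TrainingConfig(steps=5, seed=3, mlp=FAST_MLP)
    res = train(toy_table, toy_graph, cfg)
    a = elbo_estimate(res.posterior, res.scale_model, toy_table, toy_graph, cfg)
    b = elbo_estimate(res.posterior, res.scale_model, toy_table, toy_graph, cfg)
    assert a == b
    assert np.isfinite(a)


def test_flat_likelihood_elbo_matches_quadrature_kl():
    """With an uninformative observation the ELBO reduces to −KL(q‖prior),
    which 1-D quadrature can evaluate exactly."""
    import pandas as pd
    from dwmerge import priors, truncnorm
    from dwmerge.refl_io import ReflectionTable

    big_sig = 1e6
    df = pd.DataFrame([(1, 0, 0, "+", "a", 0, 0.0, big_sig, False, 1, 2.0)],
                      columns=["h", "k", "l", "friedel_sign", "dataset_id",
                               "image_id", "I", "sigI", "centric", "epsilon", "d"])
    t = ReflectionTable.from_frame(df)
    g = DatasetGraph(["a"], [])
    cfg = TrainingConfig(steps=1, seed=0, scale_mode="fixed", n_samples=4000)
    res = train(t, g, cfg)
    q = res.posterior
    elbo = elbo_estimate(q, None, t, g, cfg, n_samples=20000)
    const = -np.log(np.sqrt(2 * np.pi) * big_sig)  # flat-likelihood offset

    mu, sg = q.mu[0], q.sigma[0]

    def integrand(F):
        lq = truncnorm.logpdf_core(F, mu, sg)
        lp = priors.wilson_logpdf(F, 1, False)
        return np.exp(lq) * (lp - lq)

    kl_neg, _ = integrate.quad(integrand, 1e-9, mu + 12 * sg, limit=200)
    # Monte-Carlo SE of the estimate at S=20000 is well below 0.02
    assert elbo - const == pytest.approx(kl_neg, abs=0.02)


def test_training_is_reproducible_and_trace_finite(toy_table, toy_graph):
    cfg = TrainingConfig(steps=30, seed=11, mlp=FAST_MLP)
    res1 = train(toy_table, toy_graph, cfg)
    res2 = train(toy_table, toy_graph, cfg)
    np.testing.assert_allclose(res1.posterior.mu, res2.posterior.mu, atol=1e-6)
    assert np.all(np.isfinite(res1.trace))


def test_r_zero_dag_equals_independent_runs():
    table, graph, gt, _ = _small_sim(
        seed=4, nodes=("parent", "child"), edges=(("parent", "child", 0.9),),
        noise_floor=1e-3)
    cfg = TrainingConfig(steps=300, seed=0, scale_mode="fixed")
    g0 = graph.with_r(0.0)
    g_ind = DatasetGraph(list(graph.nodes), [])
    m0 = merge_posterior(train(table, g0, cfg).posterior)
    mi = merge_posterior(train(table, g_ind, cfg).posterior)
    j = m0.merge(mi, on=["dataset_id", "h", "k", "l", "friedel_sign"],
                 suffixes=("_dag", "_ind"))
    cc = stats.pearsonr(j["F_dag"], j["F_ind"]).statistic
    assert cc >= 0.999


def test_posterior_support_and_merge_positivity(toy_table, toy_graph):
    res = train(toy_table, toy_graph, TrainingConfig(steps=40, seed=2,
                                                     mlp=FAST_MLP))
    assert np.all(res.posterior.sigma > 0)
    merged = merge_posterior(res.posterior)
    assert np.all(merged["F"] >= 0)
    assert np.all(merged["sigF"] > 0)


def test_amplitude_recovery_on_low_noise_single_dataset():
    table, graph, gt, truth = _small_sim(seed=6)
    res = train(table, graph, TrainingConfig(steps=600, seed=0, mlp=FAST_MLP))
    merged = merge_posterior(res.posterior)
    j = merged.merge(gt.reflections.assign(F_true=gt.datasets["only"]["F"]),
                     on=["h", "k", "l"])
    assert stats.pearsonr(j["F"], j["F_true"]).statistic > 0.9


def test_optimize_r_recovers_and_rejects_spurious_correlation():
    table, graph, gt, _ = _small_sim(
        seed=1, n_reflections=250, multiplicity=4, noise_floor=0.2,
        nodes=("parent", "child"), edges=(("parent", "child", 0.99),),
        image_log_scale_sd=0.0, resolution_falloff=0.0, detector_gradient=0.0)
    cfg = TrainingConfig(steps=500, seed=0, scale_mode="fixed",
                         r_mode="optimized")
    r_hat = optimize_r(table, graph, cfg)[("parent", "child")]
    assert 0.9 <= r_hat < 1.0
    # simulate independent data but declare an edge to optimize
    t3, g3, _, _ = _small_sim(
        seed=3, n_reflections=250, multiplicity=4, noise_floor=0.2,
        nodes=("parent", "child"), edges=(),
        image_log_scale_sd=0.0, resolution_falloff=0.0, detector_gradient=0.0)
    from dwmerge.refl_io import GraphEdge
    g_declared = DatasetGraph(["parent", "child"],
                              [GraphEdge("parent", "child", 0.5)])
    r_ind = optimize_r(t3, g_declared, cfg)[("parent", "child")]
    assert r_ind <= 0.3


def test_multi_start_r_optimization_converges():
    table, _, _, _ = _small_sim(
        seed=5, n_reflections=250, multiplicity=4, noise_floor=0.2,
        nodes=("parent", "child"), edges=(("parent", "child", 0.9),),
        image_log_scale_sd=0.0, resolution_falloff=0.0, detector_gradient=0.0)
    from dwmerge.refl_io import GraphEdge
    cfg = TrainingConfig(steps=500, seed=0, scale_mode="fixed",
                         r_mode="optimized")
    outs = []
    for r0 in (0.5, 0.9):
        g = DatasetGraph(["parent", "child"],
                         [GraphEdge("parent", "child", r0)])
        outs.append(optimize_r(table, g, cfg)[("parent", "child")])
    assert abs(outs[0] - outs[1]) < 0.05


def test_config_validation():
    with pytest.raises(ConfigError):
        TrainingConfig(steps=0).validate()
    with pytest.raises(ConfigError):
        TrainingConfig(r_mode="bayes").validate()
    with pytest.raises(ConfigError):
        TrainingConfig(likelihood="poisson").validate()
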