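"""Variational scaling and merging: the ELBO and its optimizer.

The probabilistic model: each observed intensity I_{h,i} is a noisy reading of
Σ_{h,i}·F_h², where F_h is the structure factor amplitude of reflection h in
its dataset and Σ_{h,i} a smooth multiplicative scale predicted from
metadata. Amplitudes carry a Wilson prior — univariate for root datasets,
and for child datasets the double-Wilson conditional (folded normal for
centrics, Rice for acentrics) evaluated at the same-sample parent amplitude.
The surrogate posterior over each F_h is an independent truncated normal on
[0, ∞); scales come from the log-normal qΣ of the MLP scale model.

The Monte-Carlo evidence lower bound, averaged over S reparameterized joint
samples, is

    ELBO = (1/S) Σ_s [ Σ_i log p(I_i | F², Σ, σ_I)
                       − Σ_h ( log q(F_h,s) − log p(F_h,s) ) ]

maximized by adaptive-moment gradient ascent over (μ_q, σ_q, θ) and, when
requested, the per-edge correlation r through a sigmoid transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special as _sp

from . import autodiff as ad
from . import priors, truncnorm
from .exceptions import ConfigError, VIError
from .refl_io import (MERGED_KEY_COLUMNS, DatasetGraph, ReflectionTable,
                      validate_graph)
from .scaling import FeatureSpec, FeatureTransform, MLPConfig, ScaleModel

__all__ = ["TrainingConfig", "SurrogatePosterior", "TrainResult",
           "likelihood_logpdf", "elbo_estimate", "train", "optimize_r"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class TrainingConfig:
    steps: int = 2000
    learning_rate: float = 1e-3
    #: final learning rate of the geometric decay schedule; equal to
    #: ``learning_rate`` for a flat schedule. Decay quiets the stochastic
    #: jitter of the surrogate means, which matters when a tight structured
    #: prior leaves only a small ΔF signal.
    final_learning_rate: float = 1e-4
    n_samples: int = 8              # Monte-Carlo samples S per step
    seed: int = 0
    r_mode: str = "fixed"           # "fixed" | "optimized"
    likelihood: str = "normal"      # "normal" | "student-t"
    student_t_dof: float = 16.0
    scale_mode: str = "mlp"         # "mlp" | "fixed" (constant global scale)
    features: FeatureSpec = field(default_factory=FeatureSpec)
    mlp: MLPConfig = field(default_factory=MLPConfig)

    def validate(self) -> "TrainingConfig":
        if self.steps < 1 or self.n_samples < 1:
            raise ConfigError("steps and n_samples must be >= 1")
        if self.r_mode not in ("fixed", "optimized"):
            raise ConfigError(f"unknown r_mode '{self.r_mode}'")
        if self.likelihood not in ("normal", "student-t"):
            raise ConfigError(f"unknown likelihood '{self.likelihood}'")
        if self.scale_mode not in ("mlp", "fixed"):
            raise ConfigError(f"unknown scale_mode '{self.scale_mode}'")
        return self


@dataclass
class SurrogatePosterior:
    """Truncated-normal surrogate parameters per merged reflection."""

    index: pd.DataFrame        # dataset_id,h,k,l,friedel_sign,centric,epsilon,d,n_obs
    mu: np.ndarray
    sigma: np.ndarray


@dataclass
class TrainResult:
    posterior: SurrogatePosterior
    scale_model: ScaleModel | None
    trace: np.ndarray                      # per-step ELBO estimates
    r_hat: dict[tuple[str, str], float]    # per edge (parent, child)
    sigma0: float                          # global intensity scale


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _normal_ll_core(I, sigI, mean):
    z = (I - mean) / sigI
    return -0.5 * ad.square(z) - np.log(sigI) - _LOG_SQRT_2PI


def _student_t_ll_core(I, sigI, mean, dof):
    c = (_sp.gammaln((dof + 1) / 2) - _sp.gammaln(dof / 2)
         - 0.5 * np.log(dof * np.pi))
    z = (I - mean) / sigI
    return c - np.log(sigI) - 0.5 * (dof + 1) * ad.log1p(ad.square(z) / dof)


def likelihood_logpdf(I, sigI, F, Sigma, family: str = "normal",
                      dof: float = 16.0):
    """Log-density of an observed intensity given amplitude and scale.

    Normal family: I ~ N(F²·Σ, σ_I); student-t: same location/scale with the
    configured degrees of freedom (a robustness option).
    """
    sigI = np.asarray(sigI, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if np.any(sigI <= 0):
        raise ValueError("sigI must be > 0")
    if np.any(Sigma <= 0):
        raise ValueError("Sigma must be > 0")
    mean = np.asarray(F, dtype=float) ** 2 * Sigma
    I = np.asarray(I, dtype=float)
    if family == "normal":
        return _normal_ll_core(I, sigI, mean)
    if family == "student-t":
        return _student_t_ll_core(I, sigI, mean, float(dof))
    raise ValueError(f"unknown likelihood family '{family}'")


# ---------------------------------------------------------------------------
# problem assembly
# ---------------------------------------------------------------------------

class _Problem:
    """Static index structures shared by every ELBO evaluation."""

    def __init__(self, t: ReflectionTable, g: DatasetGraph, cfg: TrainingConfig):
        cfg.validate()
        g = validate_graph(g, t)
        self.graph = g
        df = t.data

        key = list(MERGED_KEY_COLUMNS)
        grouped = df.groupby(key, sort=False)
        index = grouped.agg(
            centric=("centric", "first"), epsilon=("epsilon", "first"),
            d=("d", "first"), n_obs=("I", "size"), I_mean=("I", "mean"),
        ).reset_index()
        # order datasets topologically so parents precede children
        rank = {ds: i for i, ds in enumerate(g.order)}
        index["_rank"] = index["dataset_id"].map(rank)
        index = index.sort_values(["_rank", "h", "k", "l", "friedel_sign"],
                                  kind="stable").drop(columns="_rank")
        index = index.reset_index(drop=True)
        self.index = index
        H = len(index)

        lookup = {(row.dataset_id, row.h, row.k, row.l, row.friedel_sign): i
                  for i, row in enumerate(index.itertuples(index=False))}
        self.refl_of_obs = np.array(
            [lookup[key_] for key_ in
             zip(df["dataset_id"], df["h"], df["k"], df["l"], df["friedel_sign"])],
            dtype=int)

        edge_index = {e.child: k for k, e in enumerate(g.edges)}
        parent_idx = np.full(H, -1, dtype=int)
        edge_of_refl = np.full(H, -1, dtype=int)
        for i, row in enumerate(index.itertuples(index=False)):
            parent_ds = g.parent_of(row.dataset_id)
            if parent_ds is None:
                continue
            j = lookup.get((parent_ds, row.h, row.k, row.l, row.friedel_sign))
            if j is None:
                other = "-" if row.friedel_sign == "+" else "+"
                j = lookup.get((parent_ds, row.h, row.k, row.l, other))
            if j is not None:
                parent_idx[i] = j
                edge_of_refl[i] = edge_index[row.dataset_id]
        self.parent_idx = parent_idx
        self.edge_of_refl = edge_of_refl

        centric = index["centric"].to_numpy(dtype=bool)
        is_child = parent_idx >= 0
        self.sub_root_cen = np.flatnonzero(~is_child & centric)
        self.sub_root_ace = np.flatnonzero(~is_child & ~centric)
        self.sub_child_cen = np.flatnonzero(is_child & centric)
        self.sub_child_ace = np.flatnonzero(is_child & ~centric)
        self.epsilon = index["epsilon"].to_numpy(dtype=float)

        self.I = df["I"].to_numpy(dtype=float)
        self.sigI = df["sigI"].to_numpy(dtype=float)
        self.n_obs = len(df)
        self.sigma0 = float(max(np.mean(self.I), 1e-6))

        if cfg.scale_mode == "mlp":
            self.transform = FeatureTransform(cfg.features).fit(t)
            self.X = self.transform.transform(t)
            # classical scaling pass: linear regression of log-intensities on
            # the features seeds the scale model's skip connection, so smooth
            # image/resolution trends start inside Σ rather than inside F
            floor = max(1e-9, 1e-3 * self.sigma0)
            y = np.log(np.clip(self.I, floor, None))
            labels = self.transform.labels()
            smooth = np.array([lab in ("cont:inv_d2", "cont:image_id")
                               or lab.startswith(("img:", "ds:"))
                               for lab in labels])
            self.skip_init = np.zeros(self.X.shape[1])
            if smooth.any():
                A = np.column_stack([np.ones_like(y), self.X[:, smooth]])
                beta, *_ = np.linalg.lstsq(A, y, rcond=None)
                self.skip_init[smooth] = beta[1:]
            self.obs_base = np.exp(self.X @ self.skip_init)
        else:
            self.transform = None
            self.X = None
            self.skip_init = None
            self.obs_base = np.ones(self.n_obs)

    def init_params(self):
        """Method-of-moments initialization of the surrogate, using
        baseline-corrected per-reflection mean intensities."""
        H = len(self.index)
        num = np.zeros(H)
        cnt = np.zeros(H)
        np.add.at(num, self.refl_of_obs, self.I / (self.sigma0 * self.obs_base))
        np.add.at(cnt, self.refl_of_obs, 1.0)
        ratio = num / np.maximum(cnt, 1.0)
        mu0 = np.sqrt(np.maximum(ratio, 0.1 * self.epsilon))
        sigma0 = np.maximum(0.1 * mu0, 1e-2)
        return mu0, sigma0


def _edge_r_values(g: DatasetGraph) -> np.ndarray:
    return np.array([e.r for e in g.edges], dtype=float)


def _elbo_graph(problem: _Problem, cfg: TrainingConfig, mu, sigma_q, r_vec,
                scale_model: ScaleModel | None, u: np.ndarray,
                z: np.ndarray | None):
    """Assemble one Monte-Carlo ELBO estimate as an autodiff graph.

    ``mu``/``sigma_q`` are (H,) Tensors or arrays, ``r_vec`` per-edge values
    (Tensor when r is being optimized), ``u`` uniform draws (S, H), ``z``
    standard-normal draws (S, N) for the scale posterior.
    """
    S = u.shape[0]
    F = truncnorm.sample_core(mu, sigma_q, u)
    F = ad.maximum(F, 1e-10)
    logq_sum = ad.total(truncnorm.logpdf_core(F, mu, sigma_q))

    eps = problem.epsilon
    logp_sum = 0.0
    if problem.sub_root_cen.size:
        idx = problem.sub_root_cen
        logp_sum = logp_sum + ad.total(
            priors.wilson_centric_core(ad.gather(F, idx, axis=1), eps[idx]))
    if problem.sub_root_ace.size:
        idx = problem.sub_root_ace
        logp_sum = logp_sum + ad.total(
            priors.wilson_acentric_core(ad.gather(F, idx, axis=1), eps[idx]))
    for idx, centric in ((problem.sub_child_cen, True),
                         (problem.sub_child_ace, False)):
        if not idx.size:
            continue
        Fi = ad.gather(F, idx, axis=1)
        Fpa = ad.gather(F, problem.parent_idx[idx], axis=1)
        r = ad.gather(r_vec, problem.edge_of_refl[idx], axis=0)
        if centric:
            s = priors.conditional_scale_centric(r, eps[idx])
            logp_sum = logp_sum + ad.total(priors.folded_normal_core(Fi, r * Fpa, s))
        else:
            s = priors.conditional_scale_acentric(r, eps[idx])
            logp_sum = logp_sum + ad.total(priors.rice_core(Fi, r * Fpa, s))

    F_obs = ad.gather(F, problem.refl_of_obs, axis=1)
    if scale_model is not None:
        Sigma = scale_model.sample(problem.X, z)
    else:
        Sigma = problem.sigma0
    mean = ad.square(F_obs) * Sigma
    if cfg.likelihood == "normal":
        ll = _normal_ll_core(problem.I, problem.sigI, mean)
    else:
        ll = _student_t_ll_core(problem.I, problem.sigI, mean, cfg.student_t_dof)
    return (ad.total(ll) - logq_sum + logp_sum) / float(S)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def train(t: ReflectionTable, g: DatasetGraph, cfg: TrainingConfig | None = None
          ) -> TrainResult:
    """Fit the surrogate posterior, scale model, and optionally r by gradient
    ascent on the Monte-Carlo ELBO. Fully deterministic given (inputs, seed)."""
    cfg = (cfg or TrainingConfig()).validate()
    problem = _Problem(t, g, cfg)
    H = len(problem.index)
    rng = np.random.default_rng(cfg.seed)

    mu0, sig0 = problem.init_params()
    mu = ad.Tensor(mu0)
    sigma_raw = ad.Tensor(np.log(np.expm1(sig0)))

    scale_model = None
    params = [mu, sigma_raw]
    if cfg.scale_mode == "mlp":
        scale_model = ScaleModel(problem.X.shape[1], cfg.mlp, seed=cfg.seed,
                                 log_scale_offset=float(np.log(problem.sigma0)),
                                 skip_init=problem.skip_init)
        scale_model.transform = problem.transform
        params += scale_model.params

    optimize_edges = cfg.r_mode == "optimized" and len(g.edges) > 0
    opt_r = None
    if optimize_edges:
        r0 = np.clip(_edge_r_values(g), 1e-3, 1.0 - 1e-3)
        r_raw = ad.Tensor(np.log(r0) - np.log1p(-r0))
        # r lives on the logit scale and must be able to traverse several
        # units within a run; give it a faster schedule than the bulk params
        opt_r = ad.Adam([r_raw], lr=10 * cfg.learning_rate)
    else:
        r_fixed = _edge_r_values(g) if g.edges else np.zeros(0)

    opt = ad.Adam(params, lr=cfg.learning_rate)
    decay = cfg.final_learning_rate / cfg.learning_rate
    trace = np.empty(cfg.steps)
    for step in range(cfg.steps):
        frac = step / max(cfg.steps - 1, 1)
        opt.lr = cfg.learning_rate * decay ** frac
        if opt_r is not None:
            opt_r.lr = 10 * opt.lr
        u = rng.random((cfg.n_samples, H))
        zs = (rng.standard_normal((cfg.n_samples, problem.n_obs))
              if scale_model is not None else None)
        sigma_q = ad.softplus(sigma_raw) + 1e-6
        r_vec = ad.sigmoid(r_raw) * (1.0 - 1e-6) if optimize_edges else r_fixed
        elbo = _elbo_graph(problem, cfg, mu, sigma_q, r_vec, scale_model, u, zs)
        value = float(elbo.value)
        if not np.isfinite(value):
            raise VIError(f"non-finite ELBO at step {step}")
        trace[step] = value
        opt.zero_grad()
        if opt_r is not None:
            opt_r.zero_grad()
        loss = -elbo
        loss.backward()
        opt.step()
        if opt_r is not None:
            opt_r.step()

    sigma_final = np.logaddexp(0.0, sigma_raw.value) + 1e-6
    posterior = SurrogatePosterior(
        problem.index.drop(columns=["I_mean"]).copy(), mu.value.copy(),
        sigma_final)
    if optimize_edges:
        r_final = _sp.expit(r_raw.value) * (1.0 - 1e-6)
    else:
        r_final = r_fixed
    r_hat = {(e.parent, e.child): float(r_final[k])
             for k, e in enumerate(g.edges)}
    return TrainResult(posterior, scale_model, trace, r_hat, problem.sigma0)


def optimize_r(t: ReflectionTable, g: DatasetGraph,
               cfg: TrainingConfig | None = None) -> dict[tuple[str, str], float]:
    """Jointly optimize the per-edge double-Wilson r with the ELBO."""
    cfg = cfg or TrainingConfig()
    if cfg.r_mode != "optimized":
        cfg = replace(cfg, r_mode="optimized")
    return train(t, g, cfg).r_hat


def elbo_estimate(q: SurrogatePosterior, scales: ScaleModel | None,
                  t: ReflectionTable, g: DatasetGraph, cfg: TrainingConfig,
                  n_samples: int | None = None) -> float:
    """Monte-Carlo ELBO of a given surrogate state (no parameter updates)."""
    cfg = cfg.validate()
    problem = _Problem(t, g, cfg)
    # align q's parameters with this problem's reflection order
    qi = q.index.copy()
    qi["_mu"], qi["_sigma"] = q.mu, q.sigma
    merged = problem.index.merge(qi[list(MERGED_KEY_COLUMNS) + ["_mu", "_sigma"]],
                                 on=list(MERGED_KEY_COLUMNS), how="left")
    if merged["_mu"].isna().any():
        raise ValueError("surrogate posterior does not cover every reflection")
    mu = merged["_mu"].to_numpy(dtype=float)
    sigma = merged["_sigma"].to_numpy(dtype=float)
    S = int(n_samples or cfg.n_samples)
    rng = np.random.default_rng(cfg.seed)
    u = rng.random((S, len(problem.index)))
    z = (rng.standard_normal((S, problem.n_obs))
         if (scales is not None and cfg.scale_mode == "mlp") else None)
    model = scales if cfg.scale_mode == "mlp" else None
    if model is not None and model.transform is not None:
        # evaluate features with the transform the model was trained with
        problem.X = model.transform.transform(t)
    r_vec = _edge_r_values(g) if g.edges else np.zeros(0)
    elbo = _elbo_graph(problem, cfg, ad.Tensor(mu), ad.Tensor(sigma), r_vec,
                       model, u, z)
    return float(elbo.value)
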