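"""Metadata featurization and the neural scale function.

The scale model is a multilayer perceptron θ mapping per-observation metadata
(Miller index, image, detector position with positional encoding, wavelength,
dataset one-hot) to the parameters of a log-normal surrogate posterior qΣ over
the multiplicative scale of that observation. Log-normality guarantees
positive scales and gives a cheap reparameterized sampler:
Σ = exp(offset + loc(x) + scale(x)·z), z ~ N(0,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .exceptions import ConfigError
from .refl_io import ReflectionTable

__all__ = ["FeatureSpec", "FeatureTransform", "build_features",
           "MLPConfig", "ScaleModel", "sample_scales"]


@dataclass(frozen=True)
class FeatureSpec:
    """Which metadata enter the scale model and how they are encoded."""

    metadata_columns: tuple[str, ...] = ("det_x", "det_y", "wavelength")
    positional_encoding_columns: tuple[str, ...] = ("det_x", "det_y")
    n_frequencies: int = 8        # L sin/cos pairs per encoded coordinate
    include_miller: bool = True
    include_resolution: bool = True   # adds standardized 1/d²
    dataset_one_hot: bool = True
    image_one_hot_max: int = 512  # one-hot images up to this many, else scalar id


class FeatureTransform:
    """Fitted featurizer: standardization statistics and one-hot vocabularies
    are learned on the training observations and reused verbatim on held-out
    data."""

    def __init__(self, spec: FeatureSpec):
        self.spec = spec
        self._fitted = False

    # -- fitting -----------------------------------------------------------
    def fit(self, t: ReflectionTable) -> "FeatureTransform":
        df = t.data
        spec = self.spec
        for col in set(spec.metadata_columns) | set(spec.positional_encoding_columns):
            if col not in df.columns:
                raise ConfigError(f"unknown metadata column '{col}'")
        self.datasets_ = list(pd.unique(df["dataset_id"]))
        images = list(df[["dataset_id", "image_id"]].drop_duplicates()
                      .itertuples(index=False, name=None))
        self.image_one_hot_ = len(images) <= spec.image_one_hot_max
        self.image_vocab_ = {key: i for i, key in enumerate(sorted(images))}
        # min/max of encoded coordinates, for mapping into [-1, 1]
        self.pe_range_ = {c: (df[c].min(), df[c].max())
                          for c in spec.positional_encoding_columns}
        cont = self._continuous_raw(df)
        mu = cont.mean(axis=0)
        sd = cont.std(axis=0)
        keep = sd > 1e-12
        if not keep.all():
            dropped = [self.continuous_names_[i] for i in np.flatnonzero(~keep)]
            warnings.warn(f"dropping zero-variance feature column(s): {dropped}")
        self.keep_, self.mu_, self.sd_ = keep, mu, sd
        self._fitted = True
        return self

    def _continuous_raw(self, df: pd.DataFrame) -> np.ndarray:
        spec = self.spec
        cols, names = [], []
        if spec.include_miller:
            for c in ("h", "k", "l"):
                cols.append(df[c].to_numpy(dtype=float))
                names.append(c)
        if spec.include_resolution:
            cols.append(1.0 / df["d"].to_numpy(dtype=float) ** 2)
            names.append("inv_d2")
        for c in spec.metadata_columns:
            cols.append(df[c].to_numpy(dtype=float))
            names.append(c)
        if not self.image_one_hot_:
            cols.append(df["image_id"].to_numpy(dtype=float))
            names.append("image_id")
        self.continuous_names_ = names
        return np.column_stack(cols) if cols else np.empty((len(df), 0))

    # -- application -------------------------------------------------------
    def transform(self, t: ReflectionTable) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("FeatureTransform not fitted")
        df = t.data
        spec = self.spec
        blocks = []
        cont = self._continuous_raw(df)
        if cont.shape[1]:
            std = (cont - self.mu_) / np.where(self.sd_ > 1e-12, self.sd_, 1.0)
            blocks.append(std[:, self.keep_])
        # positional encoding on coordinates mapped to [-1, 1]
        for c in spec.positional_encoding_columns:
            lo, hi = self.pe_range_[c]
            span = (hi - lo) or 1.0
            x = 2.0 * (df[c].to_numpy(dtype=float) - lo) / span - 1.0
            for level in range(spec.n_frequencies):
                w = np.pi * 2.0 ** level
                blocks.append(np.column_stack([np.sin(w * x), np.cos(w * x)]))
        if spec.dataset_one_hot:
            onehot = np.zeros((len(df), len(self.datasets_)))
            for j, ds in enumerate(self.datasets_):
                onehot[df["dataset_id"].to_numpy() == ds, j] = 1.0
            blocks.append(onehot)
        if self.image_one_hot_:
            onehot = np.zeros((len(df), len(self.image_vocab_)))
            keys = list(zip(df["dataset_id"], df["image_id"]))
            for row, key in enumerate(keys):
                j = self.image_vocab_.get(key)
                if j is not None:
                    onehot[row, j] = 1.0
            blocks.append(onehot)
        X = np.hstack(blocks) if blocks else np.empty((len(df), 0))
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite entries in feature matrix")
        return X

    def fit_transform(self, t: ReflectionTable) -> np.ndarray:
        return self.fit(t).transform(t)

    def labels(self) -> list[str]:
        """Column labels of the transformed matrix, in block order."""
        if not self._fitted:
            raise RuntimeError("FeatureTransform not fitted")
        spec = self.spec
        out = [f"cont:{n}" for n, keep in
               zip(self.continuous_names_, self.keep_) if keep]
        for c in spec.positional_encoding_columns:
            for level in range(spec.n_frequencies):
                out += [f"pe:{c}:{level}:sin", f"pe:{c}:{level}:cos"]
        if spec.dataset_one_hot:
            out += [f"ds:{ds}" for ds in self.datasets_]
        if self.image_one_hot_:
            out += [f"img:{ds}:{img}" for ds, img in sorted(self.image_vocab_,
                                                            key=lambda k: self.image_vocab_[k])]
        return out


def build_features(t: ReflectionTable, spec: FeatureSpec | None = None) -> np.ndarray:
    """Deterministic feature matrix for a reflection table (fits on ``t``)."""
    return FeatureTransform(spec or FeatureSpec()).fit_transform(t)


# ---------------------------------------------------------------------------
# MLP scale model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MLPConfig:
    n_layers: int = 6
    width: int = 32
    activation: str = "silu"   # smooth, residual-friendly


def _softplus_inv(y: float) -> float:
    return float(np.log(np.expm1(y)))


class ScaleModel:
    """MLP θ: metadata → (location, dispersion) of the log-normal qΣ.

    The location head carries a trainable linear skip connection from the
    features; initializing it from a classical (method-of-moments) scaling
    pass puts the smooth image/resolution trend into Σ from step one, so the
    optimizer never has to migrate it out of 300 individual amplitudes. The
    nonlinear head is zero-initialized with biases giving loc = 0 and
    dispersion ≈ 0.1, so a fresh model emits scales with median exp(offset)
    and mild spread regardless of input dimension.
    """

    def __init__(self, n_features: int, config: MLPConfig | None = None,
                 seed: int = 0, log_scale_offset: float = 0.0,
                 skip_init: np.ndarray | None = None):
        self.config = config or MLPConfig()
        self.n_features = int(n_features)
        self.log_scale_offset = float(log_scale_offset)
        self.transform: FeatureTransform | None = None  # set by the trainer
        rng = np.random.default_rng(seed)
        dims = [self.n_features] + [self.config.width] * self.config.n_layers + [2]
        self.weights: list[ad.Tensor] = []
        self.biases: list[ad.Tensor] = []
        for i, (din, dout) in enumerate(zip(dims[:-1], dims[1:])):
            last = i == len(dims) - 2
            W = np.zeros((din, dout)) if last else \
                rng.normal(0.0, np.sqrt(2.0 / max(din, 1)), (din, dout))
            b = np.array([0.0, _softplus_inv(0.1)]) if last else np.zeros(dout)
            self.weights.append(ad.Tensor(W))
            self.biases.append(ad.Tensor(b))
        skip = (np.zeros(self.n_features) if skip_init is None
                else np.asarray(skip_init, dtype=float))
        self.w_skip = ad.Tensor(skip.reshape(-1, 1))

    @property
    def params(self) -> list[ad.Tensor]:
        return [*self.weights, *self.biases, self.w_skip]

    def _act(self, x):
        if self.config.activation == "silu":
            return x * ad.sigmoid(x)
        if self.config.activation == "tanh":
            return ad.tanh(x)
        raise ConfigError(f"unknown activation '{self.config.activation}'")

    def forward(self, X: np.ndarray):
        """Return (loc, disp) Tensors of shape (N,); disp > 0."""
        x0 = ad.Tensor(X) if not isinstance(X, ad.Tensor) else X
        h = x0
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = ad.matmul(h, W) + b
            if i < len(self.weights) - 1:
                h = self._act(h)
        loc = ad.gather(h, 0, axis=1) + ad.gather(ad.matmul(x0, self.w_skip),
                                                  0, axis=1)
        disp = ad.softplus(ad.gather(h, 1, axis=1)) + 1e-4
        return loc, disp

    def sample(self, X: np.ndarray, z: np.ndarray):
        """Reparameterized scale draws Σ = exp(offset + loc + disp·z); ``z`` may
        broadcast over a leading sample axis."""
        loc, disp = self.forward(X)
        # clamp the log-scale so badly-scaled weights can neither overflow
        # nor underflow the strictly-positive contract
        return ad.exp(ad.clip(self.log_scale_offset + loc + disp * z,
                              -80.0, 80.0))

    def mean_scale(self, X: np.ndarray) -> np.ndarray:
        """Posterior-mean scale E[Σ] = exp(offset + loc + disp²/2)."""
        loc, disp = self.forward(X)
        return np.exp(np.clip(
            self.log_scale_offset + loc.value + 0.5 * disp.value ** 2,
            -80.0, 80.0))

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict:
        return {
            "config": self.config.__dict__,
            "n_features": self.n_features,
            "log_scale_offset": self.log_scale_offset,
            "weights": [w.value.tolist() for w in self.weights],
            "biases": [b.value.tolist() for b in self.biases],
            "w_skip": self.w_skip.value.tolist(),
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "ScaleModel":
        model = cls(state["n_features"], MLPConfig(**state["config"]),
                    log_scale_offset=state["log_scale_offset"])
        for w, v in zip(model.weights, state["weights"]):
            w.value = np.asarray(v, dtype=float)
        for b, v in zip(model.biases, state["biases"]):
            b.value = np.asarray(v, dtype=float)
        model.w_skip.value = np.asarray(state["w_skip"], dtype=float)
        return model


def sample_scales(model: ScaleModel, X: np.ndarray, n_samples: int,
                  seed: int = 0) -> np.ndarray:
    """Draw ``n_samples`` reparameterized scale vectors; shape (S, N)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, X.shape[0]))
    out = model.sample(X, z)
    values = out.value if isinstance(out, ad.Tensor) else out
    if not np.all(np.isfinite(values)):
        bad = int(np.argwhere(~np.isfinite(values))[0][-1])
        raise FloatingPointError(f"non-finite scale sample at observation {bad}")
    return values
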