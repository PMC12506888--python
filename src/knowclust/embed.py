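"""Autoencoder embedding and affinity-matrix construction.

The autoencoder is a symmetric multilayer perceptron (encoder widths
``hidden_widths + [latent_dim]``, mirrored decoder; tanh activations by
default, with relu/identity selectable) trained with Adam on the
mean-squared reconstruction error.  Saturating symmetric activations retain
low-variance structure (e.g. rare cell types) that a ReLU network starves.  The affinity matrix is a
symmetric k-nearest-neighbour graph with local (Zelnik-Manor/Perona) scaling
of the Gaussian kernel bandwidth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPRegressor

from .containers import KnowclustError


@dataclass
class AutoencoderSpec:
    """Architecture and optimization settings for the autoencoder."""

    input_width: int
    hidden_widths: tuple[int, ...] = (64,)
    latent_dim: int = 16
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 64
    activation: str = "tanh"
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
        if self.latent_dim >= self.input_width:
            raise KnowclustError(
                f"latent_dim {self.latent_dim} must be smaller than the "
                f"input width {self.input_width}"
            )
        if self.epochs < 1:
            raise KnowclustError("epochs must be >= 1")
        if self.activation not in ("tanh", "relu", "identity"):
            raise KnowclustError(f"unknown activation {self.activation!r}")


@dataclass
class Autoencoder:
    """A trained symmetric autoencoder with encoder extraction."""

    spec: AutoencoderSpec
    _mlp: MLPRegressor
    loss_trace: list[float]

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Forward pass through the encoder half (hidden + latent layers)."""
        A = np.asarray(X, dtype=float)
        n_encoder_layers = len(self.spec.hidden_widths) + 1  # hidden... + latent
        for layer in range(n_encoder_layers):
            A = A @ self._mlp.coefs_[layer] + self._mlp.intercepts_[layer]
            if self.spec.activation == "relu":
                np.maximum(A, 0.0, out=A)
            elif self.spec.activation == "tanh":
                np.tanh(A, out=A)
        return A


def train_autoencoder(X: np.ndarray, spec: AutoencoderSpec):
    """Train the autoencoder on X (cells x features); returns (model, Z).

    All randomness (weight init, minibatch shuffling) is controlled by
    ``spec.seed``; two runs with the same seed give bitwise-identical traces
    and embeddings.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise KnowclustError("autoencoder input contains non-finite values")
    if X.shape[1] != spec.input_width:
        raise KnowclustError(
            f"input has {X.shape[1]} features, spec expects {spec.input_width}"
        )
    layers = tuple(spec.hidden_widths) + (spec.latent_dim,) + tuple(reversed(spec.hidden_widths))
    mlp = MLPRegressor(
        hidden_layer_sizes=layers,
        activation=spec.activation,
        solver="adam",
        alpha=0.0,
        batch_size=min(spec.batch_size, X.shape[0]),
        learning_rate_init=spec.learning_rate,
        max_iter=spec.epochs,
        shuffle=True,
        random_state=int(spec.seed) % (2**31),
        tol=0.0,
        n_iter_no_change=spec.epochs + 1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(X, X)
    # sklearn's squared loss is MSE/2 over cells and features
    trace = [2.0 * v for v in mlp.loss_curve_]
    for epoch, v in enumerate(trace):
        if not math.isfinite(v):
            raise KnowclustError(f"non-finite reconstruction loss at epoch {epoch}")
    model = Autoencoder(spec, mlp, trace)
    return model, model.encode(X)


def build_affinity(Z: np.ndarray, n_neighbors: int = 15) -> np.ndarray:
    """Locally-scaled symmetric kNN affinity on Euclidean distances in Z.

    Edge weight exp(-d_ij^2 / (sigma_i sigma_j)) where sigma_i is the distance
    from cell i to its ceil(n_neighbors/2)-th neighbour; A = max(W, W^T) with a
    zero diagonal.  Bandwidths are floored at machine-epsilon scale times the
    median pairwise distance so duplicate points cannot zero them out.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n_neighbors >= n:
        raise KnowclustError(
            f"n_neighbors={n_neighbors} must be smaller than the {n} cells"
        )
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(Z)
    dist, idx = nn.kneighbors(Z)  # column 0 is the point itself
    dist, idx = dist[:, 1:], idx[:, 1:]
    k_sigma = math.ceil(n_neighbors / 2)
    sigma = dist[:, k_sigma - 1].copy()
    if np.any(sigma <= 0):
        if n <= 2000:
            med = np.median(pdist(Z))
        else:
            rng = np.random.default_rng(0)
            sub = Z[rng.choice(n, 2000, replace=False)]
            med = np.median(pdist(sub))
        floor = max(np.finfo(float).eps * max(med, 1.0) * 1e3, np.finfo(float).tiny)
        sigma = np.maximum(sigma, floor)
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), n_neighbors)
    cols = idx.ravel()
    w = np.exp(-(dist.ravel() ** 2) / (sigma[rows] * sigma[cols]))
    W[rows, cols] = w
    A = np.maximum(W, W.T)
    np.fill_diagonal(A, 0.0)
    return A
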