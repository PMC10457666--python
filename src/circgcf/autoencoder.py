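"""Autoencoder compression of similarity descriptors into initial embeddings.

Each fused descriptor (diseases: M x M, circRNAs: N x N) is passed
through a one-hidden-layer autoencoder with logistic activations; the
hidden code becomes the entity's initial k-dimensional embedding.
Training minimizes the mean squared reconstruction error with Adam and
stops when the relative loss improvement falls below a tolerance.

When k exceeds the descriptor dimension the code is overcomplete; this
is permitted (the default k of 128 exceeds typical disease counts) and
merely logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Tensor, xavier_uniform
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = ["EncoderState", "InitialEmbeddings", "fit_autoencoder", "encode"]


@dataclass
class EncoderState:
    """Weights of a trained one-hidden-layer logistic autoencoder."""

    w: np.ndarray   # (dim, k) encode weights
    b: np.ndarray   # (k,) encode bias
    w_dec: np.ndarray  # (k, dim) decode weights
    b_dec: np.ndarray  # (dim,) decode bias
    k: int
    loss_trace: list[float] = field(default_factory=list)


@dataclass
class InitialEmbeddings:
    disease_embeddings: np.ndarray  # (M, k)
    circrna_embeddings: np.ndarray  # (N, k)

    def __post_init__(self):
        if self.disease_embeddings.shape[1] != self.circrna_embeddings.shape[1]:
            raise ValueError("disease and circRNA embedding widths differ")
        if not (np.isfinite(self.disease_embeddings).all()
                and np.isfinite(self.circrna_embeddings).all()):
            raise ValueError("embeddings contain non-finite entries")

    @property
    def k(self) -> int:
        return self.disease_embeddings.shape[1]


def fit_autoencoder(descriptor: SimilarityMatrix | np.ndarray, k: int = 128,
                    seed: int = 0, lr: float = 1e-3, tol: float = 1e-5,
                    max_epochs: int = 2000) -> EncoderState:
    """Train the autoencoder on a descriptor matrix (rows = entities)."""
    x = descriptor.values if isinstance(descriptor, SimilarityMatrix) else np.asarray(descriptor)
    dim = x.shape[1]
    if k < 1:
        raise ValueError("embedding size k must be >= 1")
    if k >= dim:
        logger.info("overcomplete code: k=%d >= descriptor dimension %d", k, dim)
    rng = np.random.default_rng(seed)
    w = Tensor(xavier_uniform((dim, k), rng), requires_grad=True)
    b = Tensor(np.zeros(k), requires_grad=True)
    w_dec = Tensor(xavier_uniform((k, dim), rng), requires_grad=True)
    b_dec = Tensor(np.zeros(dim), requires_grad=True)
    data = Tensor(x)
    opt = Adam([w, b, w_dec, b_dec], lr=lr)
    trace: list[float] = []
    prev = None
    for _ in range(max_epochs):
        hidden = (data @ w + b).sigmoid()
        recon = (hidden @ w_dec + b_dec).sigmoid()
        diff = recon - data
        loss = (diff * diff).mean()
        value = loss.item()
        if not np.isfinite(value):
            raise FloatingPointError("autoencoder loss diverged; lower the learning rate")
        trace.append(value)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if prev is not None and prev > 0 and abs(prev - value) / prev < tol:
            break
        prev = value
    return EncoderState(w.data, b.data, w_dec.data, b_dec.data, k=k, loss_trace=trace)


def encode(state: EncoderState, descriptor: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Hidden-layer codes for each descriptor row; pure function."""
    x = descriptor.values if isinstance(descriptor, SimilarityMatrix) else np.asarray(descriptor)
    if x.shape[1] != state.w.shape[0]:
        raise ValueError(
            f"descriptor dimension {x.shape[1]} does not match trained input "
            f"dimension {state.w.shape[0]}")
    return 1.0 / (1.0 + np.exp(-(x @ state.w + state.b)))


def reconstruct(state: EncoderState, descriptor: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Decode the hidden codes back to descriptor space."""
    h = encode(state, descriptor)
    return 1.0 / (1.0 + np.exp(-(h @ state.w_dec + state.b_dec)))
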