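"""Multilayer message propagation with per-layer cooperative attention.

CircRNAs and diseases form one node set of size N + M (circRNAs first).
Each propagation layer sends, along every known association edge, a
message ``m = p * (e_s W1 + (e_s ⊙ e_t) W2)`` from neighbor ``s`` to
center ``t``, where ``p = 1/sqrt(|N_t| |N_s|)`` is the symmetric graph
Laplacian decay.  A per-layer attention head (one head per layer, shared
across centers) scores each neighbor with a single feed-forward layer
``q = a · [e_t W_a ‖ e_s W_a]`` and softmax-normalizes LeakyReLU(q) over
the center's neighborhood; the attention weight multiplies the decayed
message.  The center's own self-message ``e_t W1`` bypasses attention,
and the aggregate passes through LeakyReLU.

Two equivalent computation paths exist: :func:`propagate_layer` walks
nodes and neighborhoods explicitly (the reference semantics), while
:func:`propagate` and the training loop run the vectorized form over a
flat edge list (the attention-masked Laplacian rule).  Tests pin the two
paths together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Tensor, cat, xavier_uniform
from .data_io import AssociationMatrix

__all__ = [
    "PropagationConfig",
    "PropagationWeights",
    "EmbeddingTable",
    "AttentionState",
    "LayerStack",
    "build_laplacian",
    "message",
    "attention_scores",
    "propagate_layer",
    "propagate",
]

ATTENTION_MODES = ("learned", "uniform", "none")


@dataclass
class PropagationConfig:
    layers: int = 3
    attention: str = "learned"   # learned | uniform (1/|N|) | none (weight 1)
    leaky_slope: float = 0.2
    decay: str = "sqrt"          # sqrt: 1/sqrt(NdNc); sum: 1/(Nd+Nc)

    def __post_init__(self):
        if self.layers < 1:
            raise ValueError("at least one propagation layer is required")
        if self.attention not in ATTENTION_MODES:
            raise ValueError(f"attention must be one of {ATTENTION_MODES}")
        if self.decay not in ("sqrt", "sum"):
            raise ValueError("decay must be 'sqrt' or 'sum'")


@dataclass
class EmbeddingTable:
    """(N+M) x k lookup table, circRNA rows first then disease rows."""

    rows: np.ndarray
    n_circrna: int
    n_disease: int

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.float64)
        if self.rows.shape[0] != self.n_circrna + self.n_disease:
            raise ValueError("lookup table row count must be N + M")
        if not np.isfinite(self.rows).all():
            raise ValueError("lookup table contains non-finite entries")

    @classmethod
    def from_embeddings(cls, circrna: np.ndarray, disease: np.ndarray) -> "EmbeddingTable":
        return cls(np.vstack([circrna, disease]), circrna.shape[0], disease.shape[0])


@dataclass
class PropagationWeights:
    """Per-layer transforms: W1, W2 (messages), Wa, a (attention head)."""

    layers: list[dict[str, np.ndarray]]

    @classmethod
    def initialize(cls, k_in: int, layer_dims: list[int], seed: int = 0,
                   attention_init: str = "zero") -> "PropagationWeights":
        """Xavier-uniform transforms; the attention scoring vector starts
        at zero by default so every head begins as uniform weighting and
        learns deviations from it (``attention_init="xavier"`` for a
        randomly scored start)."""
        rng = np.random.default_rng(seed)
        layers = []
        prev = k_in
        for k_out in layer_dims:
            layers.append({
                "W1": xavier_uniform((prev, k_out), rng),
                "W2": xavier_uniform((prev, k_out), rng),
                "Wa": xavier_uniform((prev, prev), rng),
                "a": (np.zeros(2 * prev) if attention_init == "zero"
                      else xavier_uniform((2 * prev,), rng)),
            })
            prev = k_out
        return cls(layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass
class AttentionState:
    """Normalized neighbor weights of one propagation layer as edge lists."""

    centers: np.ndarray
    neighbors: np.ndarray
    alpha: np.ndarray

    def weights_for(self, center: int) -> dict[int, float]:
        mask = self.centers == center
        return dict(zip(self.neighbors[mask].tolist(), self.alpha[mask].tolist()))

    def check_normalized(self, tol: float = 1e-6) -> bool:
        if len(self.centers) == 0:
            return True
        sums = np.zeros(int(self.centers.max()) + 1)
        np.add.at(sums, self.centers, self.alpha)
        occupied = np.unique(self.centers)
        return bool((self.alpha > 0).all() and np.abs(sums[occupied] - 1.0).max() <= tol)


@dataclass
class LayerStack:
    """Graph operators plus per-layer embeddings and attention states."""

    adjacency: np.ndarray             # (N+M)^2 block matrix [[0, R], [R^T, 0]]
    degrees: np.ndarray               # diagonal of D
    laplacian: np.ndarray             # D^{-1/2} A D^{-1/2}, zero rows for isolates
    n_circrna: int
    n_disease: int
    embeddings: list[np.ndarray] = field(default_factory=list)  # E(0..l)
    attention: list[AttentionState] = field(default_factory=list)

    @property
    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        centers, neighbors = np.nonzero(self.adjacency)
        return centers, neighbors

    def final_circrna(self) -> np.ndarray:
        return self.embeddings[-1][: self.n_circrna]

    def final_disease(self) -> np.ndarray:
        return self.embeddings[-1][self.n_circrna:]

    def attention_table(self):
        """All attention states as one (center, neighbor, layer, alpha)
        edge-list DataFrame, for inspection or TSV export."""
        import pandas as pd

        frames = []
        for layer, state in enumerate(self.attention, start=1):
            frames.append(pd.DataFrame({
                "center": state.centers, "neighbor": state.neighbors,
                "layer": layer, "alpha": state.alpha,
            }))
        return pd.concat(frames, ignore_index=True)


def build_laplacian(assoc: AssociationMatrix) -> LayerStack:
    """Bipartite block adjacency and its symmetric normalized Laplacian."""
    r = assoc.values.astype(np.float64)
    n, m = r.shape
    a = np.zeros((n + m, n + m))
    a[:n, n:] = r
    a[n:, :n] = r.T
    deg = a.sum(axis=1)
    inv_sqrt = np.divide(1.0, np.sqrt(deg), out=np.zeros_like(deg), where=deg > 0)
    lap = inv_sqrt[:, None] * a * inv_sqrt[None, :]
    return LayerStack(adjacency=a, degrees=deg, laplacian=lap, n_circrna=n, n_disease=m)


def _edge_decay(degrees: np.ndarray, centers: np.ndarray, neighbors: np.ndarray,
                mode: str) -> np.ndarray:
    dt, ds = degrees[centers], degrees[neighbors]
    if mode == "sqrt":
        return 1.0 / np.sqrt(dt * ds)
    return 1.0 / (dt + ds)


def message(ec: np.ndarray, ed: np.ndarray, pdc: float,
            w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Decayed message from neighbor ``ec`` toward center ``ed``."""
    return pdc * (ec @ w1 + (ec * ed) @ w2)


def attention_scores(center: np.ndarray, neighbors: np.ndarray, wa: np.ndarray,
                     a: np.ndarray, slope: float = 0.2) -> np.ndarray:
    """Softmax-normalized neighbor weights for one center node."""
    neighbors = np.atleast_2d(neighbors)
    if neighbors.shape[0] == 0:
        raise ValueError("attention requires at least one neighbor")
    k = wa.shape[1]
    tc = center @ wa
    tn = neighbors @ wa
    q = tn @ a[k:] + tc @ a[:k]
    q = np.where(q > 0, q, slope * q)
    q -= q.max()
    e = np.exp(q)
    return e / e.sum()


def propagate_layer(stack: LayerStack, layer: int, weights: PropagationWeights,
                    config: PropagationConfig | None = None
                    ) -> tuple[np.ndarray, AttentionState]:
    """One layer of explicit per-node message passing (reference path).

    ``layer`` indexes into ``weights.layers``; the input embeddings are
    ``stack.embeddings[layer]`` (so E(0) must be present).
    """
    config = config or PropagationConfig(layers=weights.n_layers)
    w = weights.layers[layer]
    e_prev = stack.embeddings[layer]
    n_nodes = e_prev.shape[0]
    out = np.empty((n_nodes, w["W1"].shape[1]))
    centers_acc, neighbors_acc, alpha_acc = [], [], []
    for t in range(n_nodes):
        nbrs = np.flatnonzero(stack.adjacency[t])
        m_self = e_prev[t] @ w["W1"]
        total = m_self.copy()
        if len(nbrs):
            if config.attention == "learned":
                alpha = attention_scores(e_prev[t], e_prev[nbrs], w["Wa"], w["a"],
                                         config.leaky_slope)
            elif config.attention == "uniform":
                alpha = np.full(len(nbrs), 1.0 / len(nbrs))
            else:
                alpha = np.ones(len(nbrs))
            for s, al in zip(nbrs, alpha):
                pdc = _edge_decay(stack.degrees, np.array([t]), np.array([s]),
                                  config.decay)[0]
                total += al * message(e_prev[s], e_prev[t], pdc, w["W1"], w["W2"])
            centers_acc += [t] * len(nbrs)
            neighbors_acc += nbrs.tolist()
            alpha_acc += alpha.tolist()
        out[t] = np.where(total > 0, total, config.leaky_slope * total)
    state = AttentionState(np.array(centers_acc, dtype=np.intp),
                           np.array(neighbors_acc, dtype=np.intp),
                           np.array(alpha_acc, dtype=np.float64))
    return out, state


def forward_layers(e0: Tensor, stack: LayerStack, weight_tensors: list[dict[str, Tensor]],
                   config: PropagationConfig) -> tuple[list[Tensor], list[AttentionState]]:
    """Vectorized multilayer propagation over the flat edge list.

    Differentiable; shared by :func:`propagate` (inference) and the
    training loop.  Returns embeddings E(1..l) and per-layer attention.
    """
    centers, neighbors = stack.edges
    n_nodes = stack.adjacency.shape[0]
    pdc = Tensor(_edge_decay(stack.degrees, centers, neighbors, config.decay)[:, None])
    if config.attention == "uniform":
        fixed_alpha = 1.0 / stack.degrees[centers]
    elif config.attention == "none":
        fixed_alpha = np.ones(len(centers))
    else:
        fixed_alpha = None
    embeddings: list[Tensor] = []
    states: list[AttentionState] = []
    e_prev = e0
    for w in weight_tensors:
        self_msg = e_prev @ w["W1"]
        es = e_prev.take(neighbors)
        et = e_prev.take(centers)
        msg = (es @ w["W1"] + (es * et) @ w["W2"]) * pdc
        if fixed_alpha is None:
            k = w["Wa"].shape[1]
            transformed = e_prev @ w["Wa"]
            a_c = w["a"].take(np.arange(k)).reshape(k, 1)
            a_n = w["a"].take(np.arange(k, 2 * k)).reshape(k, 1)
            q = (transformed.take(centers) @ a_c + transformed.take(neighbors) @ a_n).reshape(-1)
            alpha = q.leaky_relu(config.leaky_slope).segment_softmax(centers, n_nodes)
        else:
            alpha = Tensor(fixed_alpha)
        agg = (msg * alpha.reshape(-1, 1)).segment_sum(centers, n_nodes)
        e_prev = (self_msg + agg).leaky_relu(config.leaky_slope)
        embeddings.append(e_prev)
        states.append(AttentionState(centers.copy(), neighbors.copy(), alpha.data.copy()))
    return embeddings, states


def propagate(initial: EmbeddingTable, assoc: AssociationMatrix,
              weights: PropagationWeights | None = None,
              config: PropagationConfig | None = None, seed: int = 0) -> LayerStack:
    """Run the full multilayer propagation and collect every layer."""
    config = config or PropagationConfig()
    if weights is None:
        k = initial.rows.shape[1]
        weights = PropagationWeights.initialize(k, [k] * config.layers, seed)
    if weights.n_layers != config.layers:
        raise ValueError("weight layer count does not match config.layers")
    stack = build_laplacian(assoc)
    if stack.adjacency.shape[0] != initial.rows.shape[0]:
        raise ValueError("lookup table size does not match the association graph")
    tensors = [{k: Tensor(v) for k, v in layer.items()} for layer in weights.layers]
    embs, states = forward_layers(Tensor(initial.rows), stack, tensors, config)
    stack.embeddings = [initial.rows.copy()] + [e.data for e in embs]
    stack.attention = states
    return stack
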