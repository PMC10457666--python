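"""End-to-end optimization with the pairwise ranking (BPR) objective.

Training jointly fits the lookup table (optionally frozen), the
propagation transforms, the per-layer attention heads, and the
collaborative-filtering head by minimizing

    L = sum_{(c,i,j)} -ln sigma(y'_ci - y'_cj) + lambda * ||Theta||^2

over triples (c, i, j) pairing, for each circRNA c, a known disease i
with a sampled unknown disease j.  The graph is small, so each epoch is
one full-batch Adam step over freshly sampled triples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import Adam, Tensor
from .data_io import AssociationMatrix, PairSet
from .propagation import (
    PropagationConfig,
    PropagationWeights,
    EmbeddingTable,
    build_laplacian,
    forward_layers,
)
from .predictor import (
    LSTMParams,
    PredictorHead,
    ScoreMatrix,
    aggregate_layers,
    aggregate_tensors,
    head_forward,
    score_all,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "ExperimentConfig",
    "TrainTrace",
    "TrainedModel",
    "bpr_loss",
    "make_triples",
    "train",
]


@dataclass
class TrainConfig:
    """Hyperparameters of the ranking optimization."""

    epochs: int = 2000
    lr: float = 1e-3
    reg: float = 1e-5            # lambda, the L2 coefficient on Theta
    seed: int = 0
    layers: int = 3
    embed_k: int = 128
    aggregator: str = "concat"
    attention: str = "learned"   # learned | uniform | none
    leaky_slope: float = 0.2
    decay: str = "sqrt"
    mlp_hidden: list[int] | None = None
    finetune_lookup: bool = True
    negative_pool: str = "unknown"  # unknown: any unlinked disease; sampled: the balanced negative set

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.reg < 0:
            raise ValueError("regularization must be non-negative")

    def propagation_config(self) -> PropagationConfig:
        return PropagationConfig(layers=self.layers, attention=self.attention,
                                 leaky_slope=self.leaky_slope, decay=self.decay)


@dataclass
class ExperimentConfig:
    """Everything a cross-validation or prediction run needs."""

    train: TrainConfig = field(default_factory=TrainConfig)
    init: str = "similarity"     # similarity | random (ablation of the lookup table)
    delta: float = 0.5           # semantic-similarity decay
    gamma_prime: float = 1.0     # GIP bandwidth scale
    ae_epochs: int = 2000
    ae_lr: float = 1e-3
    ae_tol: float = 1e-5
    gip_full_matrix: bool = False  # compute GIP on the full matrix inside CV (leaky)
    mask_test_edges: bool = True   # remove test positives from the propagation graph
    center_codes: bool = True      # zero-mean the lookup table columns

    @classmethod
    def fast(cls, seed: int = 0) -> "ExperimentConfig":
        """Desk-scale experiment configuration for the synthetic fixture.

        Low-capacity settings (narrow MLP, frozen lookup, k = 64, 300
        epochs) that generalize on a few hundred training pairs, with
        interaction profiles computed on the full association matrix as
        in the original evaluation protocol.
        """
        return cls(train=TrainConfig(epochs=300, embed_k=64, seed=seed,
                                     mlp_hidden=[8, 4], finetune_lookup=False),
                   ae_epochs=2000, gip_full_matrix=True)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "ExperimentConfig":
        payload = dict(payload)
        train = payload.pop("train", {})
        return cls(train=TrainConfig(**train), **payload)


@dataclass
class TrainTrace:
    losses: list[float]
    seed: int

    def smoothed(self, window: int = 21) -> np.ndarray:
        x = np.asarray(self.losses)
        if len(x) < window:
            return x
        kernel = np.ones(window) / window
        return np.convolve(x, kernel, mode="valid")


@dataclass
class TrainedModel:
    """Checkpoint: every fitted parameter plus the config that made it."""

    lookup: EmbeddingTable
    weights: PropagationWeights
    head: PredictorHead
    config: TrainConfig

    def score_matrix(self, assoc: AssociationMatrix) -> ScoreMatrix:
        from .propagation import propagate

        stack = propagate(self.lookup, assoc, self.weights,
                          self.config.propagation_config())
        finals = aggregate_layers(stack, self.config.aggregator, self.head.lstm)
        return score_all(finals, self.head, assoc.circrna_ids(), assoc.disease_ids())

    def score_pairs(self, assoc: AssociationMatrix,
                    pairs: list[tuple[int, int]]) -> np.ndarray:
        scores = self.score_matrix(assoc).values
        return np.array([scores[r, c] for r, c in pairs])


def bpr_loss(scores_pos: np.ndarray, scores_neg: np.ndarray,
             params_norm_sq: float = 0.0, reg: float = 0.0) -> float:
    """Pairwise ranking loss: sum of -ln sigma(pos - neg) plus L2 term."""
    pos, neg = np.asarray(scores_pos, float), np.asarray(scores_neg, float)
    if pos.shape != neg.shape:
        raise ValueError("positive and negative score lists must pair up")
    diff = pos - neg
    logsig = np.minimum(diff, 0.0) - np.log1p(np.exp(-np.abs(diff)))
    return float(-logsig.sum() + reg * params_norm_sq)


def make_triples(pairs: PairSet, seed: int = 0, n_disease: int | None = None,
                 pool: str = "unknown") -> list[tuple[int, int, int]]:
    """For each positive (c, i), draw a negative disease j for the same c.

    With ``pool="unknown"`` (default) j is drawn uniformly from every
    disease c is not positively linked to — the ranking objective
    contrasts confirmed pairs against the whole unknown set.  With
    ``pool="sampled"`` j comes from the balanced sampled negative set of
    the same circRNA, falling back to any unknown disease (when
    ``n_disease`` is given); positives with no candidate are skipped
    with a log entry.
    """
    rng = np.random.default_rng(seed)
    neg_by_circ: dict[int, list[int]] = {}
    for c, j in pairs.negatives:
        neg_by_circ.setdefault(c, []).append(j)
    pos_by_circ: dict[int, set[int]] = {}
    for c, i in pairs.positives:
        pos_by_circ.setdefault(c, set()).add(i)
    triples = []
    skipped = 0
    for c, i in pairs.positives:
        if pool == "unknown" and n_disease is not None:
            candidates = [j for j in range(n_disease) if j not in pos_by_circ[c]]
        else:
            candidates = neg_by_circ.get(c)
            if not candidates and n_disease is not None:
                candidates = [j for j in range(n_disease) if j not in pos_by_circ[c]]
        if not candidates:
            skipped += 1
            continue
        triples.append((c, i, candidates[rng.integers(len(candidates))]))
    if skipped:
        logger.info("skipped %d positives with no sampleable negative", skipped)
    return triples


def _build_params(initial: EmbeddingTable, config: TrainConfig, seed: int):
    """Create all trainable tensors: lookup, propagation, head, LSTM."""
    k = initial.rows.shape[1]
    e0 = Tensor(initial.rows.copy(), requires_grad=config.finetune_lookup)
    raw_weights = PropagationWeights.initialize(k, [k] * config.layers, seed)
    needs_attention = config.attention == "learned"
    prop_t = []
    for layer in raw_weights.layers:
        entry = {"W1": Tensor(layer["W1"], requires_grad=True),
                 "W2": Tensor(layer["W2"], requires_grad=True)}
        if needs_attention:
            entry["Wa"] = Tensor(layer["Wa"], requires_grad=True)
            entry["a"] = Tensor(layer["a"], requires_grad=True)
        else:
            entry["Wa"] = Tensor(layer["Wa"])
            entry["a"] = Tensor(layer["a"])
        prop_t.append(entry)
    d = config.layers * k if config.aggregator == "concat" else k
    raw_head = PredictorHead.initialize(d, config.mlp_hidden, seed=seed + 1)
    head_t = {
        "mlp_w": [Tensor(w, requires_grad=True) for w in raw_head.mlp_weights],
        "mlp_b": [Tensor(b, requires_grad=True) for b in raw_head.mlp_biases],
        "h": Tensor(raw_head.h, requires_grad=True),
    }
    lstm_t = None
    if config.aggregator == "lstm":
        raw_lstm = LSTMParams.initialize(k, seed=seed + 2)
        lstm_t = {part: {g: Tensor(arr, requires_grad=True)
                         for g, arr in getattr(raw_lstm, part).items()}
                  for part in ("wx", "wh", "b")}
    params = [e0] + [t for layer in prop_t for t in layer.values()] \
        + head_t["mlp_w"] + head_t["mlp_b"] + [head_t["h"]]
    if lstm_t is not None:
        params += [t for part in lstm_t.values() for t in part.values()]
    return e0, prop_t, head_t, lstm_t, params


def train(assoc: AssociationMatrix, initial: EmbeddingTable, pairs: PairSet,
          config: TrainConfig | None = None) -> tuple[TrainedModel, TrainTrace]:
    """Full-batch Adam optimization of the whole model."""
    config = config or TrainConfig()
    stack = build_laplacian(assoc)
    if stack.adjacency.shape[0] != initial.rows.shape[0]:
        raise ValueError("lookup table does not match the association graph")
    prop_cfg = config.propagation_config()
    e0, prop_t, head_t, lstm_t, params = _build_params(initial, config, config.seed)
    trainable = [p for p in params if p.requires_grad]
    opt = Adam(trainable, lr=config.lr)
    n = assoc.n_circrna
    losses: list[float] = []
    for epoch in range(config.epochs):
        triple_seed = int(np.random.default_rng([config.seed, epoch]).integers(2**31))
        triples = make_triples(pairs, seed=triple_seed, n_disease=assoc.n_disease,
                               pool=config.negative_pool)
        if not triples:
            raise ValueError("no usable training triples")
        c_idx = np.array([t[0] for t in triples])
        i_idx = np.array([t[1] for t in triples]) + n
        j_idx = np.array([t[2] for t in triples]) + n
        embs, _ = forward_layers(e0, stack, prop_t, prop_cfg)
        finals = aggregate_tensors(embs, config.aggregator, lstm_t)
        ec = finals.take(c_idx)
        s_pos = head_forward(ec, finals.take(i_idx), head_t)
        s_neg = head_forward(ec, finals.take(j_idx), head_t)
        loss = -(s_pos - s_neg).log_sigmoid().sum()
        if config.reg > 0:
            penalty = None
            for p in trainable:
                term = (p * p).sum()
                penalty = term if penalty is None else penalty + term
            loss = loss + config.reg * penalty
        value = loss.item()
        if not np.isfinite(value):
            raise FloatingPointError(f"training loss diverged at epoch {epoch}")
        losses.append(value)
        opt.zero_grad()
        loss.backward()
        opt.step()
    weights = PropagationWeights([
        {name: t.data.copy() for name, t in layer.items()} for layer in prop_t
    ])
    head = PredictorHead(
        [t.data.copy() for t in head_t["mlp_w"]],
        [t.data.copy() for t in head_t["mlp_b"]],
        head_t["h"].data.copy(),
        lstm=LSTMParams(
            wx={g: lstm_t["wx"][g].data.copy() for g in LSTMParams.GATES},
            wh={g: lstm_t["wh"][g].data.copy() for g in LSTMParams.GATES},
            b={g: lstm_t["b"][g].data.copy() for g in LSTMParams.GATES},
        ) if lstm_t is not None else None,
    )
    lookup = EmbeddingTable(e0.data.copy(), initial.n_circrna, initial.n_disease)
    model = TrainedModel(lookup=lookup, weights=weights, head=head, config=config)
    return model, TrainTrace(losses=losses, seed=config.seed)
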