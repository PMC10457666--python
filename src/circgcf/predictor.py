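"""Layer aggregation and the neural collaborative-filtering scorer.

Per-layer embeddings from propagation are aggregated (concatenation by
default; weighted sum, max pooling, or an LSTM over the layer sequence
are alternatives) into final representations ``ec*`` and ``ed*``.  A
pair is scored by fusing two branches:

* **GMF**: the element-wise product ``ec* ⊙ ed*`` (linear latent-factor
  interaction);
* **MLP**: a tower network on the concatenation ``[ec* ‖ ed*]``
  (nonlinear interaction).

The score is the sum of the fusion-weighted concatenation
``y' = sum(h ⊙ [E_gmf ‖ E_mlp])`` with no output activation;
probabilities, where needed, are obtained downstream with a logistic
link.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Tensor, cat, maximum, xavier_uniform
from .propagation import LayerStack

__all__ = [
    "AGGREGATORS",
    "FinalEmbeddings",
    "LSTMParams",
    "PredictorHead",
    "ScoreMatrix",
    "aggregate_layers",
    "gmf",
    "mlp_branch",
    "score_pair",
    "score_all",
]

AGGREGATORS = ("concat", "sum", "max_pool", "lstm")


@dataclass
class FinalEmbeddings:
    circrna: np.ndarray   # (N, d) with d = l*k for concat, k otherwise
    disease: np.ndarray   # (M, d)
    aggregator: str = "concat"

    @property
    def dim(self) -> int:
        return self.circrna.shape[1]


@dataclass
class LSTMParams:
    """One-layer LSTM run over the layer sequence; final hidden state kept."""

    wx: dict[str, np.ndarray]  # input weights per gate i/f/o/g, each (k, k)
    wh: dict[str, np.ndarray]  # hidden weights per gate
    b: dict[str, np.ndarray]   # biases per gate

    GATES = ("i", "f", "o", "g")

    @classmethod
    def initialize(cls, k: int, seed: int = 0) -> "LSTMParams":
        rng = np.random.default_rng(seed)
        return cls(
            wx={g: xavier_uniform((k, k), rng) for g in cls.GATES},
            wh={g: xavier_uniform((k, k), rng) for g in cls.GATES},
            b={g: np.zeros(k) for g in cls.GATES},
        )


@dataclass
class PredictorHead:
    """MLP tower weights plus the GMF/MLP fusion vector h."""

    mlp_weights: list[np.ndarray]
    mlp_biases: list[np.ndarray]
    h: np.ndarray
    lstm: LSTMParams | None = None

    @classmethod
    def initialize(cls, d: int, hidden: list[int] | None = None,
                   seed: int = 0) -> "PredictorHead":
        """Default tower: 2d -> d -> d/2 with ReLU activations."""
        if hidden is None:
            hidden = [d, max(d // 2, 1)]
        rng = np.random.default_rng(seed)
        dims = [2 * d] + hidden
        ws = [xavier_uniform((a, b), rng) for a, b in zip(dims[:-1], dims[1:])]
        bs = [np.zeros(b) for b in dims[1:]]
        h = xavier_uniform((d + dims[-1],), rng)
        return cls(ws, bs, h)

    @classmethod
    def gmf_only(cls, d: int) -> "PredictorHead":
        """Degenerate head: no MLP, h = ones, so y' = dot(ec*, ed*)."""
        return cls([], [], np.ones(d))

    @property
    def mlp_out_dim(self) -> int:
        return self.mlp_biases[-1].shape[0] if self.mlp_biases else 0


@dataclass
class ScoreMatrix:
    values: np.ndarray
    circrna_ids: list[str] = field(default_factory=list)
    disease_ids: list[str] = field(default_factory=list)
    provenance: str = ""

    def ranked_candidates(self, known: np.ndarray | None = None,
                          disease: str | None = None, top: int | None = None):
        """Unknown pairs sorted by descending score as a DataFrame."""
        import pandas as pd

        n, m = self.values.shape
        rows = []
        for i in range(n):
            for j in range(m):
                if known is not None and known[i, j]:
                    continue
                if disease is not None and self.disease_ids[j] != disease:
                    continue
                rows.append((self.circrna_ids[i] if self.circrna_ids else str(i),
                             self.disease_ids[j] if self.disease_ids else str(j),
                             self.values[i, j]))
        df = pd.DataFrame(rows, columns=["circrna_id", "disease_id", "score"])
        df = df.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df.head(top) if top else df


def aggregate_tensors(embeddings: list[Tensor], aggregator: str,
                      lstm: dict[str, dict[str, Tensor]] | None = None) -> Tensor:
    """Differentiable layer aggregation shared with the training loop."""
    if aggregator == "concat":
        return embeddings[0] if len(embeddings) == 1 else cat(embeddings, axis=1)
    if aggregator == "sum":
        out = embeddings[0]
        for e in embeddings[1:]:
            out = out + e
        return out / len(embeddings)
    if aggregator == "max_pool":
        out = embeddings[0]
        for e in embeddings[1:]:
            out = maximum(out, e)
        return out
    if aggregator == "lstm":
        if lstm is None:
            raise ValueError("lstm aggregator requires LSTM parameters")
        h = Tensor(np.zeros_like(embeddings[0].data))
        c = Tensor(np.zeros_like(embeddings[0].data))
        for x in embeddings:
            i = (x @ lstm["wx"]["i"] + h @ lstm["wh"]["i"] + lstm["b"]["i"]).sigmoid()
            f = (x @ lstm["wx"]["f"] + h @ lstm["wh"]["f"] + lstm["b"]["f"]).sigmoid()
            o = (x @ lstm["wx"]["o"] + h @ lstm["wh"]["o"] + lstm["b"]["o"]).sigmoid()
            g = (x @ lstm["wx"]["g"] + h @ lstm["wh"]["g"] + lstm["b"]["g"]).tanh()
            c = f * c + i * g
            h = o * c.tanh()
        return h
    raise ValueError(f"unknown aggregator {aggregator!r}; choose one of {AGGREGATORS}")


def aggregate_layers(stack: LayerStack, aggregator: str = "concat",
                     lstm: LSTMParams | None = None) -> FinalEmbeddings:
    """Aggregate E(1..l) into final circRNA and disease representations."""
    layers = stack.embeddings[1:]
    if not layers:
        raise ValueError("layer stack holds no propagated embeddings")
    lstm_t = _lstm_tensors(lstm) if (aggregator == "lstm" and lstm is not None) else None
    out = aggregate_tensors([Tensor(e) for e in layers], aggregator, lstm_t).data
    return FinalEmbeddings(out[: stack.n_circrna], out[stack.n_circrna:], aggregator)


def _lstm_tensors(lstm: LSTMParams) -> dict[str, dict[str, Tensor]]:
    return {part: {g: Tensor(arr) for g, arr in getattr(lstm, part).items()}
            for part in ("wx", "wh", "b")}


def gmf(ec_star: np.ndarray, ed_star: np.ndarray) -> np.ndarray:
    """Generalized matrix factorization feature: element-wise product."""
    ec_star, ed_star = np.asarray(ec_star), np.asarray(ed_star)
    if ec_star.shape != ed_star.shape:
        raise ValueError("GMF requires equal embedding dimensions")
    return ec_star * ed_star


def mlp_branch(ec_star: np.ndarray, ed_star: np.ndarray, head: PredictorHead) -> np.ndarray:
    """MLP tower on the concatenation [ec* || ed*], ReLU at every layer."""
    x = np.concatenate([np.atleast_2d(ec_star), np.atleast_2d(ed_star)], axis=1)
    if head.mlp_weights and x.shape[1] != head.mlp_weights[0].shape[0]:
        raise ValueError("MLP input dimension mismatch")
    for w, b in zip(head.mlp_weights, head.mlp_biases):
        x = np.maximum(x @ w + b, 0.0)
    return x


def _score_batch(ec: np.ndarray, ed: np.ndarray, head: PredictorHead) -> np.ndarray:
    g = gmf(ec, ed)
    g = np.atleast_2d(g)
    d = g.shape[1]
    out = g @ head.h[:d]
    if head.mlp_weights:
        out = out + mlp_branch(ec, ed, head) @ head.h[d:]
    return out


def score_pair(ec_star: np.ndarray, ed_star: np.ndarray, head: PredictorHead) -> float:
    """y' for one pair: sum of the h-weighted [E_gmf || E_mlp]."""
    return float(_score_batch(np.atleast_2d(ec_star), np.atleast_2d(ed_star), head)[0])


def score_all(finals: FinalEmbeddings, head: PredictorHead,
              circrna_ids: list[str] | None = None,
              disease_ids: list[str] | None = None,
              provenance: str = "") -> ScoreMatrix:
    """Full N x M score matrix, vectorized over disease-major batches."""
    n, m = finals.circrna.shape[0], finals.disease.shape[0]
    values = np.empty((n, m))
    for j in range(m):
        ed = np.broadcast_to(finals.disease[j], finals.circrna.shape)
        values[:, j] = _score_batch(finals.circrna, ed, head)
    return ScoreMatrix(values, circrna_ids or [], disease_ids or [], provenance)


def head_forward(ec: Tensor, ed: Tensor, head_t: dict) -> Tensor:
    """Differentiable scorer used in training; mirrors the numpy path."""
    g = ec * ed
    d = g.data.shape[1]
    scores = g @ head_t["h"].take(np.arange(d)).reshape(d, 1)
    if head_t["mlp_w"]:
        x = cat([ec, ed], axis=1)
        for w, b in zip(head_t["mlp_w"], head_t["mlp_b"]):
            x = (x @ w + b).relu()
        dm = x.data.shape[1]
        scores = scores + x @ head_t["h"].take(np.arange(d, d + dm)).reshape(dm, 1)
    return scores.reshape(-1)
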