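"""Cross-validation, ranking metrics, and ablation experiments.

Each fold removes its test positives from the propagation graph,
rebuilds similarities and initial embeddings from training data only,
trains the model on the training pairs, and scores the held-out pairs.
Metrics (all reported in percent): AUC (trapezoidal ROC), AUPR
(precision-recall step integration), accuracy and F1 at a logistic
probability threshold of 0.5, and NDCG over the full ranked fold with
binary gains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm

from .autoencoder import fit_autoencoder, encode
from .data_io import AssociationMatrix, DiseaseDAG, PairSet, kfold_split, sample_negatives
from .propagation import EmbeddingTable
from .similarity import circrna_descriptor, disease_descriptor
from .training import ExperimentConfig, TrainTrace, TrainedModel, train
from ._nn import xavier_uniform

logger = logging.getLogger(__name__)

__all__ = [
    "METRIC_NAMES",
    "MetricsReport",
    "compute_metrics",
    "initial_embeddings",
    "cross_validate",
    "run_ablation",
    "ABLATION_VARIANTS",
]

METRIC_NAMES = ("auc", "aupr", "acc", "f1", "ndcg")
ABLATION_VARIANTS = ("full", "random_init", "no_attention")


@dataclass
class MetricsReport:
    """Per-fold metrics plus their mean and standard deviation (percent)."""

    folds: list[dict[str, float]]
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)
    loss_traces: list[TrainTrace] = field(default_factory=list)

    def __post_init__(self):
        if self.folds and not self.mean:
            self.mean = {m: float(np.mean([f[m] for f in self.folds])) for m in self.folds[0]}
            self.std = {m: float(np.std([f[m] for f in self.folds])) for m in self.folds[0]}

    def to_dict(self) -> dict:
        r = lambda d: {k: round(v, 2) for k, v in d.items()}
        return {"folds": [r(f) for f in self.folds],
                "mean": r(self.mean), "std": r(self.std)}


def compute_metrics(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Ranking and classification metrics for one fold, in percent."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("metrics require both positive and negative labels")
    prob = 1.0 / (1.0 + np.exp(-scores))
    pred = (prob >= 0.5).astype(int)
    return {
        "auc": 100.0 * skm.roc_auc_score(labels, scores),
        "aupr": 100.0 * skm.average_precision_score(labels, scores),
        "acc": 100.0 * skm.accuracy_score(labels, pred),
        "f1": 100.0 * skm.f1_score(labels, pred, zero_division=0),
        "ndcg": 100.0 * skm.ndcg_score(labels[None, :], scores[None, :]),
    }


def initial_embeddings(assoc: AssociationMatrix, dag: DiseaseDAG | None,
                       config: ExperimentConfig, seed: int) -> EmbeddingTable:
    """Similarity-descriptor autoencoder embeddings, or random features
    for the lookup-table ablation."""
    k = config.train.embed_k
    if config.init == "random":
        rng = np.random.default_rng(seed)
        rows = xavier_uniform((assoc.n_circrna + assoc.n_disease, k), rng)
        return EmbeddingTable(rows, assoc.n_circrna, assoc.n_disease)
    dsim = disease_descriptor(assoc, dag, delta=config.delta,
                              gamma_prime=config.gamma_prime)
    csim = circrna_descriptor(assoc, dsim, gamma_prime=config.gamma_prime)
    ds_state = fit_autoencoder(dsim, k=k, seed=seed, lr=config.ae_lr,
                               tol=config.ae_tol, max_epochs=config.ae_epochs)
    cs_state = fit_autoencoder(csim, k=k, seed=seed + 1, lr=config.ae_lr,
                               tol=config.ae_tol, max_epochs=config.ae_epochs)
    cs = encode(cs_state, csim)
    ds = encode(ds_state, dsim)
    table = EmbeddingTable.from_embeddings(cs, ds)
    if config.center_codes:
        # logistic codes carry a large shared offset; removing the
        # column means keeps the discriminative directions from being
        # washed out by the constant component during propagation
        table = EmbeddingTable(table.rows - table.rows.mean(axis=0),
                               table.n_circrna, table.n_disease)
    return table


def _run_fold(assoc: AssociationMatrix, dag: DiseaseDAG | None,
              config: ExperimentConfig, split, fold: int,
              seed: int) -> tuple[dict[str, float], TrainTrace, TrainedModel]:
    test_pos, test_neg = split.test_pairs(fold)
    train_pos, train_neg = split.train_pairs(fold)
    assoc_train = assoc.masked(test_pos) if config.mask_test_edges else assoc
    sim_source = assoc if config.gip_full_matrix else assoc_train
    lookup = initial_embeddings(sim_source, dag, config, seed=seed)
    train_cfg = config.train
    train_cfg = type(train_cfg)(**{**train_cfg.__dict__, "seed": seed})
    model, trace = train(assoc_train, lookup,
                         PairSet(train_pos, train_neg), train_cfg)
    pairs = list(test_pos) + list(test_neg)
    labels = np.array([1] * len(test_pos) + [0] * len(test_neg))
    scores = model.score_pairs(assoc_train, pairs)
    return compute_metrics(scores, labels), trace, model


def cross_validate(assoc: AssociationMatrix, dag: DiseaseDAG | None = None,
                   config: ExperimentConfig | None = None, k: int = 5,
                   seed: int = 0) -> MetricsReport:
    """k-fold cross-validation of the full pipeline (default k = 5)."""
    config = config or ExperimentConfig()
    pairs = sample_negatives(assoc, seed=seed)
    split = kfold_split(pairs, k=k, seed=seed)
    fold_metrics, traces = [], []
    for fold in range(k):
        fold_seed = int(np.random.default_rng([seed, fold]).integers(2**31))
        m, trace, _ = _run_fold(assoc, dag, config, split, fold, fold_seed)
        logger.info("fold %d: %s", fold + 1,
                    " ".join(f"{k_}={v:.2f}" for k_, v in m.items()))
        fold_metrics.append(m)
        traces.append(trace)
    return MetricsReport(folds=fold_metrics, loss_traces=traces)


def heldout_recovery(assoc: AssociationMatrix, dag: DiseaseDAG | None,
                     held_out: list[tuple[str, str]],
                     config: ExperimentConfig | None = None,
                     seed: int = 0) -> float:
    """Train on all known pairs and rank held-out positives (pairs absent
    from the association table) against an equal number of sampled
    unknown cells.  Returns the AUC in percent.

    Held-out pairs whose circRNA or disease never appears in the table,
    or that coincide with a known cell, are skipped — they carry no
    usable information for a profile-based method.
    """
    config = config or ExperimentConfig()
    targets = []
    for c, d in held_out:
        if c in assoc.circrna_index and d in assoc.disease_index:
            r, col = assoc.circrna_index[c], assoc.disease_index[d]
            if assoc.values[r, col] == 0:
                targets.append((r, col))
    if not targets:
        raise ValueError("no scoreable held-out pairs")
    lookup = initial_embeddings(assoc, dag, config, seed=seed)
    pairs = sample_negatives(assoc, seed=seed)
    train_cfg = type(config.train)(**{**config.train.__dict__, "seed": seed})
    from .training import train

    model, _ = train(assoc, lookup, pairs, train_cfg)
    rng = np.random.default_rng(seed + 1)
    zeros = np.argwhere(assoc.values == 0)
    target_set = set(targets)
    candidates = [i for i, cell in enumerate(map(tuple, zeros))
                  if cell not in target_set]
    chosen = rng.choice(candidates, size=len(targets), replace=False)
    negatives = [tuple(zeros[i]) for i in chosen]
    scores = model.score_pairs(assoc, targets + negatives)
    labels = np.array([1] * len(targets) + [0] * len(negatives))
    from sklearn.metrics import roc_auc_score

    return 100.0 * roc_auc_score(labels, scores)


def run_ablation(variant: str, assoc: AssociationMatrix,
                 dag: DiseaseDAG | None = None,
                 base: ExperimentConfig | None = None, k: int = 5,
                 seed: int = 0) -> MetricsReport:
    """Cross-validate one model variant.

    Variants: ``full``, ``random_init`` (random lookup table),
    ``no_attention`` (uniform neighbor weights), ``aggregator:<choice>``,
    ``layers:<n>``.
    """
    base = base or ExperimentConfig()
    config = ExperimentConfig.from_dict(base.to_dict())
    if variant == "full":
        pass
    elif variant == "random_init":
        config.init = "random"
    elif variant == "no_attention":
        config.train.attention = "uniform"
    elif variant.startswith("aggregator:"):
        config.train.aggregator = variant.split(":", 1)[1]
    elif variant.startswith("layers:"):
        config.train.layers = int(variant.split(":", 1)[1])
    else:
        raise ValueError(
            f"unknown ablation variant {variant!r}; use one of {ABLATION_VARIANTS} "
            "or 'aggregator:<choice>' / 'layers:<n>'")
    return cross_validate(assoc, dag, config, k=k, seed=seed)
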