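"""Similarity matrices for diseases and circRNAs, and their fusion.

Four similarities feed the model's initial features:

* **Disease semantic similarity** (Wang's DAG method): each disease
  contributes to its ancestors with a factor that decays by ``delta`` per
  hierarchy edge; two diseases are similar in proportion to the
  contributions of their shared ancestors.
* **Gaussian interaction-profile (GIP) kernel**: RBF similarity between
  binary association profiles, with the bandwidth normalized by the mean
  squared profile norm.
* **circRNA functional similarity**: best-match averaging of the
  semantic similarities of the diseases two circRNAs are associated with.

The fused descriptors use the informative similarity where it is defined
(semantic for diseases, functional for circRNAs) and fall back to the
GIP kernel elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import AssociationMatrix, DiseaseDAG

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "semantic_contributions",
    "semantic_similarity",
    "gip_kernel",
    "functional_similarity",
    "fuse_disease_descriptor",
    "fuse_circrna_descriptor",
    "disease_descriptor",
    "circrna_descriptor",
]

_SYM_TOL = 1e-12


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity in [0, 1] with an id -> position map."""

    values: np.ndarray
    index: dict[str, int]
    kind: str = "fused"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if v.shape[0] != len(self.index):
            raise ValueError("similarity index size does not match matrix")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("similarity matrix is not symmetric")
        if v.size and (v.min() < -_SYM_TOL or v.max() > 1 + _SYM_TOL):
            raise ValueError("similarity values must lie in [0, 1]")
        self.values = np.clip((v + v.T) / 2.0, 0.0, 1.0)

    @property
    def ids(self) -> list[str]:
        return list(self.index)


def semantic_contributions(dag: DiseaseDAG, disease: str, delta: float = 0.5) -> dict[str, float]:
    """Contribution of each ancestor term to ``disease``.

    The disease itself contributes 1; an ancestor ``t`` contributes
    ``delta ** d(disease, t)`` where ``d`` is the shortest child-to-parent
    path length (the maximal product of per-edge decays).
    """
    import networkx as nx

    g = dag.to_networkx()
    if disease not in g:
        raise KeyError(f"disease {disease!r} is not in the hierarchy")
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    depths = nx.single_source_shortest_path_length(g, disease)
    return {term: delta**depth for term, depth in depths.items()}


def semantic_similarity(dag: DiseaseDAG, diseases: list[str], delta: float = 0.5) -> SimilarityMatrix:
    """Wang-style DAG semantic similarity between the listed diseases."""
    contribs = [semantic_contributions(dag, d, delta) for d in diseases]
    totals = [sum(c.values()) for c in contribs]
    n = len(diseases)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = contribs[i].keys() & contribs[j].keys()
            if shared:
                num = sum(contribs[i][t] + contribs[j][t] for t in shared)
                values[i, j] = values[j, i] = num / (totals[i] + totals[j])
    return SimilarityMatrix(values, {d: i for i, d in enumerate(diseases)}, kind="semantic")


def gip_kernel(profiles: np.ndarray, ids: list[str], gamma_prime: float = 1.0) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over rows of ``profiles``.

    ``K(i, j) = exp(-gamma * ||p_i - p_j||^2)`` with
    ``gamma = gamma_prime / mean_i ||p_i||^2``.
    """
    p = np.asarray(profiles, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] == 0:
        raise ValueError("profiles must be a non-empty 2-D matrix")
    mean_sq = (p**2).sum(axis=1).mean()
    if mean_sq == 0:
        raise ValueError("all interaction profiles are zero; GIP bandwidth undefined")
    gamma = gamma_prime / mean_sq
    sq = (p**2).sum(axis=1)
    dist2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (p @ p.T), 0.0)
    values = np.exp(-gamma * dist2)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, {x: i for i, x in enumerate(ids)}, kind="gip")


def functional_similarity(assoc: AssociationMatrix, disease_sim: SimilarityMatrix) -> SimilarityMatrix:
    """circRNA similarity by best-match averaging over associated diseases.

    ``FS(c1, c2) = [sum_{d in D1} max_{d' in D2} sim(d, d')
    + sum_{d in D2} max_{d' in D1} sim(d, d')] / (|D1| + |D2|)``.
    circRNAs with no associated disease get an undefined (zero)
    off-diagonal row; callers substitute the GIP kernel there.
    """
    if list(disease_sim.index) != assoc.disease_ids():
        raise ValueError("disease similarity index does not match association columns")
    s = disease_sim.values
    disease_sets = [np.flatnonzero(row) for row in assoc.values]
    empty = [i for i, ds in enumerate(disease_sets) if len(ds) == 0]
    if empty:
        logger.warning("functional similarity undefined for %d circRNA(s) with no associations", len(empty))
    n = assoc.n_circrna
    values = np.eye(n)
    for i in range(n):
        di = disease_sets[i]
        if len(di) == 0:
            continue
        for j in range(i + 1, n):
            dj = disease_sets[j]
            if len(dj) == 0:
                continue
            block = s[np.ix_(di, dj)]
            values[i, j] = values[j, i] = (
                block.max(axis=1).sum() + block.max(axis=0).sum()
            ) / (len(di) + len(dj))
    return SimilarityMatrix(values, {c: i for i, c in enumerate(assoc.circrna_ids())},
                            kind="functional")


def _fuse(primary: SimilarityMatrix, fallback: SimilarityMatrix,
          has_primary: np.ndarray, kind: str) -> SimilarityMatrix:
    if list(primary.index) != list(fallback.index):
        raise ValueError("cannot fuse similarity matrices with different indices")
    mask = np.asarray(has_primary, dtype=bool)
    mask = mask & mask.T  # keep the fused matrix symmetric
    values = np.where(mask, primary.values, fallback.values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, dict(primary.index), kind=kind)


def fuse_disease_descriptor(semantic: SimilarityMatrix, gip: SimilarityMatrix,
                            has_semantic: np.ndarray) -> SimilarityMatrix:
    """Semantic similarity where defined, GIP kernel elsewhere (DSim)."""
    return _fuse(semantic, gip, has_semantic, kind="fused")


def fuse_circrna_descriptor(functional: SimilarityMatrix, gip: SimilarityMatrix,
                            has_functional: np.ndarray) -> SimilarityMatrix:
    """Functional similarity where defined, GIP kernel elsewhere (CSim)."""
    return _fuse(functional, gip, has_functional, kind="fused")


def disease_descriptor(assoc: AssociationMatrix, dag: DiseaseDAG | None,
                       delta: float = 0.5, gamma_prime: float = 1.0) -> SimilarityMatrix:
    """Full disease descriptor: semantic (where the DAG covers both
    diseases and they share an ancestor) fused with the GIP kernel over
    association-matrix columns."""
    ids = assoc.disease_ids()
    gip = gip_kernel(assoc.values.T, ids, gamma_prime)
    m = assoc.n_disease
    semantic_values = np.eye(m)
    has_semantic = np.zeros((m, m), dtype=bool)
    if dag is not None:
        covered = [d for d in ids if d in dag.nodes()]
        if covered:
            sub = semantic_similarity(dag, covered, delta)
            contribs = {d: semantic_contributions(dag, d, delta) for d in covered}
            pos = {d: ids.index(d) for d in covered}
            for a in covered:
                for b in covered:
                    i, j = pos[a], pos[b]
                    semantic_values[i, j] = sub.values[sub.index[a], sub.index[b]]
                    has_semantic[i, j] = bool(contribs[a].keys() & contribs[b].keys())
    semantic = SimilarityMatrix(semantic_values, {d: i for i, d in enumerate(ids)},
                                kind="semantic")
    return fuse_disease_descriptor(semantic, gip, has_semantic)


def circrna_descriptor(assoc: AssociationMatrix, disease_sim: SimilarityMatrix,
                       gamma_prime: float = 1.0) -> SimilarityMatrix:
    """Full circRNA descriptor: functional similarity (where both
    circRNAs have known associations) fused with the GIP kernel over
    association-matrix rows."""
    ids = assoc.circrna_ids()
    gip = gip_kernel(assoc.values, ids, gamma_prime)
    functional = functional_similarity(assoc, disease_sim)
    has_assoc = assoc.values.sum(axis=1) > 0
    has_functional = has_assoc[:, None] & has_assoc[None, :]
    return fuse_circrna_descriptor(functional, gip, has_functional)
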