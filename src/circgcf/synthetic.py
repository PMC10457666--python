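"""Synthetic circRNA-disease datasets with planted co-cluster structure.

Real association data concentrates links inside latent disease/circRNA
communities, and the disease ontology's subtree structure correlates
with those communities.  The generator reproduces both features: it
assigns circRNAs and diseases to clusters uniformly at random, draws
each association independently with probability ``p_in`` when the
cluster labels match and ``p_out`` otherwise, and builds a single-rooted
DAG with one chain-shaped subtree per disease cluster so that semantic
similarity is higher within clusters than between them.  A fraction of
the positives is held out as recovery targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data_io import (
    AssociationMatrix,
    AssociationTable,
    DiseaseDAG,
    build_matrix,
    write_associations,
    write_dag,
)

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "default_fixture",
           "shuffle_within_columns"]


@dataclass
class SyntheticSpec:
    n_circrna: int = 200
    n_disease: int = 50
    n_clusters: int = 5
    p_in: float = 0.25
    p_out: float = 0.01
    dag_depth: int = 3
    holdout_fraction: float = 0.10
    seed: int = 17

    def __post_init__(self):
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.n_clusters > min(self.n_circrna, self.n_disease):
            raise ValueError("more clusters than entities")
        if self.dag_depth < 1:
            raise ValueError("dag_depth must be >= 1")


@dataclass
class SyntheticDataset:
    table: AssociationTable
    dag: DiseaseDAG
    circrna_clusters: np.ndarray
    disease_clusters: np.ndarray
    held_out: list[tuple[str, str]]
    spec: SyntheticSpec = field(default_factory=SyntheticSpec)

    def matrix(self) -> AssociationMatrix:
        return build_matrix(self.table)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_associations(self.table, outdir / "associations.tsv")
        write_dag(self.dag, outdir / "disease_dag.tsv")
        manifest = {
            "spec": asdict(self.spec),
            "circrna_clusters": self.circrna_clusters.tolist(),
            "disease_clusters": self.disease_clusters.tolist(),
            "held_out": [list(p) for p in self.held_out],
        }
        (outdir / "ground_truth.json").write_text(json.dumps(manifest, indent=1))


def _circ_id(i: int) -> str:
    return f"circ{i:04d}"


def _disease_id(j: int) -> str:
    return f"disease{j:03d}"


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a planted-partition bipartite dataset plus its aligned DAG."""
    rng = np.random.default_rng(spec.seed)
    circ_clusters = rng.integers(spec.n_clusters, size=spec.n_circrna)
    dis_clusters = rng.integers(spec.n_clusters, size=spec.n_disease)
    probs = np.where(circ_clusters[:, None] == dis_clusters[None, :],
                     spec.p_in, spec.p_out)
    adj = rng.random((spec.n_circrna, spec.n_disease)) < probs
    positives = [( _circ_id(i), _disease_id(j)) for i, j in np.argwhere(adj)]
    if not positives:
        raise ValueError("specification yields zero positive associations")
    n_hold = int(len(positives) * spec.holdout_fraction)
    held_idx = set(rng.choice(len(positives), size=n_hold, replace=False).tolist())
    held_out = [positives[i] for i in sorted(held_idx)]
    kept = [p for i, p in enumerate(positives) if i not in held_idx]
    table = AssociationTable(kept, provenance=f"synthetic(seed={spec.seed})")
    dag = _cluster_dag(dis_clusters, spec.dag_depth)
    return SyntheticDataset(table, dag, circ_clusters, dis_clusters, held_out, spec)


def _cluster_dag(dis_clusters: np.ndarray, depth: int) -> DiseaseDAG:
    """One root, one chain per cluster, diseases as leaves at ``depth``."""
    edges: list[tuple[str, str]] = []
    attach: dict[int, str] = {}
    for g in sorted(set(dis_clusters.tolist())):
        parent = "root"
        for level in range(1, depth):
            node = f"branch{g}_{level}"
            edges.append((node, parent))
            parent = node
        attach[g] = parent
    for j, g in enumerate(dis_clusters):
        edges.append((_disease_id(j), attach[int(g)]))
    return DiseaseDAG(edges)


def default_fixture() -> SyntheticDataset:
    """The documented test fixture: 200 x 50 entities, 5 clusters,
    p_in = 0.25, p_out = 0.01, DAG depth 3, 10% hold-out, seed 17."""
    return generate(SyntheticSpec())


def shuffle_within_columns(matrix: AssociationMatrix, seed: int = 0) -> AssociationMatrix:
    """Permute each disease column independently, destroying the
    circRNA-disease alignment while keeping per-disease prevalence."""
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    for j in range(values.shape[1]):
        values[:, j] = rng.permutation(values[:, j])
    return AssociationMatrix(values, matrix.circrna_index, matrix.disease_index)
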