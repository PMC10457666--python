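"""Reading, writing, and partitioning circRNA-disease association data.

Associations arrive as two-column text tables (circRNA id, disease id) in
the dialect the public curation databases export.  This module turns them
into a binary N x M adjacency matrix (rows = circRNAs, columns =
diseases, both sorted lexicographically), samples negative pairs from the
unknown cells, and produces the k-fold splits used by cross-validation.
All randomness is behind explicit integer seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AssociationTable",
    "AssociationMatrix",
    "DiseaseDAG",
    "PairSet",
    "FoldSplit",
    "read_associations",
    "write_associations",
    "read_dag",
    "write_dag",
    "build_matrix",
    "sample_negatives",
    "kfold_split",
    "count_unknown_pairs",
    "write_matrix",
    "read_matrix",
]


@dataclass
class AssociationTable:
    """Deduplicated list of (circrna_id, disease_id) records."""

    records: list[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self):
        seen: set[tuple[str, str]] = set()
        deduped = []
        for c, d in self.records:
            c, d = str(c).strip(), str(d).strip()
            if not c or not d:
                raise ValueError("association record with empty id")
            if (c, d) not in seen:
                seen.add((c, d))
                deduped.append((c, d))
        self.records = deduped

    def __len__(self) -> int:
        return len(self.records)

    def circrnas(self) -> list[str]:
        return sorted({c for c, _ in self.records})

    def diseases(self) -> list[str]:
        return sorted({d for _, d in self.records})


@dataclass
class AssociationMatrix:
    """Binary adjacency with ordered id -> index maps."""

    values: np.ndarray
    circrna_index: dict[str, int]
    disease_index: dict[str, int]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.circrna_index), len(self.disease_index)):
            raise ValueError("matrix shape does not match index sizes")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix entries must be 0/1")

    @property
    def n_circrna(self) -> int:
        return self.values.shape[0]

    @property
    def n_disease(self) -> int:
        return self.values.shape[1]

    def circrna_ids(self) -> list[str]:
        return list(self.circrna_index)

    def disease_ids(self) -> list[str]:
        return list(self.disease_index)

    def positive_pairs(self) -> list[tuple[int, int]]:
        return [(int(r), int(c)) for r, c in np.argwhere(self.values == 1)]

    def masked(self, pairs: list[tuple[int, int]]) -> "AssociationMatrix":
        """Copy with the given cells zeroed (e.g. held-out test positives)."""
        values = self.values.copy()
        for r, c in pairs:
            values[r, c] = 0
        return AssociationMatrix(values, self.circrna_index, self.disease_index)


@dataclass
class DiseaseDAG:
    """Child -> parent edge list of a disease ontology hierarchy."""

    edges: list[tuple[str, str]]

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for c, p in self.edges:
            out.add(c)
            out.add(p)
        return out

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes())
        # edge direction: child -> parent (toward the root)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("disease hierarchy contains a cycle")
        return g


@dataclass
class PairSet:
    positives: list[tuple[int, int]]
    negatives: list[tuple[int, int]]

    def __post_init__(self):
        self.positives = [(int(r), int(c)) for r, c in self.positives]
        self.negatives = [(int(r), int(c)) for r, c in self.negatives]
        if set(self.positives) & set(self.negatives):
            raise ValueError("positive and negative pairs overlap")


@dataclass
class FoldSplit:
    """k-fold assignment, kept separately for positives and negatives."""

    k: int
    seed: int
    positive_folds: list[list[tuple[int, int]]]
    negative_folds: list[list[tuple[int, int]]] = field(default_factory=list)

    def test_pairs(self, fold: int) -> tuple[list, list]:
        neg = self.negative_folds[fold] if self.negative_folds else []
        return self.positive_folds[fold], neg

    def train_pairs(self, fold: int) -> tuple[list, list]:
        pos = [p for f, fold_pairs in enumerate(self.positive_folds) if f != fold for p in fold_pairs]
        neg = [p for f, fold_pairs in enumerate(self.negative_folds) if f != fold for p in fold_pairs]
        return pos, neg

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "positive_folds": [[list(p) for p in f] for f in self.positive_folds],
            "negative_folds": [[list(p) for p in f] for f in self.negative_folds],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldSplit":
        payload = json.loads(Path(path).read_text())
        return cls(
            k=payload["k"],
            seed=payload["seed"],
            positive_folds=[[tuple(p) for p in f] for f in payload["positive_folds"]],
            negative_folds=[[tuple(p) for p in f] for f in payload["negative_folds"]],
        )


def read_associations(path: str | Path, dialect: str = "circrna_first") -> AssociationTable:
    """Read a two-column association list (TSV or CSV, optional header).

    ``dialect`` is ``"circrna_first"`` (default) or ``"disease_first"``.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty association file")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    records: list[tuple[str, str]] = []
    lines = text.splitlines()
    start = 1 if _looks_like_header(lines[0], sep) else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise ValueError(f"{path}:{lineno}: malformed association line {line!r}")
        a, b = parts[0], parts[1]
        records.append((a, b) if dialect == "circrna_first" else (b, a))
    return AssociationTable(records, provenance=str(path))


def _looks_like_header(line: str, sep: str) -> bool:
    lowered = [p.strip().lower() for p in line.split(sep)[:2]]
    keywords = ("circ", "rna", "disease", "id", "name")
    return all(any(k in cell for k in keywords) for cell in lowered)


def write_associations(table: AssociationTable, path: str | Path) -> None:
    lines = ["circrna_id\tdisease_id"]
    lines += [f"{c}\t{d}" for c, d in table.records]
    Path(path).write_text("\n".join(lines) + "\n")


def read_dag(path: str | Path) -> DiseaseDAG:
    df = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"], dtype=str)
    if df.isna().any().any():
        raise ValueError(f"{path}: malformed DAG edge list")
    dag = DiseaseDAG(list(df.itertuples(index=False, name=None)))
    dag.to_networkx()  # validates acyclicity
    return dag


def write_dag(dag: DiseaseDAG, path: str | Path) -> None:
    Path(path).write_text("\n".join(f"{c}\t{p}" for c, p in dag.edges) + "\n")


def build_matrix(table: AssociationTable) -> AssociationMatrix:
    """Binary adjacency from a table; ids ordered lexicographically."""
    if not table.records:
        raise ValueError("cannot build a matrix from an empty association table")
    circ = {c: i for i, c in enumerate(table.circrnas())}
    dis = {d: j for j, d in enumerate(table.diseases())}
    values = np.zeros((len(circ), len(dis)), dtype=np.int8)
    for c, d in table.records:
        values[circ[c], dis[d]] = 1
    return AssociationMatrix(values, circ, dis)


def sample_negatives(matrix: AssociationMatrix, count: int | None = None,
                     seed: int = 0) -> PairSet:
    """Uniform sample of unknown (zero) cells as negatives.

    ``count`` defaults to the number of positives, giving the balanced
    positive/negative design used for training and evaluation.
    """
    positives = matrix.positive_pairs()
    if count is None:
        count = len(positives)
    zeros = np.argwhere(matrix.values == 0)
    if count > len(zeros):
        raise ValueError(f"requested {count} negatives but only {len(zeros)} unknown cells exist")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(zeros), size=count, replace=False)
    negatives = [tuple(zeros[i]) for i in sorted(chosen)]
    return PairSet(positives=positives, negatives=negatives)


def kfold_split(pairs: PairSet, k: int = 5, seed: int = 0) -> FoldSplit:
    """Shuffle then partition positives and negatives into k near-equal folds."""
    if k < 2:
        raise ValueError("k must be at least 2")
    for name, cls in (("positives", pairs.positives), ("negatives", pairs.negatives)):
        if cls and len(cls) < k:
            raise ValueError(f"k={k} exceeds the number of {name} ({len(cls)})")
    rng = np.random.default_rng(seed)

    def split(items):
        if not items:
            return [[] for _ in range(k)]
        order = rng.permutation(len(items))
        return [[items[i] for i in order[f::k]] for f in range(k)]

    return FoldSplit(k=k, seed=seed, positive_folds=split(pairs.positives),
                     negative_folds=split(pairs.negatives))


def count_unknown_pairs(matrix: AssociationMatrix) -> int:
    """Number of cells with no recorded association (candidates to score)."""
    return int(matrix.values.size - matrix.values.sum())


def write_matrix(values: np.ndarray, row_ids: list[str], col_ids: list[str],
                 path: str | Path) -> None:
    pd.DataFrame(values, index=row_ids, columns=col_ids).to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns]
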