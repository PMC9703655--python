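"""Core data containers shared across the package.

Conventions: rows are cell lines, columns are features (or drugs). All id
lists are ordered and must be unique; matrices are float64 numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

OMICS_NAMES = ("expression", "mutation", "cnv", "rppa", "metabolomics")
EMBEDDING_KINDS = ("graph", "dense")


class FormatError(ValueError):
    """Malformed input table (duplicate ids, bad shape, non-finite values)."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class OmicsMatrix:
    """One omics block: a (cell lines x features) real matrix.

    ``embedding_kind`` records whether the block is meant to pass through an
    interactome-masked (graph) or an ordinary dense embedding layer.
    """

    omics_name: str
    cell_line_ids: list
    feature_ids: list
    values: np.ndarray
    embedding_kind: str = "dense"

    def __post_init__(self):
        if self.embedding_kind not in EMBEDDING_KINDS:
            raise ValueError(f"embedding_kind must be one of {EMBEDDING_KINDS}")
        self.cell_line_ids = list(self.cell_line_ids)
        self.feature_ids = list(self.feature_ids)
        _check_unique(self.cell_line_ids, "cell-line")
        _check_unique(self.feature_ids, "feature")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_line_ids), len(self.feature_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cell_line_ids)} cell lines x {len(self.feature_ids)} features"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError(f"non-finite entries in omics block {self.omics_name!r}")

    @property
    def n_cells(self) -> int:
        return len(self.cell_line_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_cells(self, ids) -> "OmicsMatrix":
        pos = {c: i for i, c in enumerate(self.cell_line_ids)}
        idx = [pos[c] for c in ids]
        return OmicsMatrix(self.omics_name, list(ids), self.feature_ids,
                           self.values[idx], self.embedding_kind)

    def subset_features(self, ids) -> "OmicsMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in pos]
        if missing:
            raise KeyError(f"features absent from block {self.omics_name!r}: "
                           f"{missing[:5]}")
        idx = [pos[f] for f in ids]
        return OmicsMatrix(self.omics_name, self.cell_line_ids, list(ids),
                           self.values[:, idx], self.embedding_kind)


@dataclass
class InteractomeEdges:
    """Undirected protein-protein interaction edge set.

    Edges are stored as canonically ordered symbol pairs, so (a, b) and
    (b, a) are the same edge and self-loops are allowed but not duplicated.
    """

    edges: set = field(default_factory=set)

    def __post_init__(self):
        self.edges = {self.canonical(a, b) for a, b in self.edges}

    @staticmethod
    def canonical(a: str, b: str) -> tuple:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str) -> None:
        self.edges.add(self.canonical(a, b))

    def has_edge(self, a: str, b: str) -> bool:
        return self.canonical(a, b) in self.edges

    @property
    def node_symbols(self) -> set:
        out = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class DrugResponseTable:
    """log IC50 responses (cell lines x drugs) with an observed-entry mask."""

    cell_line_ids: list
    drug_ids: list
    values: np.ndarray
    observed_mask: np.ndarray

    def __post_init__(self):
        self.cell_line_ids = list(self.cell_line_ids)
        self.drug_ids = list(self.drug_ids)
        _check_unique(self.cell_line_ids, "cell-line")
        _check_unique(self.drug_ids, "drug")
        self.values = np.asarray(self.values, dtype=np.float64)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        shape = (len(self.cell_line_ids), len(self.drug_ids))
        if self.values.shape != shape:
            raise FormatError(f"response values shape {self.values.shape} != {shape}")
        if self.observed_mask.shape != self.values.shape:
            raise FormatError("observed_mask shape differs from values shape")
        if not np.all(np.isfinite(self.values[self.observed_mask])):
            raise FormatError("non-finite observed response entries")

    @property
    def n_cells(self) -> int:
        return len(self.cell_line_ids)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    def subset_cells(self, ids) -> "DrugResponseTable":
        pos = {c: i for i, c in enumerate(self.cell_line_ids)}
        idx = [pos[c] for c in ids]
        return DrugResponseTable(list(ids), self.drug_ids,
                                 self.values[idx], self.observed_mask[idx])

    def subset_drugs(self, ids) -> "DrugResponseTable":
        pos = {d: i for i, d in enumerate(self.drug_ids)}
        idx = [pos[d] for d in ids]
        return DrugResponseTable(self.cell_line_ids, list(ids),
                                 self.values[:, idx], self.observed_mask[:, idx])


@dataclass
class AdjacencyMatrix:
    """Binary interactome affinity matrix A aligned to a feature ordering.

    Symmetric with unit diagonal: each feature always reaches its own hidden
    unit, so no unit of the graph embedding is fully disconnected.
    """

    feature_ids: list
    A: np.ndarray

    def __post_init__(self):
        self.feature_ids = list(self.feature_ids)
        _check_unique(self.feature_ids, "feature")
        self.A = np.asarray(self.A, dtype=np.float64)
        n = len(self.feature_ids)
        if self.A.shape != (n, n):
            raise FormatError(f"adjacency shape {self.A.shape} != ({n}, {n})")
        if not np.array_equal(self.A, self.A.T):
            raise FormatError("adjacency matrix is not symmetric")
        if not np.all(np.isin(self.A, (0.0, 1.0))):
            raise FormatError("adjacency entries must be binary")
        if not np.all(np.diag(self.A) == 1.0):
            raise FormatError("adjacency diagonal must be all ones")


@dataclass
class StandardizationStats:
    """Per-feature location/scale fitted on training cell lines only."""

    feature_ids: list
    mean: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        self.feature_ids = list(self.feature_ids)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.scale = np.asarray(self.scale, dtype=np.float64)
        n = len(self.feature_ids)
        if self.mean.shape != (n,) or self.scale.shape != (n,):
            raise FormatError("stats shape does not match feature ids")
        if np.any(self.scale <= 0):
            raise ValueError("standardization scale must be positive")


@dataclass
class MultiOmicsDataset:
    """M omics blocks + responses sharing one cell-line ordering.

    ``adjacency`` maps the name of each graph-embedded block to its
    AdjacencyMatrix (feature order identical to the block's).
    """

    omics_blocks: list
    responses: DrugResponseTable
    adjacency: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.omics_blocks) < 1:
            raise ValueError("need at least one omics block")
        ref = self.responses.cell_line_ids
        for b in self.omics_blocks:
            if b.cell_line_ids != ref:
                raise FormatError(
                    f"cell-line ordering of block {b.omics_name!r} differs from responses"
                )
        names = [b.omics_name for b in self.omics_blocks]
        _check_unique(names, "omics block")
        for name, adj in self.adjacency.items():
            block = self.block(name)
            if adj.feature_ids != block.feature_ids:
                raise FormatError(f"adjacency feature order differs from block {name!r}")

    @property
    def n_blocks(self) -> int:
        return len(self.omics_blocks)

    @property
    def cell_line_ids(self) -> list:
        return self.responses.cell_line_ids

    def block(self, name: str) -> OmicsMatrix:
        for b in self.omics_blocks:
            if b.omics_name == name:
                return b
        raise KeyError(name)

    def block_names(self) -> list:
        return [b.omics_name for b in self.omics_blocks]

    def subset_cells(self, ids) -> "MultiOmicsDataset":
        return MultiOmicsDataset(
            [b.subset_cells(ids) for b in self.omics_blocks],
            self.responses.subset_cells(ids),
            self.adjacency,
        )

    def select_blocks(self, names) -> "MultiOmicsDataset":
        blocks = [self.block(n) for n in names]
        adj = {n: self.adjacency[n] for n in names if n in self.adjacency}
        return MultiOmicsDataset(blocks, self.responses, adj)
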