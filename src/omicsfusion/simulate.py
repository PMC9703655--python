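"""Synthetic multi-omics generator with a planted, recoverable signal.

The generator emulates the structure of the cell-line drug-screening setting:
M omics blocks over a shared cell-line panel, an Erdos-Renyi interactome over
the gene-level features, and per-drug log-IC50 responses built as a linear
combination of per-omics scores. One designated block (by default the
mutation block, with share ``dominance``) drives most of the response
variance, so attention analysis and ablation have a known right answer.

Responses follow

    y_ij = sum_m sqrt(share_m) * s_m(i, j) + eps,   eps ~ N(0, noise_sd^2)

where s_m is a unit-variance linear score of block m's (standardized,
optionally graph-smoothed) features with a drug-specific sparse coefficient
vector. Default sizes follow the real study conditions where they are
desk-scale (522 cell lines, 22 drugs, 215 RPPA proteins, 227 metabolites,
<5%% missing responses); the gene-level blocks are scaled to 300 genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .datatypes import (
    DrugResponseTable,
    InteractomeEdges,
    MultiOmicsDataset,
    OmicsMatrix,
)
from .preprocess import build_adjacency

DEFAULT_FEATURE_COUNTS = {
    "expression": 300,
    "mutation": 300,
    "cnv": 300,
    "rppa": 215,
    "metabolomics": 227,
}
DEFAULT_EMBEDDING_KINDS = {
    "expression": "graph",
    "mutation": "graph",
    "cnv": "graph",
    "rppa": "dense",
    "metabolomics": "dense",
}


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic generator.

    ``dominance`` is the fraction of response signal variance carried by
    ``dominant_omics``; the remaining share is split evenly across the other
    blocks. ``graph_signal`` makes the scores of graph-embedded blocks depend
    on interactome-smoothed features, so the planted signal actually
    propagates along the known graph.
    """

    n_cells: int = 522
    feature_counts: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_COUNTS))
    embedding_kinds: dict = field(default_factory=lambda: dict(DEFAULT_EMBEDDING_KINDS))
    edge_prob: float = 0.03
    dominant_omics: str = "mutation"
    dominance: float = 0.9
    n_drugs: int = 22
    noise_sd: float = 0.3
    missing_rate: float = 0.03
    graph_signal: bool = True
    coef_density: float = 0.1
    mutation_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1 or self.n_drugs < 1:
            raise ValueError("counts must be >= 1")
        if any(c < 1 for c in self.feature_counts.values()):
            raise ValueError("feature counts must be >= 1")
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ValueError("edge_prob must be in [0, 1]")
        if not 0.0 <= self.dominance <= 1.0:
            raise ValueError("dominance must be in [0, 1]")
        if self.dominant_omics not in self.feature_counts:
            raise ValueError(f"dominant omics {self.dominant_omics!r} has no block")
        if len(self.feature_counts) == 1 and self.dominance != 1.0:
            raise ValueError("a single block must carry dominance 1.0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 < self.coef_density <= 1.0:
            raise ValueError("coef_density must be in (0, 1]")
        for name, kind in self.embedding_kinds.items():
            if kind not in ("graph", "dense"):
                raise ValueError(f"bad embedding kind {kind!r} for {name!r}")

    @property
    def shares(self) -> dict:
        """Per-block signal variance shares; they sum to one."""
        names = list(self.feature_counts)
        others = [n for n in names if n != self.dominant_omics]
        rest = (1.0 - self.dominance) / len(others) if others else 0.0
        out = {n: rest for n in others}
        out[self.dominant_omics] = self.dominance
        return out


def simulate_interactome(n_genes: int, edge_prob: float,
                         seed: Union[int, np.random.Generator],
                         symbols: Optional[list] = None) -> InteractomeEdges:
    """Erdos-Renyi interactome: each unordered gene pair is an edge
    independently with probability ``edge_prob``."""
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if symbols is None:
        symbols = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    iu, ju = np.triu_indices(n_genes, k=1)
    pick = rng.random(iu.shape[0]) < edge_prob
    edges = InteractomeEdges()
    for i, j in zip(iu[pick], ju[pick]):
        edges.add(symbols[i], symbols[j])
    return edges


def _feature_symbols(name: str, n: int) -> list:
    prefix = {"rppa": "P", "metabolomics": "MET"}.get(name)
    if prefix is None:
        return [f"G{i:04d}" for i in range(1, n + 1)]   # shared gene namespace
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def simulate_dataset(cfg: SimulationConfig) -> tuple[MultiOmicsDataset, dict]:
    """Draw one dataset plus the ground truth needed to verify recovery.

    Continuous blocks are standard normal per feature; the mutation block is
    Bernoulli(mutation_rate) indicators. The ground-truth dict records the
    signal shares, the per-drug coefficient vectors (on the standardized,
    smoothed feature scale), the interactome and the noiseless scores.
    """
    rng = np.random.default_rng(cfg.seed)
    names = list(cfg.feature_counts)
    cells = [f"CL{i:04d}" for i in range(1, cfg.n_cells + 1)]
    drugs = [f"D{j:02d}" for j in range(1, cfg.n_drugs + 1)]

    gene_blocks = [n for n in names if _feature_symbols(n, 1)[0].startswith("G")]
    n_genes = max((cfg.feature_counts[n] for n in gene_blocks), default=0)
    edges = (simulate_interactome(n_genes, cfg.edge_prob, rng)
             if n_genes else InteractomeEdges())

    shares = cfg.shares
    blocks, adjacency, coefficients, scores = [], {}, {}, {}
    y = np.zeros((cfg.n_cells, cfg.n_drugs))
    for name in names:
        n_m = cfg.feature_counts[name]
        feats = _feature_symbols(name, n_m)
        if name == "mutation":
            X = (rng.random((cfg.n_cells, n_m)) < cfg.mutation_rate).astype(np.float64)
            p = cfg.mutation_rate
            Z = (X - p) / np.sqrt(p * (1 - p))
        else:
            X = rng.standard_normal((cfg.n_cells, n_m))
            Z = X
        kind = cfg.embedding_kinds.get(name, "dense")
        blocks.append(OmicsMatrix(name, cells, feats, X, kind))

        if kind == "graph":
            adj = build_adjacency(edges, feats)
            adjacency[name] = adj
        if kind == "graph" and cfg.graph_signal:
            # column-normalized smoothing: unit j averages its interactors
            Asm = adj.A / adj.A.sum(axis=0, keepdims=True)
            S_in = Z @ Asm
            C = Asm.T @ Asm          # population covariance of smoothed features
        else:
            S_in = Z
            C = None                 # identity

        B = np.zeros((n_m, cfg.n_drugs))
        for j in range(cfg.n_drugs):
            support = rng.random(n_m) < cfg.coef_density
            if not support.any():
                support[rng.integers(n_m)] = True
            c = np.where(support, rng.standard_normal(n_m), 0.0)
            var = c @ C @ c if C is not None else c @ c
            B[:, j] = c / np.sqrt(var)
        s = S_in @ B                 # (n_cells, n_drugs), unit variance per drug
        coefficients[name] = B
        scores[name] = s
        y += np.sqrt(shares[name]) * s

    y_noiseless = y.copy()
    if cfg.noise_sd > 0:
        y = y + cfg.noise_sd * rng.standard_normal(y.shape)
    mask = rng.random(y.shape) >= cfg.missing_rate

    responses = DrugResponseTable(cells, drugs, y, mask)
    dataset = MultiOmicsDataset(blocks, responses, adjacency)
    ground_truth = {
        "shares": shares,
        "dominant_omics": cfg.dominant_omics,
        "coefficients": coefficients,
        "scores": scores,
        "y_noiseless": y_noiseless,
        "edges": edges,
        "graph_signal": cfg.graph_signal,
        "noise_sd": cfg.noise_sd,
    }
    return dataset, ground_truth


def ground_truth_to_jsonable(gt: dict) -> dict:
    """Ground truth as plain lists for a JSON sidecar file."""
    return {
        "shares": gt["shares"],
        "dominant_omics": gt["dominant_omics"],
        "graph_signal": bool(gt["graph_signal"]),
        "noise_sd": float(gt["noise_sd"]),
        "coefficients": {k: v.tolist() for k, v in gt["coefficients"].items()},
        "edges": sorted(list(e) for e in gt["edges"].edges),
    }
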