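"""Feature filtering, standardization, cell-line alignment, drug selection
and interactome adjacency construction.

The filters follow the strict ">" reading of the "over 95%" rules: a feature
is dropped when its zero fraction strictly exceeds the threshold, and a drug
is kept when its coverage strictly exceeds the threshold.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .datatypes import (
    AdjacencyMatrix,
    DrugResponseTable,
    InteractomeEdges,
    MultiOmicsDataset,
    OmicsMatrix,
    StandardizationStats,
)


class EmptyBlockError(ValueError):
    """A filter or intersection left no features / drugs / cell lines."""


def filter_low_information_features(m: OmicsMatrix,
                                    zero_fraction: float = 0.95) -> OmicsMatrix:
    """Drop features that are exactly zero in strictly more than
    ``zero_fraction`` of the cell lines (expression with no signal, mutations
    or CNV with no effect). Survivor order is preserved; idempotent."""
    if not 0.0 < zero_fraction <= 1.0:
        raise ValueError("zero_fraction must be in (0, 1]")
    frac_zero = np.mean(m.values == 0.0, axis=0)
    keep = frac_zero <= zero_fraction
    if not keep.any():
        raise EmptyBlockError(
            f"empty omics block: every feature of {m.omics_name!r} is zero in "
            f"more than {zero_fraction:.0%} of cell lines"
        )
    features = [f for f, k in zip(m.feature_ids, keep) if k]
    return OmicsMatrix(m.omics_name, m.cell_line_ids, features,
                       m.values[:, keep], m.embedding_kind)


def standardize(m: OmicsMatrix,
                stats: Optional[StandardizationStats] = None
                ) -> tuple[OmicsMatrix, StandardizationStats]:
    """Per-feature (x - mean) / scale.

    With ``stats=None`` the mean and sample standard deviation (ddof=1) are
    computed from the given rows (the training fold); otherwise the supplied
    training statistics are applied unchanged (the test-fold path). Constant
    features get scale 1 so they map to zeros instead of dividing by zero.
    """
    if stats is None:
        mean = m.values.mean(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # n_cells == 1
            sd = m.values.std(axis=0, ddof=1)
        sd = np.where(np.isfinite(sd) & (sd > 0), sd, 1.0)
        stats = StandardizationStats(m.feature_ids, mean, sd)
    elif stats.feature_ids != m.feature_ids:
        raise ValueError(
            f"standardization stats feature ids do not match block {m.omics_name!r}"
        )
    out = OmicsMatrix(m.omics_name, m.cell_line_ids, m.feature_ids,
                      (m.values - stats.mean) / stats.scale, m.embedding_kind)
    return out, stats


def align_cell_lines(blocks: list, responses: DrugResponseTable,
                     adjacency: Optional[dict] = None) -> MultiOmicsDataset:
    """Keep only cell lines present in every omics block and the response
    table, re-indexed to a deterministic sorted order."""
    if len(blocks) < 1:
        raise ValueError("need at least one omics block")
    common = set(responses.cell_line_ids)
    for b in blocks:
        common &= set(b.cell_line_ids)
    if not common:
        raise EmptyBlockError("no cell line is present in all omics blocks and responses")
    order = sorted(common)
    return MultiOmicsDataset(
        [b.subset_cells(order) for b in blocks],
        responses.subset_cells(order),
        adjacency or {},
    )


def select_top_drugs(r: DrugResponseTable, coverage: float = 0.95,
                     k: Optional[int] = None) -> DrugResponseTable:
    """Keep drugs tested on strictly more than ``coverage`` of the cell
    lines; with ``k`` given, keep the k highest-coverage survivors (ties
    broken by drug id). coverage=0 disables the coverage filter. Survivors
    keep their input order."""
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    cov = r.observed_mask.mean(axis=0)
    if coverage > 0.0:
        keep = [d for d, c in zip(r.drug_ids, cov) if c > coverage]
    else:
        keep = list(r.drug_ids)
    if not keep:
        raise EmptyBlockError(
            f"no drug is observed in more than {coverage:.0%} of cell lines"
        )
    if k is not None:
        if k < 1:
            raise ValueError("k must be >= 1")
        covmap = dict(zip(r.drug_ids, cov))
        ranked = sorted(keep, key=lambda d: (-covmap[d], d))[:k]
        keep = [d for d in keep if d in set(ranked)]
    return r.subset_drugs(keep)


def build_adjacency(edges: InteractomeEdges, feature_ids) -> AdjacencyMatrix:
    """Binary affinity matrix over ``feature_ids``: A[i, j] = 1 iff the
    features interact or i == j. Features absent from the interactome keep
    only the self-loop, so no embedding unit is fully disconnected."""
    feature_ids = list(feature_ids)
    n = len(feature_ids)
    pos = {f: i for i, f in enumerate(feature_ids)}
    A = np.eye(n)
    for a, b in edges.edges:
        i, j = pos.get(a), pos.get(b)
        if i is not None and j is not None:
            A[i, j] = 1.0
            A[j, i] = 1.0
    return AdjacencyMatrix(feature_ids, A)
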