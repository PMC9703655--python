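"""Evaluation statistics for drug-response prediction.

MSE over observed entries, the per-drug-averaged coefficient of
determination

    R^2 = (1/n_d) sum_j [ 1 - sum_i (y_ij - yhat_ij)^2 / sum_i (y_ij - ybar_j)^2 ]

with ybar_j the mean observed response of drug j on the evaluated set, and
Top-k drug accuracy: the rate at which a cell line's truly most effective
drug (lowest observed true log IC50) appears among the k drugs with the
lowest predicted values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class PredictionSet:
    """Aligned predictions/truths with an observed-entry mask."""

    predictions: np.ndarray
    truths: np.ndarray
    observed_mask: np.ndarray
    drug_ids: list
    cell_line_ids: list

    def __post_init__(self):
        self.predictions = np.asarray(self.predictions, dtype=np.float64)
        self.truths = np.asarray(self.truths, dtype=np.float64)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        shape = (len(self.cell_line_ids), len(self.drug_ids))
        for name, a in (("predictions", self.predictions), ("truths", self.truths),
                        ("observed_mask", self.observed_mask)):
            if a.shape != shape:
                raise ValueError(f"{name} shape {a.shape} != {shape}")


def mse(ps: PredictionSet) -> float:
    """Mean squared error over observed entries (equals the all-entry
    average 1/(n_c n_d) sum sum (y - yhat)^2 when fully observed)."""
    m = ps.observed_mask
    n = int(m.sum())
    if n == 0:
        raise ValueError("mse: no observed entries")
    d = ps.truths[m] - ps.predictions[m]
    return float(d @ d / n)


def r_squared(ps: PredictionSet) -> float:
    """Per-drug-averaged R^2 over observed entries; range (-inf, 1].

    Drugs whose observed truths are constant (or with <2 observations) are
    excluded with a warning, since their total sum of squares is zero.
    """
    vals = []
    for j, drug in enumerate(ps.drug_ids):
        m = ps.observed_mask[:, j]
        y = ps.truths[m, j]
        if y.size < 2 or np.all(y == y[0]):
            warnings.warn(
                f"drug {drug!r} excluded from R^2: constant or <2 observed truths"
            )
            continue
        yhat = ps.predictions[m, j]
        ss_res = np.sum((y - yhat) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        vals.append(1.0 - ss_res / ss_tot)
    if not vals:
        raise ValueError("r_squared: no drug with non-constant observed truths")
    return float(np.mean(vals))


def _ranked_drugs(values: np.ndarray, observed: np.ndarray, drug_ids: list) -> list:
    """Observed drug indices sorted ascending by value, ties by drug id."""
    idx = np.flatnonzero(observed)
    return sorted(idx, key=lambda j: (values[j], drug_ids[j]))


def top_k_accuracy(ps: PredictionSet, k: int) -> float:
    """Percentage of cell lines whose truly most effective drug is among the
    k lowest predicted log IC50 values (observed drugs only).

    Ties are broken by drug-id order; cell lines with no observed drug are
    excluded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = 0
    n_eval = 0
    for i in range(len(ps.cell_line_ids)):
        obs = ps.observed_mask[i]
        if not obs.any():
            continue
        n_eval += 1
        best_true = _ranked_drugs(ps.truths[i], obs, ps.drug_ids)[0]
        top_pred = _ranked_drugs(ps.predictions[i], obs, ps.drug_ids)[:k]
        if best_true in top_pred:
            hits += 1
    if n_eval == 0:
        raise ValueError("top_k_accuracy: no cell line with observed drugs")
    return 100.0 * hits / n_eval


def per_drug_mse_ranking(ps: PredictionSet) -> list:
    """(drug, MSE) pairs ordered by ascending per-drug MSE, ties by drug id."""
    rows = []
    for j, drug in enumerate(ps.drug_ids):
        m = ps.observed_mask[:, j]
        if not m.any():
            continue
        d = ps.truths[m, j] - ps.predictions[m, j]
        rows.append((drug, float(d @ d / m.sum())))
    rows.sort(key=lambda t: (t[1], t[0]))
    return rows


@dataclass
class EvaluationReport:
    """Bundle of the headline statistics for one prediction set."""

    mse: float
    r2: float
    top1_pct: float
    top3_pct: float
    per_drug_mse: list
    attention_scores: Optional[pd.DataFrame] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"value": [self.mse, self.r2, self.top1_pct, self.top3_pct]},
            index=["MSE", "R2", "Top-1 (%)", "Top-3 (%)"],
        )


def evaluate_predictions(ps: PredictionSet,
                         attention_scores: Optional[pd.DataFrame] = None
                         ) -> EvaluationReport:
    return EvaluationReport(
        mse=mse(ps),
        r2=r_squared(ps),
        top1_pct=top_k_accuracy(ps, 1),
        top3_pct=top_k_accuracy(ps, 3),
        per_drug_mse=per_drug_mse_ranking(ps),
        attention_scores=attention_scores,
    )


def attention_report(scores: np.ndarray, omics_labels: list, drug_labels: list,
                     out_tsv=None, out_png=None, atol: float = 1e-6
                     ) -> pd.DataFrame:
    """Tabulate (and optionally plot) per-omics attention scores.

    ``scores`` is (M x n_d); each drug's column must sum to 1 within
    ``atol`` (the softmax normalization), otherwise this raises. The values
    are written untransformed.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (len(omics_labels), len(drug_labels)):
        raise ValueError(
            f"scores shape {scores.shape} != ({len(omics_labels)}, {len(drug_labels)})"
        )
    colsums = scores.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > atol):
        raise ValueError("attention scores columns must each sum to 1")
    df = pd.DataFrame(scores, index=list(omics_labels), columns=list(drug_labels))
    if out_tsv is not None:
        df.to_csv(out_tsv, sep="\t")
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(6.0, 0.35 * len(drug_labels)), 1.0 + 0.5 * len(omics_labels))
        )
        im = ax.imshow(scores, aspect="auto", cmap="viridis", vmin=0.0, vmax=1.0)
        ax.set_xticks(range(len(drug_labels)), drug_labels, rotation=90, fontsize=7)
        ax.set_yticks(range(len(omics_labels)), omics_labels)
        ax.set_xlabel("drug")
        fig.colorbar(im, ax=ax, label="attention score")
        fig.tight_layout()
        fig.savefig(out_png, dpi=150)
        plt.close(fig)
    return df
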