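"""Planted-signal recovery study on synthetic data.

This is the package's standing correctness experiment: simulate a
three-block multi-omics panel whose drug responses are driven mostly
(share 0.9) by the mutation block, run the full two-stage pipeline under
cross-validation, and check that (i) the attention layer recovers the
dominant block, (ii) ablation ranks every mutation-containing combination
above every combination without it, and (iii) the test R^2 stays close to a
ridge-regression oracle fitted on all blocks.

Study design notes (see docs/methods.md for the full rationale): the three
blocks are the gene-level graph-embedded omics so that all sub-networks get
identical epoch budgets; panels are targeted-panel sized (60-100 genes,
p/n < 0.25) so stage-1 fits are well-determined; and the training
configuration uses early stopping with no dropout, since the default
dropout rates are calibrated for real omics three orders of magnitude
wider.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .metrics import PredictionSet, r_squared
from .preprocess import standardize
from .simulate import SimulationConfig, simulate_dataset
from .training import TrainingConfig, ablation_run, cross_validate, make_folds

RECOVERY_FEATURES = {"expression": 80, "mutation": 100, "cnv": 60}

RECOVERY_SIMULATION = dict(
    n_cells=600,
    feature_counts=RECOVERY_FEATURES,
    embedding_kinds={name: "graph" for name in RECOVERY_FEATURES},
    dominant_omics="mutation",
    dominance=0.9,
    n_drugs=22,
    noise_sd=0.3,
    missing_rate=0.03,
)

RECOVERY_TRAINING = dict(
    dropout={name: 0.0 for name in RECOVERY_FEATURES},
    default_dropout=0.0,
    early_stopping=True,
)


def recovery_simulation_config(seed: int) -> SimulationConfig:
    return SimulationConfig(**RECOVERY_SIMULATION, seed=seed)


def recovery_training_config() -> TrainingConfig:
    return TrainingConfig(**RECOVERY_TRAINING)


def ridge_oracle_r2(dataset, seed: int, n_folds: int = 3,
                    alpha: float = 1.0) -> float:
    """Per-drug ridge regression on all blocks concatenated, evaluated with
    the same fold partition the network's cross-validation uses."""
    from sklearn.linear_model import Ridge

    resp = dataset.responses
    rng = np.random.default_rng(seed)
    folds = make_folds(resp.n_cells, n_folds, rng)
    r2s = []
    for f, test_idx in enumerate(folds):
        train_idx = np.sort(np.concatenate(
            [folds[g] for g in range(n_folds) if g != f]))
        tr_ids = [resp.cell_line_ids[i] for i in train_idx]
        te_ids = [resp.cell_line_ids[i] for i in test_idx]
        Xtr_parts, Xte_parts = [], []
        for block in dataset.omics_blocks:
            trb, st = standardize(block.subset_cells(tr_ids))
            teb, _ = standardize(block.subset_cells(te_ids), st)
            Xtr_parts.append(trb.values)
            Xte_parts.append(teb.values)
        Xtr, Xte = np.hstack(Xtr_parts), np.hstack(Xte_parts)
        Ytr, Mtr = resp.values[train_idx], resp.observed_mask[train_idx]
        Yte, Mte = resp.values[test_idx], resp.observed_mask[test_idx]
        pred = np.zeros_like(Yte)
        for j in range(resp.n_drugs):
            m = Mtr[:, j]
            pred[:, j] = Ridge(alpha=alpha).fit(Xtr[m], Ytr[m, j]).predict(Xte)
        r2s.append(r_squared(PredictionSet(pred, Yte, Mte, resp.drug_ids, te_ids)))
    return float(np.mean(r2s))


def run_recovery_study(seed: int, include_ablation: bool = True) -> dict:
    """Run the full study and return its measured quantities.

    Both the simulation and the training folds derive their seeds from
    ``seed``; the returned dict holds the cross-validated test metrics, the
    dominant block's attention summary, the ridge oracle and (optionally)
    the ablation table plus a flag for the dominant-block ordering.
    """
    sim_seed = int(seed) % (2 ** 31)
    cv_seed = (int(seed) + 10007) % (2 ** 31)
    sim_cfg = recovery_simulation_config(sim_seed)
    train_cfg = recovery_training_config()
    dataset, ground_truth = simulate_dataset(sim_cfg)
    dominant = ground_truth["dominant_omics"]

    cv = cross_validate(dataset, train_cfg, seed=cv_seed)
    mean_att = cv.mean_attention()
    out = {
        "dominant_omics": dominant,
        "cv_mse": float(cv.mean["mse"]),
        "cv_r2": float(cv.mean["r2"]),
        "cv_top1_pct": float(cv.mean["top1"]),
        "cv_top3_pct": float(cv.mean["top3"]),
        "dominant_attention_mean": float(mean_att.loc[dominant].mean()),
        "dominant_argmax_fraction": float(
            (mean_att.idxmax(axis=0) == dominant).mean()),
        "ridge_oracle_r2": ridge_oracle_r2(dataset, cv_seed,
                                           train_cfg.n_folds),
        "n_cells": sim_cfg.n_cells,
        "n_drugs": sim_cfg.n_drugs,
        "attention_by_omics": {k: float(v)
                               for k, v in mean_att.mean(axis=1).items()},
    }
    if include_ablation:
        table = ablation_run(dataset, train_cfg, seed=cv_seed)
        with_dom = table[table["combination"].str.split("-")
                         .map(lambda c: dominant in c)]
        without_dom = table[~table["combination"].str.split("-")
                            .map(lambda c: dominant in c)]
        out["ablation_table"] = table
        out["ablation_dominant_outranks_all"] = bool(
            with_dom["mse"].max() < without_dom["mse"].min())
    return out
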