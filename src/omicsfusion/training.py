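"""Two-stage optimization of the fusion network.

Stage 1 trains each omics sub-network alone to predict all drug responses
(masked MSE, Adam). Stage 2 freezes every sub-network and learns only the
attention logits and the output bias; the freeze is asserted on every run by
hashing the sub-network parameters before and after.

Gradients are derived by hand for the three-layer sub-network and for the
kill-matrix attention layer; because the kill matrix zeroes every
off-diagonal normalized weight, only the n_d x M diagonal logits
W3(d, m, d) receive gradient and are optimized.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import MultiOmicsDataset, OmicsMatrix
from .layers import (
    AttentionParams,
    SubNetworkParams,
    dropout_mask,
    fuse_and_predict,
    attention_scores,
    init_attention_params,
    init_subnetwork_params,
    subnetwork_forward,
)
from .metrics import PredictionSet, mse, r_squared, top_k_accuracy
from .preprocess import standardize

DEFAULT_DROPOUT = {
    "expression": 0.2, "mutation": 0.2, "metabolomics": 0.2,
    "cnv": 0.4, "rppa": 0.4,
}
DEFAULT_HIDDEN = {
    "expression": 64, "metabolomics": 64, "mutation": 32, "cnv": 32, "rppa": 128,
}
DEFAULT_EMBED = {"metabolomics": 200}


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class TrainingConfig:
    """Optimization hyperparameters.

    Defaults: Adam at learning rate 0.001,
    ~200 epochs for graph-embedded sub-networks vs ~1000 for dense ones,
    per-omics dropout 0.2 (expression/mutation/metabolomics) or 0.4
    (CNV/RPPA), hidden sizes 64/32/32/128/64 and a 200-unit dense embedding
    for metabolomics, with three-fold cross-validation. Minibatches of 32
    cell lines are used so the fixed epoch budgets translate into enough
    optimizer steps (``batch_size=None`` gives full-batch).
    """

    learning_rate: float = 0.001
    epochs_graph: int = 200
    epochs_dense: int = 1000
    epochs_attention: int = 200
    batch_size: Optional[int] = 32
    dropout: dict = field(default_factory=lambda: dict(DEFAULT_DROPOUT))
    hidden_sizes: dict = field(default_factory=lambda: dict(DEFAULT_HIDDEN))
    embedding_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EMBED))
    default_dropout: float = 0.2
    default_hidden: int = 64
    n_folds: int = 3
    seed: int = 0
    early_stopping: bool = False
    val_fraction: float = 0.1
    patience: int = 25

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        for name in ("epochs_graph", "epochs_dense", "epochs_attention"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1 or None")
        for v in list(self.dropout.values()) + [self.default_dropout]:
            if not 0.0 <= v < 1.0:
                raise ValueError("dropout rates must be in [0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    def dropout_for(self, omics_name: str) -> float:
        return self.dropout.get(omics_name, self.default_dropout)

    def hidden_for(self, omics_name: str) -> int:
        return self.hidden_sizes.get(omics_name, self.default_hidden)

    def embed_for(self, omics_name: str, n_features: int) -> int:
        return self.embedding_sizes.get(omics_name, n_features)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        return cls(**d)


class Adam:
    """Adaptive-moment optimizer updating a list of arrays in place."""

    def __init__(self, params: list, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def masked_mse_loss(pred: np.ndarray, truth: np.ndarray,
                    mask: np.ndarray) -> float:
    """Mean squared error over entries where ``mask`` is true."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if pred.shape != truth.shape or pred.shape != mask.shape:
        raise ValueError("pred, truth and mask must share one shape")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("masked_mse_loss: mask is all false")
    d = pred[mask] - truth[mask]
    return float(d @ d / n)


def _subnet_loss_and_grads(p: SubNetworkParams, X, Y, Mk,
                           rng: Optional[np.random.Generator]):
    """Forward + hand-derived backward pass; rng=None disables dropout."""
    Weff = p.W1 * p.A if p.A is not None else p.W1
    Z1 = X @ Weff + p.b1
    H1 = np.maximum(Z1, 0.0)
    m1 = dropout_mask(rng, H1.shape, p.dropout_embed) if rng is not None else 1.0
    D1 = H1 * m1
    Z2 = D1 @ p.W2 + p.b2
    H2 = np.maximum(Z2, 0.0)
    m2 = dropout_mask(rng, H2.shape, p.dropout_hidden) if rng is not None else 1.0
    D2 = H2 * m2
    O = D2 @ p.Wh + p.bh

    cnt = int(Mk.sum())
    R = (O - Y) * Mk
    loss = float((R * R).sum() / cnt)

    dO = 2.0 * R / cnt
    dWh = D2.T @ dO
    dbh = dO.sum(axis=0)
    dZ2 = (dO @ p.Wh.T) * m2 * (Z2 > 0)
    dW2 = D1.T @ dZ2
    db2 = dZ2.sum(axis=0)
    dZ1 = (dZ2 @ p.W2.T) * m1 * (Z1 > 0)
    dW1 = X.T @ dZ1
    if p.A is not None:
        dW1 = dW1 * p.A      # masked entries never move
    db1 = dZ1.sum(axis=0)
    return loss, [dW1, db1, dW2, db2, dWh, dbh]


def _batches(idx: np.ndarray, batch_size: Optional[int], rng: np.random.Generator):
    perm = rng.permutation(idx)
    b = batch_size or len(idx)
    for start in range(0, len(idx), b):
        yield perm[start:start + b]


def _holdout_split(n: int, cfg: TrainingConfig, rng: np.random.Generator):
    """(fit_idx, val_idx): a 10%-style validation split when early stopping
    is on, otherwise everything is fitted."""
    if not cfg.early_stopping:
        return np.arange(n), None
    n_val = max(1, int(round(cfg.val_fraction * n)))
    if n_val >= n:
        raise ValueError("validation split leaves no training rows")
    perm = rng.permutation(n)
    return perm[n_val:], perm[:n_val]


def train_subnetwork(block: OmicsMatrix, responses, adjacency,
                     cfg: TrainingConfig, seed: int,
                     epochs: Optional[int] = None,
                     record_history: bool = False):
    """Stage 1: fit one omics sub-network to all drug responses.

    ``adjacency`` (an AdjacencyMatrix or None) selects graph vs dense
    embedding and with it the epoch budget (epochs_graph vs epochs_dense).
    Returns (SubNetworkParams, history), history being the full-data
    evaluation-mode loss per epoch when requested.
    """
    X = block.values
    Y, Mk = responses.values, responses.observed_mask
    if X.shape[0] != Y.shape[0]:
        raise ValueError("block and responses have different cell-line counts")
    rng = np.random.default_rng(seed)
    A = adjacency.A if adjacency is not None else None
    if A is not None and adjacency.feature_ids != block.feature_ids:
        raise ValueError("adjacency feature order differs from omics block")
    params = init_subnetwork_params(
        n_features=block.n_features,
        hidden_size=cfg.hidden_for(block.omics_name),
        n_outputs=responses.values.shape[1],
        rng=rng,
        A=A,
        embedding_size=cfg.embed_for(block.omics_name, block.n_features),
        dropout_embed=cfg.dropout_for(block.omics_name),
        dropout_hidden=cfg.dropout_for(block.omics_name),
    )
    if epochs is None:
        epochs = cfg.epochs_graph if A is not None else cfg.epochs_dense
    opt = Adam(params.trainable(), cfg.learning_rate)
    fit_idx, val_idx = _holdout_split(X.shape[0], cfg, rng)
    best_loss, best_state, since_best = np.inf, None, 0
    history = []
    for epoch in range(epochs):
        for idx in _batches(fit_idx, cfg.batch_size, rng):
            if not Mk[idx].any():
                continue
            loss, grads = _subnet_loss_and_grads(params, X[idx], Y[idx], Mk[idx], rng)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite stage-1 loss for {block.omics_name!r} at epoch {epoch}"
                )
            opt.step(grads)
        if record_history:
            out = subnetwork_forward(X, params)
            history.append(masked_mse_loss(out, Y, Mk))
        if val_idx is not None and Mk[val_idx].any():
            val_loss = masked_mse_loss(subnetwork_forward(X[val_idx], params),
                                       Y[val_idx], Mk[val_idx])
            if val_loss < best_loss:
                best_loss, best_state, since_best = val_loss, params.copy(), 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
    if best_state is not None:
        params = best_state
    return params, history


def _params_digest(subnets: list) -> str:
    h = hashlib.sha256()
    for p in subnets:
        for arr in p.trainable() + ([p.A] if p.A is not None else []):
            h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def _softmax_rows(a: np.ndarray) -> np.ndarray:
    e = np.exp(a - a.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def train_attention(subnets: list, Xs: list, responses_values, observed_mask,
                    cfg: TrainingConfig, seed: int,
                    epochs: Optional[int] = None,
                    record_history: bool = False):
    """Stage 2: learn attention logits and output bias over frozen heads.

    ``Xs`` are the (already standardized) per-omics input matrices aligned
    with ``subnets``. Sub-network parameters are asserted byte-identical
    before and after. Returns (AttentionParams, history).
    """
    if len(subnets) != len(Xs):
        raise ValueError("one input matrix per sub-network required")
    Y = np.asarray(responses_values, dtype=np.float64)
    Mk = np.asarray(observed_mask, dtype=bool)
    n_d = Y.shape[1]
    for p in subnets:
        if p.n_outputs != n_d:
            raise ValueError("kill-matrix fusion requires head size n_f == n_d")
    before = _params_digest(subnets)
    # eval-mode heads, used for prediction and the loss history
    H = np.stack([subnetwork_forward(X, p) for X, p in zip(Xs, subnets)])
    M = len(subnets)
    rng = np.random.default_rng(seed)
    att = init_attention_params(n_d, M, rng)
    rows = np.arange(n_d)
    a = att.W3[rows, :, rows].copy()        # (n_d, M) trainable diagonal logits
    b = att.b.copy()
    opt = Adam([a, b], cfg.learning_rate)
    if epochs is None:
        epochs = cfg.epochs_attention
    fit_idx, val_idx = _holdout_split(Y.shape[0], cfg, rng)
    best_loss, best_state, since_best = np.inf, None, 0

    def _eval_loss(rows):
        w = _softmax_rows(a)
        pred = np.einsum("mnd,dm->nd", H[:, rows, :], w) + b
        return masked_mse_loss(pred, Y[rows], Mk[rows])

    history = []
    for epoch in range(epochs):
        for idx in _batches(fit_idx, cfg.batch_size, rng):
            Mb = Mk[idx]
            if not Mb.any():
                continue
            w = _softmax_rows(a)
            # frozen sub-network weights, but dropout stays active while the
            # attention layer trains, exactly as when non-trainable layers sit
            # inside a training graph; this keeps memorized heads from
            # dominating the fusion.
            Hb = np.stack([
                subnetwork_forward(X[idx], p, train_mode=True, rng=rng)
                for X, p in zip(Xs, subnets)
            ])
            pred = np.einsum("mbd,dm->bd", Hb, w) + b
            cnt = int(Mb.sum())
            R = (pred - Y[idx]) * Mb
            loss = float((R * R).sum() / cnt)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite stage-2 loss at epoch {epoch}")
            dpred = 2.0 * R / cnt
            db = dpred.sum(axis=0)
            dw = np.einsum("bd,mbd->dm", dpred, Hb)
            da = w * (dw - (w * dw).sum(axis=1, keepdims=True))
            opt.step([da, db])
        if record_history:
            w = _softmax_rows(a)
            pred = np.einsum("mnd,dm->nd", H, w) + b
            history.append(masked_mse_loss(pred, Y, Mk))
        if val_idx is not None and Mk[val_idx].any():
            val_loss = _eval_loss(val_idx)
            if val_loss < best_loss:
                best_loss, best_state, since_best = val_loss, (a.copy(), b.copy()), 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
    if best_state is not None:
        a, b = best_state
    att.W3[rows, :, rows] = a
    att.b = b
    if _params_digest(subnets) != before:
        raise AssertionError("stage-2 training modified frozen sub-network parameters")
    return att, history


def predict_fused(subnets: list, att: AttentionParams, Xs: list) -> np.ndarray:
    heads = [subnetwork_forward(X, p) for X, p in zip(Xs, subnets)]
    return fuse_and_predict(heads, att)


# ---------------------------------------------------------------------------
# cross-validation and ablation
# ---------------------------------------------------------------------------

def make_folds(n: int, n_folds: int, rng: np.random.Generator) -> list:
    """Disjoint, exhaustive random partition of range(n) into n_folds groups."""
    if n_folds < 2 or n_folds > n:
        raise ValueError("need 2 <= n_folds <= n")
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, n_folds)]


def _fold_seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _standardize_fold(block: OmicsMatrix, train_idx, test_idx):
    train_ids = [block.cell_line_ids[i] for i in train_idx]
    test_ids = [block.cell_line_ids[i] for i in test_idx]
    assert not set(train_ids) & set(test_ids), "train/test cell lines overlap"
    train_block, stats = standardize(block.subset_cells(train_ids))
    test_block, _ = standardize(block.subset_cells(test_ids), stats)
    return train_block, test_block, stats


def _train_fold(data: MultiOmicsDataset, cfg: TrainingConfig, train_idx,
                test_idx, seed: int):
    """Standardize on training cells, run both stages, return everything a
    caller needs to evaluate the fold."""
    seeds = _fold_seeds(seed, data.n_blocks + 1)
    subnets, Xtr, Xte = [], [], []
    resp = data.responses
    train_resp = resp.values[train_idx], resp.observed_mask[train_idx]
    for b, (block, s) in enumerate(zip(data.omics_blocks, seeds)):
        tr, te, _ = _standardize_fold(block, train_idx, test_idx)
        adj = data.adjacency.get(block.omics_name)
        sub, _ = train_subnetwork(
            tr,
            type(resp)(tr.cell_line_ids, resp.drug_ids, *train_resp),
            adj, cfg, seed=s,
        )
        subnets.append(sub)
        Xtr.append(tr.values)
        Xte.append(te.values)
    att, _ = train_attention(subnets, Xtr, *train_resp, cfg, seed=seeds[-1])
    return subnets, att, Xtr, Xte


@dataclass
class CrossValidationResult:
    """Per-fold and aggregate test metrics plus per-fold attention scores."""

    fold_metrics: pd.DataFrame
    attention_by_fold: list        # list of (M x n_d) DataFrames
    omics_names: list

    @property
    def mean(self) -> pd.Series:
        return self.fold_metrics.mean()

    @property
    def sd(self) -> pd.Series:
        return self.fold_metrics.std(ddof=1)

    def mean_attention(self) -> pd.DataFrame:
        return sum(self.attention_by_fold) / len(self.attention_by_fold)

    def summary(self) -> str:
        lines = ["cross-validation (mean +/- sd over folds)"]
        for k in self.fold_metrics.columns:
            lines.append(f"  {k:10s} {self.mean[k]: .4f} +/- {self.sd[k]:.4f}")
        return "\n".join(lines)


def cross_validate(data: MultiOmicsDataset, cfg: TrainingConfig,
                   seed: Optional[int] = None) -> CrossValidationResult:
    """K-fold cross-validation of the full two-stage model.

    Standardization statistics and both training stages use training cells
    only; metrics are computed on the held-out cells of each fold and
    aggregated as unweighted mean +/- sample standard deviation.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    folds = make_folds(data.responses.n_cells, cfg.n_folds, rng)
    all_idx = np.concatenate(folds)
    assert len(np.unique(all_idx)) == data.responses.n_cells, "folds are not a partition"

    rows, att_frames = [], []
    fseeds = _fold_seeds(seed + 1, cfg.n_folds)
    drug_ids = data.responses.drug_ids
    for f, test_idx in enumerate(folds):
        train_idx = np.sort(np.concatenate([folds[g] for g in range(cfg.n_folds) if g != f]))
        subnets, att, _, Xte = _train_fold(data, cfg, train_idx, test_idx, fseeds[f])
        pred = predict_fused(subnets, att, Xte)
        ps = PredictionSet(
            pred, data.responses.values[test_idx],
            data.responses.observed_mask[test_idx], drug_ids,
            [data.cell_line_ids[i] for i in test_idx],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("always")
            rows.append({
                "fold": f, "mse": mse(ps), "r2": r_squared(ps),
                "top1": top_k_accuracy(ps, 1), "top3": top_k_accuracy(ps, 3),
            })
        att_frames.append(pd.DataFrame(
            attention_scores(att.normalized()),
            index=data.block_names(), columns=drug_ids,
        ))
    metrics = pd.DataFrame(rows).set_index("fold")
    return CrossValidationResult(metrics, att_frames, data.block_names())


def ablation_run(data: MultiOmicsDataset, cfg: TrainingConfig,
                 subsets: Optional[list] = None,
                 seed: Optional[int] = None,
                 retrain_subnetworks: bool = False) -> pd.DataFrame:
    """Cross-validated performance of every non-empty omics combination.

    Stage-1 sub-networks are trained once per fold and reused across
    combinations (set ``retrain_subnetworks`` to retrain per combination);
    one attention stage is trained per combination. Rows are sorted by
    ascending mean MSE (best first).
    """
    names = data.block_names()
    if subsets is None:
        subsets = [c for r in range(1, len(names) + 1)
                   for c in combinations(names, r)]
    subsets = [tuple(s) for s in subsets]
    for s in subsets:
        if not s or any(n not in names for n in s):
            raise ValueError(f"invalid omics subset: {s}")

    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    folds = make_folds(data.responses.n_cells, cfg.n_folds, rng)
    fseeds = _fold_seeds(seed + 1, cfg.n_folds)
    resp = data.responses
    acc = {s: {"mse": [], "r2": []} for s in subsets}
    for f, test_idx in enumerate(folds):
        train_idx = np.sort(np.concatenate([folds[g] for g in range(cfg.n_folds) if g != f]))
        subnets, _, Xtr, Xte = _train_fold(data, cfg, train_idx, test_idx, fseeds[f])
        train_resp = resp.values[train_idx], resp.observed_mask[train_idx]
        pos = {n: i for i, n in enumerate(names)}
        for s in subsets:
            sel = [pos[n] for n in s]
            if retrain_subnetworks:
                sub_sel, xtr_sel, xte_sel = [], [], []
                for i in sel:
                    block = data.omics_blocks[i]
                    tr, te, _ = _standardize_fold(block, train_idx, test_idx)
                    p, _ = train_subnetwork(
                        tr, type(resp)(tr.cell_line_ids, resp.drug_ids, *train_resp),
                        data.adjacency.get(block.omics_name), cfg,
                        seed=_fold_seeds(fseeds[f] + 7, len(names))[i],
                    )
                    sub_sel.append(p)
                    xtr_sel.append(tr.values)
                    xte_sel.append(te.values)
            else:
                sub_sel = [subnets[i] for i in sel]
                xtr_sel = [Xtr[i] for i in sel]
                xte_sel = [Xte[i] for i in sel]
            att, _ = train_attention(sub_sel, xtr_sel, *train_resp, cfg,
                                     seed=fseeds[f] + 13 + subsets.index(s))
            pred = predict_fused(sub_sel, att, xte_sel)
            ps = PredictionSet(
                pred, resp.values[test_idx], resp.observed_mask[test_idx],
                resp.drug_ids, [data.cell_line_ids[i] for i in test_idx],
            )
            acc[s]["mse"].append(mse(ps))
            acc[s]["r2"].append(r_squared(ps))
    rows = [{
        "combination": "-".join(s),
        "mse": float(np.mean(acc[s]["mse"])),
        "mse_sd": float(np.std(acc[s]["mse"], ddof=1)),
        "r2": float(np.mean(acc[s]["r2"])),
        "r2_sd": float(np.std(acc[s]["r2"], ddof=1)),
    } for s in subsets]
    df = pd.DataFrame(rows).sort_values(["mse", "combination"]).reset_index(drop=True)
    return df
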