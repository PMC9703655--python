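"""Forward computation of every layer of the fusion network.

The network processes each omics block m through its own sub-network

    embedding (graph-masked or dense) -> hidden dense -> linear head

where the graph embedding masks its weight matrix element-wise with the
interactome adjacency A, so each hidden unit only sees features that
interact with it. The M head outputs (each of size n_f = n_d, one entry
per drug) are fused by an attention layer whose weights are softmax-
normalized across omics and masked by the identity-pattern "kill matrix",
so drug d's output is a convex combination of the M per-omics predictions
for drug d (plus a bias).

Everything here is pure computation on numpy arrays; training lives in
:mod:`omicsfusion.training`. Inputs may be single feature vectors ``(n_m,)``
or batches ``(n, n_m)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def identity(x: np.ndarray) -> np.ndarray:
    return x


ACTIVATIONS = {"relu": relu, "identity": identity}


def _check_matching(x, W, name):
    if x.shape[-1] != W.shape[0]:
        raise ValueError(
            f"{name}: input dimension {x.shape[-1]} does not match weight "
            f"rows {W.shape[0]}"
        )


def dense_embedding_forward(x: np.ndarray, W1: np.ndarray, b1: np.ndarray,
                            f: Callable = relu) -> np.ndarray:
    """f(W1^T x + b1) for a dense embedding layer."""
    x = np.asarray(x, dtype=np.float64)
    _check_matching(x, W1, "dense_embedding_forward")
    if b1.shape[-1] != W1.shape[1]:
        raise ValueError("dense_embedding_forward: bias length mismatch")
    return f(x @ W1 + b1)


def graph_embedding_forward(x: np.ndarray, W1: np.ndarray, A: np.ndarray,
                            b1: np.ndarray, f: Callable = relu) -> np.ndarray:
    """f((W1 . A)^T x + b1) with "." the element-wise interactome mask.

    W1 and A must both be (n_m x n_m); entries of W1 where A is zero have no
    effect on the output.
    """
    x = np.asarray(x, dtype=np.float64)
    if W1.shape != A.shape or W1.shape[0] != W1.shape[1]:
        raise ValueError(
            f"graph_embedding_forward: W1 {W1.shape} and A {A.shape} must be "
            "equal square shapes"
        )
    _check_matching(x, W1, "graph_embedding_forward")
    return f(x @ (W1 * A) + b1)


def dense_layer_forward(y1: np.ndarray, W2: np.ndarray, b2: np.ndarray,
                        f: Callable = relu) -> np.ndarray:
    """f(W2^T y1 + b2): the post-embedding hidden dense layer."""
    y1 = np.asarray(y1, dtype=np.float64)
    _check_matching(y1, W2, "dense_layer_forward")
    return f(y1 @ W2 + b2)


@dataclass
class SubNetworkParams:
    """Parameters of one omics sub-network.

    ``A is None`` means a dense embedding (embedding size free); a graph
    embedding requires W1 square with A of the same shape, so the embedding
    size equals the input size. The head output size n_f must equal the
    number of drugs for the kill-matrix fusion to apply.
    """

    W1: np.ndarray
    b1: np.ndarray
    A: Optional[np.ndarray]
    W2: np.ndarray
    b2: np.ndarray
    Wh: np.ndarray
    bh: np.ndarray
    dropout_embed: float = 0.0
    dropout_hidden: float = 0.0
    f: str = "relu"

    def __post_init__(self):
        if self.A is not None and self.W1.shape != self.A.shape:
            raise ValueError("graph embedding requires W1 and A of equal shape")

    @property
    def n_features(self) -> int:
        return self.W1.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.Wh.shape[1]

    def copy(self) -> "SubNetworkParams":
        return SubNetworkParams(
            self.W1.copy(), self.b1.copy(),
            None if self.A is None else self.A.copy(),
            self.W2.copy(), self.b2.copy(), self.Wh.copy(), self.bh.copy(),
            self.dropout_embed, self.dropout_hidden, self.f,
        )

    def trainable(self) -> list:
        return [self.W1, self.b1, self.W2, self.b2, self.Wh, self.bh]


def dropout_mask(rng: np.random.Generator, shape, rate: float) -> np.ndarray:
    """Inverted-dropout multiplier: zeros with probability ``rate``, kept
    units scaled by 1/(1-rate) so inference needs no rescaling."""
    if rate <= 0.0:
        return np.ones(shape)
    return (rng.random(shape) >= rate) / (1.0 - rate)


def subnetwork_forward(x: np.ndarray, params: SubNetworkParams,
                       train_mode: bool = False,
                       rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """head(dense(embed(x))): this omics' per-drug prediction (linear head).

    Dropout (after each hidden activation, never after the head) is applied
    only when ``train_mode`` is set, making inference deterministic.
    """
    f = ACTIVATIONS[params.f]
    if params.A is not None:
        h1 = graph_embedding_forward(x, params.W1, params.A, params.b1, f)
    else:
        h1 = dense_embedding_forward(x, params.W1, params.b1, f)
    if train_mode:
        if rng is None:
            raise ValueError("train_mode requires an rng for dropout")
        h1 = h1 * dropout_mask(rng, h1.shape, params.dropout_embed)
    h2 = dense_layer_forward(h1, params.W2, params.b2, f)
    if train_mode:
        h2 = h2 * dropout_mask(rng, h2.shape, params.dropout_hidden)
    return h2 @ params.Wh + params.bh


# ---------------------------------------------------------------------------
# attention fusion
# ---------------------------------------------------------------------------

def kill_matrix(n_d: int, n_f: int) -> np.ndarray:
    """k(d, i) = 1 iff d = i: forces drug d's output neuron to attend only
    to position d of each omics head."""
    k = np.zeros((n_d, n_f))
    np.fill_diagonal(k, 1.0)
    return k


def attention_normalize(W3: np.ndarray, k: Optional[np.ndarray] = None) -> np.ndarray:
    """Normalized attention weights W(d,m,i) = exp(W3(d,m,i)) k(d,i) / sum_m exp(W3(d,m,i)).

    The softmax runs over the omics axis m with max-subtraction for
    stability, so arbitrary finite raw weights (including +/-50 extremes)
    normalize without overflow. For every (d, i), sum_m W(d,m,i) = k(d,i).
    """
    W3 = np.asarray(W3, dtype=np.float64)
    if W3.ndim != 3:
        raise ValueError("W3 must have shape (n_d, M, n_f)")
    n_d, _, n_f = W3.shape
    if k is None:
        k = kill_matrix(n_d, n_f)
    if k.shape != (n_d, n_f):
        raise ValueError(f"kill matrix shape {k.shape} != ({n_d}, {n_f})")
    shifted = W3 - W3.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    W = e / e.sum(axis=1, keepdims=True)
    return W * k[:, None, :]


@dataclass
class AttentionParams:
    """Raw attention weights W3 (n_d x M x n_f), output bias b (n_d).

    The kill matrix is the fixed identity pattern, derived from the shapes;
    the output activation g is the identity (regression on log IC50).
    """

    W3: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.W3 = np.asarray(self.W3, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.W3.ndim != 3:
            raise ValueError("W3 must have shape (n_d, M, n_f)")
        if self.n_drugs != self.W3.shape[2]:
            raise ValueError(
                f"kill-matrix fusion requires n_f == n_d, got n_f={self.W3.shape[2]}"
                f" n_d={self.W3.shape[0]}"
            )
        if self.b.shape != (self.n_drugs,):
            raise ValueError("bias length must equal the drug count")

    @property
    def n_drugs(self) -> int:
        return self.W3.shape[0]

    @property
    def n_omics(self) -> int:
        return self.W3.shape[1]

    @property
    def k(self) -> np.ndarray:
        return kill_matrix(self.n_drugs, self.W3.shape[2])

    def normalized(self) -> np.ndarray:
        return attention_normalize(self.W3, self.k)

    def copy(self) -> "AttentionParams":
        return AttentionParams(self.W3.copy(), self.b.copy())


def fuse_and_predict(heads: list, att: AttentionParams,
                     g: Callable = identity) -> np.ndarray:
    """y_d = g( sum_m W(d,m,d) heads_m[d] + b_d ).

    With g the identity and zero bias each drug's output is a convex
    combination of that drug's per-omics head predictions.
    """
    if len(heads) != att.n_omics:
        raise ValueError(f"expected {att.n_omics} heads, got {len(heads)}")
    heads = [np.asarray(h, dtype=np.float64) for h in heads]
    n_d = att.n_drugs
    for h in heads:
        if h.shape[-1] != n_d:
            raise ValueError(
                f"head size {h.shape[-1]} != drug count {n_d}: kill-matrix "
                "fusion requires n_f == n_d"
            )
    W = att.normalized()
    diag = np.einsum("dmd->dm", W)           # (n_d, M) convex weights
    out = att.b + sum(heads[m] * diag[:, m] for m in range(att.n_omics))
    return g(out)


def attention_scores(W_normalized: np.ndarray) -> np.ndarray:
    """Per-omics attention scores: score(m, d) = sum_i W(d, m, i).

    Under the kill matrix only i = d contributes, so this equals W(d, m, d);
    every column of the (M x n_d) result sums to one.
    """
    return W_normalized.sum(axis=2).T


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def init_subnetwork_params(n_features: int, hidden_size: int, n_outputs: int,
                           rng: np.random.Generator,
                           A: Optional[np.ndarray] = None,
                           embedding_size: Optional[int] = None,
                           dropout_embed: float = 0.0,
                           dropout_hidden: float = 0.0) -> SubNetworkParams:
    """Glorot-uniform weights, zero biases. A graph embedding (A given)
    forces embedding_size == n_features."""
    if A is not None:
        e = n_features
    else:
        e = embedding_size if embedding_size is not None else n_features
    return SubNetworkParams(
        W1=glorot_uniform(rng, n_features, e),
        b1=np.zeros(e),
        A=A,
        W2=glorot_uniform(rng, e, hidden_size),
        b2=np.zeros(hidden_size),
        Wh=glorot_uniform(rng, hidden_size, n_outputs),
        bh=np.zeros(n_outputs),
        dropout_embed=dropout_embed,
        dropout_hidden=dropout_hidden,
    )


def init_attention_params(n_drugs: int, n_omics: int,
                          rng: np.random.Generator) -> AttentionParams:
    W3 = glorot_uniform(rng, n_omics, n_drugs, shape=(n_drugs, n_omics, n_drugs))
    return AttentionParams(W3=W3, b=np.zeros(n_drugs))
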