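"""Independent explicit-loop reference implementations of the evaluation
statistics and forward primitives, shared by the oracle-equivalence tests.
Deliberately written as plain Python loops, never vectorized."""

import numpy as np


def mse_loop(ps):
    total, n = 0.0, 0
    for i in range(len(ps.cell_line_ids)):
        for j in range(len(ps.drug_ids)):
            if ps.observed_mask[i, j]:
                total += (ps.truths[i, j] - ps.predictions[i, j]) ** 2
                n += 1
    return total / n


def r2_loop(ps):
    vals = []
    for j in range(len(ps.drug_ids)):
        ys, yh = [], []
        for i in range(len(ps.cell_line_ids)):
            if ps.observed_mask[i, j]:
                ys.append(ps.truths[i, j])
                yh.append(ps.predictions[i, j])
        if len(ys) < 2 or len(set(ys)) == 1:
            continue
        ybar = sum(ys) / len(ys)
        ss_res = sum((a - b) ** 2 for a, b in zip(ys, yh))
        ss_tot = sum((a - ybar) ** 2 for a in ys)
        vals.append(1 - ss_res / ss_tot)
    return sum(vals) / len(vals)


def topk_loop(ps, k):
    hits, n = 0, 0
    for i in range(len(ps.cell_line_ids)):
        obs = [j for j in range(len(ps.drug_ids)) if ps.observed_mask[i, j]]
        if not obs:
            continue
        n += 1
        best = min(obs, key=lambda j: (ps.truths[i, j], ps.drug_ids[j]))
        ranked = sorted(obs, key=lambda j: (ps.predictions[i, j], ps.drug_ids[j]))
        if best in ranked[:k]:
            hits += 1
    return 100.0 * hits / n


def ranking_loop(ps):
    rows = []
    for j, d in enumerate(ps.drug_ids):
        obs = [i for i in range(len(ps.cell_line_ids)) if ps.observed_mask[i, j]]
        if not obs:
            continue
        v = sum((ps.truths[i, j] - ps.predictions[i, j]) ** 2 for i in obs) / len(obs)
        rows.append((d, v))
    return sorted(rows, key=lambda t: (t[1], t[0]))


def dense_loop(x, W, b, f):
    out = np.empty(W.shape[1])
    for j in range(W.shape[1]):
        acc = b[j]
        for i in range(W.shape[0]):
            acc += W[i, j] * x[i]
        out[j] = acc
    return f(out)


def softmax_loop(W3, k):
    n_d, M, n_f = W3.shape
    out = np.zeros_like(W3)
    for d in range(n_d):
        for i in range(n_f):
            denom = sum(np.exp(W3[d, m, i]) for m in range(M))
            for m in range(M):
                out[d, m, i] = np.exp(W3[d, m, i]) * k[d, i] / denom
    return out
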