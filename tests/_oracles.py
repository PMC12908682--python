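"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain nested loops against the written
definitions, deliberately sharing no code with the package internals.
"""

import numpy as np


def attention_oracle(x_q, x_kv, layer):
    """Nested-loop multi-head attention using the layer's weights.

    x_q: (B, Lq, d); x_kv: (B, Lk, d).  Returns (output, weights) with
    weights (B, H, Lq, Lk).
    """
    wq, bq = layer.w_q.weight.data, layer.w_q.bias.data
    wk, bk = layer.w_k.weight.data, layer.w_k.bias.data
    wv, bv = layer.w_v.weight.data, layer.w_v.bias.data
    wo, bo = layer.w_o.weight.data, layer.w_o.bias.data
    H, dh = layer.heads, layer.d_head
    B, Lq, d = x_q.shape
    Lk = x_kv.shape[1]
    out = np.zeros((B, Lq, d))
    weights = np.zeros((B, H, Lq, Lk))
    for b in range(B):
        for i in range(Lq):
            head_outs = []
            for h in range(H):
                sl = slice(h * dh, (h + 1) * dh)
                q = x_q[b, i] @ wq[:, sl] + bq[sl]
                scores = np.zeros(Lk)
                for j in range(Lk):
                    k = x_kv[b, j] @ wk[:, sl] + bk[sl]
                    scores[j] = q @ k / np.sqrt(dh)
                e = np.exp(scores - scores.max())
                a = e / e.sum()
                weights[b, h, i] = a
                o = np.zeros(dh)
                for j in range(Lk):
                    v = x_kv[b, j] @ wv[:, sl] + bv[sl]
                    o += a[j] * v
                head_outs.append(o)
            out[b, i] = np.concatenate(head_outs) @ wo + bo
    return out, weights


def auroc_oracle(scores, labels):
    """Exhaustive pair counting with half credit for ties."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def aupr_oracle(scores, labels):
    """Average precision by the recall-step sum over distinct score
    thresholds (tied scores enter together), from first principles."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    n_pos = int((labels == 1).sum())
    ap, prev_recall = 0.0, 0.0
    for thr in sorted(set(scores), reverse=True):
        kept = scores >= thr
        tp = int(((labels == 1) & kept).sum())
        fp = int(((labels == 0) & kept).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def profile_oracle(attn_map, sample):
    """Loop-based head-mean/query-sum promoter profile."""
    H, B, Lq, Lk = attn_map.shape
    out = np.zeros(Lk)
    for j in range(Lk):
        acc = 0.0
        for i in range(Lq):
            s = 0.0
            for h in range(H):
                s += attn_map[h, sample, i, j]
            acc += s / H
        out[j] = acc
    return out
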