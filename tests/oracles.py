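"""Brute-force reference implementations used as independent oracles."""

import numpy as np


def numeric_grad(f, x, eps=1e-6):
    """Central finite differences of a scalar function w.r.t. array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def naive_conv2d(x, w, b, stride, pad):
    """Quadruple-loop cross-correlation."""
    N, C, H, W = x.shape
    Cout, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad,) * 2, (pad,) * 2))
    Ho = (H + 2 * pad - k) // stride + 1
    Wo = (W + 2 * pad - k) // stride + 1
    out = np.zeros((N, Cout, Ho, Wo))
    for n in range(N):
        for co in range(Cout):
            for i in range(Ho):
                for j in range(Wo):
                    patch = xp[n, :, i * stride:i * stride + k,
                               j * stride:j * stride + k]
                    out[n, co, i, j] = (patch * w[co]).sum()
            if b is not None:
                out[n, co] += b[co]
    return out


def naive_depthwise(x, w, stride, pad):
    """Per-channel loop convolution."""
    N, C, H, W = x.shape
    k = w.shape[-1]
    xp = np.pad(x, ((0, 0), (0, 0), (pad,) * 2, (pad,) * 2))
    Ho = (H + 2 * pad - k) // stride + 1
    Wo = (W + 2 * pad - k) // stride + 1
    out = np.zeros((N, C, Ho, Wo))
    for n in range(N):
        for c in range(C):
            for i in range(Ho):
                for j in range(Wo):
                    patch = xp[n, c, i * stride:i * stride + k,
                               j * stride:j * stride + k]
                    out[n, c, i, j] = (patch * w[c]).sum()
    return out


def all_pairs_auc(scores, labels):
    """Concordant-pair count AUC (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    total, conc = 0, 0.0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                conc += 1.0
            elif p == n:
                conc += 0.5
    return conc / total


def cumulative_ap(scores, labels):
    """Direct summation of precision at each positive hit."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    labels = np.asarray(labels, dtype=bool)[order]
    n_pos = labels.sum()
    ap, tp = 0.0, 0
    for k, hit in enumerate(labels, start=1):
        if hit:
            tp += 1
            ap += tp / k
    return ap / n_pos
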