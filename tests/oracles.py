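"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately written as plain nested loops or pair
enumeration, sharing no code with the package's vectorised paths.
"""

import numpy as np


def loop_conv2d(x, w, b, padding):
    """Direct nested-loop 2-D cross-correlation, stride 1, zero padding.

    x: (C, H, W); w: (O, C, kh, kw); b: (O,) or None.
    """
    C, H, W = x.shape
    O, _, kh, kw = w.shape
    ph, pw = padding
    xp = np.zeros((C, H + 2 * ph, W + 2 * pw))
    xp[:, ph:ph + H, pw:pw + W] = x
    Ho, Wo = H + 2 * ph - kh + 1, W + 2 * pw - kw + 1
    out = np.zeros((O, Ho, Wo))
    for o in range(O):
        for i in range(Ho):
            for j in range(Wo):
                acc = 0.0
                for c in range(C):
                    for di in range(kh):
                        for dj in range(kw):
                            acc += xp[c, i + di, j + dj] * w[o, c, di, dj]
                out[o, i, j] = acc + (b[o] if b is not None else 0.0)
    return out


def loop_upsample2x(x):
    """Per-pixel bilinear x2 upsampling with half-pixel-centre mapping."""
    C, H, W = x.shape
    out = np.zeros((C, 2 * H, 2 * W))
    for c in range(C):
        for i in range(2 * H):
            for j in range(2 * W):
                si = min(max((i + 0.5) / 2 - 0.5, 0), H - 1)
                sj = min(max((j + 0.5) / 2 - 0.5, 0), W - 1)
                i0, j0 = int(np.floor(si)), int(np.floor(sj))
                i1, j1 = min(i0 + 1, H - 1), min(j0 + 1, W - 1)
                wi, wj = si - i0, sj - j0
                out[c, i, j] = (x[c, i0, j0] * (1 - wi) * (1 - wj)
                                + x[c, i1, j0] * wi * (1 - wj)
                                + x[c, i0, j1] * (1 - wi) * wj
                                + x[c, i1, j1] * wi * wj)
    return out


def loop_mag_aggregate(attention, x1):
    """Triple loop over attention map m, channel and pixel."""
    N, H, W = attention.shape
    C = x1.shape[0]
    out = np.zeros((C, H, W))
    for m in range(N):
        for c in range(C):
            for i in range(H):
                for j in range(W):
                    out[c, i, j] += attention[m, i, j] * x1[c, i, j]
    return out


def loop_se(u, w_reduce, w_expand):
    """Scalar-loop squeeze/excitation/scale.

    u: (C, H, W); w_reduce: (hidden, C); w_expand: (C, hidden).
    """
    C, H, W = u.shape
    z = np.array([u[k].sum() / (H * W) for k in range(C)])
    hidden = np.maximum(w_reduce @ z, 0.0)
    s = 1.0 / (1.0 + np.exp(-(w_expand @ hidden)))
    out = np.zeros_like(u)
    for k in range(C):
        out[k] = s[k] * u[k]
    return out, s


def pairwise_auc(scores, labels):
    """AUC as the concordant-pair fraction (ties count one half)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = conc = 0.0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                conc += 1
            elif p == n:
                conc += 0.5
    return conc / total


def enumerate_confusion(pred, gt):
    tp = fp = tn = fn = 0
    for p, g in zip(np.asarray(pred).ravel(), np.asarray(gt).ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def boundary_set(mask):
    """Mask pixels with at least one background 4-neighbour (pixels
    beyond the image border count as foreground)."""
    m = np.asarray(mask).astype(bool)
    H, W = m.shape
    pts = []
    for i in range(H):
        for j in range(W):
            if not m[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < H and 0 <= nj < W and not m[ni, nj]:
                    pts.append((i, j))
                    break
    return pts


def brute_bf_score(pred, gt, theta):
    """Boundary F1 by exhaustive nearest-distance matching."""
    pb, gb = boundary_set(pred), boundary_set(gt)
    if not pb and not gb:
        return 1.0
    if not pb or not gb:
        return 0.0

    def matched(points, targets):
        hits = 0
        for p in points:
            d = min(np.hypot(p[0] - t[0], p[1] - t[1]) for t in targets)
            if d <= theta:
                hits += 1
        return hits / len(points)

    prec, rec = matched(pb, gb), matched(gb, pb)
    if prec + rec == 0:
        return 0.0
    return 2 * prec * rec / (prec + rec)
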