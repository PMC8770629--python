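"""Independent brute-force oracles used across the test suite.

Everything here is written as plain pixel/element loops, deliberately
sharing no code with the package implementation, so each test compares two
independent routes to the same quantity.
"""

from __future__ import annotations

import math


def confusion_counts(pred, gt):
    tp = fp = fn = tn = 0
    for i in range(len(pred)):
        for j in range(len(pred[0])):
            p, g = pred[i][j], gt[i][j]
            if p and g:
                tp += 1
            elif p and not g:
                fp += 1
            elif g and not p:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def overlap_metrics_loop(pred, gt):
    tp, fp, fn, _ = confusion_counts(pred, gt)
    if tp + fp + fn == 0:
        return 1.0, 1.0, 1.0, 1.0
    dsc = 2 * tp / (2 * tp + fp + fn)
    ji = tp / (tp + fp + fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return dsc, ji, precision, recall


def hausdorff_loop(a, b, spacing):
    """Max over both directed distances, all-pairs, physical units."""
    pa = [(i * spacing[0], j * spacing[1]) for i in range(len(a)) for j in range(len(a[0])) if a[i][j]]
    pb = [(i * spacing[0], j * spacing[1]) for i in range(len(b)) for j in range(len(b[0])) if b[i][j]]

    def directed(src, dst):
        worst = 0.0
        for p in src:
            best = math.inf
            for q in dst:
                d = math.hypot(p[0] - q[0], p[1] - q[1])
                if d < best:
                    best = d
            if best > worst:
                worst = best
        return worst

    return max(directed(pa, pb), directed(pb, pa))


def csa_error_loop(pred, gt, spacing):
    px = spacing[0] * spacing[1]
    a_pred = sum(sum(row) for row in pred) * px
    a_gt = sum(sum(row) for row in gt) * px
    return abs(a_pred - a_gt) / a_gt * 100.0


def bce_loop(p, g, eps=1e-7):
    total = 0.0
    n = 0
    for i in range(len(p)):
        for j in range(len(p[0])):
            pc = min(max(p[i][j], eps), 1 - eps)
            total += -(g[i][j] * math.log(pc) + (1 - g[i][j]) * math.log(1 - pc))
            n += 1
    return total / n


def dice_loop(p, g, smooth=1e-6):
    inter = sp = sg = 0.0
    for i in range(len(p)):
        for j in range(len(p[0])):
            inter += p[i][j] * g[i][j]
            sp += p[i][j]
            sg += g[i][j]
    return 1.0 - (2 * inter + smooth) / (sp + sg + smooth)


def whd_loop(p, g, alpha=-9.0, eps=1e-6):
    """Weighted Hausdorff surrogate written directly from its definition."""
    h, w = len(p), len(p[0])
    gt_pts = [(i, j) for i in range(h) for j in range(w) if g[i][j]]
    if not gt_pts:
        raise ValueError("empty ground truth")
    d_max = math.hypot(h - 1, w - 1)

    s = sum(p[i][j] for i in range(h) for j in range(w))
    term1 = 0.0
    for i in range(h):
        for j in range(w):
            dmin = min(math.hypot(i - y, j - x) for (y, x) in gt_pts)
            term1 += p[i][j] * dmin
    term1 /= s + eps

    term2 = 0.0
    n = h * w
    for (y, x) in gt_pts:
        acc = 0.0
        for i in range(h):
            for j in range(w):
                d = math.hypot(i - y, j - x)
                f = p[i][j] * d + (1 - p[i][j]) * d_max + eps
                acc += f**alpha
        term2 += (acc / n) ** (1.0 / alpha)
    term2 /= len(gt_pts)
    return term1 + term2


def pearson_loop(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def km_product_limit(times, events):
    """Product-limit estimate as (time, S(time)) at each distinct event time."""
    data = sorted(zip(times, events))
    s = 1.0
    out = []
    distinct = sorted({t for t, e in data if e == 1})
    for t in distinct:
        at_risk = sum(1 for tt, _ in data if tt >= t)
        d = sum(1 for tt, e in data if tt == t and e == 1)
        s *= 1.0 - d / at_risk
        out.append((t, s))
    return out


def cox_grid_coef(times, events, x, lo=-5.0, hi=5.0, step=1e-3):
    """Exhaustive grid maximisation of the Cox partial likelihood.

    Only valid for tie-free event times (where Efron = Breslow = exact).
    """
    data = sorted(zip(times, events, x))

    def pll(beta):
        total = 0.0
        for t_i, e_i, x_i in data:
            if not e_i:
                continue
            risk = [xj for tj, _, xj in data if tj >= t_i]
            total += beta * x_i - math.log(sum(math.exp(beta * xj) for xj in risk))
        return total

    best_beta, best_val = lo, -math.inf
    beta = lo
    while beta <= hi:
        v = pll(beta)
        if v > best_val:
            best_val, best_beta = v, beta
        beta += step
    return best_beta
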