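"""Independent brute-force oracles used to validate the implementation.

Everything here is written as directly as possible — explicit loops over
pairs, risk tables and co-occurrence counts — and stays independent of the
code paths it checks.
"""

import numpy as np


def auc_bruteforce(scores, labels):
    """AUC as the exhaustive pairwise ranking probability (ties count 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def icc21_anova(x):
    """ICC(2,1) from hand-expanded two-way ANOVA sums of squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def net_benefit_oracle(probs, labels, threshold):
    """Net benefit from explicit confusion counting at one threshold."""
    tp = fp = 0
    for p, y in zip(probs, labels):
        if p >= threshold:
            if y == 1:
                tp += 1
            else:
                fp += 1
    n = len(labels)
    return tp / n - (fp / n) * threshold / (1 - threshold)


def hosmer_lemeshow_oracle(probs, labels, n_bins=10):
    """Hand-summed (O-E)^2 / (E (1 - E/n_g)) over equal-count risk bins."""
    order = np.argsort(probs, kind="stable")
    groups = np.array_split(order, n_bins)
    stat = 0.0
    used = 0
    for g in groups:
        if len(g) == 0:
            continue
        o = sum(labels[i] for i in g)
        e = sum(probs[i] for i in g)
        n_g = len(g)
        denom = e * (1 - e / n_g)
        stat += (o - e) ** 2 / denom
        used += 1
    return stat, used - 2


def glcm_counts_oracle(image, mask, offset, symmetric=True):
    """Co-occurrence counts by explicit voxel-pair enumeration."""
    levels = sorted(set(int(v) for v in image[mask]))
    lut = {g: i for i, g in enumerate(levels)}
    mat = np.zeros((len(levels), len(levels)))
    nx, ny, nz = image.shape
    dx, dy, dz = offset
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                x2, y2, z2 = x + dx, y + dy, z + dz
                if not (0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz):
                    continue
                if not mask[x2, y2, z2]:
                    continue
                mat[lut[int(image[x, y, z])], lut[int(image[x2, y2, z2])]] += 1
    if symmetric:
        mat = mat + mat.T
    return mat, levels


def entropy_from_counts(mat):
    p = mat / mat.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def km_oracle(times, events):
    """Hand product-limit estimate at each distinct event time."""
    out = [(0.0, 1.0)]
    s = 1.0
    for t in sorted(set(t for t, e in zip(times, events) if e == 1)):
        n_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        s *= 1 - d / n_risk
        out.append((t, s))
    return out


def logrank_oracle(times_a, events_a, times_b, events_b):
    """O-E accumulation over the pooled risk table, df=1 chi-square."""
    times = list(times_a) + list(times_b)
    events = list(events_a) + list(events_b)
    is_a = [True] * len(times_a) + [False] * len(times_b)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(t for t, e in zip(times, events) if e == 1)):
        n = sum(1 for ti in times if ti >= t)
        n_a = sum(1 for ti, a in zip(times, is_a) if ti >= t and a)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        d_a = sum(
            1 for ti, ei, a in zip(times, events, is_a)
            if ti == t and ei == 1 and a
        )
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def optimal_cutoff_oracle(scores, times, events, min_group_frac=0.1):
    """Exhaustive max-chi-square scan over all admissible midpoints."""
    uniq = sorted(set(scores))
    n = len(scores)
    min_n = max(1, int(np.ceil(min_group_frac * n)))
    best = None
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        c = (lo + hi) / 2
        low_idx = [i for i, s in enumerate(scores) if s <= c]
        high_idx = [i for i in range(n) if i not in low_idx]
        if len(low_idx) < min_n or len(high_idx) < min_n:
            continue
        ev_low = [events[i] for i in low_idx]
        ev_high = [events[i] for i in high_idx]
        if sum(ev_low) + sum(ev_high) == 0:
            continue
        try:
            chi2 = logrank_oracle(
                [times[i] for i in low_idx], ev_low,
                [times[i] for i in high_idx], ev_high,
            )
        except ZeroDivisionError:
            continue
        if best is None or chi2 > best[1]:
            best = (c, chi2)
    return best


def pearson_prune_oracle(table, r_threshold):
    """Direct nested-loop version of the correlation pruning rule."""
    cols = sorted(table.columns)
    alive = {c: True for c in cols}

    def corr(a, b):
        return abs(np.corrcoef(table[a], table[b])[0, 1])

    while True:
        live = [c for c in cols if alive[c]]
        if len(live) < 2:
            break
        best_pair, best_r = None, -1.0
        for i, a in enumerate(live):
            for b in live[i + 1:]:
                r = corr(a, b)
                if r > best_r:
                    best_r, best_pair = r, (a, b)
        if best_r <= r_threshold:
            break
        a, b = best_pair
        mean_a = np.mean([corr(a, c) for c in live if c != a])
        mean_b = np.mean([corr(b, c) for c in live if c != b])
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)
        alive[drop] = False
    return [c for c in table.columns if alive[c]]
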