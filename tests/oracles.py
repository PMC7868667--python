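"""Independent brute-force reference implementations used only by tests.

Each oracle is a deliberately naive, loop-based transcription of the method's
defining formulas, written separately from the production code so that the
two can disagree.
"""

import numpy as np


def jaccard_brute(profiles):
    """Set-based pairwise Jaccard over the rows of a 0/1 matrix."""
    sets = [set(np.flatnonzero(row)) for row in np.asarray(profiles)]
    n = len(sets)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0
            else:
                union = sets[i] | sets[j]
                out[i, j] = len(sets[i] & sets[j]) / len(union) if union else 0.0
    return out


def full_kernel_brute(w):
    """Off-diagonal row mass 1/2, diagonal 1/2; identity row when isolated."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    p = np.zeros((n, n))
    for i in range(n):
        s = sum(w[i, j] for j in range(n) if j != i)
        if s <= 0:
            p[i, i] = 1.0
            continue
        for j in range(n):
            p[i, j] = 0.5 if j == i else w[i, j] / (2 * s)
    return p


def knn_brute(w, k):
    """Top-k neighbours (self excluded, ties to the lower index), row-normalized."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    s = np.zeros((n, n))
    for i in range(n):
        neigh = sorted((j for j in range(n) if j != i),
                       key=lambda j: (-w[i, j], j))[:k]
        d = sum(w[i, j] for j in neigh)
        for j in neigh:
            s[i, j] = w[i, j] / d if d > 0 else 1.0 / k
    return s


def cross_diffuse_brute(ws, k, t, renormalize=True):
    """Straight-line transcription of the cross-diffusion recursion."""
    m = len(ws)
    ps = [full_kernel_brute(w) for w in ws]
    ss = [knn_brute(w, k) for w in ws]
    for _ in range(t):
        new = []
        for v in range(m):
            others = sum(ps[u] for u in range(m) if u != v) / (m - 1)
            upd = ss[v] @ others @ ss[v].T
            if renormalize:
                upd = full_kernel_brute(upd)
            new.append(upd)
        ps = new
    fused = sum(ps) / m
    fused = (fused + fused.T) / 2
    if fused.max() > 0:
        fused = fused / fused.max()
    return fused


def gba_brute(sim, assoc, i, j):
    """Similarity-weighted vote over the other drugs, self term excluded."""
    sim = np.asarray(sim, dtype=float)
    assoc = np.asarray(assoc, dtype=float)
    num = sum(sim[i, l] * assoc[l, j] for l in range(sim.shape[0]) if l != i)
    den = sum(sim[i, l] for l in range(sim.shape[0]) if l != i)
    return num / den if den > 0 else 0.0


def auc_brute(pos, neg):
    """Concordant-pair count with ties worth 1/2."""
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def aupr_brute(pos, neg):
    """Average precision with positives placed after equal-scoring negatives."""
    ranked = sorted([(s, 1) for s in pos] + [(s, 0) for s in neg],
                    key=lambda x: (-x[0], x[1]))
    hits = 0
    precisions = []
    for rank, (_, is_pos) in enumerate(ranked, start=1):
        hits += is_pos
        if is_pos:
            precisions.append(hits / rank)
    return sum(precisions) / len(pos)
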