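"""Independent brute-force reference implementations used as test oracles.

These are deliberately written in the most transparent form possible
(scalar loops, full distance matrices, explicit tallies) and stay
independent of the library code paths they check.
"""

import math

import numpy as np


def fps_bruteforce(coords, m, start_index=0):
    """Greedy maximin selection by explicit O(N^2 m) search."""
    n = len(coords)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    selected = [start_index]
    while len(selected) < m:
        best, best_score = None, -1.0
        for i in range(n):
            if i in selected:
                continue
            score = min(d[i, j] for j in selected)
            if score > best_score:  # strict: ties keep the lowest index
                best, best_score = i, score
        selected.append(best)
    return np.array(selected)


def knn_bruteforce(coords, centroid_indices, k):
    """k nearest by full distance-matrix sort, ties by lowest index."""
    out = []
    for ci in centroid_indices:
        d = np.linalg.norm(coords - coords[ci], axis=1)
        order = sorted(range(len(coords)), key=lambda i: (d[i], i))
        out.append(order[:k])
    return np.array(out)


def pose_scalar(coords, FI, mu, nu):
    """Element-wise scalar evaluation of the trigonometric encoding."""
    n_pairs = FI // 6
    out = np.zeros((len(coords), FI))
    for i, (x, y, z) in enumerate(coords):
        chans = []
        for a in (x, y, z):
            for t in range(n_pairs):
                w = nu ** (6.0 * t / FI)
                chans.append(math.sin(mu * a / w))
                chans.append(math.cos(mu * a / w))
        out[i] = chans
    return out


def metrics_counting(truth, pred, n_classes):
    """Per-point tally of confusion counts, accuracy and mIoU."""
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(truth, pred):
        cm[t, p] += 1
    acc = sum(cm[i, i] for i in range(n_classes)) / len(truth)
    ious = []
    for i in range(n_classes):
        union = cm[i, :].sum() + cm[:, i].sum() - cm[i, i]
        if union > 0:
            ious.append(cm[i, i] / union)
    return cm, acc, float(np.mean(ious))
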