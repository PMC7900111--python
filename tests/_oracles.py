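"""Independent brute-force oracles used to check the evaluation stack.

Everything here is deliberately naive — explicit voxel loops, flood
fill, exhaustive threshold scans, full permutation enumeration — and
shares no code with the package implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def oracle_voxel_metrics(pred, gt, mask):
    """Count TP/FP/FN/TN with an explicit voxel loop and apply the definitions."""
    tp = fp = fn = tn = 0
    for idx in np.ndindex(pred.shape):
        if not mask[idx]:
            continue
        p, g = bool(pred[idx]), bool(gt[idx])
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    dice = 1.0 if tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)
    iou = 1.0 if tp + fp + fn == 0 else tp / (tp + fp + fn)
    precision = 1.0 if (tp + fp == 0 and fn == 0) else (tp / (tp + fp) if tp + fp else 0.0)
    recall = 1.0 if tp + fn == 0 else tp / (tp + fn)
    fpr = fp / (fp + tn) if fp + tn else 0.0
    return {"dice": dice, "iou": iou, "precision": precision, "recall": recall,
            "fpr": fpr, "tp": tp, "fp": fp, "fn": fn, "tn": tn}


def oracle_flood_fill_components(mask):
    """26-connected components via breadth-first flood fill.

    Returns a list of voxel-index sets, one per component.
    """
    mask = np.asarray(mask).astype(bool)
    seen = np.zeros_like(mask)
    offsets = [(i, j, k)
               for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    components = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        comp = set()
        while queue:
            v = queue.pop()
            comp.add(v)
            for off in offsets:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= w[d] < mask.shape[d] for d in range(3)) \
                        and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        components.append(comp)
    return components


def oracle_count_fp(pred, gt, spacing, min_volume_mm3):
    """FP lesions = flood-fill components with no GT overlap, after the size filter."""
    voxel_vol = float(np.prod(spacing))
    fp = 0
    for comp in oracle_flood_fill_components(pred):
        if len(comp) * voxel_vol < min_volume_mm3:
            continue
        if not any(gt[v] for v in comp):
            fp += 1
    return fp


def oracle_youden(probs, gt, mask):
    """Exhaustive scan over every observed probability plus {0, 1}.

    Returns (threshold, J) with ties broken toward the larger threshold.
    """
    pos = [float(probs[idx]) for idx in np.ndindex(probs.shape) if mask[idx] and gt[idx]]
    neg = [float(probs[idx]) for idx in np.ndindex(probs.shape) if mask[idx] and not gt[idx]]
    best_t, best_j = None, -np.inf
    for t in sorted(set(pos) | set(neg) | {0.0, 1.0}):
        sens = sum(v >= t for v in pos) / len(pos)
        spec = sum(v < t for v in neg) / len(neg)
        j = sens + spec - 1.0
        if j >= best_j:  # >= so ties move toward the larger threshold
            best_t, best_j = t, j
    return best_t, best_j


def oracle_rank_sum_p(a, b):
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Assumes no ties.  p = fraction of assignments whose rank sum deviates
    from its mean by at least as much as the observed one.
    """
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n, m = len(a), len(b)
    w_obs = sum(ranks[v] for v in a)
    mu = n * (n + m + 1) / 2.0
    count = total = 0
    for subset in combinations(range(1, n + m + 1), n):
        total += 1
        if abs(sum(subset) - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


def oracle_auc(probs, labels):
    """Mann-Whitney AUC: P(pos > neg) + 0.5 P(tie), by explicit pairing."""
    pos = [p for p, y in zip(probs, labels) if y]
    neg = [p for p, y in zip(probs, labels) if not y]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))
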