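"""Naive reference implementations used to validate the fast code paths.

These deliberately share no code with the production modules: entropy and
the MDL cost are re-derived from their definitions in plain Python, every
midpoint is evaluated (no boundary-point shortcut), and signature selection
enumerates all k-subsets.  They are exponential/quadratic and only usable
on small instances — which is the point: on instances small enough to
enumerate, the production discretizer and IP solver must agree with them
exactly.
"""

from __future__ import annotations

import math
from itertools import combinations


def _entropy(labels: list) -> float:
    n = len(labels)
    ent = 0.0
    for c in set(labels):
        p = labels.count(c) / n
        ent -= p * math.log2(p)
    return ent


def _mdl_threshold(parent: list, left: list, right: list) -> float:
    n = len(parent)
    c = len(set(parent))
    c1, c2 = len(set(left)), len(set(right))
    delta = math.log2(3.0**c - 2.0) - (
        c * _entropy(parent) - c1 * _entropy(left) - c2 * _entropy(right)
    )
    return math.log2(n - 1) / n + delta / n


def mdlp_cuts_reference(values, labels) -> list[float]:
    """Recursive entropy/MDL cuts, evaluating all midpoints naively."""
    pairs = sorted(zip([float(v) for v in values], list(labels)), key=lambda t: t[0])

    def recurse(seq: list[tuple[float, str]]) -> list[float]:
        n = len(seq)
        if n < 2:
            return []
        y = [lab for _, lab in seq]
        parent_ent = _entropy(y)
        best = None
        for i in range(n - 1):
            if seq[i][0] == seq[i + 1][0]:
                continue
            cut = (seq[i][0] + seq[i + 1][0]) / 2.0
            left = [lab for v, lab in seq if v < cut]
            right = [lab for v, lab in seq if v >= cut]
            gain = parent_ent - (
                len(left) / n * _entropy(left) + len(right) / n * _entropy(right)
            )
            if best is None or gain > best[1]:
                best = (cut, gain, left, right)
        if best is None:
            return []
        cut, gain, left, right = best
        if gain <= _mdl_threshold(y, left, right):
            return []
        lower = [t for t in seq if t[0] < cut]
        upper = [t for t in seq if t[0] >= cut]
        return sorted([cut] + recurse(lower) + recurse(upper))

    return recurse(pairs)


def exhaustive_signature_optimum(instance, alpha: int, beta: int):
    """Best coverage over all C(m, k) subsets; None when infeasible.

    Returns ``(objective, selected_set)``; the coverage of a subset is
    recounted pair-by-pair from the instance's boolean rows.
    """
    forced = set(instance.forced)
    features = instance.features
    col = {f: j for j, f in enumerate(features)}
    best = None
    for combo in combinations(features, instance.k):
        sel = set(combo)
        if not forced <= sel:
            continue
        cols = [col[f] for f in sel]
        ok = True
        for row in instance.diff:
            if sum(row[j] for j in cols) < alpha:
                ok = False
                break
        if ok:
            for row in instance.agree:
                if sum(row[j] for j in cols) < beta:
                    ok = False
                    break
        if not ok:
            continue
        cov = int(sum(row[j] for row in instance.diff for j in cols))
        cov += int(sum(row[j] for row in instance.agree for j in cols))
        if best is None or cov > best[0]:
            best = (cov, sel)
    return best
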