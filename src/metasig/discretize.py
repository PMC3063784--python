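"""Recursive entropy-minimisation discretization with the MDL stopping rule.

Used here as a supervised feature *filter*: a candidate binary cut on a
feature is accepted only when its information gain about the class labels
exceeds the minimum-description-length cost of encoding the cut,

    gain(S; T) > log2(N - 1) / N + delta(S; T) / N,

with ``delta = log2(3^c - 2) - [c Ent(S) - c1 Ent(S1) - c2 Ent(S2)]`` where
``N = |S|`` and ``c, c1, c2`` count the distinct classes present in the
parent and the two children.  Accepted cuts are refined recursively within
each induced interval; a feature for which no cut at all is accepted carries
too little class information and is discarded.

Candidate cut points are restricted to *boundary points* — midpoints
between adjacent distinct values whose class composition differs — which is
sufficient for optimality of the entropy criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import CLASS_OTHER, PanelMatrix


def class_entropy(labels) -> float:
    """Shannon entropy of a label multiset, in bits."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty label set is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def best_cut(values, labels) -> tuple[float, float] | None:
    """Best binary cut of a feature by weighted child entropy.

    Returns ``(cut, gain)`` where ``cut`` is a midpoint threshold (samples
    with value < cut go left) minimising
    ``E(T) = |S1|/|S| Ent(S1) + |S2|/|S| Ent(S2)``; ``gain = Ent(S) - E(T)``.
    Ties are broken toward the smallest cut value.  None when no candidate
    cut exists (fewer than two distinct values).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size < 2:
        return None
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = labels[order]
    classes, y_codes = np.unique(y, return_inverse=True)
    k = classes.size
    n = v.size

    # last index of each distinct-value run except the final run
    run_ends = np.nonzero(np.diff(v))[0]
    if run_ends.size == 0:
        return None
    onehot = np.zeros((n, k), dtype=np.int64)
    onehot[np.arange(n), y_codes] = 1
    cum = np.cumsum(onehot, axis=0)

    parent_counts = cum[-1]
    parent_ent = _entropy_from_counts(parent_counts)

    # per-run class-count rows, to restrict candidates to boundary points
    run_bounds = np.concatenate([run_ends, [n - 1]])
    run_counts = np.diff(
        np.vstack([np.zeros(k, dtype=np.int64), cum[run_bounds]]), axis=0
    )

    best: tuple[float, float] | None = None
    for r, edge in enumerate(run_ends):
        left_run, right_run = run_counts[r], run_counts[r + 1]
        # skip midpoints between two runs pure in the same class
        if (
            np.count_nonzero(left_run) == 1
            and np.count_nonzero(right_run) == 1
            and np.argmax(left_run) == np.argmax(right_run)
        ):
            continue
        left_counts = cum[edge]
        n_left = edge + 1
        e_split = (
            n_left / n * _entropy_from_counts(left_counts)
            + (n - n_left) / n * _entropy_from_counts(parent_counts - left_counts)
        )
        gain = parent_ent - e_split
        cut = (v[edge] + v[edge + 1]) / 2.0
        if best is None or gain > best[1]:
            best = (cut, gain)
    return best


def mdl_accept(parent, left, right, gain: float) -> bool:
    """Minimum-description-length acceptance test for a binary cut."""
    parent = np.asarray(parent)
    left = np.asarray(left)
    right = np.asarray(right)
    n = parent.size
    c = np.unique(parent).size
    c1 = np.unique(left).size
    c2 = np.unique(right).size
    ent = class_entropy(parent)
    ent1 = class_entropy(left) if left.size else 0.0
    ent2 = class_entropy(right) if right.size else 0.0
    delta = np.log2(3.0**c - 2.0) - (c * ent - c1 * ent1 - c2 * ent2)
    threshold = np.log2(n - 1) / n + delta / n if n > 1 else np.inf
    return gain > threshold


def discretize_feature(values, labels) -> list[float]:
    """Sorted list of MDL-accepted cut values; empty means the feature fails."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    cuts: list[float] = []

    def recurse(idx: np.ndarray) -> None:
        v, y = values[idx], labels[idx]
        found = best_cut(v, y)
        if found is None:
            return
        cut, gain = found
        left_mask = v < cut
        left, right = y[left_mask], y[~left_mask]
        if left.size == 0 or right.size == 0:
            return
        if not mdl_accept(y, left, right, gain):
            return
        cuts.append(cut)
        recurse(idx[left_mask])
        recurse(idx[~left_mask])

    recurse(np.arange(values.size))
    return sorted(cuts)


@dataclass
class DiscretizationScheme:
    """Per-feature accepted cuts and the induced integer-interval matrix.

    ``discrete`` holds only the features that passed (non-empty cut list);
    a sample's interval index is the number of cuts strictly below (or equal
    to) its value — cuts are half-open thresholds ``value >= cut``.
    """

    cuts: dict[str, list[float]]
    discrete: pd.DataFrame
    labels: pd.Series

    @property
    def passed(self) -> list[str]:
        return list(self.discrete.columns)

    @property
    def pass_fraction(self) -> float:
        return len(self.discrete.columns) / max(len(self.cuts), 1)

    def passed_mask(self) -> dict[str, bool]:
        return {f: bool(c) for f, c in self.cuts.items()}


def apply_cuts(values: np.ndarray, cuts: list[float]) -> np.ndarray:
    """Interval index of each value: count of cuts at or below it."""
    return np.searchsorted(np.asarray(cuts, dtype=float), values, side="right")


def filter_matrix(panel: PanelMatrix, labels: pd.Series | None = None) -> DiscretizationScheme:
    """Fit the MDL filter on (training) case/control samples.

    Samples labelled 'other' are excluded.  The scheme is a training-set
    object only: downstream classification uses continuous values, so the
    discrete matrix is never applied to held-out samples.
    """
    labels = panel.labels if labels is None else labels
    keep = labels[labels != CLASS_OTHER].index
    y = labels.loc[keep]
    if y.nunique() < 2:
        raise ValueError("discretization filter needs both classes present")
    X = panel.values.loc[keep]
    yv = y.to_numpy()
    cuts: dict[str, list[float]] = {}
    cols: dict[str, np.ndarray] = {}
    for name in X.columns:
        v = X[name].to_numpy(dtype=float)
        c = discretize_feature(v, yv)
        cuts[name] = c
        if c:
            cols[name] = apply_cuts(v, c)
    discrete = pd.DataFrame(cols, index=keep, dtype=np.int64)
    return DiscretizationScheme(cuts=cuts, discrete=discrete, labels=y)
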