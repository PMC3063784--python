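"""Exact (alpha, beta)-k feature-set selection over a discretized matrix.

The combinatorial feature-selection model: choose exactly ``k`` features so
that every pair of training samples with *different* class labels is
distinguished by at least ``alpha`` of the chosen features (their
discretized values differ), and every pair with the *same* label agrees on
at least ``beta`` of them.  Among feasible signatures, prefer one that
explains the differences and similarities of as many sample pairs as
possible: each feature is weighted by the number of between-class pairs it
distinguishes plus the number of within-class pairs on which it agrees, and
the total weight of the chosen set is maximised.

``alpha`` is set to the largest value for which the problem stays feasible
at fixed ``k`` with ``beta`` ignored; the minimum over between-class pairs
of the number of distinguishing features (capped at ``k``) bounds it from
above.  ``beta`` is then the largest value (bounded analogously by the
within-class agreement counts) that keeps the joint problem feasible
without disturbing ``k`` or ``alpha``.

A previously known signature may be *forced* into the solution; forced
features that failed the upstream entropy filter are dropped with a
warning, since they carry no discretized information.

The integer program is solved exactly with HiGHS via
:func:`scipy.optimize.milp`, single-threaded with a fixed variable order
(features in name order) for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

logger = logging.getLogger(__name__)


class InfeasibleError(RuntimeError):
    """The selection instance admits no feasible signature."""


@dataclass
class CoverageInstance:
    """Pair-coverage structure of a discretized training set.

    ``diff`` is a boolean matrix (between-class pairs x features): entry
    ``[p, f]`` says feature ``f`` takes different interval values on the two
    samples of pair ``p``.  ``agree`` is the analogue for within-class pairs
    (equal interval values).
    """

    features: list[str]
    between_pairs: list[tuple[str, str]]
    within_pairs: list[tuple[str, str]]
    diff: np.ndarray  # bool, len(between_pairs) x len(features)
    agree: np.ndarray  # bool, len(within_pairs) x len(features)
    k: int
    forced: list[str] = field(default_factory=list)
    alpha: int | None = None
    beta: int | None = None
    unseparable_pairs: list[tuple[str, str]] = field(default_factory=list)

    def feature_weights(self) -> np.ndarray:
        """Pairs explained per feature: diff-coverage + agree-coverage."""
        w = self.diff.sum(axis=0).astype(np.int64)
        if self.agree.size:
            w = w + self.agree.sum(axis=0).astype(np.int64)
        return w

    def coverage_of(self, selected: set[str]) -> int:
        """Total pair coverage of a feature set (solver-independent check)."""
        mask = np.array([f in selected for f in self.features])
        total = int(self.diff[:, mask].sum())
        if self.agree.size:
            total += int(self.agree[:, mask].sum())
        return total

    def satisfies(self, selected: set[str], alpha: int, beta: int) -> bool:
        mask = np.array([f in selected for f in self.features])
        if self.diff.size and (self.diff[:, mask].sum(axis=1) < alpha).any():
            return False
        if self.agree.size and (self.agree[:, mask].sum(axis=1) < beta).any():
            return False
        return True


@dataclass
class Signature:
    """A selected feature set with solver metadata."""

    selected: list[str]  # sorted feature identifiers, |selected| = k
    objective: int
    solver_status: Literal["optimal", "feasible", "infeasible"]
    alpha: int | None = None
    beta: int | None = None
    forced: list[str] = field(default_factory=list)

    def as_set(self) -> set[str]:
        return set(self.selected)


def build_instance(
    scheme,
    k: int,
    forced: list[str] | None = None,
    strict: bool = True,
) -> CoverageInstance:
    """Enumerate all sample pairs of a discretization scheme.

    ``scheme`` is a :class:`~metasig.discretize.DiscretizationScheme` fit on
    the training samples; its integer matrix supplies the differ/agree
    relations.  Forced features that did not pass the filter are dropped
    (logged), mirroring the rule that only the filtered part of a known
    signature can be forced.

    A between-class pair whose discretized profiles are identical cannot be
    separated by any feature set.  With ``strict=True`` this raises; with
    ``strict=False`` such pairs are recorded in ``unseparable_pairs`` and
    drive the alpha cap to zero, as the minimum-count rule implies — used
    by the pruning loop, where suspected mislabelled samples routinely
    shadow a sample of their true class.
    """
    forced = list(forced or [])
    features = sorted(scheme.discrete.columns)
    if k < 1:
        raise ValueError("k must be at least 1")
    D = scheme.discrete[features].to_numpy()
    labels = scheme.labels.to_numpy()
    ids = list(scheme.discrete.index)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("coverage instance requires exactly 2 classes")

    kept_forced = [f for f in forced if f in set(features)]
    dropped = [f for f in forced if f not in set(features)]
    for f in dropped:
        logger.warning("forced feature %r failed the entropy filter; dropped from forced set", f)
    if len(kept_forced) > k:
        raise ValueError(f"k={k} smaller than surviving forced set ({len(kept_forced)})")

    idx_a = np.nonzero(labels == classes[0])[0]
    idx_b = np.nonzero(labels == classes[1])[0]

    between_pairs: list[tuple[str, str]] = []
    diff_rows: list[np.ndarray] = []
    for i in idx_a:
        for j in idx_b:
            between_pairs.append((ids[i], ids[j]))
            diff_rows.append(D[i] != D[j])
    within_pairs: list[tuple[str, str]] = []
    agree_rows: list[np.ndarray] = []
    for group in (idx_a, idx_b):
        for a_pos in range(len(group)):
            for b_pos in range(a_pos + 1, len(group)):
                i, j = group[a_pos], group[b_pos]
                within_pairs.append((ids[i], ids[j]))
                agree_rows.append(D[i] == D[j])

    diff = np.array(diff_rows, dtype=bool).reshape(len(between_pairs), len(features))
    agree = np.array(agree_rows, dtype=bool).reshape(len(within_pairs), len(features))

    empty = np.nonzero(~diff.any(axis=1))[0] if diff.size else np.array([], dtype=int)
    unseparable = [between_pairs[i] for i in empty]
    if unseparable:
        pair = unseparable[0]
        if strict:
            raise InfeasibleError(
                f"samples {pair[0]!r} and {pair[1]!r} have different labels but identical "
                "discretized profiles; no feature set can separate them"
            )
        logger.warning(
            "%d between-class pair(s) share identical discretized profiles "
            "(first: %r vs %r); alpha falls to 0 for this instance",
            len(unseparable), pair[0], pair[1],
        )

    return CoverageInstance(
        features=features,
        between_pairs=between_pairs,
        within_pairs=within_pairs,
        diff=diff,
        agree=agree,
        k=k,
        forced=kept_forced,
        unseparable_pairs=unseparable,
    )


def alpha_cap(instance: CoverageInstance) -> int:
    """Upper bound on alpha: min over between-class pairs of |D(p)|, capped at k."""
    if not instance.between_pairs:
        raise ValueError("instance has no between-class pairs")
    return int(min(instance.k, instance.diff.sum(axis=1).min()))


def max_alpha(instance: CoverageInstance) -> int:
    """Largest alpha for which the problem is feasible at fixed k (beta ignored).

    The pair-count minimum (:func:`alpha_cap`) bounds alpha from above but a
    single k-set must satisfy *all* pairs simultaneously, so feasibility is
    verified by the IP, decrementing from the cap.
    """
    for alpha in range(alpha_cap(instance), -1, -1):
        if _solve_ip(instance, alpha, 0, feasibility_only=True) is not None:
            return alpha
    raise InfeasibleError(f"no alpha >= 0 is feasible at k={instance.k}")


def max_beta(instance: CoverageInstance, alpha: int) -> int:
    """Largest beta keeping (alpha, beta, k, forced) jointly feasible.

    Starts from the cap ``min(k, min_q |S(q)|)`` and decrements, testing
    feasibility of the full integer program at each candidate.
    """
    if not instance.within_pairs:
        return 0
    cap = int(min(instance.k, instance.agree.sum(axis=1).min()))
    for beta in range(cap, -1, -1):
        if _solve_ip(instance, alpha, beta, feasibility_only=True) is not None:
            return beta
    raise InfeasibleError(f"no beta >= 0 is feasible at alpha={alpha}, k={instance.k}")


def _solve_ip(
    instance: CoverageInstance,
    alpha: int,
    beta: int,
    feasibility_only: bool = False,
) -> tuple[np.ndarray, float] | None:
    """Solve the selection IP with HiGHS; None when infeasible."""
    m = len(instance.features)
    weights = instance.feature_weights().astype(float)
    c = np.zeros(m) if feasibility_only else -weights

    constraints = []
    ones = np.ones((1, m))
    constraints.append(LinearConstraint(ones, lb=instance.k, ub=instance.k))
    if alpha > 0 and instance.diff.size:
        A = sparse.csr_matrix(instance.diff.astype(np.int8))
        constraints.append(LinearConstraint(A, lb=alpha, ub=np.inf))
    if beta > 0 and instance.agree.size:
        B = sparse.csr_matrix(instance.agree.astype(np.int8))
        constraints.append(LinearConstraint(B, lb=beta, ub=np.inf))

    lb = np.zeros(m)
    forced_set = set(instance.forced)
    for i, f in enumerate(instance.features):
        if f in forced_set:
            lb[i] = 1.0
    res = milp(
        c=c,
        constraints=constraints,
        integrality=np.ones(m),
        bounds=Bounds(lb=lb, ub=np.ones(m)),
        options={"presolve": True, "mip_rel_gap": 0.0},
    )
    if not res.success or res.x is None:
        return None
    x = np.round(res.x).astype(int)
    return x, float(res.fun)


def solve(instance: CoverageInstance, alpha: int | None = None, beta: int | None = None) -> Signature:
    """Exact coverage-maximising signature under the (alpha, beta, k) rules.

    When ``alpha``/``beta`` are omitted they are derived with
    :func:`max_alpha` and :func:`max_beta`.  The returned signature's
    constraints are re-verified by direct set arithmetic, independently of
    the solver.
    """
    if alpha is None:
        alpha = max_alpha(instance)
    if beta is None:
        beta = max_beta(instance, alpha)
    out = _solve_ip(instance, alpha, beta)
    if out is None:
        raise InfeasibleError(
            f"selection IP infeasible at alpha={alpha}, beta={beta}, k={instance.k}, "
            f"|forced|={len(instance.forced)}"
        )
    x, _ = out
    selected = sorted(f for f, chosen in zip(instance.features, x) if chosen)
    sel_set = set(selected)
    if len(selected) != instance.k or not set(instance.forced) <= sel_set:
        raise RuntimeError("solver returned a structurally invalid signature")
    if not instance.satisfies(sel_set, alpha, beta):
        raise RuntimeError("solver solution violates coverage constraints")
    instance.alpha, instance.beta = alpha, beta
    return Signature(
        selected=selected,
        objective=instance.coverage_of(sel_set),
        solver_status="optimal",
        alpha=alpha,
        beta=beta,
        forced=list(instance.forced),
    )
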