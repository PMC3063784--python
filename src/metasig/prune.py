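"""Iterative data-pruning loop: filter -> select -> classify -> prune.

Each iteration re-fits the entropy filter on the *current* training set,
re-derives alpha and beta, solves the feature-set IP, trains the classifier
panel on the resulting signature and counts, per training sample, how many
panel members disagree with its recorded label under resubstitution.
Samples contradicted by more than a fraction ``tau`` of the panel
(strictly: at least the smallest integer count exceeding ``tau * N``) are
removed together, and the loop repeats on the reduced training set.

Stopping rules: no sample crosses the threshold; the reduced training set
yields the same signature (as a set) as the previous iteration; the
training set has shrunk below a floor; or a hard iteration cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from . import discretize, ensemble, featureset
from .preprocessing import PanelMatrix
from .preprocessing import split_metafeature_name


@dataclass
class PruneConfig:
    k: int = 10
    forced: list[str] = field(default_factory=list)
    threshold_fraction: float = 0.30
    min_train_fraction: float = 0.5
    max_iterations: int = 10
    panel_seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must lie strictly in (0, 1)")
        if not 0.0 < self.min_train_fraction <= 1.0:
            raise ValueError("min_train_fraction must lie in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class PruneIteration:
    index: int
    train_ids: list[str]
    signature: featureset.Signature
    report: ensemble.EnsembleReport
    disagreement: pd.Series
    removed: list[str]


@dataclass
class PruneTrace:
    iterations: list[PruneIteration]
    stop_reason: str

    @property
    def final_signature(self) -> featureset.Signature:
        return self.iterations[-1].signature

    @property
    def removed_samples(self) -> list[str]:
        out: list[str] = []
        for it in self.iterations:
            out.extend(it.removed)
        return out


def flag_threshold(n_classifiers: int, tau: float) -> int:
    """Smallest disagreement count that means 'more than tau * N disagree'.

    ``ceil(tau * N)`` when ``tau * N`` is fractional, ``tau * N + 1`` when it
    is an integer (the rule is strict).  For a 25-member panel at tau = 0.30
    this is 8.
    """
    if n_classifiers < 1:
        raise ValueError("panel size must be >= 1")
    raw = tau * n_classifiers
    nearest = round(raw)
    if abs(raw - nearest) < 1e-9:  # tau * N is an integer up to float error
        return int(nearest) + 1
    return int(math.ceil(raw))


def run_prune_loop(
    train: PanelMatrix,
    config: PruneConfig,
    eval_sets: dict[str, PanelMatrix] | None = None,
    panel: ensemble.ClassifierPanel | None = None,
) -> PruneTrace:
    """Run the four-step loop until one of the stopping rules fires.

    ``train`` must already be z-scored and metafeature-expanded; 'other'
    samples, if present, are dropped up front (they carry no usable label).
    """
    config.validate()
    panel = panel or ensemble.default_panel(config.panel_seed)
    current = train.classified()
    n_original = current.n_samples
    floor = config.min_train_fraction * n_original
    cutoff = flag_threshold(panel.size, config.threshold_fraction)

    iterations: list[PruneIteration] = []
    prev_signature: set[str] | None = None
    stop_reason = "max-iterations"

    for it in range(1, config.max_iterations + 1):
        scheme = discretize.filter_matrix(current)
        instance = featureset.build_instance(
            scheme, k=config.k, forced=config.forced, strict=False
        )
        signature = featureset.solve(instance)
        report = ensemble.fit_predict(panel, current, signature.selected, eval_sets)

        d = report.disagreement
        flagged = sorted(d.index[d >= cutoff], key=list(current.values.index).index)
        iterations.append(
            PruneIteration(
                index=it,
                train_ids=list(current.values.index),
                signature=signature,
                report=report,
                disagreement=d,
                removed=[],
            )
        )

        if prev_signature is not None and signature.as_set() == prev_signature:
            stop_reason = "signature-unchanged"
            break
        prev_signature = signature.as_set()

        if not flagged:
            stop_reason = "no-sample-over-threshold"
            break
        remaining = [s for s in current.values.index if s not in set(flagged)]
        if len(remaining) < floor:
            stop_reason = "train-too-small"
            break
        iterations[-1].removed = flagged
        current = current.subset_samples(remaining)

    return PruneTrace(iterations=iterations, stop_reason=stop_reason)


def strip_single_features(signature: featureset.Signature) -> featureset.Signature:
    """Keep only the metafeatures of a mixed signature (post-processing).

    Used to test whether the single proteins in a selected signature carry
    essential information, or whether the imbalance terms alone suffice.
    """
    metas = [f for f in signature.selected if split_metafeature_name(f) is not None]
    return featureset.Signature(
        selected=metas,
        objective=signature.objective,
        solver_status=signature.solver_status,
        alpha=signature.alpha,
        beta=signature.beta,
        forced=[f for f in signature.forced if f in metas],
    )
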