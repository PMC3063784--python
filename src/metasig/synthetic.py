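"""Synthetic protein-panel generator with planted imbalance signals.

Emulates the statistical regime of a z-scored plasma signalling-protein
panel used for case/control biomarker discovery:

* a background of uninformative proteins scattered around a per-sample
  baseline (the baseline cancels when rows are later z-scored);
* a few *single markers* whose raw abundance is shifted in cases;
* *imbalance pairs* ``(f1, f2)`` that share a large per-sample offset (so
  each member alone has heavily overlapping class distributions) plus an
  antisymmetric class shift of ``+/- imbalance_effect / 2`` with opposite
  sign on the two members — only the difference ``f1 - f2`` separates the
  classes;
* an optional fraction of training samples whose recorded label is flipped,
  modelling clinically mislabelled participants.

Raw abundances are produced; z-scoring is always left to the pipeline so
that the single normalisation code path is exercised everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import CLASS_CASE, CLASS_CONTROL, PanelMatrix, metafeature_name


class ConfigError(ValueError):
    """A generator configuration violates one of its invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the planted-signal generative model.

    Effects are in raw abundance units; ``background_sd`` sets the scale of
    uninformative variation, so effect-to-noise ratios are
    ``single_effect / background_sd`` and
    ``imbalance_effect / background_sd``.
    """

    n_proteins: int = 60
    n_samples_per_class: tuple[int, int] = (40, 40)  # (cases, controls)
    n_single_markers: int = 3
    single_effect: float = 2.0
    n_imbalance_pairs: int = 2
    imbalance_effect: float = 3.0
    shared_noise_sd: float = 8.0
    background_sd: float = 1.0
    mislabel_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 2:
            raise ConfigError("n_proteins must be >= 2")
        if min(self.n_samples_per_class) < 1:
            raise ConfigError("need at least one sample per class")
        if self.n_single_markers < 0 or self.n_imbalance_pairs < 0:
            raise ConfigError("marker counts must be non-negative")
        if self.n_single_markers + 2 * self.n_imbalance_pairs > self.n_proteins:
            raise ConfigError(
                "n_single_markers + 2*n_imbalance_pairs exceeds n_proteins "
                f"({self.n_single_markers} + 2*{self.n_imbalance_pairs} > {self.n_proteins})"
            )
        if not 0.0 <= self.mislabel_fraction <= 1.0:
            raise ConfigError("mislabel_fraction must lie in [0, 1]")
        if self.background_sd <= 0:
            raise ConfigError("background_sd must be positive")
        if self.shared_noise_sd < 0:
            raise ConfigError("shared_noise_sd must be non-negative")


@dataclass
class SyntheticDataset:
    """Generated panel plus the ground truth needed to score recovery."""

    panel: PanelMatrix  # raw abundances with *observed* labels
    true_labels: pd.Series
    single_markers: list[str]
    imbalance_pairs: list[tuple[str, str]]
    mislabelled: list[str]
    config: GeneratorConfig

    @property
    def observed_labels(self) -> pd.Series:
        return self.panel.labels

    def planted_metafeatures(self) -> list[str]:
        """Canonical metafeature names of the planted imbalance pairs."""
        return [metafeature_name(a, b) for a, b in self.imbalance_pairs]


def _protein_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"P{idx:0{width}d}" for idx in range(n)]


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Draw one dataset from the planted-signal model.

    Layout of the protein axis: single markers first, then imbalance-pair
    members (consecutively), then background proteins.  Deterministic for a
    fixed config (seed included).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_case, n_control = config.n_samples_per_class
    n = n_case + n_control
    p = config.n_proteins
    names = _protein_names(p)
    sample_ids = [f"s{idx}" for idx in range(n)]
    y_true = np.array([CLASS_CASE] * n_case + [CLASS_CONTROL] * n_control)
    is_case = y_true == CLASS_CASE

    # per-sample baseline shared by all proteins; cancelled by row z-scoring
    baseline = rng.normal(0.0, 1.0, size=(n, 1))
    X = baseline + rng.normal(0.0, config.background_sd, size=(n, p))

    singles = names[: config.n_single_markers]
    for j in range(config.n_single_markers):
        X[is_case, j] += config.single_effect

    pairs: list[tuple[str, str]] = []
    offset = config.n_single_markers
    for q in range(config.n_imbalance_pairs):
        j1, j2 = offset + 2 * q, offset + 2 * q + 1
        pairs.append((names[j1], names[j2]))
        shared = rng.normal(0.0, config.shared_noise_sd, size=n)
        X[:, j1] += shared
        X[:, j2] += shared
        half = np.where(is_case, config.imbalance_effect / 2.0, -config.imbalance_effect / 2.0)
        X[:, j1] += half
        X[:, j2] -= half

    y_obs = y_true.copy()
    n_flip = round(config.mislabel_fraction * n)
    flipped_ids: list[str] = []
    if n_flip:
        flip_idx = rng.choice(n, size=n_flip, replace=False)
        for i in flip_idx:
            y_obs[i] = CLASS_CONTROL if y_obs[i] == CLASS_CASE else CLASS_CASE
        flipped_ids = sorted((sample_ids[i] for i in flip_idx), key=sample_ids.index)

    panel = PanelMatrix(
        values=pd.DataFrame(X, index=sample_ids, columns=names),
        labels=pd.Series(y_obs, index=sample_ids),
    )
    return SyntheticDataset(
        panel=panel,
        true_labels=pd.Series(y_true, index=sample_ids),
        single_markers=singles,
        imbalance_pairs=pairs,
        mislabelled=flipped_ids,
        config=config,
    )


# ---------------------------------------------------------------------------
# TSV + JSON-sidecar serialisation


def write_dataset(dataset: SyntheticDataset, path: str | Path) -> None:
    """Write the panel as TSV and the planted truth as a JSON sidecar.

    TSV layout: first column ``sample_id``, second ``label``, then one
    column per protein.  Values round-trip at full double precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    write_panel(dataset.panel, path)
    truth = {
        "true_labels": dataset.true_labels.to_dict(),
        "single_markers": dataset.single_markers,
        "imbalance_pairs": [list(p) for p in dataset.imbalance_pairs],
        "mislabelled": dataset.mislabelled,
        "config": asdict(dataset.config),
    }
    path.with_suffix(path.suffix + ".truth.json").write_text(json.dumps(truth, indent=2))


def write_panel(panel: PanelMatrix, path: str | Path) -> None:
    out = panel.values.copy()
    out.insert(0, "label", panel.labels)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_dataset(path: str | Path) -> PanelMatrix:
    """Read a TSV panel written by :func:`write_dataset` / :func:`write_panel`."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"{path}: cannot parse TSV: {exc}") from exc
    if "label" not in frame.columns:
        raise ValueError(f"{path}: missing required 'label' column")
    labels = frame["label"].astype(str)
    values = frame.drop(columns=["label"])
    for col in values.columns:
        converted = pd.to_numeric(values[col], errors="coerce")
        bad = converted.isna() & values[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise ValueError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        values[col] = converted
    return PanelMatrix(values=values.astype(float), labels=labels)
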