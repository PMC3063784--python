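"""Diagnostic summaries: stacked z-score profiles, histograms, metric tables.

The stacked profile sums, per sample, the (z-score or z-score-difference)
values of the signature columns; plotted in input order it shows at a
glance whether the signature's total is systematically displaced in the
case group.  Rendering does no computation of its own — every number drawn
comes from an already-serialised report object.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .ensemble import EnsembleReport
from .preprocessing import CLASS_CASE, CLASS_CONTROL, PanelMatrix

_CLASS_COLOURS = {CLASS_CASE: "#c62828", CLASS_CONTROL: "#1565c0", "other": "#2e7d32"}


@dataclass
class StackedProfile:
    sums: pd.Series  # per-sample total over signature columns
    labels: pd.Series
    signature: list[str]


def stacked_profile(
    panel: PanelMatrix,
    signature: list[str],
    sample_order: list[str] | None = None,
) -> StackedProfile:
    """Per-sample sum of the signature columns, in the given sample order."""
    missing = [c for c in signature if c not in panel.values.columns]
    if missing:
        raise KeyError(f"unknown signature columns: {missing}")
    order = list(sample_order) if sample_order is not None else list(panel.values.index)
    sums = panel.values.loc[order, signature].sum(axis=1)
    return StackedProfile(sums=sums, labels=panel.labels.loc[order], signature=list(signature))


def render_profile(profile: StackedProfile, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 3))
    colours = [_CLASS_COLOURS.get(c, "grey") for c in profile.labels]
    ax.bar(range(len(profile.sums)), profile.sums.to_numpy(), color=colours, width=0.8)
    ax.set_xlabel("sample")
    ax.set_ylabel("stacked signature value")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_histogram(histogram: pd.Series, path: str | Path, panel_size: int | None = None) -> None:
    """Bar plot of disagreement counts; valid (empty axes) for no data."""
    fig, ax = plt.subplots(figsize=(6, 3))
    if len(histogram):
        ax.bar(histogram.index.astype(int), histogram.to_numpy(), color="#37474f")
    ax.set_xlabel("classifiers disagreeing with clinical label")
    ax.set_ylabel("samples")
    if panel_size:
        ax.set_xlim(0.5, panel_size + 0.5)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def metric_table(report: EnsembleReport) -> pd.DataFrame:
    """Average/sd of accuracy, sensitivity, specificity over the panel.

    One row per evaluation set, columns in the conventional
    avg/stdev x acc/sens/spec layout.
    """
    table = report.summary.copy()
    table.columns = [f"{'avg' if stat == 'mean' else 'stdev'} {metric[:4]}" for metric, stat in table.columns]
    order = ["avg accu", "stdev accu", "avg sens", "stdev sens", "avg spec", "stdev spec"]
    return table[order].rename(
        columns={
            "avg accu": "avg acc",
            "stdev accu": "stdev acc",
        }
    )


def write_metric_table(report: EnsembleReport, path: str | Path) -> None:
    metric_table(report).to_csv(path, sep="\t", float_format="%.4f")
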