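"""Per-sample z-scoring and pairwise-difference metafeature expansion.

A plasma antibody-array panel reports, for each sample, the abundance of
``n`` proteins.  Abundances are standardised *within each sample*: protein
``j`` in sample ``i`` becomes ``z_ij = (x_ij - mu_i) / sigma_i`` where
``mu_i`` and ``sigma_i`` are the mean and standard deviation of sample
``i``'s row over all panel proteins.  Every z-score is therefore relative to
the rest of the panel, not to other samples.

Metafeatures model relative imbalance between two signalling proteins: for
every unordered pair ``(a, b)`` the derived column ``z_a - z_b`` is added.
The two orientations carry identical information (one is the negation of the
other), so only the canonical orientation — ``a`` before ``b`` in panel
order — is kept, giving exactly ``n (n - 1) / 2`` metafeature columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd

CLASS_CASE = "case"
CLASS_CONTROL = "control"
CLASS_OTHER = "other"  # excluded from metrics (e.g. other-dementia samples)

VALID_CLASSES = frozenset({CLASS_CASE, CLASS_CONTROL, CLASS_OTHER})

METAFEATURE_SEP = "|-|"


class DegenerateSampleError(ValueError):
    """A sample row cannot be z-scored (zero standard deviation)."""


@dataclass(frozen=True)
class FeatureProvenance:
    """Where a column came from: a measured protein or a difference of two.

    For metafeatures ``members`` is the ordered pair ``(a, b)`` with ``a``
    preceding ``b`` in panel order; the stored column is ``z_a - z_b``.
    """

    kind: Literal["base", "metafeature"]
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind == "base" and len(self.members) != 1:
            raise ValueError("base feature provenance needs exactly one member")
        if self.kind == "metafeature" and len(self.members) != 2:
            raise ValueError("metafeature provenance needs exactly two members")


@dataclass
class PanelMatrix:
    """Samples x features abundance matrix with class labels and provenance.

    ``values`` is indexed by sample id with one column per feature;
    ``labels`` maps each sample id to 'case', 'control' or 'other'.
    """

    values: pd.DataFrame
    labels: pd.Series
    provenance: dict[str, FeatureProvenance] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"missing values in columns {bad}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        if not self.values.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.values.index)
            if self.labels.isna().any():
                raise ValueError("labels missing for some samples")
        unknown = set(self.labels.unique()) - VALID_CLASSES
        if unknown:
            raise ValueError(f"unknown class labels {sorted(unknown)}")
        if not self.provenance:
            self.provenance = {c: FeatureProvenance("base", (c,)) for c in self.values.columns}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def base_features(self) -> list[str]:
        return [c for c in self.values.columns if self.provenance[c].kind == "base"]

    def metafeatures(self) -> list[str]:
        return [c for c in self.values.columns if self.provenance[c].kind == "metafeature"]

    def subset_samples(self, sample_ids) -> "PanelMatrix":
        ids = list(sample_ids)
        return PanelMatrix(
            values=self.values.loc[ids].copy(),
            labels=self.labels.loc[ids].copy(),
            provenance=dict(self.provenance),
        )

    def classified(self) -> "PanelMatrix":
        """Restrict to case/control samples (drop 'other')."""
        keep = self.labels[self.labels != CLASS_OTHER].index
        return self.subset_samples(keep)


def metafeature_name(a: str, b: str) -> str:
    """Canonical column name for the difference z_a - z_b."""
    return f"{a}{METAFEATURE_SEP}{b}"


def split_metafeature_name(name: str) -> tuple[str, str] | None:
    """Inverse of :func:`metafeature_name`; None for base features."""
    if METAFEATURE_SEP not in name:
        return None
    a, b = name.split(METAFEATURE_SEP, 1)
    return a, b


def zscore_rows(raw: PanelMatrix, sd_convention: Literal["sample", "population"] = "sample") -> PanelMatrix:
    """Standardise each sample's row across all base-panel proteins.

    Only base features may be present.  With the default "sample" convention
    the standard deviation uses the n-1 denominator; "population" uses n.
    Raises :class:`DegenerateSampleError` when a sample's row is constant.
    """
    if raw.metafeatures():
        raise ValueError("zscore_rows expects a base-feature panel (no metafeatures)")
    X = raw.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features per sample to z-score")
    ddof = 1 if sd_convention == "sample" else 0
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=ddof, keepdims=True)
    degenerate = np.nonzero(sd.ravel() == 0.0)[0]
    if degenerate.size:
        sid = raw.values.index[degenerate[0]]
        raise DegenerateSampleError(f"sample {sid!r} has zero row standard deviation")
    Z = (X - mu) / sd
    return PanelMatrix(
        values=pd.DataFrame(Z, index=raw.values.index, columns=raw.values.columns),
        labels=raw.labels.copy(),
        provenance=dict(raw.provenance),
    )


def expand_metafeatures(z: PanelMatrix) -> PanelMatrix:
    """Append one difference column per unordered protein pair.

    Input must contain only base features (already z-scored).  Output columns
    are the n base features followed by the n(n-1)/2 canonical pair
    differences in lexicographic panel order.
    """
    base = z.base_features()
    if len(base) != z.n_features:
        raise ValueError("expand_metafeatures expects a base-feature panel")
    if len(base) < 2:
        raise ValueError("need at least 2 base features to form pairs")
    Z = z.values.to_numpy(dtype=float)
    pairs = list(combinations(range(len(base)), 2))
    diff = np.empty((Z.shape[0], len(pairs)), dtype=float)
    names: list[str] = []
    prov = dict(z.provenance)
    for col, (ia, ib) in enumerate(pairs):
        a, b = base[ia], base[ib]
        diff[:, col] = Z[:, ia] - Z[:, ib]
        name = metafeature_name(a, b)
        names.append(name)
        prov[name] = FeatureProvenance("metafeature", (a, b))
    values = pd.concat(
        [z.values, pd.DataFrame(diff, index=z.values.index, columns=names)],
        axis=1,
    )
    return PanelMatrix(values=values, labels=z.labels.copy(), provenance=prov)
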