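"""Entropy discretization and the MDL filter, checked against a naive oracle.

The oracle re-implements recursive MDL discretization from the definitions,
evaluating *every* midpoint between adjacent distinct values at every
recursion level (the production code restricts candidates to class-boundary
midpoints, which is an optimisation, not a behavioural change).
"""

import numpy as np
import pandas as pd
import pytest

from metasig.discretize import (
    apply_cuts,
    best_cut,
    class_entropy,
    discretize_feature,
    filter_matrix,
    mdl_accept,
)
from metasig.preprocessing import PanelMatrix
from tests.conftest import make_panel


# --- independent oracle -----------------------------------------------------


def oracle_entropy(labels):
    labels = list(labels)
    ent = 0.0
    for c in set(labels):
        p = labels.count(c) / len(labels)
        ent -= p * np.log2(p)
    return ent


def oracle_best_cut(values, labels):
    """All-midpoints exhaustive search, smallest cut wins ties."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    y = np.asarray(labels)[order]
    n = len(v)
    parent = class_entropy(y)
    best = None
    for i in range(n - 1):
        if v[i] == v[i + 1]:
            continue
        cut = (v[i] + v[i + 1]) / 2.0
        left, right = y[: i + 1], y[i + 1 :]
        e = len(left) / n * class_entropy(left) + len(right) / n * class_entropy(right)
        gain = parent - e
        if best is None or gain > best[1]:
            best = (cut, gain)
    return best


def oracle_mdlp(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    out = []

    def rec(mask):
        v, y = values[mask], labels[mask]
        if v.size < 2:
            return
        found = oracle_best_cut(v, y)
        if found is None:
            return
        cut, gain = found
        lm = v < cut
        if not mdl_accept(y, y[lm], y[~lm], gain):
            return
        out.append(cut)
        idx = np.nonzero(mask)[0]
        m_left = np.zeros_like(mask)
        m_left[idx[lm]] = True
        m_right = np.zeros_like(mask)
        m_right[idx[~lm]] = True
        rec(m_left)
        rec(m_right)

    rec(np.ones(values.size, dtype=bool))
    return sorted(out)


# --- unit examples ----------------------------------------------------------


class TestClassEntropy:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            (["A"] * 4, 0.0),
            (["A", "A", "B", "B"], 1.0),
            (["A", "A", "A", "B"], -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))),
        ],
    )
    def test_known_values(self, labels, expected):
        assert class_entropy(labels) == pytest.approx(expected, abs=1e-12)

    def test_uniform_k_classes(self):
        assert class_entropy(list("ABCDABCD")) == pytest.approx(2.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            class_entropy([])


class TestBestCut:
    def test_perfect_split(self):
        cut, gain = best_cut([1, 2, 3, 4], ["A", "A", "B", "B"])
        assert cut == pytest.approx(2.5)
        assert gain == pytest.approx(1.0)

    def test_single_distinct_value(self):
        assert best_cut([3.0, 3.0, 3.0], ["A", "B", "A"]) is None

    def test_alternating_labels_matches_exhaustive(self):
        values, labels = [1.0, 2.0, 3.0, 4.0], ["A", "B", "A", "B"]
        got = best_cut(values, labels)
        exp = oracle_best_cut(values, labels)
        assert got is not None and exp is not None
        assert got[0] == exp[0]
        assert got[1] == pytest.approx(exp[1], abs=1e-12)


class TestMdlAccept:
    def test_perfect_binary_split_accepted(self):
        # threshold = (log2 3 + log2 7 - 2) / 4 ~ 0.5984 < gain 1.0
        parent = ["A", "A", "B", "B"]
        assert mdl_accept(parent, ["A", "A"], ["B", "B"], 1.0)
        threshold = np.log2(3) / 4 + (np.log2(7) - 2) / 4
        assert threshold == pytest.approx(0.5984, abs=5e-4)
        assert not mdl_accept(parent, ["A", "A"], ["B", "B"], threshold)

    def test_pure_parent_rejected(self):
        assert not mdl_accept(["A", "A", "A", "A"], ["A", "A"], ["A", "A"], 0.0)


class TestDiscretizeFeature:
    def test_perfectly_separated_single_cut(self):
        cuts = discretize_feature([1, 2, 3, 10, 11, 12], ["A"] * 3 + ["B"] * 3)
        assert cuts == [6.5]

    def test_constant_feature_discarded(self):
        assert discretize_feature([2.0] * 6, ["A", "B"] * 3) == []

    def test_three_cluster_aba_two_cuts(self):
        values = list(range(16)) + list(range(30, 46)) + list(range(60, 76))
        labels = ["A"] * 16 + ["B"] * 16 + ["A"] * 16
        cuts = discretize_feature(values, labels)
        assert cuts == oracle_mdlp(values, labels)
        assert len(cuts) == 2

    def test_interval_index_counts_cuts_below(self, rng):
        values = rng.normal(size=30)
        cuts = [-0.5, 0.8]
        idx = apply_cuts(values, cuts)
        expected = [int(v >= -0.5) + int(v >= 0.8) for v in values]
        np.testing.assert_array_equal(idx, expected)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_instances(self, rng):
        """Pass/fail and cut positions agree with the naive oracle, 250 instances."""
        mismatches = 0
        for _ in range(250):
            n = int(rng.integers(4, 31))
            if rng.random() < 0.5:
                values = rng.normal(size=n)
            else:  # integer grid forces ties between equal values
                values = rng.integers(0, 6, size=n).astype(float)
            labels = rng.choice(["A", "B"], size=n)
            got = discretize_feature(values, labels)
            exp = oracle_mdlp(values, labels)
            if not np.allclose(got, exp) or (len(got) > 0) != (len(exp) > 0):
                mismatches += 1
        assert mismatches == 0

    def test_monotone_transform_invariance(self, rng):
        """Strictly increasing transforms preserve pass/fail and assignments."""
        for _ in range(30):
            n = int(rng.integers(6, 40))
            values = rng.normal(size=n)
            labels = rng.choice(["A", "B"], size=n)
            cuts = discretize_feature(values, labels)
            transformed = np.exp(values / 2.0) + 3.0
            cuts_t = discretize_feature(transformed, labels)
            assert (len(cuts) > 0) == (len(cuts_t) > 0)
            np.testing.assert_array_equal(
                apply_cuts(values, cuts), apply_cuts(transformed, cuts_t)
            )


class TestImbalanceScenario:
    def test_pair_members_fail_alone_but_difference_passes(self):
        """Two proteins share so much sample-level noise that neither passes
        the filter, yet their difference separates the classes cleanly."""
        from metasig import studies
        from metasig.preprocessing import expand_metafeatures, zscore_rows
        from metasig.synthetic import GeneratorConfig, generate

        ds = generate(GeneratorConfig(seed=0, **studies.PAIR_RECOVERY_CONFIG))
        scheme = filter_matrix(expand_metafeatures(zscore_rows(ds.panel)))
        members = [p for pair in ds.imbalance_pairs for p in pair]
        assert all(m not in scheme.passed for m in members)
        assert all(m in scheme.passed for m in ds.planted_metafeatures())


class TestFilterMatrix:
    def test_requires_both_classes(self):
        p = make_panel([[1.0, 2.0], [2.0, 1.0]], ["case", "case"])
        with pytest.raises(ValueError, match="both classes"):
            filter_matrix(p)

    def test_fit_excludes_other_samples(self):
        # the 'other' sample would destroy the perfect split if included
        X = [[0.0], [1.0], [10.0], [11.0], [5.0]]
        p = make_panel(X, ["control", "control", "case", "case", "other"])
        scheme = filter_matrix(p)
        assert scheme.passed == ["f0"]
        assert "s4" not in scheme.discrete.index

    def test_passed_iff_nonempty_cuts(self, rng):
        X = np.column_stack(
            [
                np.r_[rng.normal(0, 1, 10), rng.normal(8, 1, 10)],  # separates
                rng.normal(size=20),  # noise
            ]
        )
        p = make_panel(X, ["control"] * 10 + ["case"] * 10)
        scheme = filter_matrix(p)
        for f, cuts in scheme.cuts.items():
            assert (f in scheme.passed) == bool(cuts)
        assert "f0" in scheme.passed
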