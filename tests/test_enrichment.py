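"""Tests of the differential-enrichment chain and annotation ROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from poca import (
    QuantMatrix, annotation_roc, bh_adjust, call_hits, differential_test,
    impute_perseus, log_transform_and_normalize, run_differential_enrichment,
)


def _qm(values, n_a=2, n_b=2, is_log2=False, ids=None):
    values = np.asarray(values, dtype=float)
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples)
    if ids is None:
        ids = [f"p{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=ids, columns=samples)
    return QuantMatrix(intensities=df, groups=groups, is_log2=is_log2)


# ---------------------------------------------------------------------------
# normalization


class TestLogTransformAndNormalize:
    def test_identical_samples_unchanged(self, rng):
        col = rng.uniform(1, 1e6, 50)
        qm = _qm(np.column_stack([col] * 4))
        out = log_transform_and_normalize(qm)
        np.testing.assert_allclose(out.intensities.to_numpy(),
                                   np.column_stack([np.log2(col)] * 4))

    def test_log2_shift_removed_exactly(self, rng):
        # median centering is shift-equivariant: a +2 log2 shift of one
        # sample is removed, leaving it identical to the others
        base = rng.uniform(1, 1e6, 50)
        shifted = np.column_stack([base, base * 4.0, base, base])
        out = log_transform_and_normalize(_qm(shifted))
        np.testing.assert_allclose(out.intensities["a1"],
                                   out.intensities["a0"], atol=1e-9)

    def test_all_sample_medians_equal(self, rng):
        vals = rng.lognormal(15, 2, (200, 4))
        out = log_transform_and_normalize(_qm(vals))
        medians = out.intensities.median(axis=0)
        np.testing.assert_allclose(medians, medians.iloc[0], atol=1e-9)

    def test_zeros_become_missing(self):
        vals = np.array([[4.0, 0.0, 8.0, 2.0], [2.0, 2.0, 2.0, 2.0],
                         [8.0, 8.0, 8.0, 8.0]])
        out = log_transform_and_normalize(_qm(vals))
        assert np.isnan(out.intensities.iloc[0, 1])

    def test_empty_sample_errors(self):
        vals = np.ones((3, 4))
        vals[:, 2] = 0.0
        with pytest.raises(ValueError, match="zero observed"):
            log_transform_and_normalize(_qm(vals))


# ---------------------------------------------------------------------------
# imputation


class TestImputePerseus:
    def test_no_missing_is_noop(self, rng):
        qm = _qm(rng.normal(20, 2, (50, 4)), is_log2=True)
        out = impute_perseus(qm, seed=1)
        pd.testing.assert_frame_equal(out.intensities, qm.intensities)

    def test_seed_determinism_and_observed_untouched(self, rng):
        vals = rng.normal(20, 2, (100, 4))
        vals[rng.uniform(size=vals.shape) < 0.2] = np.nan
        qm = _qm(vals)
        qm.is_log2 = True
        o1 = impute_perseus(qm, seed=5)
        o2 = impute_perseus(qm, seed=5)
        pd.testing.assert_frame_equal(o1.intensities, o2.intensities)
        mask = ~np.isnan(vals)
        np.testing.assert_array_equal(o1.intensities.to_numpy()[mask],
                                      vals[mask])

    def test_downshifted_normal_moments(self, rng):
        # 1e5 imputed draws follow Normal(mean - 1.8 sd, (0.3 sd)^2)
        n = 200_000
        vals = np.column_stack([
            rng.normal(20, 2, n), rng.normal(20, 2, n),
            rng.normal(20, 2, n), rng.normal(20, 2, n)])
        vals[:n // 2, 0] = np.nan
        qm = _qm(vals)
        qm.is_log2 = True
        obs = pd.Series(vals[n // 2:, 0])
        mu, sd = obs.mean(), obs.std(ddof=1)
        out = impute_perseus(qm, seed=3)
        imputed = out.intensities.iloc[:n // 2, 0]
        se = 0.3 * sd / np.sqrt(n // 2)
        assert imputed.mean() == pytest.approx(mu - 1.8 * sd, abs=3 * se)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sd, rel=0.05)

    def test_too_few_observed_errors(self):
        vals = np.full((3, 4), np.nan)
        vals[0, :] = 20.0
        vals[:, 1:] = 20.0
        qm = _qm(vals)
        qm.is_log2 = True
        with pytest.raises(ValueError, match="fewer than 2"):
            impute_perseus(qm)


# ---------------------------------------------------------------------------
# Welch test


class TestDifferentialTest:
    def test_equal_groups_give_zero_fc(self, rng):
        half = rng.normal(20, 2, (50, 2))
        qm = _qm(np.hstack([half, half]), is_log2=True)
        table = differential_test(qm)
        np.testing.assert_allclose(table["log2fc"], 0.0, atol=1e-12)

    def test_textbook_welch_example(self):
        qm = _qm(np.array([[10.0, 12.0, 8.0, 10.0]]), is_log2=True)
        table = differential_test(qm)
        assert table["log2fc"].iloc[0] == pytest.approx(2.0)
        # hand Welch on A=(10,12), B=(8,10): t = 2/sqrt(2), df = 2
        va = vb = 2.0
        t = 2.0 / np.sqrt(va / 2 + vb / 2)
        df = (va / 2 + vb / 2) ** 2 / ((va / 2) ** 2 + (vb / 2) ** 2)
        p_hand = 2 * stats.t.sf(t, df)
        assert table["p_value"].iloc[0] == pytest.approx(p_hand, abs=1e-12)

    def test_label_permutation_negates_fc_preserves_p(self, rng):
        vals = rng.normal(20, 2, (100, 4))
        qm = _qm(vals, is_log2=True)
        fwd = differential_test(qm, group_a="A", group_b="B")
        rev = differential_test(qm, group_a="B", group_b="A")
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], atol=1e-12)

    def test_zero_variance_equal_means_p_one(self):
        qm = _qm(np.array([[5.0, 5.0, 5.0, 5.0], [5.0, 5.0, 7.0, 7.0]]),
                 is_log2=True)
        table = differential_test(qm)
        assert table["p_value"].iloc[0] == 1.0
        assert not table["test_failed"].iloc[0]
        assert table["test_failed"].iloc[1]
        assert np.isnan(table["p_value"].iloc[1])


# ---------------------------------------------------------------------------
# BH adjustment


def bh_oracle(p):
    """Direct min-over-tail formula: adj_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_idx, i in enumerate(order):
        tail = [m * p[j] / (list(order).index(j) + 1)
                for j in order[rank_idx:]]
        adj[i] = min(min(tail), 1.0)
    return adj


class TestBhAdjust:
    @pytest.mark.parametrize("p, expected", [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.05, 0.01], [0.05, 0.02]),
    ])
    def test_closed_form_cases(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 30))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-9)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_nan_passthrough(self):
        adj = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], [0.02, 0.04])


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_monotone_and_dominates_raw(p):
    """BH is rank-monotone and never below the raw p-value."""
    adj = bh_adjust(p)
    p = np.asarray(p)
    assert np.all(adj >= p - 1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# hit calling


class TestCallHits:
    def _table(self, fc, q):
        return pd.DataFrame({"log2fc": [fc], "p_value": [q], "adj_p": [q]},
                            index=["p0"])

    @pytest.mark.parametrize("fc, q, expect", [
        (3.0, 0.01, True),
        (1.0, 0.01, False),   # strictly greater than 2-fold
        (3.0, 0.05, False),   # strictly below FDR 0.05
        (1.0001, 0.0499, True),
        (-3.0, 0.01, False),  # directional by default
    ])
    def test_strict_thresholds(self, fc, q, expect):
        out = call_hits(self._table(fc, q))
        assert bool(out["is_hit"].iloc[0]) is expect

    def test_two_sided_mode(self):
        out = call_hits(self._table(-3.0, 0.01), two_sided=True)
        assert bool(out["is_hit"].iloc[0])

    def test_requires_adj_p(self):
        with pytest.raises(ValueError, match="adj_p"):
            call_hits(pd.DataFrame({"log2fc": [1.0]}))


# ---------------------------------------------------------------------------
# annotation ROC


def auc_pair_count_oracle(scores, labels):
    """Tie-corrected Mann–Whitney pair count: P(score+ > score-) + P(=)/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestAnnotationRoc:
    def _table(self, scores, ids=None):
        ids = ids or [f"p{i}" for i in range(len(scores))]
        return pd.DataFrame({"log2fc": scores}, index=ids)

    def test_perfect_separation(self):
        table = self._table([3, 2, 1, 0, -1])
        roc = annotation_roc(table, {"p0", "p1"})
        assert roc.auc == pytest.approx(1.0)
        assert roc.youden_max == pytest.approx(1.0)

    def test_worked_pair_count_example(self):
        table = self._table([3, 2, 1, 0, -1])
        # positives {3, -1} vs negatives {2, 1, 0}: concordant pairs are
        # 3>2, 3>1, 3>0 and none for -1, so AUC = 3/6 = 0.5
        roc = annotation_roc(table, {"p0", "p4"})
        assert roc.auc == pytest.approx(
            auc_pair_count_oracle([3, 2, 1, 0, -1],
                                  [True, False, False, False, True]))
        assert roc.auc == pytest.approx(0.5)

    def test_matches_pair_count_oracle_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 25))
            scores = rng.integers(-3, 4, n).astype(float)  # many ties
            labels = rng.uniform(size=n) < 0.4
            if labels.all() or not labels.any():
                continue
            table = self._table(list(scores))
            pos = {f"p{i}" for i in range(n) if labels[i]}
            roc = annotation_roc(table, pos)
            assert roc.auc == pytest.approx(
                auc_pair_count_oracle(scores, labels), abs=1e-9)

    def test_random_labels_auc_near_half(self, rng):
        aucs = []
        scores = rng.normal(size=2000)
        table = self._table(list(scores))
        for _ in range(50):
            pos = {f"p{i}" for i in rng.choice(2000, 300, replace=False)}
            aucs.append(annotation_roc(table, pos).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_single_class_errors(self):
        table = self._table([1.0, 2.0])
        with pytest.raises(ValueError):
            annotation_roc(table, {"p0", "p1"})

    def test_youden_threshold_separates(self):
        table = self._table([5, 4, 3, -3, -4, -5])
        roc = annotation_roc(table, {"p0", "p1", "p2"})
        assert -3 < roc.youden_optimal_threshold <= 5
        assert roc.youden_max == pytest.approx(1.0)


class TestEndToEnd:
    def test_full_chain_orders_operations(self, rng):
        vals = rng.lognormal(15, 2, (100, 4))
        samples = [f"a{i}" for i in range(2)] + [f"b{i}" for i in range(2)]
        df = pd.DataFrame(vals, index=[f"p{i}" for i in range(100)],
                          columns=samples)
        groups = pd.Series(["A", "A", "B", "B"], index=samples)
        table = run_differential_enrichment(df, groups, seed=4)
        assert set(table.columns) >= {"log2fc", "p_value", "adj_p", "is_hit"}
        valid = table["adj_p"].notna()
        assert np.all(table.loc[valid, "adj_p"] >= table.loc[valid, "p_value"] - 1e-12)
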