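"""Agreement statistics and LOSO bookkeeping."""

import itertools

import numpy as np
import pytest

from wristpose.evaluate import (
    FoldResult,
    _audit_fold_isolation,
    cohen_kappa,
    contingency_table,
    landis_koch_label,
    normalize_rows,
    summarize_folds,
    within_k_bins,
)

from conftest import make_window_set


def kappa_oracle(true, pred):
    """Direct p_o/p_e arithmetic from raw contingency counts."""
    n = len(true)
    classes = sorted(set(true) | set(pred))
    p_o = sum(t == p for t, p in zip(true, pred)) / n
    p_e = sum(
        (sum(t == k for t in true) / n) * (sum(p == k for p in pred) / n)
        for k in classes
    )
    if p_e == 1:
        return 1.0
    return (p_o - p_e) / (1 - p_e)


class TestCohenKappa:
    def test_perfect_agreement_is_one(self):
        assert cohen_kappa([0, 1, 2, 1], [0, 1, 2, 1]) == 1.0

    def test_perfect_disagreement_two_items(self):
        # p_o = 0, p_e = 0.5 by hand -> kappa = -1
        assert cohen_kappa([0, 1], [1, 0]) == pytest.approx(-1.0)

    def test_constant_identical_sequences_degenerate_case(self):
        assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa([0, 1], [0])

    def test_exhaustive_small_instances_match_oracle(self):
        """All label pairs up to length 4 over 3 classes, exhaustively."""
        for length in range(1, 5):
            for true in itertools.product(range(3), repeat=length):
                for pred in itertools.product(range(3), repeat=length):
                    assert cohen_kappa(list(true), list(pred)) == pytest.approx(
                        kappa_oracle(true, pred)
                    ), (true, pred)

    def test_random_longer_instances_match_oracle_and_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(5, 40)
            true = rng.integers(0, 4, n)
            pred = rng.integers(0, 4, n)
            ours = cohen_kappa(true, pred)
            assert ours == pytest.approx(kappa_oracle(true.tolist(), pred.tolist()))
            if len(set(true) | set(pred)) > 1:
                assert ours == pytest.approx(cohen_kappa_score(true, pred))

    def test_kappa_equals_accuracy_under_uniform_balanced_marginals(self):
        """With uniform marginals over K classes, p_e = 1/K and
        kappa = (acc - 1/K)/(1 - 1/K); constructed so acc = kappa map is
        checkable: at acc = 1 both are 1, at acc = 1/K kappa = 0."""
        true = np.repeat([0, 1, 2], 30)
        pred = true.copy()
        for c in range(3):  # rotate 10 of each class forward: marginals stay uniform
            idx = np.flatnonzero(true == c)[:10]
            pred[idx] = (c + 1) % 3
        assert np.all(np.bincount(pred) == 30)
        acc = np.mean(true == pred)
        k = cohen_kappa(true, pred)
        assert k == pytest.approx((acc - 1 / 3) / (1 - 1 / 3))


class TestLandisKoch:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (-0.2, "Poor"), (0.0, "Slight"), (0.20, "Slight"), (0.28, "Fair"),
            (0.40, "Fair"), (0.41, "Moderate"), (0.60, "Moderate"),
            (0.7, "Substantial"), (0.85, "Almost Perfect"), (1.0, "Almost Perfect"),
        ],
    )
    def test_threshold_bands(self, kappa, label):
        assert landis_koch_label(kappa) == label

    def test_out_of_range_rejected(self):
        for bad in (-1.5, 1.5, np.nan):
            with pytest.raises(ValueError):
                landis_koch_label(bad)


class TestContingency:
    def test_diagonal_counts(self):
        table = contingency_table([0, 0, 1], [0, 0, 1], n_classes=2)
        np.testing.assert_array_equal(table, [[2, 0], [0, 1]])

    def test_row_normalized_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        true = rng.integers(0, 5, 200)
        pred = rng.integers(0, 5, 200)
        norm = contingency_table(true, pred, 5, normalize="row")
        np.testing.assert_allclose(norm.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_rows_become_nan_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            norm = normalize_rows(np.array([[0, 0], [3, 1]]))
        assert np.all(np.isnan(norm[0]))
        np.testing.assert_allclose(norm[1], [0.75, 0.25])

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            contingency_table([0, 5], [0, 1], n_classes=5)


class TestWithinKBins:
    def test_printed_extreme_flexion_row_within_one_bin(self):
        """Row [0.30, 0.69, 0, 0.01, 0] for the most-flexed class: the
        within-1-bin rate is 0.30 + 0.69 = 0.99."""
        m = np.array(
            [
                [0.30, 0.69, 0.00, 0.01, 0.00],
                [0.00, 0.55, 0.39, 0.03, 0.03],
                [0.00, 0.03, 0.64, 0.29, 0.04],
                [0.00, 0.00, 0.15, 0.65, 0.20],
                [0.00, 0.00, 0.02, 0.18, 0.80],
            ]
        )
        rates = within_k_bins(m, k=1)
        assert rates[0] == pytest.approx(0.99)

    def test_identity_matrix_is_one_for_any_k(self):
        for k in (0, 1, 3):
            np.testing.assert_allclose(within_k_bins(np.eye(4), k=k), 1.0)

    def test_full_span_k_gives_one_everywhere(self):
        rng = np.random.default_rng(0)
        m = rng.random((5, 5))
        m /= m.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(within_k_bins(m, k=4), 1.0)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            within_k_bins(np.zeros((2, 3)))


class TestFoldBookkeeping:
    def _fold(self, true, pred, target="fe", participant=1):
        counts = contingency_table(true, pred, 5)
        return FoldResult(
            test_participant=participant,
            target=target,
            accuracy=float(np.mean(np.array(true) == np.array(pred))),
            kappa=cohen_kappa(true, pred),
            contingency=counts,
            n_test_windows=len(true),
            y_true=np.array(true),
            y_pred=np.array(pred),
        )

    def test_inconsistent_accuracy_rejected(self):
        counts = contingency_table([0, 1], [0, 1], 5)
        with pytest.raises(ValueError, match="accuracy"):
            FoldResult(1, "fe", 0.5, 1.0, counts, 2)

    def test_summary_mean_and_standard_error(self):
        folds = [
            self._fold([0, 1, 2, 3], [0, 1, 2, 3], participant=1),
            self._fold([0, 1, 2, 3], [0, 1, 2, 0], participant=2),
        ]
        s = summarize_folds(folds, "fe")
        accs = np.array([1.0, 0.75])
        assert s.mean_accuracy == pytest.approx(accs.mean())
        assert s.se_accuracy == pytest.approx(accs.std(ddof=1) / np.sqrt(2))
        # cumulative table sums counts before normalization
        assert s.cumulative_counts.sum() == 8

    def test_label_shuffle_drives_kappa_to_chance(self):
        """Permuting one side of a large label pairing yields kappa ~ 0."""
        rng = np.random.default_rng(3)
        true = rng.integers(0, 5, 20000)
        k = cohen_kappa(rng.permutation(true), true)
        assert abs(k) < 0.05


class TestFoldIsolation:
    def test_overlapping_sets_are_detected(self):
        ws = make_window_set(np.linspace(-30, 30, 40))
        with pytest.raises(RuntimeError, match="fold isolation"):
            _audit_fold_isolation(ws, ws.select(np.arange(5)))

    def test_disjoint_sets_pass(self):
        a = make_window_set(np.linspace(-30, 30, 20), seed=1)
        b = make_window_set(np.linspace(-30, 30, 20), seed=2)
        _audit_fold_isolation(a, b)
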