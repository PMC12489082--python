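"""ADASYN against a brute-force oracle, augmentation algebra, splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beltscan.errors import ValidationError
from beltscan.resampling import (
    LabeledTable,
    adasyn,
    augment_images,
    balance_dataset,
    hflip,
    largest_remainder,
    leakage_safe_split,
    rot180,
    vflip,
)


def brute_force_delta(minority, majority, k):
    """Hand k-NN: majority fraction among each minority point's neighbors."""
    combined = np.vstack([minority, majority])
    deltas = []
    for i, x in enumerate(minority):
        d = np.linalg.norm(combined - x, axis=1)
        d[i] = np.inf
        neigh = np.argsort(d, kind="stable")[:k]
        deltas.append(sum(1 for j in neigh if j >= len(minority)))
    return np.array(deltas)


class TestAdasyn:
    def test_26_vs_134_at_beta_one_generates_exactly_108(self, rng):
        minority = rng.normal(size=(26, 128))
        majority = rng.normal(loc=3.0, size=(134, 128))
        synth, parents = adasyn(minority, majority, k=5, beta=1.0, seed=0)
        assert len(synth) == 108
        assert len(parents) == 108

    def test_balanced_input_generates_nothing(self, rng):
        x = rng.normal(size=(20, 4))
        synth, _ = adasyn(x[:10], x[10:], k=3, beta=1.0, seed=0)
        assert len(synth) == 0

    def test_toy_allocation_matches_the_hand_oracle(self):
        minority = np.array([[0.0, 0.0], [0.0, 1.0]])
        majority = np.array([[5.0, 5.0], [5.0, 6.0], [6.0, 5.0], [6.0, 6.0]])
        k = 3
        delta = brute_force_delta(minority, majority, k)
        # both minority points have 1 minority + 2 majority among 3 neighbors
        np.testing.assert_array_equal(delta, [2, 2])
        synth, parents = adasyn(minority, majority, k=k, beta=1.0, seed=0)
        assert len(synth) == 2  # G = 4 - 2, split 1 + 1 by equal weights
        # every synthetic point lies on the segment between the two minority points
        for s in synth:
            assert abs(s[0]) <= 1e-12
            assert -1e-12 <= s[1] <= 1 + 1e-12

    def test_synthetic_points_are_convex_combinations_of_minority_pairs(self, rng):
        minority = rng.normal(size=(12, 6))
        majority = rng.normal(loc=2.0, size=(40, 6))
        synth, parents = adasyn(minority, majority, k=5, beta=1.0, seed=3)
        assert len(synth) == 28
        for s, (i, z) in zip(synth, parents):
            a, b = minority[i], minority[z]
            span = b - a
            denom = float(span @ span)
            lam = 0.0 if denom == 0 else float((s - a) @ span) / denom
            assert -1e-9 <= lam <= 1 + 1e-9
            np.testing.assert_allclose(s, a + lam * span, atol=1e-9)

    def test_determinism_under_seed(self, rng):
        minority = rng.normal(size=(8, 3))
        majority = rng.normal(loc=2.0, size=(30, 3))
        s1, p1 = adasyn(minority, majority, seed=11)
        s2, p2 = adasyn(minority, majority, seed=11)
        np.testing.assert_array_equal(s1, s2)
        assert p1 == p2

    def test_fewer_than_two_minority_points_rejected(self, rng):
        with pytest.raises(ValidationError):
            adasyn(rng.normal(size=(1, 3)), rng.normal(size=(5, 3)))

    @given(
        m=st.integers(2, 15),
        extra=st.integers(0, 40),
        beta=st.floats(0.1, 1.0),
        seed=st.integers(0, 10),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_allocation_total_is_exact_for_any_sizes(self, m, extra, beta, seed):
        rng = np.random.default_rng(seed)
        minority = rng.normal(size=(m, 4))
        majority = rng.normal(loc=1.5, size=(m + extra, 4))
        synth, _ = adasyn(minority, majority, k=5, beta=beta, seed=seed)
        assert len(synth) == round(beta * extra)


class TestLargestRemainder:
    @given(
        n=st.integers(1, 30),
        total=st.integers(0, 500),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sums_exactly_to_the_total(self, n, total, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0, 1, size=n)
        w = w / w.sum()
        alloc = largest_remainder(w * total, total)
        assert alloc.sum() == total
        assert np.all(alloc >= 0)


class TestBalance:
    @staticmethod
    def table(n0, n1, dim=8, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(size=(n0, dim)),
                       rng.normal(loc=4.0, size=(n1, dim))])
        y = np.array([0] * n0 + [1] * n1)
        ids = [f"c{i}" for i in range(n0 + n1)]
        return LabeledTable(X, y, ids)

    def test_26_vs_134_becomes_134_each_268_total(self):
        out = balance_dataset(self.table(26, 134))
        assert out.class_counts() == {0: 134, 1: 134}
        assert len(out) == 268
        assert out.provenance.count("synthetic") == 108
        for i in range(len(out)):
            if out.provenance[i] == "synthetic":
                assert len(out.parents[i]) == 2

    def test_already_balanced_is_unchanged(self):
        t = self.table(30, 30)
        assert balance_dataset(t) is t

    @pytest.mark.parametrize("n0,n1,beta", [(5, 20, 1.0), (10, 37, 0.5),
                                            (4, 50, 0.25)])
    def test_row_count_is_input_plus_allocation(self, n0, n1, beta):
        out = balance_dataset(self.table(n0, n1), beta=beta)
        assert len(out) == n0 + n1 + round(beta * (n1 - n0))

    def test_single_class_rejected(self):
        t = LabeledTable(np.zeros((5, 3)), np.ones(5), [f"c{i}" for i in range(5)])
        with pytest.raises(ValidationError):
            balance_dataset(t)


class TestAugmentation:
    @staticmethod
    def images(n=12, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 255, size=(n, 8, 10, 3)).astype(np.uint8)
        return LabeledTable(X, rng.integers(0, 2, size=n),
                            [f"img{i}" for i in range(n)])

    def test_quadruples_the_count_with_copied_labels(self):
        t = self.images(12)
        out = augment_images(t)
        assert len(out) == 48
        np.testing.assert_array_equal(out.y, np.tile(t.y, 4))
        assert out.provenance.count("augmented") == 36

    def test_flips_are_involutions(self):
        x = self.images().X
        np.testing.assert_array_equal(hflip(hflip(x)), x)
        np.testing.assert_array_equal(vflip(vflip(x)), x)
        np.testing.assert_array_equal(rot180(rot180(x)), x)

    def test_rotation_equals_both_flips_pixel_exact(self):
        x = self.images().X
        np.testing.assert_array_equal(rot180(x), vflip(hflip(x)))
        np.testing.assert_array_equal(rot180(x), hflip(vflip(x)))

    def test_empty_set_rejected(self):
        t = LabeledTable(np.zeros((0, 4, 4, 3)), np.zeros(0), [])
        with pytest.raises(ValidationError):
            augment_images(t)


class TestLeakageSafeSplit:
    @staticmethod
    def augmented_table(n=140):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(n, 4, 4, 1))
        t = LabeledTable(X, rng.uniform(1, 30, size=n),
                         [f"case{i:03d}" for i in range(n)])
        return augment_images(t)

    def test_removing_test_descendants_leaves_520_of_560(self):
        table = self.augmented_table(140)
        test_ids = {f"case{i:03d}" for i in range(10)}
        train, val, test = leakage_safe_split(table, test_ids, 0.8, seed=0)
        assert len(table) == 560
        assert len(test) == 10
        assert len(train) + len(val) == 520

    def test_empty_test_ids_split_the_full_pool(self):
        table = self.augmented_table(20)
        train, val, test = leakage_safe_split(table, set(), 0.8, seed=0)
        assert len(test) == 0
        assert len(train) + len(val) == len(table)

    def test_no_case_appears_on_both_sides(self):
        table = self.augmented_table(40)
        test_ids = {f"case{i:03d}" for i in range(0, 40, 7)}
        train, val, test = leakage_safe_split(table, test_ids, 0.8, seed=3)

        def roots(t):
            out = set()
            for i in range(len(t)):
                out |= set(t.parents[i]) if t.parents[i] else {t.case_ids[i]}
            return out

        assert roots(train) & roots(val) == set()
        assert roots(train) & roots(test) == set()
        assert roots(val) & roots(test) == set()

    def test_deterministic_under_seed(self):
        table = self.augmented_table(30)
        a = leakage_safe_split(table, {"case001"}, 0.8, seed=9)
        b = leakage_safe_split(table, {"case001"}, 0.8, seed=9)
        for ta, tb in zip(a, b):
            assert ta.case_ids == tb.case_ids

    def test_unknown_test_id_rejected(self):
        table = self.augmented_table(10)
        with pytest.raises(ValidationError):
            leakage_safe_split(table, {"nope"}, 0.8, seed=0)
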