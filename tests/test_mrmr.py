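"""Mutual information estimator and MRMR greedy selection vs brute force."""

import math
from collections import Counter

import numpy as np
import pytest

import boldfusion as bf
from boldfusion.mrmr import discretize


# ---------------------------------------------------------------------------
# independent oracle: plug-in MI via dictionaries, naive greedy selection
# ---------------------------------------------------------------------------

def oracle_mi(a, b):
    """Plug-in MI (bits) computed with plain Python counting."""
    n = len(a)
    joint = Counter(zip(a.tolist(), b.tolist()))
    pa = Counter(a.tolist())
    pb = Counter(b.tolist())
    total = 0.0
    for (va, vb), c in joint.items():
        pxy = c / n
        total += pxy * math.log2(pxy * n * n / (pa[va] * pb[vb]))
    return total


def oracle_mrmr(X, y, m, criterion, bins=8):
    """Naive greedy MRMR sharing only the discretizer with the package."""
    codes = [discretize(X[:, j], bins) for j in range(X.shape[1])]
    ycode = discretize(y, bins)
    K = X.shape[1]
    rel = [oracle_mi(codes[j], ycode) for j in range(K)]
    selected = [max(range(K), key=lambda j: (rel[j], -j))]
    while len(selected) < m:
        candidates = [j for j in range(K) if j not in selected]
        scores = {}
        for j in candidates:
            red = sum(oracle_mi(codes[i], codes[j]) for i in selected) / len(selected)
            if criterion == "MID":
                scores[j] = rel[j] - red
            else:
                scores[j] = rel[j] / red if red > 0 else rel[j] - red
        selected.append(max(candidates, key=lambda j: (scores[j], -j)))
    return selected


class TestMutualInformation:
    def test_identity_of_four_equiprobable_values_is_two_bits(self):
        x = np.tile([0, 1, 2, 3], 25)
        assert bf.mutual_information(x, x) == pytest.approx(2.0)

    def test_constant_is_independent_of_everything(self, rng):
        y = rng.integers(0, 3, size=50)
        assert bf.mutual_information(np.zeros(50), y) == 0.0

    def test_small_joint_table_matches_direct_sum(self):
        # joint counts [[2,1],[1,2]] over n=6
        x = np.array([0, 0, 0, 1, 1, 1])
        y = np.array([0, 0, 1, 0, 1, 1])
        expected = (
            2 * (2 / 6) * math.log2((2 / 6) / (0.5 * 0.5))
            + 2 * (1 / 6) * math.log2((1 / 6) / (0.5 * 0.5))
        )
        assert bf.mutual_information(x, y) == pytest.approx(expected)
        assert expected == pytest.approx(0.0817, abs=5e-5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bf.mutual_information(np.zeros(5), np.zeros(6))

    @pytest.mark.parametrize("seed", range(6))
    def test_symmetry_nonnegativity_entropy_bound(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 4, size=60)
        y = r.integers(0, 3, size=60)
        mi_xy = bf.mutual_information(x, y)
        assert mi_xy == pytest.approx(bf.mutual_information(y, x), abs=1e-12)
        assert mi_xy >= 0.0
        h_x = bf.mutual_information(x, x)
        h_y = bf.mutual_information(y, y)
        assert mi_xy <= min(h_x, h_y) + 1e-12


class TestRelevanceRedundancy:
    def test_feature_identical_to_labels_has_relevance_h_of_y(self, rng):
        y = rng.integers(0, 4, size=80)
        fm = bf.FeatureMatrix(y[:, None].astype(float), y)
        h_y = bf.mutual_information(y, y)
        assert bf.relevance(fm, [0]) == pytest.approx(h_y)

    def test_relevance_is_the_mean_of_per_feature_mi(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.integers(0, 2, size=60)
        fm = bf.FeatureMatrix(X, y)
        per = [bf.mutual_information(X[:, j], y) for j in range(4)]
        assert bf.relevance(fm, [0, 1, 2, 3]) == pytest.approx(np.mean(per))

    def test_noise_feature_has_near_zero_relevance_at_large_n(self, rng):
        X = rng.normal(size=(5000, 1))
        y = rng.integers(0, 2, size=5000)
        fm = bf.FeatureMatrix(X, y)
        assert bf.relevance(fm, [0]) < 0.01  # small-sample bias bound

    def test_single_feature_redundancy_is_its_self_information(self, rng):
        x = rng.integers(0, 4, size=100).astype(float)
        fm = bf.FeatureMatrix(x[:, None], rng.integers(0, 2, 100))
        assert bf.redundancy(fm, [0]) == pytest.approx(
            bf.mutual_information(x, x)
        )

    def test_duplicated_pair_redundancy_collapses_to_self_information(self, rng):
        x = rng.integers(0, 4, size=100).astype(float)
        fm = bf.FeatureMatrix(np.column_stack([x, x]), rng.integers(0, 2, 100))
        # all four ordered-pair terms equal I(F,F)
        assert bf.redundancy(fm, [0, 1]) == pytest.approx(bf.mutual_information(x, x))

    def test_independent_features_redundancy_approaches_mean_self_information(self, rng):
        X = rng.integers(0, 4, size=(20000, 2)).astype(float)
        fm = bf.FeatureMatrix(X, rng.integers(0, 2, 20000))
        h = [bf.mutual_information(X[:, j], X[:, j]) for j in range(2)]
        assert bf.redundancy(fm, [0, 1]) == pytest.approx(sum(h) / 4, abs=0.01)

    def test_empty_set_rejected(self, rng):
        fm = bf.FeatureMatrix(rng.normal(size=(10, 2)), rng.integers(0, 2, 10))
        with pytest.raises(ValueError):
            bf.relevance(fm, [])
        with pytest.raises(ValueError):
            bf.redundancy(fm, [])


class TestSelection:
    def test_m_equals_one_returns_the_most_relevant_feature(self, rng):
        X = rng.normal(size=(100, 6))
        y = rng.integers(0, 2, size=100)
        X[:, 4] = y + 0.05 * rng.normal(size=100)
        result = bf.mrmr_select(bf.FeatureMatrix(X, y), 1)
        assert result.indices == [4]

    def test_duplicate_of_the_best_feature_is_deferred(self, rng):
        n = 60
        y = np.tile([0, 1, 2, 3], 15)
        f1 = y.copy()
        f1[rng.choice(n, 5, replace=False)] = rng.integers(0, 4, 5)
        f3 = y.copy()
        f3[rng.choice(n, 10, replace=False)] = rng.integers(0, 4, 10)
        X = np.column_stack([f1, f1, f3, rng.integers(0, 4, n)]).astype(float)
        result = bf.mrmr_select(bf.FeatureMatrix(X, y), 3, criterion="MID")
        assert result.indices[0] == 0  # most relevant, lowest index on the tie
        assert result.indices[1] == 2  # independent informative beats the duplicate
        assert 1 not in result.indices[:2]

    @pytest.mark.parametrize("criterion", ["MID", "MIQ"])
    def test_greedy_matches_brute_force_oracle_for_all_m(self, criterion):
        r = np.random.default_rng(77)
        n, K = 100, 10
        y = r.integers(0, 3, size=n)
        X = r.normal(size=(n, K))
        X[:, 2] += y  # informative
        X[:, 5] = X[:, 2] + 0.1 * r.normal(size=n)  # redundant partner
        X[:, 7] -= 0.8 * y
        fm = bf.FeatureMatrix(X, y)
        for m in range(1, K + 1):
            ours = bf.mrmr_select(fm, m, criterion=criterion).indices
            assert ours == oracle_mrmr(X, y, m, criterion), f"m={m}"

    def test_traces_match_direct_definitions(self, rng):
        X = rng.normal(size=(80, 6))
        y = rng.integers(0, 2, size=80)
        X[:, 1] += y
        fm = bf.FeatureMatrix(X, y)
        result = bf.mrmr_select(fm, 4)
        for step in range(4):
            S = result.indices[: step + 1]
            assert result.relevance_trace[step] == pytest.approx(
                bf.relevance(fm, S), abs=1e-10
            )
            assert result.redundancy_trace[step] == pytest.approx(
                bf.redundancy(fm, S), abs=1e-10
            )

    def test_invalid_requests_rejected(self, rng):
        fm = bf.FeatureMatrix(rng.normal(size=(30, 4)), rng.integers(0, 2, 30))
        with pytest.raises(ValueError):
            bf.mrmr_select(fm, 5)
        with pytest.raises(ValueError):
            bf.mrmr_select(fm, 2, criterion="MAD")
        single = bf.FeatureMatrix(rng.normal(size=(30, 4)), np.zeros(30))
        with pytest.raises(ValueError, match="2 classes"):
            bf.mrmr_select(single, 2)

    def test_selection_is_deterministic(self, rng):
        X = rng.normal(size=(60, 8))
        y = rng.integers(0, 2, size=60)
        fm = bf.FeatureMatrix(X, y)
        assert bf.mrmr_select(fm, 5).indices == bf.mrmr_select(fm, 5).indices


class TestSelectorEstimator:
    def test_transform_keeps_selection_order_and_supports_sklearn_api(self, rng):
        X = rng.normal(size=(60, 12))
        y = rng.integers(0, 2, size=60)
        X[:, 9] += 2 * y
        sel = bf.MrmrSelector(n_features_to_select=4).fit(X, y)
        assert sel.get_support().sum() == 4
        assert sel.selection_.indices[0] == 9
        np.testing.assert_array_equal(
            sel.transform(X)[:, 0], X[:, sel.selection_.indices[0]]
        )
        params = sel.get_params()
        assert params["n_features_to_select"] == 4
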