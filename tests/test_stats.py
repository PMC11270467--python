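"""Statistical toolbox vs independent oracles (enumeration, step-up,
permutation)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from methylzyg import (
    UndefinedTestError,
    ValidationError,
    bh_adjust,
    enrichment_scan,
    fisher_exact,
    kruskal_dunn,
    log2_cpm,
    mann_whitney_u,
    score_by_class,
)


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided p by summing hypergeometric point probabilities (fixed
    margins) no larger than the observed one, with 1e-7 relative slack."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(ks, n, r1, c1)
    observed = sps.hypergeom.pmf(a, n, r1, c1)
    return float(min(np.sum(pmf[pmf <= observed * (1 + 1e-7)]), 1.0))


def bh_stepup_oracle(p):
    """Direct step-up definition: q_(i) = min_{j >= i} m * p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


class TestFisherExact:
    def test_perfect_independence(self):
        odds_ratio, p = fisher_exact([[5, 5], [5, 5]])
        assert odds_ratio == 1.0
        assert p == pytest.approx(1.0)

    def test_small_table_against_enumeration(self):
        _, p = fisher_exact([[3, 1], [1, 3]])
        assert p == pytest.approx(fisher_enumeration_oracle(3, 1, 1, 3), abs=1e-12)

    def test_odds_ratio_conventions(self):
        assert fisher_exact([[3, 0], [0, 3]])[0] == math.inf
        assert fisher_exact([[0, 3], [3, 0]])[0] == 0.0
        assert math.isnan(fisher_exact([[0, 3], [0, 3]])[0])

    def test_all_zero_rejected(self):
        with pytest.raises(UndefinedTestError):
            fisher_exact([[0, 0], [0, 0]])
        with pytest.raises(ValidationError):
            fisher_exact([[1.5, 0], [0, 1]])

    def test_margin_sweep_against_enumeration(self, rng):
        # random sample of tables with margins <= 15 (exhaustive sweep lives
        # in the acceptance suite)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 8, 4))
            if a + b + c + d == 0:
                continue
            _, p = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(
                fisher_enumeration_oracle(a, b, c, d), abs=1e-12
            )


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_evaluated_stepup(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_matches_stepup_oracle_and_monotone(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_stepup_oracle(p), atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_readjustment_never_decreases(self, rng):
        # q'_(i) = min_{j>=i} (m/j) q_(j) >= q_(i) since q is monotone and
        # m/j >= 1; exact idempotence holds for flat adjusted vectors
        q = bh_adjust(np.sort(rng.random(20)))
        assert np.all(bh_adjust(q) >= q - 1e-12)
        flat = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(bh_adjust(flat), flat, atol=1e-12)


def mwu_permutation_oracle(x, y):
    """Exact two-sided p over all C(n1+n2, n1) group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    observed = ranks[:n1].sum() - n1 * (n1 + 1) / 2  # U of x

    def u_values():
        for combo in itertools.combinations(range(len(pooled)), n1):
            yield ranks[list(combo)].sum() - n1 * (n1 + 1) / 2

    n_total = math.comb(len(pooled), n1)
    mean_u = n1 * len(y) / 2
    observed_dev = abs(observed - mean_u)
    extreme = sum(1 for u in u_values() if abs(u - mean_u) >= observed_dev - 1e-9)
    return extreme / n_total


class TestMannWhitney:
    def test_identical_groups(self):
        result = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert result.statistic == pytest.approx(4.5)  # n^2 / 2
        assert result.p_value == pytest.approx(1.0)

    def test_complete_separation_exact(self):
        result = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert result.statistic == 0
        assert result.method == "exact"
        assert result.p_value == pytest.approx(0.1)  # 2 * 1/20

    def test_method_switch_recorded(self, rng):
        big = rng.normal(size=30)
        assert mann_whitney_u(big, rng.normal(size=30)).method == "asymptotic"
        tied = [1.0, 1.0, 2.0]
        assert mann_whitney_u(tied, [3.0, 4.0]).method == "asymptotic"
        assert mann_whitney_u([1.0, 2.0], [3.0, 4.0]).method == "exact"

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    def test_exact_p_matches_permutation_enumeration(self, rng):
        for _ in range(10):
            n1, n2 = rng.integers(2, 8, 2)
            x = rng.permutation(np.arange(1.0, n1 + n2 + 1))[: int(n1)]
            y = np.setdiff1d(np.arange(1.0, n1 + n2 + 1), x)
            result = mann_whitney_u(x, y)
            assert result.method == "exact"
            assert result.p_value == pytest.approx(
                mwu_permutation_oracle(x, y), abs=1e-12
            )


class TestKruskalDunn:
    def test_hand_evaluated_h(self):
        result = kruskal_dunn({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        assert result.statistic == pytest.approx(32 / 7)

    def test_relabelling_invariance(self):
        groups = [[1, 4], [2, 5], [3, 6]]
        h0 = kruskal_dunn(groups).statistic
        h1 = kruskal_dunn(groups[::-1]).statistic
        assert h0 == pytest.approx(h1)

    def test_all_tied_rejected(self):
        with pytest.raises(UndefinedTestError):
            kruskal_dunn({"a": [1, 1], "b": [1, 1], "c": [1, 1]})

    def test_posthoc_gated_on_omnibus(self, rng):
        null_groups = {k: rng.normal(size=10) for k in "abc"}
        shifted = {
            "a": rng.normal(size=20),
            "b": rng.normal(size=20),
            "c": rng.normal(5, 1, size=20),
        }
        # a clearly null layout yields no posthoc; a strong shift does
        weak = kruskal_dunn({"a": [1, 4, 7], "b": [2, 5, 8], "c": [3, 6, 9]})
        assert weak.posthoc is None
        strong = kruskal_dunn(shifted)
        assert strong.p_value < 0.05
        assert strong.posthoc is not None
        assert len(strong.posthoc) == 3
        # the shifted group drives the significant pairs
        sig = strong.posthoc[strong.posthoc["q_value"] < 0.05]
        assert {"c"} <= set(sig["group1"]).union(sig["group2"])

    def test_dunn_z_against_direct_formula(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0], "c": [7.0, 8.0, 9.0]}
        result = kruskal_dunn(groups, posthoc_gate=1.1)
        n = 9
        variance = n * (n + 1) / 12.0  # no ties
        mean_ranks = {"a": 2.0, "b": 5.0, "c": 8.0}
        row = result.posthoc.set_index(["group1", "group2"]).loc[("a", "c")]
        expected_z = (mean_ranks["a"] - mean_ranks["c"]) / math.sqrt(
            variance * (2 / 3)
        )
        assert row["z"] == pytest.approx(expected_z, abs=1e-12)


class TestEnrichmentScan:
    def _data(self, rng, n=20, m=5):
        status = pd.Series(
            np.arange(n) < n // 2, index=[f"S{i}" for i in range(n)]
        )
        features = pd.DataFrame(
            rng.integers(0, 2, (n, m)),
            index=status.index,
            columns=[f"f{j}" for j in range(m)],
        )
        return status, features

    def test_perfect_association_is_extreme(self, rng):
        status, features = self._data(rng)
        features["mirror"] = status.astype(int)
        scan = enrichment_scan(status, features)
        best = scan.loc[scan["feature"] == "mirror"].iloc[0]
        assert best["p_value"] == scan["p_value"].min()
        assert best["q_value"] <= scan["q_value"].max()
        assert best["odds_ratio"] == math.inf

    def test_zero_variance_feature_skipped(self, rng):
        status, features = self._data(rng)
        features["constant"] = 1
        scan = enrichment_scan(status, features)
        assert "constant" not in set(scan["feature"])
        assert len(scan) == len(features.columns) - 1

    def test_misaligned_samples_rejected(self, rng):
        status, features = self._data(rng)
        with pytest.raises(ValidationError):
            enrichment_scan(status, features.iloc[:-1])


class TestScoreByClass:
    def test_no_signal_flat_scores(self):
        classes = pd.Series(
            ["a"] * 10 + ["b"] * 10, index=[f"S{i}" for i in range(20)]
        )
        scores = pd.Series(5.0, index=classes.index)
        comparison, _ = score_by_class(classes, scores)
        assert comparison.p_value > 0.99

    def test_threshold_inclusive_at_42(self):
        classes = pd.Series(["a", "a", "b", "b"], index=list("wxyz"))
        scores = pd.Series([41.9, 42.0, 42.0, 10.0], index=list("wxyz"))
        _, table = score_by_class(classes, scores, hrd_threshold=42)
        counts = table.set_index("class")["n_ge_threshold"]
        assert counts["a"] == 1 and counts["b"] == 1

    def test_three_classes_use_kruskal(self, rng):
        classes = pd.Series(
            ["a"] * 15 + ["b"] * 15 + ["c"] * 15,
            index=[f"S{i}" for i in range(45)],
        )
        scores = pd.Series(rng.normal(size=45), index=classes.index)
        comparison, _ = score_by_class(classes, scores)
        assert comparison.statistic_name == "KruskalWallisH"

    def test_shifted_class_detected(self, rng):
        """A +30 HRD-score shift in one zygosity class is found by the
        omnibus test in the vast majority of replicates."""
        hits = 0
        reps = 50
        for _ in range(reps):
            classes = pd.Series(
                ["high+LOH"] * 40 + ["low-LOH"] * 40 + ["low+LOH"] * 40,
                index=[f"S{i}" for i in range(120)],
            )
            scores = pd.Series(
                np.concatenate(
                    [
                        rng.normal(50, 15, 40),  # +30 shift
                        rng.normal(20, 15, 40),
                        rng.normal(20, 15, 40),
                    ]
                ),
                index=classes.index,
            )
            comparison, _ = score_by_class(classes, scores)
            if comparison.p_value < 0.01:
                hits += 1
        assert hits / reps >= 0.95


class TestLog2Cpm:
    def test_direct_formula(self):
        counts = pd.DataFrame(
            {"S1": [0, 1_000_000], "S2": [10, 90]}, index=["g1", "g2"]
        )
        out = log2_cpm(counts)
        expected = math.log2(0.5 / 1_000_001 * 1e6)
        assert out.loc["g1", "S1"] == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance_limit(self):
        small = pd.DataFrame({"S1": [100, 900]}, index=["g1", "g2"])
        big = small * 1000
        diff = (log2_cpm(big) - log2_cpm(small)).abs().to_numpy().max()
        assert diff < 0.01

    def test_monotone_in_count(self):
        counts = pd.DataFrame({"S1": [1, 2, 500]}, index=["g1", "g2", "g3"])
        out = log2_cpm(counts)["S1"]
        assert out["g1"] < out["g2"] < out["g3"]

    def test_zero_library_rejected(self):
        with pytest.raises(ValidationError, match="library"):
            log2_cpm(pd.DataFrame({"S1": [0, 0]}, index=["g1", "g2"]))
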