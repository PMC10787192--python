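import itertools

import numpy as np
import pytest

from drtransfer.evaluation import (auroc, domain_distance,
                                   domain_distance_per_member,
                                   evaluate_predictions, fisher_combined,
                                   mann_whitney_one_sided,
                                   precision_at_percentile)
from drtransfer.predictor import LatentEmbedding


def _u_stat(r, s):
    return sum((ri > si) + 0.5 * (ri == si) for ri in r for si in s)


def enumeration_pvalue(r, s):
    """Oracle: exact one-sided P by enumerating every assignment of the
    pooled observations to the two groups."""
    pooled = list(r) + list(s)
    u_obs = _u_stat(r, s)
    n_r = len(r)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_r):
        rr = [pooled[i] for i in idx]
        ss = [pooled[i] for i in range(len(pooled)) if i not in idx]
        count += _u_stat(rr, ss) >= u_obs
        total += 1
    return count / total


class TestMannWhitney:
    def test_separated_groups(self):
        u, p = mann_whitney_one_sided([3, 4], [1, 2])
        assert u == 4
        assert p == pytest.approx(1 / 6)

    def test_singletons(self):
        _, p = mann_whitney_one_sided([2], [1])
        assert p == pytest.approx(0.5)

    def test_reversed_groups(self):
        u, p = mann_whitney_one_sided([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1.0)

    def test_exact_path_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_r, n_s = rng.integers(2, 5, size=2)
            pooled = rng.permutation(np.arange(1.0, n_r + n_s + 1))
            r, s = pooled[:n_r], pooled[n_r:]
            _, p = mann_whitney_one_sided(r, s)
            assert p == pytest.approx(enumeration_pvalue(r, s), abs=1e-12)

    def test_exact_and_normal_paths_agree(self):
        rng = np.random.default_rng(1)
        gaps = []
        for _ in range(100):
            pooled = rng.permutation(np.arange(1.0, 13.0))
            r, s = pooled[:6], pooled[6:]
            _, p_exact = mann_whitney_one_sided(r, s)
            from scipy.stats import mannwhitneyu
            p_norm = mannwhitneyu(r, s, alternative="greater",
                                  method="asymptotic").pvalue
            gaps.append(abs(p_exact - p_norm))
        assert max(gaps) < 0.02

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            mann_whitney_one_sided([], [1.0])


class TestFisher:
    def test_boundary_all_ones(self):
        x, p = fisher_combined([1.0, 1.0])
        assert x == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_single_p_identity(self):
        _, p = fisher_combined([0.05])
        assert p == pytest.approx(0.05)

    def test_closed_form_chi4(self):
        x, p = fisher_combined([0.1, 0.1])
        assert x == pytest.approx(-4 * np.log(0.1))
        assert p == pytest.approx((1 + x / 2) * np.exp(-x / 2), rel=1e-6)
        assert p == pytest.approx(0.05605, abs=5e-5)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_combined([0.0, 0.5])


class TestPrecisionAtPercentile:
    def test_bottom_half_all_sensitive(self):
        out = precision_at_percentile([1, 2, 3, 4], ["sensitive", "sensitive",
                                                     "resistant", "resistant"], 50)
        assert (out["TP"], out["FP"]) == (2, 0)
        assert out["precision"] == 1.0

    def test_all_resistant_zero_precision(self):
        out = precision_at_percentile([1, 2, 3, 4], ["resistant"] * 4, 50)
        assert out["precision"] == 0.0

    def test_all_sensitive_full_precision(self):
        out = precision_at_percentile([1, 2, 3, 4], ["sensitive"] * 4, 50)
        assert out["precision"] == 1.0

    def test_empty_bottom_set_flagged(self):
        out = precision_at_percentile([2.0, 2.0, 2.0, 2.0],
                                      ["sensitive"] * 4, 25)
        assert out["empty"] and np.isnan(out["precision"])

    @pytest.mark.parametrize("k", [0.0, 60.0, -5.0])
    def test_k_range_enforced(self, k):
        with pytest.raises(ValueError):
            precision_at_percentile([1, 2], ["sensitive", "resistant"], k)


class TestAuroc:
    def test_perfect_ordering(self):
        assert auroc([1, 2, 9, 10], ["sensitive", "sensitive",
                                     "resistant", "resistant"]) == 1.0

    def test_reversed_ordering(self):
        assert auroc([9, 10, 1, 2], ["sensitive", "sensitive",
                                     "resistant", "resistant"]) == 0.0

    def test_pairwise_counting_example(self):
        # (pos, neg) pairs: (1,2)+, (1,4)+, (3,2)-, (3,4)+ -> 3/4
        a = auroc([1, 2, 3, 4], ["sensitive", "resistant",
                                 "sensitive", "resistant"])
        assert a == pytest.approx(0.75)

    def test_equals_scaled_u_statistic(self):
        rng = np.random.default_rng(2)
        preds = rng.normal(size=30)
        labels = ["sensitive" if x else "resistant"
                  for x in rng.random(30) < 0.4]
        r = preds[np.array(labels) == "resistant"]
        s = preds[np.array(labels) == "sensitive"]
        u, _ = mann_whitney_one_sided(r, s)
        assert auroc(preds, labels) == pytest.approx(u / (len(r) * len(s)),
                                                     abs=1e-10)

    def test_one_class_error(self):
        with pytest.raises(ValueError):
            auroc([1, 2], ["sensitive", "sensitive"])

    def test_matches_sklearn_reference(self):
        """Independent cross-check against scikit-learn's ROC AUC."""
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(7)
        preds = np.round(rng.normal(size=50), 1)   # force some ties
        labels = ["sensitive" if x else "resistant"
                  for x in rng.random(50) < 0.5]
        ref = roc_auc_score([l == "sensitive" for l in labels], -preds)
        assert auroc(preds, labels) == pytest.approx(ref, abs=1e-12)


class TestDomainDistance:
    def test_identical_centroids_zero(self):
        a = LatentEmbedding(["a", "b"], np.array([[0.0, 1.0], [2.0, -1.0]]))
        b = LatentEmbedding(["c", "d"], np.array([[2.0, -1.0], [0.0, 1.0]]))
        assert domain_distance(a, b) == pytest.approx(0.0)

    def test_two_singletons(self):
        a = LatentEmbedding(["a"], np.array([[0.0, 0.0]]))
        b = LatentEmbedding(["b"], np.array([[0.0, 2.0]]))
        assert domain_distance(a, b) == pytest.approx(2.0)  # (1/2) * 4

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        va, vb = rng.normal(size=(4, 3)), rng.normal(size=(6, 3))
        base = domain_distance(LatentEmbedding(list("abcd"), va),
                               LatentEmbedding(list("efghij"), vb))
        shift = np.array([5.0, -2.0, 100.0])
        moved = domain_distance(LatentEmbedding(list("abcd"), va + shift),
                                LatentEmbedding(list("efghij"), vb + shift))
        assert moved == pytest.approx(base, rel=1e-9)

    def test_matches_scipy_ward_merge_cost(self):
        """Cross-check against scipy's Ward linkage on two singleton groups
        merged last: the final linkage height is sqrt(2 * merge cost)."""
        from scipy.cluster.hierarchy import linkage
        rng = np.random.default_rng(4)
        va, vb = rng.normal(size=(3, 2)), rng.normal(size=(3, 2)) + 8.0
        ours = domain_distance(LatentEmbedding(list("abc"), va),
                               LatentEmbedding(list("def"), vb))
        heights = linkage(np.vstack([va, vb]), method="ward")[:, 2]
        # the last merge joins the two well-separated groups
        approx = heights[-1] ** 2 / 2.0
        # scipy's height reflects the actual sub-cluster structure; with
        # tight, well-separated groups the centroid formula dominates
        assert ours == pytest.approx(approx, rel=0.05)

    def test_per_member_report(self, fixture_run):
        out = domain_distance_per_member(fixture_run["model"],
                                         fixture_run["src_norm"],
                                         fixture_run["tgt_norm"])
        assert len(out["per_member"]) == fixture_run["model"].n_members
        assert out["ci"][0] <= out["mean"] <= out["ci"][1]


class TestEvalReport:
    def test_assembled_report(self, tmp_path):
        rng = np.random.default_rng(5)
        preds = rng.normal(size=40)
        labels = ["sensitive" if p < 0 else "resistant" for p in preds]
        rep = evaluate_predictions(preds, labels, drug="x",
                                   percentiles=(25, 50))
        assert 0 < rep.p_value <= 1
        assert rep.auroc == 1.0          # labels derived from the preds
        assert len(rep.precision_table) == 2
        rep.to_json(tmp_path / "rep.json")
        assert (tmp_path / "rep.json").exists()
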