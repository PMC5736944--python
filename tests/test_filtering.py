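import numpy as np
import pytest
from scipy import stats

from mph import (
    ExpressionMatrix,
    Profiles,
    SyntheticSpec,
    fold_change_rank,
    simulate,
    simulate_null,
    ttest_filter,
)


def _two_group_matrix(rows, n_a=3, n_b=3):
    """rows: list of (gene_id, values_a, values_b)."""
    gene_ids = [r[0] for r in rows]
    values = np.array([list(r[1]) + list(r[2]) for r in rows], dtype=float)
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    cond = {s: ("A" if s.startswith("a") else "B") for s in samples}
    return ExpressionMatrix(gene_ids, samples, values, cond)


class TestTtestFilter:
    def test_identical_groups_get_p_one(self):
        x = _two_group_matrix([("g1", (1, 2, 3), (1, 2, 3))])
        res = ttest_filter(x, "A", "B", alpha=0.05)
        assert res.pvalue_of["g1"] == 1.0
        assert res.selected_gene_ids == []

    def test_constant_equal_groups_get_p_one_not_nan(self):
        x = _two_group_matrix([("g1", (5, 5, 5), (5, 5, 5))])
        res = ttest_filter(x, "A", "B", alpha=0.05)
        assert res.pvalue_of["g1"] == 1.0

    def test_matches_pooled_variance_closed_form(self):
        a, b = (10.0, 11.0, 9.0), (1.0, 2.0, 0.0)
        x = _two_group_matrix([("g1", a, b)])
        res = ttest_filter(x, "A", "B", alpha=0.05, equal_var=True)
        # independent closed-form oracle: pooled two-sample t
        na, nb = 3, 3
        sp2 = (np.var(a, ddof=1) * (na - 1) + np.var(b, ddof=1) * (nb - 1)) / (na + nb - 2)
        t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p = 2 * stats.t.sf(abs(t), na + nb - 2)
        assert res.statistic_of["g1"] == pytest.approx(t, rel=1e-12)
        assert res.pvalue_of["g1"] == pytest.approx(p, rel=1e-12)
        assert "g1" in res.selected_gene_ids

    def test_recovers_planted_differential_genes(self, rng):
        I, n_diff = 500, 50
        base = rng.uniform(2, 8, size=I)
        a = base[:, None] + rng.normal(0, 0.5, size=(I, 3))
        b = base[:, None] + rng.normal(0, 0.5, size=(I, 3))
        b[:n_diff] += 5.0  # strong planted effect
        values = np.clip(np.hstack([a, b]), 0, None)
        x = ExpressionMatrix(
            [f"g{i}" for i in range(I)],
            [f"s{j}" for j in range(6)],
            values,
            {f"s{j}": ("A" if j < 3 else "B") for j in range(6)},
        )
        res = ttest_filter(x, "A", "B", alpha=0.05)
        hits = sum(1 for i in range(n_diff) if f"g{i}" in set(res.selected_gene_ids))
        assert hits >= 45

    def test_condition_with_single_sample_rejected(self):
        x = _two_group_matrix([("g1", (1, 2, 3), (4, 5, 6))])
        x.condition_of["b1"] = "C"
        x.condition_of["b2"] = "C"
        with pytest.raises(ValueError, match="2 samples"):
            ttest_filter(x, "A", "B")

    def test_alpha_one_selects_only_p_below_one(self):
        x = _two_group_matrix([("g1", (1, 2, 3), (1, 2, 3)),
                               ("g2", (1, 2, 3), (1.5, 2.5, 3.5))])
        res = ttest_filter(x, "A", "B", alpha=1.0)
        assert res.selected_gene_ids == ["g2"]

    def test_type_one_error_calibrated_on_null_data(self):
        """Under homogeneous data with arbitrary labels the selection
        fraction approximates alpha."""
        ds = simulate_null(SyntheticSpec(
            I=2000, J=8, seed=13,
            conditions={f"s{j}": "one" for j in range(8)},
        ))
        x = ds.expression
        for j, s in enumerate(x.sample_ids):
            x.condition_of[s] = "A" if j < 4 else "B"
        res = ttest_filter(x, "A", "B", alpha=0.05)
        frac = len(res.selected_gene_ids) / x.n_genes
        assert 0.03 <= frac <= 0.07  # 0.05 +- ~4 binomial sd


class TestFoldChangeRank:
    def test_direct_ratio_and_direction(self):
        w = Profiles(["g1", "g2"], ["a", "b"], [[8.0, 2.0], [5.0, 5.0]])
        r = fold_change_rank(w, "a", "b", top_n=2)
        assert r.fc_of["g1"] == pytest.approx(4.0, rel=1e-6)
        assert r.direction_of["g1"] == "a"
        assert r.fc_of["g2"] == pytest.approx(1.0, rel=1e-6)
        assert r.ranked_gene_ids == ["g1", "g2"]  # no-change gene ranks last

    def test_ties_break_lexicographically(self):
        w = Profiles(["gb", "ga"], ["a", "b"], [[4.0, 2.0], [4.0, 2.0]])
        r = fold_change_rank(w, "a", "b", top_n=2)
        assert r.ranked_gene_ids == ["ga", "gb"]

    def test_top_n_exceeding_gene_count_warns(self):
        w = Profiles(["g1"], ["a", "b"], [[2.0, 1.0]])
        with pytest.warns(UserWarning, match="returning all"):
            r = fold_change_rank(w, "a", "b", top_n=10)
        assert r.ranked_gene_ids == ["g1"]

    def test_planted_markers_rank_on_top(self, default_dataset):
        ds = default_dataset
        w = ds.truth_profiles["cond1"]
        r = fold_change_rank(w, "comp1", "comp2", top_n=ds.expression.n_genes)
        n_markers = len(ds.truth_markers.all_genes())
        top = set(r.ranked_gene_ids[:n_markers])
        assert set(ds.truth_markers.all_genes()) <= top

    def test_invariant_to_global_rescaling(self, rng):
        vals = rng.uniform(1, 10, size=(20, 2))
        w1 = Profiles([f"g{i}" for i in range(20)], ["a", "b"], vals)
        w2 = Profiles([f"g{i}" for i in range(20)], ["a", "b"], vals * 7.3)
        r1 = fold_change_rank(w1, "a", "b", top_n=20)
        r2 = fold_change_rank(w2, "a", "b", top_n=20)
        assert r1.ranked_gene_ids == r2.ranked_gene_ids
        for g in r1.fc_of:
            assert r1.fc_of[g] == pytest.approx(r2.fc_of[g], rel=1e-4)
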