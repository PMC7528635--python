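import numpy as np
import pandas as pd
import pytest

from cptdetect.audit import (
    assign_groups,
    audit_cohort,
    audit_report,
    chi_square_imbalance,
    estimate_group_effect,
    filter_degenerate,
    merge_equal_groups,
)
from tests.conftest import make_records


def direct_chi_square(table: np.ndarray) -> tuple[float, int]:
    """Textbook sum((O-E)^2/E) without continuity correction."""
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = rowsum * colsum / table.sum()
    stat = ((table - expected) ** 2 / expected).sum()
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return float(stat), dof


def records_from_contingency(table: np.ndarray, factor: str = "dow") -> pd.DataFrame:
    rows = []
    for i, diag in enumerate(["ADHD", "control"][: table.shape[0]]):
        for j in range(table.shape[1]):
            for _ in range(int(table[i, j])):
                rows.append({"diagnosis": diag, factor: j + 1})
    return pd.DataFrame(rows)


class TestAssignGroups:
    def test_two_ages_two_groups(self):
        df = make_records({(6, 0, 1, 1): (1, 1), (7, 0, 1, 1): (1, 1)})
        groups = assign_groups(df)
        assert len(groups) == 2
        assert all(g.n_i == 2 for g in groups)

    def test_empty_table_empty_list(self):
        df = make_records({})
        assert assign_groups(df) == []

    def test_partition_property_on_cohort(self, default_cohort):
        groups = assign_groups(default_cohort)
        assert len(groups) <= 7 * 2 * 7 * 3  # 294 possible cells
        all_ids = sorted(i for g in groups for i in g.member_ids)
        assert all_ids == sorted(default_cohort["child_id"])

    def test_missing_factor_lists_ids(self, default_cohort):
        df = default_cohort.copy()
        df.loc[df.index[:2], "dow"] = np.nan
        with pytest.raises(ValueError, match="missing factor"):
            assign_groups(df)


class TestChiSquare:
    def test_reconstructed_gender_table_statistic(self):
        # diagnosis x gender counts recovered from the printed marginals
        # (213/245 per class, 267 boys overall, 67% vs 51% boys per class)
        df = records_from_contingency(np.array([[142, 71], [125, 120]]), factor="gender")
        stat, dof, p = chi_square_imbalance(df, "gender")
        assert round(stat, 2) == 10.84
        assert dof == 1
        assert p < 0.001

    def test_perfectly_balanced_table_is_zero(self):
        df = records_from_contingency(np.array([[50, 50], [50, 50]]), factor="gender")
        stat, _, p = chi_square_imbalance(df, "gender")
        assert stat == 0.0
        assert p == 1.0

    def test_matches_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            table = rng.integers(5, 80, size=(2, 3))
            df = records_from_contingency(table)
            stat, dof, _ = chi_square_imbalance(df, "dow")
            expect, edof = direct_chi_square(table.astype(float))
            assert dof == edof == 2
            assert np.isclose(stat, expect)

    def test_single_class_rejected(self):
        df = records_from_contingency(np.array([[10, 10]]), factor="gender")
        with pytest.raises(ValueError, match="diagnosis"):
            chi_square_imbalance(df, "gender")


class TestGroupEffect:
    def test_identical_values_give_zero_effect(self):
        df = make_records({(8, 0, 1, 1): (5, 5)})
        for c in ("z_attention", "z_timeliness", "z_hyperactivity", "z_impulsiveness"):
            df[c] = 1.0
        [g] = assign_groups(df)
        g = estimate_group_effect(g, df.set_index("child_id"))
        assert g.effect == 0.0

    def test_uniform_unit_shift_gives_unit_composite_effect(self):
        df = make_records({(8, 0, 1, 1): (5, 5)})
        for c in ("z_attention", "z_timeliness", "z_hyperactivity", "z_impulsiveness"):
            df[c] = np.where(df["diagnosis"] == "ADHD", 1.0, 0.0)
        [g] = assign_groups(df)
        g = estimate_group_effect(g, df.set_index("child_id"))
        assert np.isclose(g.effect, 1.0)

    def test_monte_carlo_recovery_of_configured_shift(self):
        df = make_records({(8, 0, 1, 1): (200, 200)}, z_shift_adhd=0.8, seed=5)
        [g] = assign_groups(df)
        g = estimate_group_effect(g, df.set_index("child_id"))
        assert abs(g.effect - 0.8) < 3 * g.effect_se

    def test_singleton_class_flagged_inestimable(self):
        df = make_records({(8, 0, 1, 1): (1, 5)})
        [g] = assign_groups(df)
        g = estimate_group_effect(g, df.set_index("child_id"))
        assert not g.estimable


class TestMerging:
    def test_single_group_unchanged(self):
        df = make_records({(8, 0, 1, 1): (10, 10)})
        groups = assign_groups(df)
        out = merge_equal_groups(groups, df.set_index("child_id"))
        assert len(out.groups) == 1

    def test_equal_effect_groups_merge_at_rate_one_minus_alpha(self):
        alpha, trials, merged = 0.05, 200, 0
        for t in range(trials):
            df = make_records({(6, 0, 1, 1): (300, 300), (7, 0, 1, 1): (300, 300)},
                              z_shift_adhd=0.5, seed=1000 + t)
            groups = assign_groups(df)
            out = merge_equal_groups(groups, df.set_index("child_id"), alpha=alpha)
            merged += len(out.groups) == 1
        rate = merged / trials
        se = np.sqrt(alpha * (1 - alpha) / trials)
        assert abs(rate - (1 - alpha)) < max(3 * se, 0.05)

    def test_opposite_effects_never_merge(self):
        for t in range(50):
            df = make_records({(6, 0, 1, 1): (300, 300)}, z_shift_adhd=1.0, seed=t)
            df2 = make_records({(7, 0, 1, 1): (300, 300)}, z_shift_adhd=-1.0, seed=500 + t)
            df2["child_id"] += len(df)
            both = pd.concat([df, df2], ignore_index=True)
            groups = assign_groups(both)
            out = merge_equal_groups(groups, both.set_index("child_id"))
            assert len(out.groups) == 2

    def test_order_stable_under_input_shuffle(self, default_cohort):
        idx = default_cohort.set_index("child_id")
        groups = assign_groups(default_cohort)
        for g in groups:
            estimate_group_effect(g, idx)
        a = merge_equal_groups(list(groups), idx)
        b = merge_equal_groups(list(reversed(groups)), idx)
        assert [g.key for g in a.groups] == [g.key for g in b.groups]

    def test_bad_alpha_rejected(self):
        df = make_records({(8, 0, 1, 1): (5, 5)})
        with pytest.raises(ValueError, match="alpha"):
            merge_equal_groups(assign_groups(df), df.set_index("child_id"), alpha=1.5)


class TestDegenerateFilter:
    def test_pure_groups_removed_mixed_retained(self):
        df = make_records({(6, 0, 1, 1): (0, 10), (7, 0, 1, 1): (10, 0),
                           (8, 0, 1, 1): (3, 7)})
        res = filter_degenerate(assign_groups(df))
        assert len(res.groups) == 1
        assert len(res.removed_groups) == 2
        assert all(g.p_i in (0.0, 1.0) for g in res.removed_groups)
        assert all(0.0 < g.p_i < 1.0 for g in res.groups)

    def test_retained_fraction_arithmetic(self):
        df = make_records({(6, 0, 6, 1): (0, 13), (8, 0, 1, 1): (215, 230)})
        res = filter_degenerate(assign_groups(df))
        assert res.n_retained == 445
        assert np.isclose(res.retained_fraction, 445 / 458)

    def test_partition_conserved_through_filter(self, default_cohort):
        res = audit_cohort(default_cohort, merge=False, absorb=False)
        total = res.n_retained + sum(g.n_i for g in res.removed_groups)
        assert total == len(default_cohort)
        assert min(min(g.p_i, 1 - g.p_i) for g in res.groups) > 0


class TestFullAudit:
    def test_absorption_retains_sparse_cells(self, confounded_cohort):
        res = audit_cohort(confounded_cohort)
        assert res.retained_fraction > 0.9
        assert all(0.0 < g.p_i < 1.0 for g in res.groups)

    def test_report_is_json_serializable(self, confounded_cohort):
        import json

        res = audit_cohort(confounded_cohort)
        payload = audit_report(res, confounded_cohort)
        text = json.dumps(payload)
        assert "chi_square" in payload and "gender" in payload["chi_square"]
        assert json.loads(text)["n_records"] == len(confounded_cohort)
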