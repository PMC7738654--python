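"""Unpaired t-tests, signed fold changes, and DEG classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rccpipe.diffexpr import (
    DEResult,
    call_degs,
    differential_expression,
    fold_change,
    signed_fc_from_delta,
    t_test_gene,
)


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t, coded independently."""
    a, b = list(map(float, a)), list(map(float, b))
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    s1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    s2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


class TestTTest:
    def test_identical_groups_are_null(self):
        assert t_test_gene([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_matches_pooled_variance_oracle(self):
        a, b = [3.1, 3.4, 2.9, 3.6], [2.1, 2.0, 2.4]
        t, p = t_test_gene(a, b, variant="student")
        t0, p0 = pooled_t_oracle(a, b)
        assert t == pytest.approx(t0, abs=1e-9)
        assert p == pytest.approx(p0, abs=1e-9)

    def test_welch_differs_under_unequal_variance(self):
        a = [10.0, 10.1, 9.9, 10.0, 10.2]
        b = [5.0, 9.0, 13.0, 2.0]
        t_s, p_s = t_test_gene(a, b, variant="student")
        t_w, p_w = t_test_gene(a, b, variant="welch")
        assert t_s != pytest.approx(t_w)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t_w == pytest.approx(float(ref.statistic))

    def test_constant_groups(self):
        assert t_test_gene([2, 2, 2], [2, 2]) == (0.0, 1.0)
        with pytest.warns(UserWarning, match="zero variance"):
            t, p = t_test_gene([3, 3, 3], [2, 2])
        assert p == 0.0 and t == math.inf

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            t_test_gene([1.0], [1.0, 2.0])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    def test_p_invariant_under_common_affine_transform(self, shift, scale):
        a = np.array([3.1, 3.4, 2.9, 3.6])
        b = np.array([2.1, 2.0, 2.4])
        _, p0 = t_test_gene(a, b)
        _, p1 = t_test_gene(a * scale + shift, b * scale + shift)
        assert p1 == pytest.approx(p0, rel=1e-9)


class TestFoldChange:
    @pytest.mark.parametrize(
        "delta, expected",
        [(0.0, 1.0), (1.0, 2.0), (-1.0, -2.0), (math.log2(1.5), 1.5)],
    )
    def test_signed_convention(self, delta, expected):
        assert signed_fc_from_delta(delta) == pytest.approx(expected)

    def test_fold_change_from_group_means(self):
        delta, sfc = fold_change([3.0, 5.0], [2.0, 2.0])
        assert delta == pytest.approx(2.0)
        assert sfc == pytest.approx(4.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fold_change([], [1.0])


def toy_log2(groups_sizes=(3, 3), seed=0, n_genes=6, effect=0.0):
    rng = np.random.default_rng(seed)
    n1, n2 = groups_sizes
    cols = [f"C{i}" for i in range(n1)] + [f"K{i}" for i in range(n2)]
    groups = {c: ("case" if c.startswith("C") else "control") for c in cols}
    values = rng.normal(8.0, 0.5, size=(n_genes, n1 + n2))
    values[: n_genes // 2, :n1] += effect
    df = pd.DataFrame(values, index=[f"G{i}" for i in range(n_genes)], columns=cols)
    return df, groups


class TestCalls:
    def make_de(self, rows):
        table = pd.DataFrame(rows).set_index("gene")
        table["call"] = "ns"
        return DEResult(table=table, variant="student", fc_mode="log2")

    def test_boundary_semantics(self):
        de = self.make_de(
            [
                {"gene": "A", "signed_fc": 1.5, "delta": math.log2(1.5), "p": 0.049, "t": 2.0,
                 "mean_log2_case": 1, "mean_log2_control": 0},
                {"gene": "B", "signed_fc": 1.5, "delta": math.log2(1.5), "p": 0.05, "t": 2.0,
                 "mean_log2_case": 1, "mean_log2_control": 0},
                {"gene": "C", "signed_fc": 4.0, "delta": 2.0, "p": 0.2, "t": 1.0,
                 "mean_log2_case": 2, "mean_log2_control": 0},
                {"gene": "D", "signed_fc": -1.5, "delta": -math.log2(1.5), "p": 0.01, "t": -2.0,
                 "mean_log2_case": 0, "mean_log2_control": 1},
            ]
        )
        called = call_degs(de)
        assert called.table["call"].tolist() == ["up", "ns", "ns", "down"]
        assert called.summary == {"n_detected": 4, "n_up": 1, "n_down": 1}

    def test_bh_appends_without_changing_calls(self):
        de = self.make_de(
            [
                {"gene": g, "signed_fc": 2.0, "delta": 1.0, "p": p, "t": 2.0,
                 "mean_log2_case": 1, "mean_log2_control": 0}
                for g, p in zip("ABCD", [0.01, 0.02, 0.4, 0.8])
            ]
        )
        plain = call_degs(de)
        bh = call_degs(de, correction="bh")
        assert bh.table["call"].equals(plain.table["call"])
        assert (bh.table["p_adj"] >= bh.table["p"] - 1e-12).all()

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            call_degs(self.make_de([{"gene": "A", "signed_fc": 1.0, "delta": 0.0, "p": 0.5,
                                     "t": 0.0, "mean_log2_case": 0, "mean_log2_control": 0}]),
                      alpha=1.5)


class TestTableLevel:
    def test_antisymmetry_under_group_swap(self):
        df, groups = toy_log2(effect=1.0, seed=4)
        de = call_degs(differential_expression(df, groups))
        swapped = {s: ("control" if g == "case" else "case") for s, g in groups.items()}
        de_sw = call_degs(differential_expression(df, swapped))
        np.testing.assert_allclose(de_sw.table["delta"], -de.table["delta"], atol=1e-12)
        np.testing.assert_allclose(de_sw.table["p"], de.table["p"], atol=1e-12)
        flipped = de.table["call"].map({"up": "down", "down": "up", "ns": "ns"})
        assert de_sw.table["call"].equals(flipped)

    def test_null_data_calls_match_direct_enumeration(self):
        """On 500 null genes the classifier agrees with re-deriving every call."""
        df, groups = toy_log2(groups_sizes=(11, 4), n_genes=500, seed=7)
        de = call_degs(differential_expression(df, groups))
        for gene, row in de.table.iterrows():
            expected = "ns"
            if row["p"] < 0.05 and row["signed_fc"] >= 1.5:
                expected = "up"
            elif row["p"] < 0.05 and row["signed_fc"] <= -1.5:
                expected = "down"
            assert row["call"] == expected
        # and the DEG rate stays near what alpha + the FC filter allow
        rate = (de.table["call"] != "ns").mean()
        assert rate < 0.05 + 3 * math.sqrt(0.05 * 0.95 / 500)

    def test_missing_group_labels_rejected(self):
        df, groups = toy_log2()
        groups.pop(df.columns[0])
        with pytest.raises(ValueError, match="missing group"):
            differential_expression(df, groups)

    def test_linear_fc_mode_agrees_in_sign(self):
        df, groups = toy_log2(effect=1.5, seed=9)
        log_mode = differential_expression(df, groups, fc_mode="log2")
        lin_mode = differential_expression(df, groups, fc_mode="linear")
        assert (np.sign(log_mode.table["delta"]) == np.sign(lin_mode.table["delta"])).all()
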