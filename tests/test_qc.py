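"""Background thresholds, housekeeping screening, geNorm stability, panel pick."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from rccpipe import qc
from rccpipe.qc import (
    estimate_background,
    genorm_ranking,
    genorm_stability,
    screen_housekeeping,
    select_hk_panel,
)

from conftest import make_matrix


def neg_matrix(*neg_rows):
    """Each argument is one sample's list of negative-probe counts."""
    n_probes = len(neg_rows[0])
    counts = {
        f"NEG_{p+1:02d}": [neg_rows[s][p] for s in range(len(neg_rows))]
        for p in range(n_probes)
    }
    classes = {name: "Negative" for name in counts}
    return make_matrix(counts, classes)


class TestBackground:
    def test_zero_variance_gives_mean(self):
        matrix = neg_matrix([5] * 8)
        profile = estimate_background(matrix)
        assert profile.theta.iloc[0] == 5.0

    def test_hand_computed_threshold(self):
        matrix = neg_matrix([1, 2, 3, 4, 5, 6, 7, 8])
        theta = estimate_background(matrix).theta.iloc[0]
        assert theta == pytest.approx(4.5 + 2 * math.sqrt(6), abs=1e-12)

    def test_single_negative_probe_rejected(self):
        matrix = neg_matrix([7])
        with pytest.raises(ValueError, match="negative-control"):
            estimate_background(matrix)

    def test_all_zero_negatives_warn_with_zero_theta(self):
        matrix = neg_matrix([0, 0, 0])
        with pytest.warns(UserWarning, match="zero"):
            profile = estimate_background(matrix)
        assert profile.theta.iloc[0] == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=10),
        scale=st.integers(min_value=1, max_value=20),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_permutation_invariant_and_scale_equivariant(self, counts, scale, seed):
        assume(any(counts))  # the all-zero case is covered by its own test
        rng = np.random.default_rng(seed)
        theta = estimate_background(neg_matrix(counts)).theta.iloc[0]
        shuffled = list(rng.permutation(counts))
        assert estimate_background(neg_matrix(shuffled)).theta.iloc[0] == pytest.approx(theta)
        scaled = [c * scale for c in counts]
        assert estimate_background(neg_matrix(scaled)).theta.iloc[0] == pytest.approx(
            theta * scale
        )


def hk_neg_matrix(hk_counts: dict, neg=((4, 6, 5, 7), (6, 4, 7, 5))):
    counts = dict(hk_counts)
    classes = {k: "Housekeeping" for k in hk_counts}
    for i, row in enumerate(neg):
        counts[f"NEG_{i+1:02d}"] = list(row)
        classes[f"NEG_{i+1:02d}"] = "Negative"
    return make_matrix(counts, classes)


class TestScreening:
    def test_high_signal_passes_and_near_background_fails(self):
        matrix = hk_neg_matrix(
            {
                "HK01": [500, 500, 500, 500],
                "HK02": [400, 600, 400, 600],
                "HK03": [20, 22, 19, 21],  # near background: fails k*theta in some sample
            }
        )
        background = estimate_background(matrix)
        assessment = screen_housekeeping(matrix, background)
        assert assessment.passes_background["HK01"]
        assert assessment.passes_background["HK02"]
        assert not assessment.passes_background["HK03"]

    def test_boundary_is_strict(self):
        """A count exactly at k*theta in one sample fails (strict >)."""
        flat = ((5, 5, 5, 5), (5, 5, 5, 5))  # theta = 5 in every sample
        at_boundary = hk_neg_matrix({"HK01": [15, 500, 500, 500]}, neg=flat)
        assessment = screen_housekeeping(at_boundary, estimate_background(at_boundary))
        assert not assessment.passes_background["HK01"]

    def test_no_hk_probes_rejected(self):
        matrix = neg_matrix([5, 5, 5])
        with pytest.raises(ValueError, match="Housekeeping"):
            screen_housekeeping(matrix, estimate_background(matrix))


def brute_force_m(log2: pd.DataFrame) -> pd.Series:
    """Independent geNorm M: all pairwise log-ratio SDs, averaged per gene."""
    genes = list(log2.index)
    out = {}
    for g in genes:
        sds = []
        for k in genes:
            if k == g:
                continue
            ratios = log2.loc[g] - log2.loc[k]
            mean = sum(ratios) / len(ratios)
            var = sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1)
            sds.append(math.sqrt(var))
        out[g] = sum(sds) / len(sds)
    return pd.Series(out)


class TestGeNorm:
    def test_proportional_pair_contributes_zero_sd(self):
        matrix = hk_neg_matrix(
            {
                "HK01": [100, 200, 400, 800],
                "HK02": [50, 100, 200, 400],  # exactly 0.5x HK01
                "HK03": [300, 80, 500, 90],
            }
        )
        log2 = np.log2(matrix.counts.loc[["HK01", "HK02", "HK03"]])
        assert (log2.loc["HK01"] - log2.loc["HK02"]).std(ddof=1) == pytest.approx(0.0)
        m = genorm_stability(matrix, ["HK01", "HK02", "HK03"])
        # HK01 and HK02 share the noisy partner equally; their M must agree
        assert m["HK01"] == pytest.approx(m["HK02"], abs=1e-12)
        assert m["HK03"] > m["HK01"]

    def test_identical_genes_have_zero_m(self):
        matrix = hk_neg_matrix(
            {"HK01": [64, 128, 256, 512], "HK02": [64, 128, 256, 512], "HK03": [64, 128, 256, 512]}
        )
        m = genorm_stability(matrix, ["HK01", "HK02", "HK03"])
        assert (m == 0).all()

    def test_matches_brute_force_on_toy_counts(self, toy_matrix):
        genes = ["HK01", "HK02", "HK03"]
        m = genorm_stability(toy_matrix, genes)
        oracle = brute_force_m(np.log2(toy_matrix.counts.loc[genes]))
        pd.testing.assert_series_equal(m, oracle, check_names=False, atol=1e-12, rtol=0)

    def test_two_genes_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="at least 3"):
            genorm_stability(toy_matrix, ["HK01", "HK02"])

    def test_ranking_puts_noisy_gene_last(self, toy_matrix):
        ranking = genorm_ranking(toy_matrix, ["HK01", "HK02", "HK03"])
        assert ranking[-1] == "HK03"
        assert set(ranking[:2]) == {"HK01", "HK02"}


class TestPanelSelection:
    def proportional_matrix(self, extra=None):
        hk = {
            "HK01": [100, 200, 400, 800],
            "HK02": [50, 100, 200, 400],
            "HK03": [200, 400, 800, 1600],
            "HK04": [25, 50, 100, 200],
        }
        if extra:
            hk.update(extra)
        return hk_neg_matrix(hk)

    def test_proportional_genes_selected_with_r_one(self):
        matrix = self.proportional_matrix()
        assessment = screen_housekeeping(matrix, estimate_background(matrix))
        panel = select_hk_panel(matrix, assessment, min_r=0.99, panel_size=4)
        assert panel == ["HK01", "HK02", "HK03", "HK04"]

    def test_noisy_gene_excluded_by_exhaustive_search(self):
        matrix = self.proportional_matrix(extra={"HK05": [900, 40, 700, 35]})
        assessment = screen_housekeeping(matrix, estimate_background(matrix))
        panel = select_hk_panel(matrix, assessment, min_r=0.8, panel_size=4)
        assert "HK05" not in panel

    def test_panel_size_exceeding_candidates_rejected(self, toy_matrix):
        assessment = screen_housekeeping(toy_matrix, estimate_background(toy_matrix))
        with pytest.raises(ValueError, match="panel_size"):
            select_hk_panel(toy_matrix, assessment, panel_size=10)

    def test_no_panel_above_min_r_is_an_error(self, toy_matrix):
        assessment = screen_housekeeping(toy_matrix, estimate_background(toy_matrix))
        with pytest.raises(ValueError, match="min_r|panel"):
            select_hk_panel(toy_matrix, assessment, min_r=0.9999, panel_size=3)

    def test_increasingly_noisy_gene_always_excluded(self):
        """With one HK gene made pure noise, selection drops it across seeds."""
        rng = np.random.default_rng(5)
        excluded = 0
        for _ in range(10):
            base = np.array([100, 200, 400, 800], dtype=float)
            hk = {f"HK{i+1:02d}": list((base * (0.5 + i)).astype(int)) for i in range(4)}
            hk["HK05"] = list(rng.integers(30, 3000, size=4))
            matrix = hk_neg_matrix(hk)
            assessment = screen_housekeeping(matrix, estimate_background(matrix))
            panel = select_hk_panel(matrix, assessment, min_r=0.5, panel_size=4)
            excluded += "HK05" not in panel
        assert excluded >= 9
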