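"""Sample background estimation and housekeeping-gene quality control.

Background: each sample gets its own threshold theta_s = mean + 2 * SD of
the negative-control probe counts (sample SD, n-1 denominator) — the
standard nonspecific-hybridization floor for digital counting data.

Housekeeping screening: reference genes whose raw counts sit close to that
floor carry degradation noise rather than biology, so they are flagged out
of the normalization panel (raw count must exceed ``k * theta_s`` in every
sample; default k = 3, the same cutoff the detection filter uses).

Stability: the geNorm gene-stability measure M_j is the mean, over all other
reference genes k, of the standard deviation across samples of the pairwise
log2 ratio log2(x_j) - log2(x_k).  Lower M means the gene moves in lockstep
with the rest of the reference panel.  An iterative-elimination ranking is
provided as well.

Panel selection: the final normalization panel is the subset of passing
housekeeping genes that maximizes the minimum pairwise Pearson correlation of
log2 counts, subject to a floor on that minimum — mirroring the practice of
picking a small panel with "robust signal and good expression correlation".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .rcc_io import CountMatrix


@dataclass
class BackgroundProfile:
    """Per-sample background statistics from negative-control probes.

    ``table`` is indexed by sample_id with columns mean, sd, theta where
    theta = mean + 2 * sd.
    """

    table: pd.DataFrame
    n_negative: int

    @property
    def theta(self) -> pd.Series:
        return self.table["theta"]


@dataclass
class HkAssessment:
    """Housekeeping screening and stability results."""

    passes_background: pd.Series            # bool per HK gene
    stability_m: pd.Series | None = None    # geNorm M per HK gene
    correlation: pd.DataFrame | None = None  # pairwise Pearson r on log2 counts
    selected_panel: list[str] = field(default_factory=list)

    @property
    def passing_genes(self) -> list[str]:
        return list(self.passes_background.index[self.passes_background])


def estimate_background(matrix: CountMatrix) -> BackgroundProfile:
    """theta_s = mean + 2*SD (ddof=1) of the sample's negative-control counts."""
    neg = matrix.class_counts("Negative")
    if len(neg) < 2:
        raise ValueError(f"need >= 2 negative-control probes, found {len(neg)}")
    mean = neg.mean(axis=0)
    sd = neg.std(axis=0, ddof=1)
    theta = mean + 2.0 * sd
    if (neg.to_numpy() == 0).all():
        warnings.warn("all negative-control counts are zero; theta = 0", stacklevel=2)
    table = pd.DataFrame({"mean": mean, "sd": sd, "theta": theta})
    table.index.name = "sample_id"
    return BackgroundProfile(table=table, n_negative=len(neg))


def screen_housekeeping(
    matrix: CountMatrix, background: BackgroundProfile, k: float = 3.0
) -> HkAssessment:
    """Flag HK genes as passing iff raw count > k * theta_s in every sample.

    Failing genes are flagged, never removed from the matrix.
    """
    hk = matrix.class_counts("Housekeeping")
    if hk.empty:
        raise ValueError("no Housekeeping probes in matrix")
    threshold = k * background.theta.reindex(hk.columns)
    passes = (hk > threshold).all(axis=1)
    passes.name = "passes_background"
    return HkAssessment(passes_background=passes)


def _log2_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """log2 with a pseudocount of 1 applied only when zeros are present."""
    if (counts.to_numpy() == 0).any():
        return np.log2(counts + 1.0)
    return np.log2(counts)


def genorm_stability(matrix: CountMatrix, hk_genes: list[str]) -> pd.Series:
    """geNorm stability M per gene: mean over partners of the pairwise
    log-ratio SD across samples (ddof=1). Requires >= 3 genes."""
    if len(hk_genes) < 3:
        raise ValueError("geNorm M needs at least 3 reference genes")
    log2 = _log2_counts(matrix.counts.loc[hk_genes])
    m = {}
    for g in hk_genes:
        sds = [
            (log2.loc[g] - log2.loc[partner]).std(ddof=1)
            for partner in hk_genes
            if partner != g
        ]
        m[g] = float(np.mean(sds))
    out = pd.Series(m, name="genorm_m")
    out.index.name = "gene"
    return out


def genorm_ranking(matrix: CountMatrix, hk_genes: list[str]) -> list[str]:
    """Iterative-elimination stability ranking, most stable first.

    Repeatedly recomputes M on the surviving set and drops the least stable
    gene until two remain; those final two share the top rank and are listed
    alphabetically.
    """
    remaining = list(hk_genes)
    eliminated: list[str] = []
    while len(remaining) > 2:
        m = genorm_stability(matrix, remaining)
        worst = m.sort_values(ascending=False, kind="stable").index[0]
        # tie-break: highest M, then reverse-lexicographic so ranking is deterministic
        worst_m = m.max()
        candidates = sorted(m.index[m == worst_m], reverse=True)
        worst = candidates[0]
        remaining.remove(worst)
        eliminated.append(worst)
    return sorted(remaining) + eliminated[::-1]


def hk_correlation(matrix: CountMatrix, hk_genes: list[str]) -> pd.DataFrame:
    """Pairwise Pearson r of log2(count + 1) across samples."""
    log2 = np.log2(matrix.counts.loc[hk_genes] + 1.0)
    return log2.T.corr(method="pearson")


def select_hk_panel(
    matrix: CountMatrix,
    assessment: HkAssessment,
    min_r: float = 0.8,
    panel_size: int = 4,
) -> list[str]:
    """Pick the passing-HK subset of size ``panel_size`` maximizing the minimum
    pairwise Pearson r on log2 counts, requiring that minimum >= ``min_r``.

    Ties broken by lower mean geNorm M, then lexicographically.  Exhaustive
    over subsets — panel sizes are small.
    """
    if not 0.0 < min_r <= 1.0:
        raise ValueError("min_r must lie in (0, 1]")
    candidates = assessment.passing_genes
    if panel_size > len(candidates):
        raise ValueError(
            f"panel_size {panel_size} exceeds the {len(candidates)} passing HK genes"
        )
    corr = hk_correlation(matrix, candidates)
    if assessment.stability_m is not None and len(candidates) >= 3:
        m = assessment.stability_m
    elif len(candidates) >= 3:
        m = genorm_stability(matrix, candidates)
    else:
        m = pd.Series(0.0, index=candidates)

    best: tuple[float, float, tuple[str, ...]] | None = None
    for subset in combinations(sorted(candidates), panel_size):
        sub = corr.loc[list(subset), list(subset)].to_numpy()
        pair_min = sub[np.triu_indices(panel_size, k=1)].min() if panel_size > 1 else 1.0
        mean_m = float(m.reindex(list(subset)).fillna(0.0).mean())
        key = (-pair_min, mean_m, subset)
        if pair_min >= min_r and (best is None or key < best):
            best = key
    if best is None:
        raise ValueError(
            f"no {panel_size}-gene panel reaches min pairwise r >= {min_r};"
            " lower min_r or reduce panel_size"
        )
    return list(best[2])


def qc_report(
    background: BackgroundProfile, assessment: HkAssessment
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TSV-ready tables: per-sample background and per-HK-gene assessment."""
    hk = pd.DataFrame({"passes_background": assessment.passes_background})
    if assessment.stability_m is not None:
        hk["genorm_m"] = assessment.stability_m
    hk["in_panel"] = hk.index.isin(assessment.selected_panel)
    return background.table.copy(), hk
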