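"""Housekeeping normalization: per-sample scale factors from a reference panel.

For a sample s, let g_s be the geometric mean of the panel genes' raw counts
in that sample.  The scale factor is f_s = mean(g) / g_s, where mean(g) is
the arithmetic mean of the per-sample geometric means; every count in column
s is multiplied by f_s.  After scaling, all samples share the same panel
geometric mean (the defining fixed point), so a purely multiplicative
per-sample efficiency loss — degradation — is removed exactly.

The choice of reference (mean of geometric means) only sets the overall
scale; any fixed reference gives identical downstream test statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rcc_io import CountMatrix


@dataclass
class NormalizedMatrix:
    """Scaled counts plus the factors that produced them."""

    norm_counts: pd.DataFrame   # probes x samples, real-valued
    factors: pd.DataFrame       # per sample: geomean g, factor f
    hk_panel: list[str]
    probe_classes: pd.Series
    groups: dict[str, str] | None = None
    log2_offset: float = 1.0

    @property
    def log2_counts(self) -> pd.DataFrame:
        return np.log2(self.norm_counts + self.log2_offset)

    def as_count_matrix(self) -> CountMatrix:
        """Rounded view for re-running count-scale operations (idempotence checks)."""
        return CountMatrix(
            counts=self.norm_counts.round().astype(int),
            probe_classes=self.probe_classes,
            groups=self.groups,
        )


def _geometric_means(counts: pd.DataFrame) -> pd.Series:
    """Per-column geometric mean; pseudocount 1 only when zeros are present."""
    values = counts.to_numpy(dtype=float)
    if (values == 0).any():
        values = values + 1.0
    return pd.Series(np.exp(np.log(values).mean(axis=0)), index=counts.columns)


def normalize(matrix: CountMatrix, hk_panel: list[str]) -> NormalizedMatrix:
    """Scale each sample so the housekeeping-panel geometric means agree."""
    if not hk_panel:
        raise ValueError("empty housekeeping panel")
    missing = [g for g in hk_panel if g not in matrix.counts.index]
    if missing:
        raise ValueError(f"housekeeping genes absent from matrix: {missing}")
    g = _geometric_means(matrix.counts.loc[hk_panel])
    if (g <= 0).any():
        raise ValueError("zero housekeeping geometric mean; cannot normalize")
    f = g.mean() / g
    norm = matrix.counts.astype(float).mul(f, axis=1)
    factors = pd.DataFrame({"geomean": g, "factor": f})
    factors.index.name = "sample_id"
    return NormalizedMatrix(
        norm_counts=norm,
        factors=factors,
        hk_panel=list(hk_panel),
        probe_classes=matrix.probe_classes,
        groups=matrix.groups,
    )
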