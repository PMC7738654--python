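"""Two-group differential expression on detected genes.

Each detected gene is tested with an unpaired two-sample t-test on
log2-normalized values (pooled-variance Student by default; Welch
available).  Fold change is derived from the difference of group means on
the log2 scale, delta = mean(case) - mean(control), reported both as the
linear ratio R = 2**delta and in the field's signed convention:
signed FC = R when R >= 1, else -1/R (so a halving prints as -2.0).

A gene is called differentially expressed when |signed FC| >= fc_cutoff
(inclusive, default 1.5) and its uncorrected two-sided p < alpha (strict,
default 0.05).  No multiple-testing correction is applied by default —
with very small groups the priority is sensitivity — but Benjamini-Hochberg
adjusted p-values can be appended for reference without changing the calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

VARIANTS = ("student", "welch")
FC_MODES = ("log2", "linear")


def t_test_gene(
    values_case: np.ndarray, values_control: np.ndarray, variant: str = "student"
) -> tuple[float, float]:
    """Two-sided unpaired t-test; returns (t, p).

    ``student`` pools variances (df = n1 + n2 - 2); ``welch`` uses the
    Satterthwaite df.  Degenerate zero-variance inputs: equal constant groups
    give (0, 1); unequal constant groups give (±inf, 0) with a warning.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in t-test input")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero variance in both groups with unequal means", stacklevel=2)
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def fold_change(
    values_case: np.ndarray, values_control: np.ndarray
) -> tuple[float, float]:
    """(delta, signed_fc) from log2-scale group means."""
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    delta = float(a.mean() - b.mean())
    return delta, signed_fc_from_delta(delta)


def signed_fc_from_delta(delta: float) -> float:
    ratio = 2.0 ** delta
    return float(ratio) if ratio >= 1.0 else float(-1.0 / ratio)


@dataclass
class DEResult:
    """Per-gene DE table plus the parameters that produced it."""

    table: pd.DataFrame  # mean_log2_case, mean_log2_control, delta, signed_fc, t, p, call
    variant: str
    fc_mode: str
    fc_cutoff: float | None = None
    alpha: float | None = None

    @property
    def summary(self) -> dict[str, int]:
        calls = self.table["call"]
        return {
            "n_detected": int(len(self.table)),
            "n_up": int((calls == "up").sum()),
            "n_down": int((calls == "down").sum()),
        }


def differential_expression(
    log2_values: pd.DataFrame,
    groups: dict[str, str],
    genes: list[str] | None = None,
    variant: str = "student",
    fc_mode: str = "log2",
) -> DEResult:
    """Test every gene (row) of ``log2_values``, case vs control.

    ``fc_mode='log2'`` derives the ratio from the difference of log2 means;
    ``'linear'`` uses the ratio of arithmetic means on the linear scale
    (the log2 input is inverted with its +1 offset assumed) — the two
    conventions differ only through Jensen's inequality and both are in use
    for counting data.
    """
    if fc_mode not in FC_MODES:
        raise ValueError(f"unknown fc_mode {fc_mode!r}")
    case_cols = [s for s in log2_values.columns if groups.get(s) == "case"]
    ctrl_cols = [s for s in log2_values.columns if groups.get(s) == "control"]
    unlabeled = [s for s in log2_values.columns if s not in groups]
    if unlabeled:
        raise ValueError(f"samples missing group labels: {unlabeled}")
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    rows = log2_values if genes is None else log2_values.loc[genes]

    records = []
    for gene, values in rows.iterrows():
        a = values[case_cols].to_numpy(dtype=float)
        b = values[ctrl_cols].to_numpy(dtype=float)
        t, p = t_test_gene(a, b, variant=variant)
        if fc_mode == "log2":
            delta, sfc = fold_change(a, b)
        else:
            lin_a, lin_b = 2.0 ** a - 1.0, 2.0 ** b - 1.0
            ratio = max(lin_a.mean(), 0.0) / max(lin_b.mean(), np.finfo(float).tiny)
            delta = float(np.log2(ratio)) if ratio > 0 else -np.inf
            sfc = signed_fc_from_delta(delta)
        records.append(
            {
                "gene": gene,
                "mean_log2_case": a.mean(),
                "mean_log2_control": b.mean(),
                "delta": delta,
                "signed_fc": sfc,
                "t": t,
                "p": p,
            }
        )
    table = pd.DataFrame.from_records(records).set_index("gene")
    table["call"] = "ns"
    return DEResult(table=table, variant=variant, fc_mode=fc_mode)


def call_degs(
    de: DEResult,
    fc_cutoff: float = 1.5,
    alpha: float = 0.05,
    correction: str = "none",
) -> DEResult:
    """Classify genes as up / down / ns.

    FC boundary is inclusive (|signed FC| >= fc_cutoff), the p boundary strict
    (p < alpha).  ``correction='bh'`` appends Benjamini-Hochberg adjusted
    p-values as a ``p_adj`` column; the default calls still use raw p.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if correction not in ("none", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    table = de.table.copy()
    sig = table["p"] < alpha
    table["call"] = np.where(
        sig & (table["signed_fc"] >= fc_cutoff),
        "up",
        np.where(sig & (table["signed_fc"] <= -fc_cutoff), "down", "ns"),
    )
    if correction == "bh":
        table["p_adj"] = stats.false_discovery_control(table["p"], method="bh")
    return DEResult(
        table=table, variant=de.variant, fc_mode=de.fc_mode, fc_cutoff=fc_cutoff, alpha=alpha
    )


def de_report(de: DEResult) -> pd.DataFrame:
    """Publication-style table: gene, signed FC, p (plus internals)."""
    cols = ["signed_fc", "p", "delta", "t", "call"]
    if "p_adj" in de.table.columns:
        cols.append("p_adj")
    out = de.table[cols].copy()
    return out.sort_values(["call", "p"], kind="stable")
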