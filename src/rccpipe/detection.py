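"""Signal-to-noise detection filtering against per-sample background.

With degraded input RNA, genuinely expressed genes cannot be told apart from
background at low counts, so each endogenous gene is scored by its
signal-to-noise ratio SNR = raw count / theta_s against the sample's own
background threshold, and a gene counts as detected only if its SNR clears
the cutoff (strictly) in enough samples.  The aggregation default — more
than half the samples of at least one group — keeps genes expressed in only
one condition.  Only endogenous probes are subject to the filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import BackgroundProfile
from .rcc_io import CountMatrix

SCOPES = ("any_group", "all_samples")


@dataclass
class DetectionResult:
    snr: pd.DataFrame          # endogenous genes x samples
    detected: pd.Series        # bool per endogenous gene
    cutoff: float
    min_fraction: float
    scope: str

    @property
    def detected_genes(self) -> list[str]:
        return list(self.detected.index[self.detected])

    @property
    def n_detected(self) -> int:
        return int(self.detected.sum())


def score_detection(
    matrix: CountMatrix,
    background: BackgroundProfile,
    cutoff: float = 3.0,
    min_fraction: float = 0.5,
    scope: str = "any_group",
) -> DetectionResult:
    """SNR on raw counts; detected iff SNR > cutoff in >= min_fraction of the
    samples of some group (``any_group``) or of all samples (``all_samples``)."""
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    endo = matrix.class_counts("Endogenous")
    theta = background.theta.reindex(endo.columns)
    if (theta <= 0).any():
        warnings.warn(
            "theta = 0 for some sample(s); SNR is +inf for nonzero counts there",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = endo.div(theta, axis=1)
        snr = snr.where(endo != 0, 0.0)  # 0/0 and 0/theta are both SNR 0
    passes = snr > cutoff

    if scope == "all_samples":
        detected = passes.mean(axis=1) >= min_fraction
    else:
        matrix.require_groups()
        detected = pd.Series(False, index=passes.index)
        for group in sorted(set(matrix.groups.values())):
            cols = matrix.samples_in_group(group)
            if cols:
                detected |= passes[cols].mean(axis=1) >= min_fraction
    detected.name = "detected"
    return DetectionResult(
        snr=snr, detected=detected, cutoff=cutoff, min_fraction=min_fraction, scope=scope
    )


def detection_report(result: DetectionResult) -> pd.DataFrame:
    out = result.snr.copy()
    out["detected"] = result.detected
    return out
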