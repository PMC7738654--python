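import numpy as np
import pandas as pd
import pytest

from rccpipe.rcc_io import CountMatrix


def make_matrix(counts: dict[str, list[int]], classes: dict[str, str], groups=None) -> CountMatrix:
    """Build a CountMatrix from {probe: [counts per sample]} plus class labels."""
    samples = [f"S{i + 1}" for i in range(len(next(iter(counts.values()))))]
    df = pd.DataFrame(counts, index=samples).T
    df.index.name = "probe"
    cls = pd.Series({k: classes[k] for k in df.index}, name="code_class")
    cls.index.name = "probe"
    return CountMatrix(counts=df.astype(int), probe_classes=cls, groups=groups)


@pytest.fixture
def toy_matrix():
    """3 HK + 2 negative probes, 4 samples; HK01/HK02 proportional, HK03 noisy."""
    return make_matrix(
        {
            "HK01": [100, 200, 400, 800],
            "HK02": [50, 100, 200, 400],
            "HK03": [300, 80, 500, 90],
            "NEG_01": [4, 6, 5, 7],
            "NEG_02": [6, 4, 7, 5],
        },
        {
            "HK01": "Housekeeping",
            "HK02": "Housekeeping",
            "HK03": "Housekeeping",
            "NEG_01": "Negative",
            "NEG_02": "Negative",
        },
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated dataset, shared across tests."""
    from rccpipe.simulate import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(seed=11))


def small_sim_config(**overrides):
    """A scaled-down simulation config for fast per-test datasets."""
    from rccpipe.simulate import SimulationConfig

    defaults = dict(
        n_endogenous=60,
        n_negative=8,
        n_housekeeping=8,
        de_fraction_up=0.1,
        de_fraction_down=0.1,
        dropout_fraction=0.2,
        seed=3,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def run_mini_pipeline(config, hk_min_r=0.8, panel_size=4):
    """simulate -> background -> screen -> panel -> normalize -> detect -> DE."""
    from rccpipe import diffexpr, qc
    from rccpipe.detection import score_detection
    from rccpipe.normalization import normalize
    from rccpipe.simulate import simulate_dataset

    matrix, truth = simulate_dataset(config)
    background = qc.estimate_background(matrix)
    assessment = qc.screen_housekeeping(matrix, background)
    panel = qc.select_hk_panel(matrix, assessment, min_r=hk_min_r, panel_size=panel_size)
    norm = normalize(matrix, panel)
    detection = score_detection(matrix, background)
    de = diffexpr.differential_expression(
        norm.log2_counts, matrix.groups, genes=detection.detected_genes
    )
    de = diffexpr.call_degs(de)
    return matrix, truth, norm, detection, de
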