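#!/usr/bin/env python
"""Generate the baseline synthetic dataset used by the downstream analyses.

Emulates a degraded-FFPE immunology-panel run: 579 endogenous genes,
15 housekeeping genes, 8 negative controls, 11 cases vs 4 controls, with
planted fold changes and a known fraction of genes lost to degradation.
Writes the count matrix, per-sample RCC fixture files and the truth tables
under results/sim/.
"""

from pathlib import Path

from rccpipe import rcc_io
from rccpipe.simulate import SimulationConfig, expected_detection_count, simulate_dataset

OUT = Path("results/sim")
SEED = 20260930


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    matrix, truth = simulate_dataset(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    rcc_io.write_counts_tsv(matrix, OUT / "counts.tsv")
    rcc_io.write_sample_sheet(matrix.groups, OUT / "samples.tsv")
    truth.genes.to_csv(OUT / "truth_genes.tsv", sep="\t")
    truth.samples.to_csv(OUT / "truth_samples.tsv", sep="\t")
    rcc_dir = OUT / "rcc"
    rcc_dir.mkdir(exist_ok=True)
    for lane in rcc_io.matrix_to_lanes(matrix):
        rcc_io.write_rcc_file(lane, rcc_dir / f"{lane.sample_id}.RCC")

    n_de = int(truth.genes["is_de"].sum())
    n_drop = int(truth.genes["is_dropout"].sum())
    print(f"simulated {matrix.counts.shape[0]} probes x {matrix.counts.shape[1]} samples (seed {SEED})")
    print(f"planted: {n_de} differential genes, {n_drop} dropout genes")
    print(f"expected detected genes: {expected_detection_count(cfg):.0f} of {cfg.n_endogenous}")
    print(f"outputs in {OUT}/ (counts.tsv, samples.tsv, truth_*.tsv, rcc/*.RCC)")


if __name__ == "__main__":
    main()
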