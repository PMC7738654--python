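"""End-to-end orchestration: simulate/load → QC → normalize → detect → DE →
enrich → report, with every intermediate written as TSV and a JSON manifest
capturing the configuration hash, seed and per-stage counts so that a run is
auditable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diffexpr, enrichment, qc, rcc_io
from .cluster import cluster as cluster_samples, linkage_to_newick, volcano_table
from .detection import score_detection
from .normalization import normalize
from .simulate import SimulationConfig, config_from_dict, config_to_dict, simulate_dataset

log = logging.getLogger("rccpipe")


@dataclass
class PipelineConfig:
    """One config object driving every stage.

    Exactly one of ``simulate`` (a SimulationConfig) or ``counts_tsv``/
    ``rcc_dir`` (+ ``sample_sheet``) must be provided.
    """

    simulate: SimulationConfig | None = None
    rcc_dir: str | None = None
    counts_tsv: str | None = None
    sample_sheet: str | None = None
    gmt_files: list[str] = field(default_factory=list)

    hk_screen_k: float = 3.0
    hk_selection: str = "correlation"      # or "genorm"
    hk_min_r: float = 0.8
    hk_panel_size: int = 4
    snr_cutoff: float = 3.0
    snr_min_fraction: float = 0.5
    snr_scope: str = "any_group"
    t_variant: str = "student"
    fc_mode: str = "log2"
    fc_cutoff: float = 1.5
    alpha: float = 0.05
    correction: str = "none"
    linkage: str = "average"
    top_n_network: int = 20

    outdir: str = "results/run"
    seed: int = 0

    def validate(self) -> None:
        has_sim = self.simulate is not None
        has_input = self.counts_tsv is not None or self.rcc_dir is not None
        if has_sim == has_input:
            raise ValueError("exactly one of a simulate block or input paths is required")
        if self.hk_selection not in ("correlation", "genorm"):
            raise ValueError(f"unknown hk_selection {self.hk_selection!r}")
        if self.simulate is not None:
            self.simulate.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"] = config_to_dict(self.simulate)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = config_from_dict(d["simulate"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _analysis_params(config: PipelineConfig) -> dict:
    # outdir is a location, not an analysis parameter: two runs of the same
    # analysis into different directories must produce identical manifests
    d = config.to_dict()
    d.pop("outdir", None)
    return d


def _config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(_analysis_params(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_input(config: PipelineConfig) -> tuple[rcc_io.CountMatrix, object | None]:
    """Return (matrix, truth-or-None) from the configured source."""
    if config.simulate is not None:
        sim = config.simulate
        matrix, truth = simulate_dataset(sim)
        return matrix, truth
    groups = rcc_io.read_sample_sheet(config.sample_sheet) if config.sample_sheet else None
    if config.counts_tsv:
        return rcc_io.read_counts_tsv(config.counts_tsv, groups=groups), None
    lanes = [rcc_io.read_rcc(p) for p in sorted(Path(config.rcc_dir).glob("*.RCC"))]
    if not lanes:
        raise FileNotFoundError(f"no .RCC files under {config.rcc_dir}")
    return rcc_io.assemble_matrix(lanes, groups=groups), None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write intermediates under ``config.outdir``, and
    return the manifest (also written as ``manifest.json``).

    Identical config + seed gives a byte-identical manifest.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage: %s", name)

    stage("input")
    matrix, truth = load_input(config)
    rcc_io.write_counts_tsv(matrix, outdir / "counts.tsv")
    if matrix.groups:
        rcc_io.write_sample_sheet(matrix.groups, outdir / "samples.tsv")
    if truth is not None:
        truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t")
        truth.samples.to_csv(outdir / "truth_samples.tsv", sep="\t")

    stage("qc")
    background = qc.estimate_background(matrix)
    assessment = qc.screen_housekeeping(matrix, background, k=config.hk_screen_k)
    passing = assessment.passing_genes
    if len(passing) >= 3:
        assessment.stability_m = qc.genorm_stability(matrix, passing)
    if config.hk_selection == "correlation":
        panel = qc.select_hk_panel(
            matrix, assessment, min_r=config.hk_min_r, panel_size=config.hk_panel_size
        )
    else:
        ranking = qc.genorm_ranking(matrix, passing)
        panel = sorted(ranking[: config.hk_panel_size])
    assessment.selected_panel = panel
    bg_table, hk_table = qc.qc_report(background, assessment)
    bg_table.to_csv(outdir / "background.tsv", sep="\t")
    hk_table.to_csv(outdir / "hk_assessment.tsv", sep="\t", index_label="gene")

    stage("normalize")
    norm = normalize(matrix, panel)
    norm.factors.to_csv(outdir / "factors.tsv", sep="\t")
    norm.norm_counts.to_csv(outdir / "normalized.tsv", sep="\t", index_label="probe")

    stage("detect")
    detection = score_detection(
        matrix,
        background,
        cutoff=config.snr_cutoff,
        min_fraction=config.snr_min_fraction,
        scope=config.snr_scope,
    )
    from .detection import detection_report

    detection_report(detection).to_csv(outdir / "detection.tsv", sep="\t", index_label="gene")

    stage("differential expression")
    matrix.require_groups()
    log2 = norm.log2_counts
    de = diffexpr.differential_expression(
        log2,
        matrix.groups,
        genes=detection.detected_genes,
        variant=config.t_variant,
        fc_mode=config.fc_mode,
    )
    de = diffexpr.call_degs(
        de, fc_cutoff=config.fc_cutoff, alpha=config.alpha, correction=config.correction
    )
    diffexpr.de_report(de).to_csv(outdir / "de_table.tsv", sep="\t", index_label="gene")
    volcano = volcano_table(de)
    volcano.to_csv(outdir / "volcano.tsv", sep="\t", index_label="gene")
    up = list(de.table.index[de.table["call"] == "up"])
    down = list(de.table.index[de.table["call"] == "down"])

    stage("enrichment")
    universe = detection.detected_genes
    if config.gmt_files:
        sets: dict[str, set[str]] = {}
        for path in config.gmt_files:
            sets.update(enrichment.read_gmt(path))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            collection = enrichment.GeneSetCollection(sets=sets, universe=set(universe))
    else:
        # simulated gene names carry no curated annotation; build a seeded
        # synthetic collection enriched for the planted up-regulated genes
        rng = np.random.default_rng(config.seed + 1)
        enriched = truth.de_genes if truth is not None else up
        collection = enrichment.synthetic_collection(universe, enriched, rng)
    for label, query in (("up", up), ("down", down)):
        if collection.sets and query:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = enrichment.ora(query, collection)
        else:
            table = pd.DataFrame(columns=["term", "K", "n", "k", "p", "neg_log10_p", "genes"])
        table.to_csv(outdir / f"enrichment_{label}.tsv", sep="\t", index=False)
        top = sorted(query, key=lambda g: de.table.at[g, "p"])[: config.top_n_network]
        net = enrichment.shared_term_network(top, collection)
        net.to_csv(outdir / f"network_{label}.tsv", sep="\t", index=False)

    stage("report")
    detected_log2 = log2.loc[detection.detected_genes]
    heat_all = cluster_samples(detected_log2, linkage=config.linkage)
    deg_rows = up + down
    heat_deg = cluster_samples(log2.loc[deg_rows], linkage=config.linkage) if len(deg_rows) >= 2 else None
    heat_all.scaled.to_csv(outdir / "heatmap_detected.tsv", sep="\t", index_label="gene")
    (outdir / "sample_dendrogram.nwk").write_text(
        linkage_to_newick(heat_all.sample_linkage, list(detected_log2.columns)) + "\n"
    )
    if heat_deg is not None:
        heat_deg.scaled.to_csv(outdir / "heatmap_degs.tsv", sep="\t", index_label="gene")
        (outdir / "deg_sample_dendrogram.nwk").write_text(
            linkage_to_newick(heat_deg.sample_linkage, list(log2.columns)) + "\n"
        )

    manifest = {
        "rccpipe_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "config": _analysis_params(config),
        "counts": {
            "n_probes": len(matrix.probe_names),
            "n_samples": len(matrix.sample_ids),
            "n_hk_passing": len(passing),
            "hk_panel": panel,
            "n_detected": detection.n_detected,
            "n_up": len(up),
            "n_down": len(down),
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
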