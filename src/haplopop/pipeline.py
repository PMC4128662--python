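"""End-to-end orchestration: filter → mask → classify → scans → report.

Every stage parameter defaults to the analysis protocol this pipeline
implements: genotype quality >= 30, depth >= 10 with a mean+3·SD upper bound,
20 kb / 4 kb diversity windows, MAF >= 10% and a 1–100 kb fit range for the
LD-based recombination estimate, 50 kb SNP thinning for structure, and the
PHS scan with a quartic genetic map, 30 kb missing-cluster termination and a
top-0.1% candidate cutoff.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, diversity, ld, phs, popstructure, qc, sites
from .io import (
    read_annotation,
    read_callable_bed,
    read_markers,
    read_reference,
    read_variants,
    write_newick,
    write_window_stats,
)


@dataclass
class PipelineConfig:
    reference: str
    vcf: str
    out_dir: str
    callable_bed: str | None = None
    annotation: str | None = None
    markers: str | None = None
    # call filtering
    min_qual: float = 30.0
    min_depth: int = 10
    depth_sd_factor: float = 3.0
    depth_rule: str = "mean_plus_3sd"
    # windows
    window_size: int = 20_000
    window_step: int = 4_000
    # LD / recombination
    maf_min: float = 0.10
    ld_max_dist: int = 500_000
    ld_bin_size: int = 1000
    fit_min: int = 1000
    fit_max: int = 100_000
    # structure
    thin_spacing: int = 50_000
    # PHS
    phs_top_fraction: float = 0.001
    miss_cluster_bp: int = 30_000
    map_degree: int = 4
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write tables plus a run manifest; returns a report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrap

    reference = stage("load_reference")(lambda: read_reference(config.reference))
    matrix = stage("load_variants")(lambda: read_variants(config.vcf, reference))
    callable_iv = (
        stage("load_callable")(lambda: read_callable_bed(config.callable_bed))
        if config.callable_bed
        else None
    )
    annotation = (
        stage("load_annotation")(lambda: read_annotation(config.annotation))
        if config.annotation
        else None
    )

    filtered = stage("filter_calls")(
        lambda: qc.filter_calls(
            matrix,
            min_qual=config.min_qual,
            min_depth=config.min_depth,
            depth_sd_factor=config.depth_sd_factor,
            depth_rule=config.depth_rule,
        )
    )
    mask = stage("mask")(lambda: qc.build_site_mask(reference, annotation))
    amatrix = stage("complete_sites")(
        lambda: qc.apply_mask_and_complete(filtered, mask, callable_intervals=callable_iv)
    )
    report["n_samples"] = amatrix.n_samples
    report["n_snps"] = amatrix.n_snps
    report["called_sites"] = {c: amatrix.called_sites(c) for c in amatrix.chrom_names}

    lengths = reference.lengths
    windows = stage("diversity")(
        lambda: diversity.window_scan(
            amatrix, config.window_size, config.window_step, chrom_lengths=lengths
        )
    )
    write_window_stats(windows, out / "windows.tsv")
    total_called = sum(report["called_sites"].values())
    report["pi_genome"] = float(
        diversity.nucleotide_diversity(amatrix.calls, total_called)
    )
    finite_d = windows["tajimas_d"].dropna()
    report["mean_window_tajimas_d"] = float(finite_d.mean()) if len(finite_d) else float("nan")

    if annotation is not None:
        class_map = stage("classify")(
            lambda: sites.classify_sites(annotation, reference, amatrix)
        )
        table = stage("class_diversity")(
            lambda: diversity.class_diversity_table(amatrix, class_map)
        )
        write_window_stats(table, out / "class_diversity.tsv")
        report["class_pi"] = dict(zip(table["class"], table["pi"]))
        genes = stage("gene_diversity")(
            lambda: [
                diversity.gene_diversity(g, amatrix, class_map, reference)
                for g in sorted(class_map.gene_codons)
            ]
        )
        import pandas as pd

        gene_df = pd.DataFrame([dataclasses.asdict(g) for g in genes])
        if len(gene_df):
            gene_df = gene_df.sort_values("tajimas_d", ascending=False)
        write_window_stats(gene_df, out / "genes.tsv")

    dist = stage("structure")(lambda: popstructure.p_distance_matrix(amatrix))
    tree = popstructure.neighbor_joining(dist)
    write_newick(tree.newick, out / "nj_tree.nwk")
    thin = popstructure.thin_snps(amatrix, spacing=config.thin_spacing, seed=config.seed)
    report["n_thinned_snps"] = int(thin.size)
    if thin.size >= 2:
        eigvals, coords = popstructure.pca(amatrix.calls[:, thin])
        np.savetxt(
            out / "pca.tsv",
            np.column_stack([coords[:, : min(4, coords.shape[1])]]),
            delimiter="\t",
            fmt="%.8g",
            header="\t".join(f"PC{i+1}" for i in range(min(4, coords.shape[1]))),
            comments="",
        )
        report["pca_eigenvalues"] = [float(v) for v in eigvals[:4]]

    pairs = stage("ld")(
        lambda: ld.pairwise_r2(amatrix, maf_min=config.maf_min, max_dist=config.ld_max_dist)
    )
    if len(pairs):
        decay = ld.bin_ld_decay(pairs, bin_size=config.ld_bin_size)
        write_window_stats(decay.table, out / "ld_decay.tsv")
        try:
            est = ld.estimate_rho(decay, fit_min=config.fit_min, fit_max=config.fit_max)
            report["rho"] = est.rho
        except ValueError:
            report["rho"] = None

    if config.markers:
        markers = stage("load_markers")(lambda: read_markers(config.markers))
        gmap = stage("phs")(lambda: phs.fit_genetic_map(markers, degree=config.map_degree))
        scan = stage("phs")(
            lambda: phs.phs_scan(
                amatrix,
                gmap,
                top_fraction=config.phs_top_fraction,
                miss_cluster_bp=config.miss_cluster_bp,
                chrom_lengths=lengths,
            )
        )
        scan_out = scan.copy()
        scan_out["pos"] = scan_out["pos"] + 1  # 1-based in output
        write_window_stats(scan_out, out / "phs.tsv")
        report["n_phs_candidates"] = int(scan["candidate"].sum())

    manifest = {
        "haplopop_version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {
            k: _sha256(p)
            for k, p in {
                "reference": config.reference,
                "vcf": config.vcf,
                "callable_bed": config.callable_bed,
                "annotation": config.annotation,
                "markers": config.markers,
            }.items()
            if p
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report
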