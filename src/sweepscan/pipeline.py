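"""End-to-end pipeline: filter → per-target scan → annotate → enrich → report.

Each target population is contrasted against the pool of all remaining
populations (the reference pool is recomputed per target). Every target
gets its own output bundle (window TSV, candidate BED/TSV, gene list,
enrichment TSV); a combined enrichment over the union of all targets'
selected genes and a run manifest are written at the top level. Reruns
with identical inputs and config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotate, io, scan as scan_mod
from .model import FilterConfig
from .scan import ScanConfig

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    sample_map: str
    chrom_lengths: str
    gff: Optional[str] = None
    terms: Optional[str] = None
    out_dir: str = "sweepscan_out"
    targets: Optional[Sequence[str]] = None  # None = every population in turn
    filter: FilterConfig = field(default_factory=FilterConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    alpha: float = 0.05
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: os.PathLike | str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fc = FilterConfig(**raw.pop("filter", {}))
        sc = ScanConfig(**raw.pop("scan", {}))
        return cls(filter=fc, scan=sc, **raw)

    def to_dict(self) -> dict:
        return {
            "vcf": self.vcf,
            "sample_map": self.sample_map,
            "chrom_lengths": self.chrom_lengths,
            "gff": self.gff,
            "terms": self.terms,
            "out_dir": self.out_dir,
            "targets": list(self.targets) if self.targets else None,
            "filter": {
                "maf_min": self.filter.maf_min,
                "missing_max": self.filter.missing_max,
            },
            "scan": {
                "window_span": self.scan.window_span,
                "step": self.scan.step,
                "outlier_quantile": self.scan.outlier_quantile,
                "min_sites_per_window": self.scan.min_sites_per_window,
            },
            "alpha": self.alpha,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dictionary."""
    for name in ("vcf", "sample_map", "chrom_lengths", "gff", "terms"):
        p = getattr(cfg, name)
        if p is not None and not os.path.exists(p):
            raise FileNotFoundError(f"{name} file not found: {p}")

    smap = io.read_sample_map(cfg.sample_map)
    targets = list(cfg.targets) if cfg.targets else smap.populations()
    unknown = [t for t in targets if t not in smap.populations()]
    if unknown:
        raise ValueError(f"targets not in sample map: {unknown}")

    g_raw = io.read_vcf(cfg.vcf, keep_samples=smap.samples)
    g = io.filter_variants(g_raw, cfg.filter)
    lengths = io.read_chrom_lengths(cfg.chrom_lengths)

    genes = annotate.read_gff3(cfg.gff) if cfg.gff else None
    terms = annotate.read_term_map(cfg.terms) if cfg.terms else None
    universe = genes["gene_id"].tolist() if genes is not None else []

    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {
        "tool": "sweepscan",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "inputs": {
            name: {"path": getattr(cfg, name), "sha256": _sha256(getattr(cfg, name))}
            for name in ("vcf", "sample_map", "chrom_lengths", "gff", "terms")
            if getattr(cfg, name) is not None
        },
        "counts": {
            "variants_raw": g_raw.n_variants,
            "variants_filtered": g.n_variants,
            "samples": g.n_samples,
            "populations": len(smap.populations()),
        },
        "targets": {},
    }

    union_genes: set[str] = set()
    for target in targets:
        tgt, ref = io.pool_reference(smap, target)
        windows, regions = scan_mod.scan(g, tgt, ref, lengths, cfg.scan)
        tdir = os.path.join(cfg.out_dir, target)
        os.makedirs(tdir, exist_ok=True)
        scan_mod.write_window_tsv(windows, os.path.join(tdir, "windows.tsv"))
        scan_mod.write_regions_bed(regions, os.path.join(tdir, "candidates.bed"))
        scan_mod.write_regions_tsv(regions, os.path.join(tdir, "candidates.tsv"))

        tcounts = {
            "target_samples": len(tgt),
            "reference_samples": len(ref),
            "windows": len(windows),
            "fst_outliers": int(windows["fst_outlier"].sum()),
            "pi_outliers": int(windows["pi_outlier"].sum()),
            "candidate_windows": int(windows["candidate"].sum()),
            "candidate_regions": len(regions),
        }
        if genes is not None:
            selected = annotate.genes_in_regions(regions, genes)
            union_genes.update(selected)
            with open(os.path.join(tdir, "genes.txt"), "w") as fh:
                fh.writelines(s + "\n" for s in selected)
            tcounts["selected_genes"] = len(selected)
            if terms is not None:
                enr = annotate.hypergeom_enrich(selected, terms, universe, cfg.alpha)
                annotate.write_enrichment_tsv(
                    enr, os.path.join(tdir, "enrichment.tsv")
                )
                tcounts["significant_terms"] = int(enr["significant"].sum()) if len(enr) else 0
        if len(regions) == 0:
            log.warning("target %s: no candidate regions", target)
        manifest["targets"][target] = tcounts

    if genes is not None and terms is not None:
        combined = annotate.hypergeom_enrich(
            sorted(union_genes), terms, universe, cfg.alpha
        )
        annotate.write_enrichment_tsv(
            combined, os.path.join(cfg.out_dir, "combined_enrichment.tsv")
        )
        manifest["counts"]["union_selected_genes"] = len(union_genes)
        manifest["counts"]["combined_significant_terms"] = (
            int(combined["significant"].sum()) if len(combined) else 0
        )

    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if cfg.make_plots:
        for target in targets:
            try:
                render_report(os.path.join(cfg.out_dir, target))
            except Exception as exc:  # plotting is best-effort
                log.warning("report for %s failed: %s", target, exc)
    return manifest


def render_report(bundle_dir: os.PathLike | str) -> list[str]:
    """Per-chromosome F_ST and diversity-score plots + a markdown summary.

    Reads the bundle's ``windows.tsv``; candidate windows are highlighted.
    Returns the list of files written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bundle_dir = os.fspath(bundle_dir)
    windows = pd.read_csv(os.path.join(bundle_dir, "windows.tsv"), sep="\t")
    written: list[str] = []
    for chrom, grp in windows.groupby("chrom"):
        mid = (grp["start"] + grp["end"]) / 2e6
        for stat, label in (("fst", "F_ST"), ("diversity_score", "-log10 pi")):
            fig, ax = plt.subplots(figsize=(8, 3))
            ax.scatter(mid, grp[stat], s=8, c="grey", label="windows")
            cand = grp[grp["candidate"].astype(bool)]
            if len(cand):
                ax.scatter(
                    (cand["start"] + cand["end"]) / 2e6,
                    cand[stat],
                    s=14,
                    c="crimson",
                    label="candidate",
                )
            ax.set_xlabel(f"{chrom} position (Mb)")
            ax.set_ylabel(label)
            ax.legend(loc="upper right", fontsize=7)
            fig.tight_layout()
            out = os.path.join(bundle_dir, f"report_{chrom}_{stat}.png")
            fig.savefig(out, dpi=120)
            plt.close(fig)
            written.append(out)

    genes_path = os.path.join(bundle_dir, "genes.txt")
    n_genes = None
    if os.path.exists(genes_path):
        with open(genes_path) as fh:
            n_genes = sum(1 for _ in fh)
    summary = os.path.join(bundle_dir, "summary.md")
    with open(summary, "w") as fh:
        fh.write(f"# Scan summary — {os.path.basename(bundle_dir)}\n\n")
        fh.write(f"- windows: {len(windows)}\n")
        fh.write(f"- candidate windows: {int(windows['candidate'].sum())}\n")
        if n_genes is not None:
            fh.write(f"- selected genes: {n_genes}\n")
    written.append(summary)
    return written
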