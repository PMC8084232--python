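"""Candidate-region gene extraction and hypergeometric term enrichment.

Genes come from a GFF3 annotation (``gene`` features); a gene is
selected when its body overlaps a candidate region by at least 1 bp
(strand ignored; intervals 0-based half-open). Term enrichment is the
one-sided hypergeometric (Fisher exact upper-tail) test per term with
Benjamini–Hochberg FDR control across all tested terms; the background
universe defaults to every gene in the annotation.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "name"]
TERM_COLUMNS = ["gene_id", "term_id", "term_name", "category"]
ENRICH_COLUMNS = [
    "term_id",
    "term_name",
    "category",
    "k",
    "K",
    "n",
    "N",
    "p_value",
    "fdr",
    "significant",
]


def read_gff3(path: os.PathLike | str) -> pd.DataFrame:
    """Read gene features from a GFF3 file into a gene table.

    The gene id is taken from the ``ID=`` attribute, falling back to
    ``gene_id``. Coordinates are converted to 0-based half-open.
    """
    db = gffutils.create_db(
        os.fspath(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    rows = []
    for f in db.features_of_type("gene"):
        gid = f.id
        if gid is None and "gene_id" in f.attributes:
            gid = f.attributes["gene_id"][0]
        name = f.attributes.get("Name", [gid])[0]
        rows.append((gid, f.seqid, f.start - 1, f.end, f.strand or ".", name))
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    if genes["gene_id"].duplicated().any():
        dupes = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in GFF: {dupes}")
    if ((genes["end"] - genes["start"]) <= 0).any():
        raise ValueError("gene with non-positive length in GFF")
    return genes.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_gff3(genes: pd.DataFrame, path: os.PathLike | str, source: str = "sweepscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.name}\n"
            )


def read_term_map(path: os.PathLike | str) -> pd.DataFrame:
    """Read a gene→term TSV: gene_id, term_id, term_name, category."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=TERM_COLUMNS, dtype=str
    )
    if len(df) and df.iloc[0]["gene_id"].lower() == "gene_id":
        df = df.iloc[1:].reset_index(drop=True)
    return df


def write_term_map(terms: pd.DataFrame, path: os.PathLike | str) -> None:
    terms.to_csv(path, sep="\t", index=False, header=False)


def genes_in_regions(regions: pd.DataFrame, genes: pd.DataFrame) -> list[str]:
    """Gene ids whose bodies overlap any region by ≥1 bp (deduplicated).

    Output is ordered by gene (chrom, start, gene_id). Raises when the
    regions and the annotation share no chromosome names at all, which
    almost always means a naming-scheme mismatch (e.g. ``chr1`` vs ``1``).
    """
    if len(regions) == 0 or len(genes) == 0:
        return []
    shared = set(regions["chrom"]) & set(genes["chrom"])
    if not shared:
        raise ValueError(
            "regions and gene annotation share no chromosome names "
            f"(regions: {sorted(set(regions['chrom']))[:5]}, "
            f"genes: {sorted(set(genes['chrom']))[:5]}); "
            "check for a chr-prefix naming mismatch"
        )
    trees: dict[str, IntervalTree] = {}
    for g in genes.itertuples():
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
    hits: set[str] = set()
    for r in regions.itertuples():
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(r.start, r.end):
            hits.add(iv.data)
    ordered = genes[genes["gene_id"].isin(hits)]
    return ordered.sort_values(["chrom", "start", "gene_id"])["gene_id"].tolist()


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, order-stable)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    selected: Iterable[str],
    terms: pd.DataFrame,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in the selected set.

    Parameters
    ----------
    selected
        Candidate gene ids; must be a subset of ``universe``.
    terms
        Gene→term table (``TERM_COLUMNS``); genes outside the universe
        are ignored, terms with no universe gene are skipped.
    universe
        Background gene set (typically every annotated gene).
    alpha
        FDR significance threshold (``significant ⇔ fdr ≤ alpha``).
    """
    universe_set = set(universe)
    selected_set = set(selected)
    stray = selected_set - universe_set
    if stray:
        raise ValueError(f"selected genes outside the universe: {sorted(stray)[:5]}")
    N = len(universe_set)
    n = len(selected_set)
    if n == 0:
        log.warning("hypergeom_enrich: empty selected gene set; nothing to test")
        return pd.DataFrame(columns=ENRICH_COLUMNS)

    rows = []
    for (term_id, term_name, category), grp in terms.groupby(
        ["term_id", "term_name", "category"], sort=True
    ):
        term_genes = set(grp["gene_id"]) & universe_set
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & selected_set)
        # P(X >= k) with X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, term_name, category, k, K, n, N, min(p, 1.0)))
    res = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "category", "k", "K", "n", "N", "p_value"],
    )
    if len(res) == 0:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    res["fdr"] = bh_fdr(res["p_value"].to_numpy())
    res["significant"] = res["fdr"] <= alpha
    return res.sort_values(["p_value", "term_id"]).reset_index(drop=True)


def term_category_counts(
    terms: pd.DataFrame, selected: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Per-category, per-term gene counts (bar-chart style summary).

    When ``selected`` is given, only selected genes are counted.
    """
    df = terms
    if selected is not None:
        df = terms[terms["gene_id"].isin(set(selected))]
    out = (
        df.groupby(["category", "term_id", "term_name"])["gene_id"]
        .nunique()
        .reset_index(name="n_genes")
        .sort_values(["category", "n_genes"], ascending=[True, False])
        .reset_index(drop=True)
    )
    return out


def write_enrichment_tsv(res: pd.DataFrame, path: os.PathLike | str) -> None:
    res.to_csv(path, sep="\t", index=False, float_format="%.6g")
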