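"""Reading/writing VCF genotypes and sample maps; the cohort-wide variant filter.

The filter mirrors a single post-calling VCFtools pass: a site is kept only
if its minor allele frequency exceeds ``maf_min`` (default 0.05) and the
fraction of missing genotype calls across the whole cohort is below
``missing_max`` (default 0.25). Both inequalities are strict.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
from cyvcf2 import VCF

from .model import MISSING, FilterConfig, GenotypeMatrix, SampleMap

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


def read_vcf(path: os.PathLike | str, keep_samples: Optional[Iterable[str]] = None) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF 4.x file.

    Multi-allelic and non-SNP records are dropped (logged). Missing,
    half (e.g. ``0/.``) and non-diploid calls all become ``MISSING``.

    Parameters
    ----------
    path
        VCF file (plain or bgzipped).
    keep_samples
        Optional subset of sample ids to load; every id must be present
        in the VCF header.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path)
    if keep_samples is not None:
        keep = list(keep_samples)
        absent = sorted(set(keep) - set(vcf.samples))
        if absent:
            raise ValueError(f"samples not in VCF header: {absent}")
        vcf.set_samples(keep)
    samples = list(vcf.samples)

    chrom, pos, ref, alt, rows = [], [], [], [], []
    n_dropped = 0
    n_halfcalls = 0
    for v in vcf:
        if (
            len(v.ALT) != 1
            or len(v.REF) != 1
            or len(v.ALT[0]) != 1
            or v.REF not in _BASES
            or v.ALT[0] not in _BASES
        ):
            n_dropped += 1
            continue
        row = np.empty(len(samples), dtype=np.int8)
        for j, call in enumerate(v.genotypes):
            alleles = call[:-1]  # last element is the phased flag
            if len(alleles) != 2 or min(alleles) < 0:
                if len(alleles) != 2 or max(alleles) >= 0:
                    n_halfcalls += 1
                row[j] = MISSING
            else:
                row[j] = alleles[0] + alleles[1]
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(row)
    vcf.close()
    if n_dropped:
        log.info("read_vcf: dropped %d multi-allelic/non-SNP records", n_dropped)
    if n_halfcalls:
        log.warning(
            "read_vcf: %d half-call/non-diploid genotypes treated as missing",
            n_halfcalls,
        )
    if not rows:
        raise ValueError(f"no biallelic SNPs in {path}")
    return GenotypeMatrix(chrom, pos, ref, alt, samples, np.vstack(rows))


def write_vcf(
    g: GenotypeMatrix,
    path: os.PathLike | str,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write the matrix as a minimal plain-text VCF 4.2 (GT field only)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if chrom_lengths:
            for c in sorted(chrom_lengths):
                fh.write(f"##contig=<ID={c},length={chrom_lengths[c]}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for i in range(g.n_variants):
            calls = "\t".join(gt_str[int(d)] for d in g.gt[i])
            fh.write(
                f"{g.chrom[i]}\t{g.pos[i]}\t.\t{g.ref[i]}\t{g.alt[i]}\t.\t.\t.\tGT\t{calls}\n"
            )


def read_sample_map(path: os.PathLike | str) -> SampleMap:
    """Read a 2-column TSV ``sample_id<TAB>population_code``.

    ``#`` comment lines are skipped; a header line whose first field is
    ``sample``/``sample_id`` (case-insensitive) is ignored.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sid, code = fields[0].strip(), fields[1].strip()
            if not pairs and sid.lower() in {"sample", "sample_id", "id"}:
                continue
            pairs.append((sid, code))
    return SampleMap(pairs)


def write_sample_map(m: SampleMap, path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation_code\n")
        for s in m.samples:
            fh.write(f"{s}\t{m.population_of(s)}\n")


@dataclass(frozen=True)
class AlleleStats:
    """Per-variant allele summaries over a sample subset.

    ``n`` counts called alleles (2 × called diploids); ``maf`` is
    ``min(p, 1−p)`` with ``p = alt_count/n`` and is reported as 0 where
    no allele was called; ``missing_fraction`` is missing calls divided
    by the subset size.
    """

    n: np.ndarray
    alt_count: np.ndarray
    maf: np.ndarray
    missing_fraction: np.ndarray


def allele_stats(g: GenotypeMatrix, sample_subset: Optional[Iterable[str]] = None) -> AlleleStats:
    """Allele counts, MAF and missingness per variant over a sample subset."""
    if sample_subset is None:
        idx = np.arange(g.n_samples)
    else:
        idx = g.sample_indices(sample_subset)
    if len(idx) == 0:
        raise ValueError("empty sample subset")
    sub = g.gt[:, idx]
    called = sub != MISSING
    n_called = called.sum(axis=1)
    n = 2 * n_called
    alt = np.where(called, sub, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    maf[n == 0] = 0.0
    missing_fraction = 1.0 - n_called / len(idx)
    return AlleleStats(n=n, alt_count=alt, maf=maf, missing_fraction=missing_fraction)


def filter_variants(g: GenotypeMatrix, cfg: FilterConfig = FilterConfig()) -> GenotypeMatrix:
    """Apply the cohort-wide MAF/missingness filter (strict boundaries)."""
    st = allele_stats(g)
    keep = (st.maf > cfg.maf_min) & (st.missing_fraction < cfg.missing_max)
    n_keep = int(keep.sum())
    log.info(
        "filter_variants: retained %d / %d sites (maf > %g, missing < %g)",
        n_keep,
        g.n_variants,
        cfg.maf_min,
        cfg.missing_max,
    )
    return g.take_variants(np.flatnonzero(keep))


def pool_reference(m: SampleMap, target: str) -> tuple[list[str], list[str]]:
    """Split samples into the target population and the pool of all others."""
    if target not in m.populations():
        raise ValueError(
            f"unknown target population {target!r}; known: {m.populations()}"
        )
    others = [c for c in m.populations() if c != target]
    if not others:
        raise ValueError(f"{target!r} is the only population; no reference pool")
    tgt = m.members(target)
    ref = [s for s in m.samples if m.population_of(s) != target]
    return tgt, ref


def read_chrom_lengths(path: os.PathLike | str) -> dict[str, int]:
    """Read a 2-column TSV ``chrom<TAB>length_bp``."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            c, ln = line.split("\t")[:2]
            if c.lower() in {"chrom", "chromosome"}:
                continue
            out[c] = int(ln)
    if not out:
        raise ValueError(f"no chromosome lengths in {path}")
    return out


def write_chrom_lengths(lengths: Mapping[str, int], path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for c in sorted(lengths):
            fh.write(f"{c}\t{lengths[c]}\n")
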