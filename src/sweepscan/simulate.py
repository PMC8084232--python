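"""Balding–Nichols multi-population SNP simulator with embedded sweeps.

Each site draws an ancestral ALT frequency p from a rescaled Beta
distribution; every population then draws its own frequency from
``Beta(p(1−F)/F, (1−p)(1−F)/F)`` with F the background differentiation.
Inside a designated sweep interval the sweep's target population instead
uses the (higher) ``sweep_fst``, and its frequency is pushed toward the
nearer boundary so the expected heterozygosity equals
``pi_scale × (expected background heterozygosity)`` for the same
ancestral frequency — emulating the diversity depression a selective
sweep leaves in the selected population. Genotypes are drawn
Binomial(2, p_pop) per diploid individual under Hardy–Weinberg, with
i.i.d. missingness at ``missing_rate``.

Defaults emulate the study design this package targets: seven
populations of 7/7/7/5/7/7/7 diploids (47 samples), two 2-Mb
chromosomes, 5,000 SNPs, background F_ST 0.05, ten 200-kb sweeps with
F_ST uplift to 0.4 and π scaled ×0.1, 10% missing calls, and an
ancestral MAF spectrum spanning the 0.05 filter boundary.

No linkage is modelled: the scan aggregates sites within windows
additively, so site independence suffices for correctness testing.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotate, io, popgen
from .model import MISSING, GenotypeMatrix, SampleMap

DEFAULT_POPULATIONS: tuple[tuple[str, int], ...] = (
    ("NJ", 7),
    ("BJ", 7),
    ("DJ", 7),
    ("HX", 5),
    ("QH", 7),
    ("ALS", 7),
    ("SNT", 7),
)


@dataclass(frozen=True)
class SweepSpec:
    """One selective-sweep interval affecting one target population."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    target_population: str
    sweep_fst: float = 0.4
    pi_scale: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad sweep interval [{self.start}, {self.end})")
        if not (0 < self.pi_scale <= 1):
            raise ValueError("pi_scale must be in (0, 1]")


def default_sweeps(
    chroms: Sequence[str] = ("chr1", "chr2"),
    populations: Sequence[tuple[str, int]] = DEFAULT_POPULATIONS,
    sweep_fst: float = 0.4,
    pi_scale: float = 0.1,
) -> tuple[SweepSpec, ...]:
    """Ten 200-kb sweeps (five per chromosome) with targets assigned round-robin.

    A sweep spans 200 kb so that, at the default 50-kb/25-kb windowing,
    the windows fully inside it are numerous enough to fill the top-5%
    outlier slots of a 2×2-Mb scan on their own — candidate regions then
    track the swept interval itself rather than its half-overlapping
    edge windows.
    """
    starts = (150_000, 550_000, 950_000, 1_350_000, 1_750_000)
    codes = [c for c, _ in populations]
    specs = []
    i = 0
    for chrom in chroms:
        for s in starts:
            specs.append(
                SweepSpec(
                    chrom=chrom,
                    start=s,
                    end=s + 200_000,
                    target_population=codes[i % len(codes)],
                    sweep_fst=sweep_fst,
                    pi_scale=pi_scale,
                )
            )
            i += 1
    return tuple(specs)


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; ``default()`` gives the standard strong-sweep fixture."""

    seed: int = 1
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    n_snps: int = 5_000
    populations: tuple[tuple[str, int], ...] = DEFAULT_POPULATIONS
    background_fst: float = 0.05
    sweeps: tuple[SweepSpec, ...] = field(default_factory=default_sweeps)
    missing_rate: float = 0.10
    ancestral_beta: tuple[float, float] = (0.6, 0.6)
    ancestral_range: tuple[float, float] = (0.02, 0.98)
    # fixture annotation layout
    gene_spacing: int = 40_000
    gene_length: int = 20_000
    n_random_terms: int = 20
    random_term_size: int = 15

    def __post_init__(self) -> None:
        if not (0 < self.background_fst < 1):
            raise ValueError("background_fst must be in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if min(self.ancestral_beta) <= 0:
            raise ValueError("ancestral Beta parameters must be positive")
        for sw in self.sweeps:
            if sw.chrom not in self.chrom_names():
                raise ValueError(f"sweep chromosome {sw.chrom!r} not simulated")
            if sw.end > self.chrom_length:
                raise ValueError("sweep interval exceeds chromosome length")
            if sw.target_population not in {c for c, _ in self.populations}:
                raise ValueError(f"unknown sweep target {sw.target_population!r}")
            if sw.sweep_fst <= self.background_fst:
                raise ValueError("sweep_fst must exceed background_fst")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}

    def sample_map(self) -> SampleMap:
        pairs = []
        for code, n in self.populations:
            for i in range(n):
                pairs.append((f"{code}_{i + 1:02d}", code))
        return SampleMap(pairs)

    def neutralised(self) -> "SimConfig":
        """Same layout with every sweep switched off (null control).

        Sweep intervals are kept (so the planted term and truth table
        are still defined) but carry background differentiation and no
        diversity depression.
        """
        null_sweeps = tuple(
            replace(
                sw,
                sweep_fst=min(self.background_fst * 1.0000001, 0.999),
                pi_scale=1.0,
            )
            for sw in self.sweeps
        )
        return replace(self, sweeps=null_sweeps)


def _bn_beta_params(p: np.ndarray, fst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam = (1.0 - fst) / fst
    return p * lam, (1.0 - p) * lam


def _scale_heterozygosity(q: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """Move q toward the nearer boundary so q'(1−q') = scale·q(1−q)."""
    disc = np.sqrt(np.maximum(1.0 - 4.0 * scale * q * (1.0 - q), 0.0))
    low = (1.0 - disc) / 2.0
    return np.where(q <= 0.5, low, 1.0 - low)


@dataclass
class SimFrequencies:
    """Per-site per-population ALT frequencies with site coordinates."""

    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    ancestral: np.ndarray
    pop_codes: list[str]
    freqs: np.ndarray  # shape (n_pops, n_sites)


def simulate_frequencies(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimFrequencies:
    """Draw site positions, ancestral and population allele frequencies."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chroms = cfg.chrom_names()
    # deterministic proportional allocation of SNPs to chromosomes
    base = cfg.n_snps // len(chroms)
    counts = [base + (1 if i < cfg.n_snps % len(chroms) else 0) for i in range(len(chroms))]
    chrom_arr, pos_arr = [], []
    for c, k in zip(chroms, counts):
        pos = np.sort(rng.choice(cfg.chrom_length, size=k, replace=False)) + 1
        chrom_arr.append(np.full(k, c, dtype=object))
        pos_arr.append(pos.astype(np.int64))
    chrom_all = np.concatenate(chrom_arr)
    pos_all = np.concatenate(pos_arr)
    S = len(pos_all)

    a, b = cfg.ancestral_beta
    lo, hi = cfg.ancestral_range
    p_anc = lo + (hi - lo) * rng.beta(a, b, size=S)

    codes = [c for c, _ in cfg.populations]
    fst_matrix = np.full((len(codes), S), cfg.background_fst)
    scale_matrix = np.ones((len(codes), S))
    for sw in cfg.sweeps:
        in_sweep = (chrom_all == sw.chrom) & (pos_all - 1 >= sw.start) & (pos_all - 1 < sw.end)
        i = codes.index(sw.target_population)
        fst_matrix[i, in_sweep] = sw.sweep_fst
        if sw.pi_scale < 1.0:
            # calibrate so E[het'] = pi_scale × E[het | background F]
            eff = sw.pi_scale * (1.0 - cfg.background_fst) / (1.0 - sw.sweep_fst)
            scale_matrix[i, in_sweep] = min(eff, 1.0)

    alpha, beta = _bn_beta_params(p_anc[None, :], fst_matrix)
    freqs = rng.beta(alpha, beta)
    freqs = _scale_heterozygosity(freqs, scale_matrix)
    return SimFrequencies(
        chrom=chrom_all, pos=pos_all, ancestral=p_anc, pop_codes=codes, freqs=freqs
    )


def sample_genotypes(
    fr: SimFrequencies, cfg: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Hardy–Weinberg Binomial(2, p) genotypes with i.i.d. missingness."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    smap = cfg.sample_map()
    S = len(fr.pos)
    cols = []
    for code, n in cfg.populations:
        p = fr.freqs[fr.pop_codes.index(code)]
        cols.append(rng.binomial(2, p[:, None], size=(S, n)).astype(np.int8))
    gt = np.concatenate(cols, axis=1)
    if cfg.missing_rate > 0:
        mask = rng.random(gt.shape) < cfg.missing_rate
        gt[mask] = MISSING
    # random REF/ALT base pairs per site
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=S)
    alt_i = (ref_i + rng.integers(1, 4, size=S)) % 4
    return GenotypeMatrix(
        fr.chrom, fr.pos, bases[ref_i], bases[alt_i], smap.samples, gt
    )


def sweep_truth(cfg: SimConfig, g: GenotypeMatrix, smap: SampleMap) -> pd.DataFrame:
    """Ground-truth table with realized in-sweep F_ST and target π per sweep."""
    rows = []
    for sw in cfg.sweeps:
        in_sweep = (
            (g.chrom == sw.chrom)
            & (g.pos - 1 >= sw.start)
            & (g.pos - 1 < sw.end)
        )
        idx = np.flatnonzero(in_sweep)
        tgt, ref = io.pool_reference(smap, sw.target_population)
        realized_fst = np.nan
        realized_pi = np.nan
        if idx.size:
            it = g.sample_indices(tgt)
            ir = g.sample_indices(ref)
            comp = popgen.wc_fst_components(g.gt[idx][:, it], g.gt[idx][:, ir])
            realized_fst = popgen.window_fst(comp)
            st = io.allele_stats(g.take_variants(idx), tgt)
            realized_pi = float(np.mean(popgen.site_pi(st.alt_count, st.n)))
        rows.append(
            (
                sw.chrom,
                sw.start,
                sw.end,
                sw.target_population,
                sw.sweep_fst,
                sw.pi_scale,
                idx.size,
                realized_fst,
                realized_pi,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "target_population",
            "sweep_fst",
            "pi_scale",
            "n_sites",
            "realized_fst",
            "realized_mean_site_pi",
        ],
    )


@dataclass
class SimResult:
    config: SimConfig
    genotypes: GenotypeMatrix
    sample_map: SampleMap
    truth: pd.DataFrame


def simulate(cfg: SimConfig = SimConfig()) -> SimResult:
    """Run the full simulation deterministically from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    fr = simulate_frequencies(cfg, rng)
    g = sample_genotypes(fr, cfg, rng)
    smap = cfg.sample_map()
    truth = sweep_truth(cfg, g, smap)
    return SimResult(config=cfg, genotypes=g, sample_map=smap, truth=truth)


def tile_genes(cfg: SimConfig) -> pd.DataFrame:
    """Genes tiled every ``gene_spacing`` bp along each chromosome."""
    rows = []
    gid = 0
    for chrom in cfg.chrom_names():
        start = 10_000
        while start + cfg.gene_length <= cfg.chrom_length - 10_000:
            rows.append(
                (f"gene{gid:04d}", chrom, start, start + cfg.gene_length, "+", f"gene{gid:04d}")
            )
            gid += 1
            start += cfg.gene_spacing
    return pd.DataFrame(rows, columns=annotate.GENE_COLUMNS)


def build_term_map(cfg: SimConfig, genes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Planted sweep term plus random decoy terms over the tiled genes.

    The planted term ("T0000") contains exactly the genes whose bodies
    overlap a truth sweep interval; decoys are uniform random gene sets.
    """
    truth_regions = pd.DataFrame(
        [(sw.chrom, sw.start, sw.end) for sw in cfg.sweeps],
        columns=["chrom", "start", "end"],
    )
    planted = annotate.genes_in_regions(truth_regions, genes)
    categories = ["BP", "CC", "MF", "pathway"]
    rows = [("T0000", "planted_sweep_term", "pathway", gid) for gid in planted]
    all_genes = genes["gene_id"].tolist()
    for t in range(cfg.n_random_terms):
        size = min(cfg.random_term_size, len(all_genes))
        chosen = rng.choice(all_genes, size=size, replace=False)
        for gid in sorted(chosen):
            rows.append(
                (f"T{t + 1:04d}", f"random_term_{t + 1}", categories[t % 4], gid)
            )
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "category", "gene_id"])
    return df[annotate.TERM_COLUMNS]


def write_fixture(out_dir: os.PathLike | str, cfg: SimConfig = SimConfig()) -> dict[str, str]:
    """Simulate and write the full fixture bundle; byte-stable for a seed.

    Writes: genotypes.vcf, samples.tsv, chrom_lengths.tsv, genes.gff3,
    terms.tsv, truth.tsv. Returns a name→path mapping.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    res = simulate(cfg)
    genes = tile_genes(cfg)
    term_rng = np.random.default_rng(cfg.seed + 10_007)
    terms = build_term_map(cfg, genes, term_rng)

    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "chrom_lengths": os.path.join(out_dir, "chrom_lengths.tsv"),
        "gff": os.path.join(out_dir, "genes.gff3"),
        "terms": os.path.join(out_dir, "terms.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    io.write_vcf(res.genotypes, paths["vcf"], cfg.chrom_lengths())
    io.write_sample_map(res.sample_map, paths["samples"])
    io.write_chrom_lengths(cfg.chrom_lengths(), paths["chrom_lengths"])
    annotate.write_gff3(genes, paths["gff"])
    annotate.write_term_map(terms, paths["terms"])
    res.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    return paths


def checksum_files(paths: Mapping[str, str] | Sequence[str]) -> dict[str, str]:
    """SHA-256 of each file (determinism checks)."""
    if isinstance(paths, Mapping):
        items = sorted(paths.items())
    else:
        items = [(p, p) for p in paths]
    out = {}
    for name, p in items:
        with open(p, "rb") as fh:
            out[name] = hashlib.sha256(fh.read()).hexdigest()
    return out
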