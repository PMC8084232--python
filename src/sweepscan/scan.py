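"""Sliding-window selection scan: window construction, outlier flagging, merging.

Windows are 0-based half-open ``[start, end)`` intervals laid every
``step`` bp (defaults 50 kb span / 25 kb step), truncated at the
chromosome end. A window enters the outlier distributions only if it
holds at least ``min_sites_per_window`` SNPs and its F_ST is defined.
Candidates are windows in the top ``outlier_quantile`` tail of BOTH the
F_ST distribution and the −log10(π_target) low-diversity score; ties at
the cutoff are kept. Overlapping or book-ended candidate windows are
merged into maximal candidate regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import popgen
from .io import allele_stats
from .model import GenotypeMatrix

log = logging.getLogger(__name__)

WINDOW_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_sites",
    "pi_target",
    "pi_ref",
    "pi_ratio",
    "diversity_score",
    "fst",
]


@dataclass(frozen=True)
class ScanConfig:
    """Sliding-window scan settings."""

    window_span: int = 50_000
    step: int = 25_000
    outlier_quantile: float = 0.05
    min_sites_per_window: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window_span):
            raise ValueError("require 0 < step <= window_span")
        if not (0.0 < self.outlier_quantile < 1.0):
            raise ValueError("outlier_quantile must be in (0, 1)")
        if self.min_sites_per_window < 1:
            raise ValueError("min_sites_per_window must be >= 1")


def make_windows(chrom_lengths: Mapping[str, int], cfg: ScanConfig = ScanConfig()) -> pd.DataFrame:
    """Enumerate sliding windows over every chromosome.

    Starts run 0, step, 2·step, …; a window is emitted iff its start is
    inside the chromosome, and the terminal window is truncated at the
    chromosome end. Ordering is deterministic by (chrom, start).
    """
    rows = []
    for chrom in sorted(chrom_lengths):
        length = int(chrom_lengths[chrom])
        if length < 1:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        for start in range(0, length, cfg.step):
            rows.append((chrom, start, min(start + cfg.window_span, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def assign_sites(g: GenotypeMatrix, windows: pd.DataFrame) -> list[np.ndarray]:
    """Map each window to the variant-row indices it contains.

    A site at 1-based position p belongs to ``[start, end)`` iff its
    0-based position p−1 lies in the interval. With step = span/2 every
    interior site lands in exactly two windows.
    """
    known = set(windows["chrom"])
    missing = set(g.chrom) - known
    if missing:
        raise ValueError(f"chromosomes absent from window set: {sorted(missing)}")
    out: list[np.ndarray] = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        in_chrom = np.flatnonzero(g.chrom == chrom)
        pos = g.pos[in_chrom]  # sorted, 1-based
        for start, end in zip(grp["start"], grp["end"]):
            lo = np.searchsorted(pos, start + 1, side="left")
            hi = np.searchsorted(pos, end, side="right")
            out.append(in_chrom[lo:hi])
    # groupby(sort=False) preserves the windows' own (chrom, start) order
    return out


def quantile_threshold(values, q: float) -> float:
    """Empirical (1−q) quantile (linear interpolation); outliers are ≥ it."""
    values = np.asarray(values, dtype=np.float64)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values for quantile threshold")
    return float(np.quantile(values, 1.0 - q))


def compute_window_stats(
    g: GenotypeMatrix,
    target_samples: Sequence[str],
    reference_samples: Sequence[str],
    chrom_lengths: Mapping[str, int],
    cfg: ScanConfig = ScanConfig(),
) -> pd.DataFrame:
    """Per-window π (target and reference), diversity score and W&C F_ST.

    Returns one row per sliding window with the columns of
    ``WINDOW_COLUMNS``. Window F_ST is NaN where undefined.
    """
    windows = make_windows(chrom_lengths, cfg)
    idx_t = g.sample_indices(target_samples)
    idx_r = g.sample_indices(reference_samples)
    if np.intersect1d(idx_t, idx_r).size:
        raise ValueError("target and reference sample sets overlap")

    st_t = allele_stats(g, target_samples)
    st_r = allele_stats(g, reference_samples)
    pi_t_site = popgen.site_pi(st_t.alt_count, st_t.n)
    pi_r_site = popgen.site_pi(st_r.alt_count, st_r.n)
    comp = popgen.wc_fst_components(g.gt[:, idx_t], g.gt[:, idx_r])

    member = assign_sites(g, windows)
    n_sites = np.array([len(m) for m in member])
    span = (windows["end"] - windows["start"]).to_numpy()
    pi_t = np.array(
        [popgen.window_pi(pi_t_site[m], s) for m, s in zip(member, span)]
    )
    pi_r = np.array(
        [popgen.window_pi(pi_r_site[m], s) for m, s in zip(member, span)]
    )
    fst = np.array([popgen.window_fst(comp, m) for m in member])
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_ratio = np.where(pi_t > 0, pi_r / np.where(pi_t > 0, pi_t, 1.0), np.nan)

    out = windows.copy()
    out["n_sites"] = n_sites
    out["pi_target"] = pi_t
    out["pi_ref"] = pi_r
    out["pi_ratio"] = pi_ratio
    out["diversity_score"] = popgen.diversity_score(pi_t)
    out["fst"] = fst
    return out


def flag_candidates(windows: pd.DataFrame, cfg: ScanConfig = ScanConfig()) -> pd.DataFrame:
    """Flag top-tail F_ST and low-diversity outliers and their intersection.

    Windows with fewer than ``min_sites_per_window`` SNPs (or undefined
    F_ST) are excluded from both empirical distributions and can never
    be flagged; this keeps empty windows from flooding the low-π tail.
    """
    out = windows.copy()
    usable = (out["n_sites"] >= cfg.min_sites_per_window) & np.isfinite(out["fst"])
    q = cfg.outlier_quantile
    fst_outlier = np.zeros(len(out), dtype=bool)
    pi_outlier = np.zeros(len(out), dtype=bool)
    if usable.any():
        fst_cut = quantile_threshold(out.loc[usable, "fst"], q)
        score_cut = quantile_threshold(out.loc[usable, "diversity_score"], q)
        fst_outlier = usable.to_numpy() & (out["fst"].to_numpy() >= fst_cut)
        pi_outlier = usable.to_numpy() & (
            out["diversity_score"].to_numpy() >= score_cut
        )
    out["fst_outlier"] = fst_outlier
    out["pi_outlier"] = pi_outlier
    out["candidate"] = fst_outlier & pi_outlier
    log.info(
        "flag_candidates: %d usable windows, %d fst outliers, %d pi outliers, %d candidates",
        int(usable.sum()),
        int(fst_outlier.sum()),
        int(pi_outlier.sum()),
        int(out["candidate"].sum()),
    )
    return out


REGION_COLUMNS = ["chrom", "start", "end", "n_windows", "max_fst", "min_pi_target"]


def merge_regions(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/book-ended candidate windows into maximal regions."""
    cand = windows[windows["candidate"]].sort_values(["chrom", "start"])
    rows = []
    cur = None
    for w in cand.itertuples():
        if cur is not None and w.chrom == cur["chrom"] and w.start <= cur["end"]:
            cur["end"] = max(cur["end"], w.end)
            cur["n_windows"] += 1
            cur["max_fst"] = max(cur["max_fst"], w.fst)
            cur["min_pi_target"] = min(cur["min_pi_target"], w.pi_target)
        else:
            if cur is not None:
                rows.append(cur)
            cur = {
                "chrom": w.chrom,
                "start": int(w.start),
                "end": int(w.end),
                "n_windows": 1,
                "max_fst": w.fst,
                "min_pi_target": w.pi_target,
            }
    if cur is not None:
        rows.append(cur)
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def scan(
    g: GenotypeMatrix,
    target_samples: Sequence[str],
    reference_samples: Sequence[str],
    chrom_lengths: Mapping[str, int],
    cfg: ScanConfig = ScanConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full scan for one contrast: window table with flags + merged regions."""
    windows = compute_window_stats(
        g, target_samples, reference_samples, chrom_lengths, cfg
    )
    windows = flag_candidates(windows, cfg)
    regions = merge_regions(windows)
    return windows, regions


def write_window_tsv(windows: pd.DataFrame, path) -> None:
    """Window table as TSV (1-based inclusive start shown alongside BED-style)."""
    out = windows.copy()
    out.insert(2, "start_1based", out["start"] + 1)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Candidate regions as 3+ column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions.itertuples()):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tregion{i}\t{r.max_fst:.6g}\n")


def write_regions_tsv(regions: pd.DataFrame, path) -> None:
    regions.to_csv(path, sep="\t", index=False, float_format="%.10g")
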