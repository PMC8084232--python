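"""Core data model: genotype matrix, sample→population map, filter settings.

Genotypes are stored as diploid ALT-allele dosages (0, 1, 2) in a dense
``int8`` matrix of shape ``(n_variants, n_samples)``; missing calls are
``MISSING`` (−1). Variant coordinates are kept 1-based (VCF convention)
inside the matrix; window arithmetic downstream converts to 0-based
half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Sentinel dosage for a missing (or half/non-diploid) genotype call.
MISSING: int = -1

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class FilterConfig:
    """Cohort-wide variant filter thresholds.

    Both boundaries are strict, i.e. a site is retained only if
    ``maf > maf_min`` and ``missing_fraction < missing_max``.
    """

    maf_min: float = 0.05
    missing_max: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError(f"maf_min must be in [0, 0.5), got {self.maf_min}")
        if not (0.0 < self.missing_max <= 1.0):
            raise ValueError(
                f"missing_max must be in (0, 1], got {self.missing_max}"
            )


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP: chromosome, 1-based position, REF and ALT bases."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in _VALID_BASES or self.alt not in _VALID_BASES:
            raise ValueError(f"alleles must be single ACGT bases: {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")


class SampleMap:
    """Sample → population assignment with basic validation.

    Each population must contain at least two samples (π needs ≥2
    chromosomes and window F_ST is unstable below two diploids).
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        pairs = list(pairs)
        ids = [s for s, _ in pairs]
        if len(ids) != len(set(ids)):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        for s, code in pairs:
            if not s or not code:
                raise ValueError(f"empty sample id or population code: {(s, code)!r}")
        self._population_of: dict[str, str] = dict(pairs)
        self.samples: list[str] = ids
        # ordered unique population codes
        codes: list[str] = []
        for _, c in pairs:
            if c not in codes:
                codes.append(c)
        self._codes = codes
        for c in codes:
            if len(self.members(c)) < 2:
                raise ValueError(f"population {c!r} has fewer than 2 samples")

    def populations(self) -> list[str]:
        """Population codes in first-appearance order."""
        return list(self._codes)

    def members(self, code: str) -> list[str]:
        if code not in self._codes:
            raise KeyError(f"unknown population {code!r}; known: {self._codes}")
        return [s for s in self.samples if self._population_of[s] == code]

    def population_of(self, sample_id: str) -> str:
        return self._population_of[sample_id]

    def __len__(self) -> int:
        return len(self.samples)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SampleMap({len(self)} samples, {len(self._codes)} populations)"


class GenotypeMatrix:
    """Dense biallelic SNP × sample dosage matrix, sorted by (chrom, pos).

    Parameters
    ----------
    chrom, pos, ref, alt
        Per-variant arrays (1-based positions).
    samples
        Ordered sample identifiers (columns).
    gt
        ``int8`` array of shape (n_variants, n_samples); entries in
        {0, 1, 2, MISSING}.
    """

    def __init__(
        self,
        chrom: Sequence[str] | np.ndarray,
        pos: Sequence[int] | np.ndarray,
        ref: Sequence[str] | np.ndarray,
        alt: Sequence[str] | np.ndarray,
        samples: Sequence[str],
        gt: np.ndarray,
    ):
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        ref = np.asarray(ref, dtype=object)
        alt = np.asarray(alt, dtype=object)
        gt = np.asarray(gt, dtype=np.int8)
        n = len(chrom)
        if not (len(pos) == len(ref) == len(alt) == n and gt.shape == (n, len(samples))):
            raise ValueError("inconsistent dimensions for genotype matrix")
        bad = ~np.isin(gt, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid dosage values: {np.unique(gt[bad])}")
        order = np.lexsort((pos, chrom))
        self.chrom = chrom[order]
        self.pos = pos[order]
        self.ref = ref[order]
        self.alt = alt[order]
        self.samples = list(samples)
        self.gt = gt[order]
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("duplicate sample ids in genotype matrix")

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Column indices of the given samples, in matrix column order."""
        wanted = set(sample_ids)
        missing = wanted - set(self.samples)
        if missing:
            raise ValueError(f"samples not in matrix: {sorted(missing)}")
        return np.array(
            [i for i, s in enumerate(self.samples) if s in wanted], dtype=np.intp
        )

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given variant rows (order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            self.chrom[index],
            self.pos[index],
            self.ref[index],
            self.alt[index],
            self.samples,
            self.gt[index],
        )

    def variants(self) -> list[Variant]:
        return [
            Variant(c, int(p), r, a)
            for c, p, r, a in zip(self.chrom, self.pos, self.ref, self.alt)
        ]

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.gt, other.gt)
        )

    def chrom_sizes(self) -> Mapping[str, int]:
        """Highest observed position per chromosome (a lower bound on length)."""
        out: dict[str, int] = {}
        for c, p in zip(self.chrom, self.pos):
            out[c] = max(out.get(c, 0), int(p))
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_variants} variants × {self.n_samples} samples)"
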