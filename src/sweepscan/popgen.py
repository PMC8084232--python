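"""Per-site and per-window Nei's π and Weir–Cockerham F_ST.

π per site is the unbiased pairwise-difference estimator
``2k(n−k)/(n(n−1))`` for ``k`` ALT alleles among ``n`` called alleles;
windowed π divides the sum of site values by the full window span in bp
(positions without an observed variant contribute 0), which is the
convention of VCFtools ``--window-pi``.

F_ST uses the Weir & Cockerham (1984) variance components ``a`` (among
populations), ``b`` (among individuals within populations) and ``c``
(within individuals), combined per window as the ratio of averages
``Σa / Σ(a+b+c)``. Negative window estimates are retained as computed;
a window whose denominator is zero has an undefined (NaN) F_ST.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MISSING

__all__ = [
    "site_pi",
    "window_pi",
    "wc_fst_components",
    "window_fst",
    "hudson_fst",
    "diversity_score",
    "SiteFstComponents",
]


def site_pi(alt_count, n):
    """Unbiased per-site nucleotide diversity.

    Parameters
    ----------
    alt_count, n
        Scalars or arrays: ALT allele count and total called alleles.

    Returns
    -------
    ``2·k·(n−k) / (n·(n−1))`` where ``n ≥ 2``, else 0.
    """
    k = np.asarray(alt_count, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("alt_count must satisfy 0 <= alt_count <= n")
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(n >= 2, 2.0 * k * (n - k) / np.maximum(n * (n - 1.0), 1.0), 0.0)
    if pi.ndim == 0:
        return float(pi)
    return pi


def window_pi(site_pis, window_span: int) -> float:
    """Per-bp π for a window: sum of site values over the full span."""
    if window_span <= 0:
        raise ValueError(f"window_span must be positive, got {window_span}")
    return float(np.sum(site_pis)) / float(window_span)


@dataclass(frozen=True)
class SiteFstComponents:
    """Weir–Cockerham variance components per site (arrays over sites).

    ``valid`` marks sites where both sample sets had at least one called
    genotype and the components are defined; invalid sites carry NaN and
    are excluded from window ratios.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    valid: np.ndarray


def _pop_summaries(gt: np.ndarray):
    """Called-diploid count, ALT frequency and observed het per site."""
    called = gt != MISSING
    n = called.sum(axis=1).astype(np.float64)
    alt = np.where(called, gt, 0).sum(axis=1).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
        h = np.where(n > 0, (gt == 1).sum(axis=1) / np.maximum(n, 1), np.nan)
    return n, p, h


def wc_fst_components(alt_dosages_target, alt_dosages_reference) -> SiteFstComponents:
    """Two-population Weir & Cockerham (1984) a, b, c per site.

    Parameters
    ----------
    alt_dosages_target, alt_dosages_reference
        Arrays of shape (n_sites, n_individuals) of diploid ALT dosages
        with ``MISSING`` for uncalled genotypes (1-D input is treated as
        a single site).
    """
    g1 = np.atleast_2d(np.asarray(alt_dosages_target))
    g2 = np.atleast_2d(np.asarray(alt_dosages_reference))
    if g1.shape[0] != g2.shape[0]:
        raise ValueError("target and reference must cover the same sites")
    n1, p1, h1 = _pop_summaries(g1)
    n2, p2, h2 = _pop_summaries(g2)

    r = 2.0
    nsum = n1 + n2
    nbar = nsum / r
    valid = (n1 >= 1) & (n2 >= 1) & (nbar > 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (nsum - (n1**2 + n2**2) / nsum) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / nsum
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / nsum

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    valid = valid & (nc > 0)
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return SiteFstComponents(a=a, b=b, c=c, valid=valid)


def window_fst(components: SiteFstComponents, site_index=None) -> float:
    """Ratio-of-averages F_ST over the (optionally indexed) sites.

    Returns NaN when no usable site exists or the pooled denominator is
    zero; negative estimates are returned as computed.
    """
    a, b, c, valid = components.a, components.b, components.c, components.valid
    if site_index is not None:
        a, b, c, valid = a[site_index], b[site_index], c[site_index], valid[site_index]
    if not np.any(valid):
        return float("nan")
    num = np.nansum(a[valid])
    den = np.nansum((a + b + c)[valid])
    if den == 0:
        return float("nan")
    return float(num / den)


def hudson_fst(alt_dosages_target, alt_dosages_reference, site_index=None) -> float:
    """Hudson's F_ST estimator (ratio of averages), for sensitivity checks.

    Per site the numerator is ``(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)``
    and the denominator ``p1(1−p2) + p2(1−p1)``, with n counted in alleles.
    """
    g1 = np.atleast_2d(np.asarray(alt_dosages_target))
    g2 = np.atleast_2d(np.asarray(alt_dosages_reference))

    def freqs(gt):
        called = gt != MISSING
        n = 2.0 * called.sum(axis=1)
        alt = np.where(called, gt, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        return n, p

    n1, p1 = freqs(g1)
    n2, p2 = freqs(g2)
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1)
            - p2 * (1 - p2) / (n2 - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    if site_index is not None:
        num, den, valid = num[site_index], den[site_index], valid[site_index]
    if not np.any(valid):
        return float("nan")
    d = np.nansum(den[valid])
    if d == 0:
        return float("nan")
    return float(np.nansum(num[valid]) / d)


def diversity_score(pi_target, epsilon: float = 1e-8):
    """−log10(π + ε): high score ⇔ low diversity.

    ``epsilon`` (default 1e-8) keeps zero-π windows finite while sitting
    far below any attainable per-bp π at realistic sample sizes, so the
    ordering among nonzero-π windows is untouched.
    """
    pi = np.asarray(pi_target, dtype=np.float64)
    if np.any(pi < 0):
        raise ValueError("pi_target must be non-negative")
    out = -np.log10(pi + epsilon)
    if out.ndim == 0:
        return float(out)
    return out
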