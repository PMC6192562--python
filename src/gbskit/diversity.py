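"""Per-site and genome-wide diversity statistics for biallelic genotype matrices.

Per site: allele frequencies over called alleles, expected heterozygosity
He = 2pq, observed heterozygosity Ho (fraction of called genotypes that are
heterozygous), and Botstein's polymorphism information content

    PIC = 1 - p^2 - q^2 - 2 p^2 q^2,

which peaks at 0.375 for a biallelic marker (at p = q = 0.5, where He peaks
at 0.5).

Genome-wide: Tajima's D, the normalized difference between pairwise
nucleotide diversity (pi) and Watterson's estimator (S / a1), and the
folded site frequency spectrum with a rare/common partition at a minor
allele count threshold.  Both are computed on the complete-data site set —
sites with any missing call are dropped so the number of sampled
chromosomes n is constant and the variance normalization of D stays exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gbskit.variant_filter import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def site_stats(matrix: GenotypeMatrix) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-locus He, Ho and PIC, plus unweighted means over loci.

    Frequencies use called alleles only.  A locus with zero called
    genotypes gets NaN statistics and is excluded from the means (with a
    logged warning).

    Returns
    -------
    (per-site DataFrame with columns ``chromosome, pos, p, He, Ho, PIC,
    mac, n_called``, dict of means keyed ``He, Ho, PIC``).  ``p`` is the
    alternate-allele frequency; ``mac`` the minor allele count.
    """
    called = matrix.called_mask()
    n_called_geno = called.sum(axis=0)
    n_chrom = 2.0 * n_called_geno
    alt_count = np.where(called, matrix.doses, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chrom > 0, alt_count / n_chrom, np.nan)
        q = 1.0 - p
        he = 2.0 * p * q
        het = ((matrix.doses == 1) & called).sum(axis=0)
        ho = np.where(n_called_geno > 0, het / n_called_geno, np.nan)
        pic = 1.0 - p**2 - q**2 - 2.0 * p**2 * q**2
        mac = np.minimum(alt_count, n_chrom - alt_count)
    n_empty = int((n_called_geno == 0).sum())
    if n_empty:
        logger.warning("%d loci with zero called genotypes excluded from means", n_empty)
    per_site = pd.DataFrame(
        {
            "chromosome": matrix.loci["chromosome"].to_numpy(),
            "pos": matrix.loci["pos"].to_numpy(),
            "p": p,
            "He": he,
            "Ho": ho,
            "PIC": pic,
            "mac": mac,
            "n_called": n_chrom.astype(np.int64),
        }
    )
    means = {
        "He": float(np.nanmean(he)) if np.isfinite(he).any() else float("nan"),
        "Ho": float(np.nanmean(ho)) if np.isfinite(ho).any() else float("nan"),
        "PIC": float(np.nanmean(pic)) if np.isfinite(pic).any() else float("nan"),
    }
    return per_site, means


@dataclass
class TajimaComponents:
    """Tajima's D with all its intermediate quantities.

    ``n`` is the number of sampled chromosomes, ``S`` the segregating-site
    count, ``pi`` the mean number of pairwise differences.  The a/b/c/e
    constants follow the standard neutral-theory normalization; ``D`` is
    ``None`` with ``note`` set when undefined (S < 2).
    """

    n: int
    S: int
    pi: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float | None
    theta_w: float | None = None
    note: str = ""


def _tajima_constants(n: int) -> tuple[float, ...]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, a2, b1, b2, c1, c2, e1, e2


def tajimas_d(matrix: GenotypeMatrix) -> TajimaComponents:
    """Genome-wide Tajima's D on the complete-data site set.

    Sites with any missing genotype are excluded so that n = 2 x samples is
    constant.  pi is computed from allele counts with the unbiased
    n/(n-1) correction, summed over segregating sites:

        pi = sum_j 2 p_j q_j n / (n - 1)

    which equals the mean pairwise difference across all chromosome pairs.
    With S < 2 segregating sites D is undefined and returned as ``None``.
    """
    n = 2 * matrix.n_samples
    if n < 4:
        raise ValueError("Tajima's D requires at least 2 diploid samples")
    complete = ~np.any(matrix.doses == MISSING, axis=0)
    doses = matrix.doses[:, complete]
    alt = doses.sum(axis=0).astype(np.int64)
    seg = (alt > 0) & (alt < n)
    S = int(seg.sum())
    a1, a2, b1, b2, c1, c2, e1, e2 = _tajima_constants(n)
    p = alt[seg] / n
    pi = float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1))
    if S < 2:
        logger.warning("Tajima's D undefined: %d segregating complete-data sites", S)
        return TajimaComponents(n, S, pi, a1, a2, b1, b2, c1, c2, e1, e2,
                                D=None, theta_w=S / a1, note="S < 2: D undefined")
    theta_w = S / a1
    var = e1 * S + e2 * S * (S - 1)
    D = (pi - theta_w) / np.sqrt(var)
    return TajimaComponents(n, S, pi, a1, a2, b1, b2, c1, c2, e1, e2,
                            D=float(D), theta_w=theta_w)


def tajimas_d_windowed(matrix: GenotypeMatrix, window_bp: int = 10_000) -> pd.DataFrame:
    """Tajima's D in fixed-width windows along each chromosome.

    Off the default pipeline path (the headline statistic is genome-wide);
    provided for scans.  Windows with fewer than two segregating
    complete-data sites get a missing D.

    Returns a DataFrame with columns ``chromosome, window_start, S, D``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    chroms = matrix.loci["chromosome"].to_numpy()
    pos = matrix.loci["pos"].to_numpy()
    rows = []
    for chrom in pd.unique(chroms):
        on_chrom = np.flatnonzero(chroms == chrom)
        starts = (pos[on_chrom] - 1) // window_bp * window_bp
        for w in np.unique(starts):
            idx = on_chrom[starts == w]
            sub = matrix.subset_loci(idx)
            comp = tajimas_d(sub)
            rows.append((chrom, int(w), comp.S, comp.D))
    return pd.DataFrame(rows, columns=["chromosome", "window_start", "S", "D"])


@dataclass
class FoldedSFS:
    """Folded site frequency spectrum over complete-data segregating sites.

    ``counts[c]`` is the number of sites with minor allele count ``c`` for
    c in 1..floor(n/2); ``proportion_rare`` is the fraction of sites at or
    below ``rare_threshold``.
    """

    counts: dict[int, int]
    n_chromosomes: int
    rare_threshold: int
    proportion_rare: float
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"minor_allele_count": list(self.counts), "n_sites": list(self.counts.values())}
        )


def folded_sfs(matrix: GenotypeMatrix, rare_threshold: int = 3) -> FoldedSFS:
    """Folded SFS and the rare-allele proportion.

    Only biallelic sites with no missing call enter the spectrum; the
    folded bin of a site is ``min(alt count, n - alt count)``; monomorphic
    sites (bin 0) are excluded.  "Rare" means a minor allele seen on at
    most ``rare_threshold`` chromosomes (default 3).
    """
    n = 2 * matrix.n_samples
    complete = ~np.any(matrix.doses == MISSING, axis=0)
    if not complete.any():
        logger.warning("no complete-data sites: empty folded SFS")
        return FoldedSFS({}, n, rare_threshold, float("nan"), 0)
    alt = matrix.doses[:, complete].sum(axis=0).astype(np.int64)
    mac = np.minimum(alt, n - alt)
    mac = mac[mac > 0]
    bins = np.arange(1, n // 2 + 1)
    counts = {int(b): int(np.sum(mac == b)) for b in bins}
    total = int(mac.size)
    rare = sum(v for c, v in counts.items() if c <= rare_threshold)
    prop = rare / total if total else float("nan")
    return FoldedSFS(counts, n, rare_threshold, prop, total)
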