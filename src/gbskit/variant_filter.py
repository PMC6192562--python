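"""The SNP filter cascade and substitution-class summary.

Two filtering stages are applied in sequence, mirroring common GBS
practice:

1. *Hard site filters* on variant-call annotations — quality by depth
   (QD), Fisher strand bias (FS) and root-mean-square mapping quality (MQ).
2. *Population filters* — restriction to biallelic SNPs, a per-site
   missingness ceiling, and a minor-allele-frequency (MAF) floor.

Retained biallelic SNPs are classified into the six unordered substitution
classes; transitions are A<->G and C<->T, transversions the other four.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel dose for a missing genotype

_BASES = frozenset("ACGT")

#: canonical order of the six unordered substitution classes
SUBSTITUTION_CLASSES = ("A/G", "C/T", "A/C", "A/T", "C/G", "G/T")
_TRANSITIONS = frozenset({"A/G", "C/T"})

_CLASS_OF_PAIR = {frozenset(cls.split("/")): cls for cls in SUBSTITUTION_CLASSES}


@dataclass
class VariantRecord:
    """One VCF site: alleles, call annotations and per-sample allele doses.

    ``genotypes`` holds the alternate-allele dose per sample (0, 1, 2) with
    :data:`MISSING` for uncalled genotypes.  ``qd``, ``fs`` and ``mq`` may be
    ``None`` when the annotation is absent from the INFO field.
    """

    chromosome: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: tuple[str, ...]
    qd: float | None = None
    fs: float | None = None
    mq: float | None = None
    genotypes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    record_id: str = "."
    info_raw: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF positions are 1-based; got {self.pos}")
        if not self.ref or not all(self.alt):
            raise ValueError("ref/alt alleles must be non-empty")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def is_snp(self) -> bool:
        """Biallelic single-nucleotide substitution."""
        return (
            len(self.alt) == 1
            and len(self.ref) == 1
            and len(self.alt[0]) == 1
            and self.ref in _BASES
            and self.alt[0] in _BASES
        )

    def missing_fraction(self) -> float:
        if self.genotypes.size == 0:
            return 0.0
        return float(np.mean(self.genotypes == MISSING))

    def minor_allele_frequency(self) -> float:
        """MAF over called alleles only (missing excluded from the denominator)."""
        called = self.genotypes[self.genotypes != MISSING]
        if called.size == 0:
            return 0.0
        # integer minor count first, so boundary frequencies are exact
        alt = int(called.sum())
        total = 2 * called.size
        return min(alt, total - alt) / total


@dataclass
class GenotypeMatrix:
    """Samples x biallelic loci with allele doses in {0, 1, 2, missing}.

    ``doses`` has shape (n_samples, n_loci), dtype int8, with
    :data:`MISSING` (-1) marking uncalled genotypes.  ``loci`` carries one
    row per locus with columns ``chromosome, pos, ref, alt``.
    """

    samples: list[str]
    loci: pd.DataFrame
    doses: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=np.int8)
        if self.doses.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dose matrix shape {self.doses.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def called_mask(self) -> np.ndarray:
        return self.doses != MISSING

    def alt_allele_frequency(self) -> np.ndarray:
        """Per-locus alternate-allele frequency over called alleles (NaN if none)."""
        called = self.called_mask()
        n_called = called.sum(axis=0)
        alt = np.where(called, self.doses, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def subset_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=self.loci.iloc[index].reset_index(drop=True),
            doses=self.doses[:, index],
        )

    def subset_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = list(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            loci=self.loci.copy(),
            doses=self.doses[idx, :],
        )


def apply_hard_filters(
    records: Iterable[VariantRecord],
    qd_min: float = 2.0,
    fs_max: float = 60.0,
    mq_min: float = 40.0,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Site-level hard filters on QD, FS and MQ annotations.

    A record is retained when ``QD > qd_min`` and ``FS < fs_max`` and
    ``MQ >= mq_min``.  QD and FS comparisons are strict; MQ is a floor
    (the conventional direction for a minimum mapping-quality threshold).
    A record missing an annotation fails that filter (conservative).
    Removals are attributed to the first failing criterion, in the order
    QD, FS, MQ.

    Returns
    -------
    (passing records, removal counts per criterion).
    """
    passing: list[VariantRecord] = []
    removed = {"QD": 0, "FS": 0, "MQ": 0}
    for rec in records:
        if rec.qd is None or not rec.qd > qd_min:
            removed["QD"] += 1
        elif rec.fs is None or not rec.fs < fs_max:
            removed["FS"] += 1
        elif rec.mq is None or not rec.mq >= mq_min:
            removed["MQ"] += 1
        else:
            passing.append(rec)
    return passing, removed


def filter_population(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    maf_min: float = 0.05,
    max_missing: float = 0.20,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Population filters: biallelic SNPs, missingness ceiling, MAF floor.

    Applied in order:

    1. biallelic-SNP restriction — a single ALT allele, both alleles single
       A/C/G/T bases (drops indels and multi-allelic sites);
    2. per-site missingness ``<= max_missing`` (strictly *more* than the
       ceiling is removed, so exactly 20% missing is retained);
    3. ``MAF > maf_min`` computed over called alleles only, so a MAF of
       exactly ``maf_min`` is removed.

    Returns
    -------
    (GenotypeMatrix of retained loci, counts surviving each step under keys
    ``input, biallelic_snp, missingness, maf``).  Zero survivors yield an
    empty matrix with a logged warning, not an error.
    """
    counts = {"input": len(records)}
    stage = [r for r in records if r.is_snp]
    counts["biallelic_snp"] = len(stage)
    stage = [r for r in stage if r.missing_fraction() <= max_missing]
    counts["missingness"] = len(stage)
    stage = [r for r in stage if r.minor_allele_frequency() > maf_min]
    counts["maf"] = len(stage)
    if not stage:
        logger.warning("no sites survived the population filters")
        loci = pd.DataFrame(columns=["chromosome", "pos", "ref", "alt"])
        return GenotypeMatrix(list(samples), loci, np.empty((len(samples), 0), np.int8)), counts
    loci = pd.DataFrame(
        {
            "chromosome": [r.chromosome for r in stage],
            "pos": [r.pos for r in stage],
            "ref": [r.ref for r in stage],
            "alt": [r.alt[0] for r in stage],
        }
    )
    doses = np.stack([r.genotypes for r in stage], axis=1).astype(np.int8)
    return GenotypeMatrix(list(samples), loci, doses), counts


@dataclass
class SubstitutionSummary:
    """Counts and fractions of the six substitution classes.

    Transitions (Ti) are A<->G and C<->T; transversions (Tv) the other four
    unordered pairs.  ``ti_tv_ratio`` is derived from the counts.
    """

    counts: dict[str, int]

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(SUBSTITUTION_CLASSES)
        if unknown:
            raise ValueError(f"unknown substitution classes: {sorted(unknown)}")
        self.counts = {cls: int(self.counts.get(cls, 0)) for cls in SUBSTITUTION_CLASSES}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def ti_count(self) -> int:
        return sum(v for k, v in self.counts.items() if k in _TRANSITIONS)

    @property
    def tv_count(self) -> int:
        return self.total - self.ti_count

    @property
    def ti_fraction(self) -> float:
        return self.ti_count / self.total if self.total else float("nan")

    @property
    def tv_fraction(self) -> float:
        return self.tv_count / self.total if self.total else float("nan")

    @property
    def ti_tv_ratio(self) -> float:
        return self.ti_count / self.tv_count if self.tv_count else float("inf")

    def to_frame(self) -> pd.DataFrame:
        rows = [(cls, n, n / self.total if self.total else float("nan"))
                for cls, n in self.counts.items()]
        rows.append(("Ti", self.ti_count, self.ti_fraction))
        rows.append(("Tv", self.tv_count, self.tv_fraction))
        return pd.DataFrame(rows, columns=["class", "count", "fraction"])


def substitution_class(ref: str, alt: str) -> str:
    """Map an unordered ref/alt base pair to one of the six classes."""
    pair = frozenset((ref.upper(), alt.upper()))
    if pair not in _CLASS_OF_PAIR:
        raise ValueError(f"not a substitution pair: {ref}/{alt}")
    return _CLASS_OF_PAIR[pair]


def classify_substitutions(matrix: GenotypeMatrix) -> SubstitutionSummary:
    """Tally retained SNPs into the six substitution classes.

    Raises if a non-SNP locus reaches this step (the cascade was violated).
    """
    counts = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    for ref, alt in zip(matrix.loci["ref"], matrix.loci["alt"]):
        counts[substitution_class(ref, alt)] += 1
    return SubstitutionSummary(counts)


def summary_from_counts(counts: Mapping[str, int]) -> SubstitutionSummary:
    """Build a substitution summary directly from per-class counts."""
    return SubstitutionSummary(dict(counts))
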