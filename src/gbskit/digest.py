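"""In-silico digestion with a degenerate-motif, dual-cut (Type IIB) restriction enzyme.

A Type IIB enzyme such as *BsaXI* recognizes a short, partially degenerate
motif and cleaves on *both* sides of it, excising a fragment that contains
the recognition site.  For reduced-representation library design the
quantities of interest are the genome-wide cut-site map, the fragment-length
distribution, and the fraction of the genome captured by a size-selection
window.

Coordinates are 0-based, half-open (BED convention) throughout; cleavage
points are inter-base positions, so a cleavage coordinate ``c`` separates
bases ``c-1`` and ``c``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes mapped to the set of concrete bases they denote.
IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT: Mapping[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


def reverse_complement_iupac(motif: str) -> str:
    """Reverse complement of an IUPAC motif (degenerate codes preserved)."""
    try:
        return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(motif.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in motif: {exc.args[0]!r}") from None


@dataclass(frozen=True)
class EnzymeSpec:
    """Recognition motif and dual-side cut geometry of a restriction enzyme.

    Parameters
    ----------
    name:
        Enzyme name, e.g. ``"BsaXI"``.
    recognition:
        IUPAC motif, possibly degenerate (``"ACNNNNNCTCC"``).
    cut_upstream:
        Signed offset in bp from the motif *start* to the 5'-side cleavage
        point.  Negative values cut upstream of the motif.
    cut_downstream:
        Signed offset in bp from the motif *end* to the 3'-side cleavage
        point.  Positive values cut downstream of the motif.
    both_strands:
        Scan the reverse complement of the motif as well.

    Notes
    -----
    Top/bottom-strand stagger (sticky ends) is deliberately ignored: one
    cleavage point per side suffices for fragment-length accounting.
    """

    name: str
    recognition: str
    cut_upstream: int
    cut_downstream: int
    both_strands: bool = True

    def __post_init__(self) -> None:
        motif = self.recognition.upper()
        for ch in motif:
            if ch not in IUPAC_CODES:
                raise ValueError(f"invalid IUPAC code in motif: {ch!r}")
        object.__setattr__(self, "recognition", motif)

    @property
    def motif_length(self) -> int:
        return len(self.recognition)

    def is_palindromic(self) -> bool:
        """True when the motif equals its own reverse complement, position-set-wise."""
        rc = reverse_complement_iupac(self.recognition)
        return all(
            set(IUPAC_CODES[a]) == set(IUPAC_CODES[b])
            for a, b in zip(self.recognition, rc)
        )


#: *BsaXI*: a Type IIB enzyme that cleaves 14 bp on either side of its
#: AC(N5)CTCC recognition site.  The flank distance is configurable; 14 bp
#: per side is the shipped default.
BSAXI = EnzymeSpec(
    name="BsaXI",
    recognition="ACNNNNNCTCC",
    cut_upstream=-14,
    cut_downstream=14,
    both_strands=True,
)


class MotifMatch(NamedTuple):
    """A recognition-motif occurrence at forward-strand coordinates."""

    chromosome: str
    start: int
    strand: str


@dataclass(frozen=True)
class CutSite:
    """A cleavage point between bases ``cleavage_pos - 1`` and ``cleavage_pos``."""

    chromosome: str
    cleavage_pos: int
    source_motif_start: int
    strand: str


@dataclass(frozen=True)
class Fragment:
    """Half-open genomic interval produced by digestion (or read mapping).

    ``terminal`` marks chromosome-end fragments, which have only one
    enzymatic end and would not amplify in a GBS assay.
    """

    chromosome: str
    start: int
    end: int
    terminal: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment start must precede end: [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive fragment-length selection bounds in bp."""

    min_bp: int
    max_bp: int

    def __post_init__(self) -> None:
        if not (0 < self.min_bp <= self.max_bp):
            raise ValueError(f"require 0 < min_bp <= max_bp, got {self}")


def _iupac_pattern(motif: str) -> re.Pattern[str]:
    parts = []
    for ch in motif:
        bases = IUPAC_CODES[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def find_recognition_sites(
    sequences: Mapping[str, str], enzyme: EnzymeSpec
) -> list[MotifMatch]:
    """Scan sequences for all occurrences of the enzyme's recognition motif.

    Forward-strand occurrences are reported with strand ``"+"``.  When
    ``enzyme.both_strands`` is set and the motif is not its own reverse
    complement, reverse-complement occurrences are reported with strand
    ``"-"`` at forward-strand coordinates (a palindromic motif would match
    every window twice; those are collapsed to a single ``"+"`` record).
    Windows containing ``N`` (or any non-ACGT symbol) never match.

    Parameters
    ----------
    sequences:
        Mapping of chromosome name to nucleotide string.
    enzyme:
        The enzyme whose motif is scanned.

    Returns
    -------
    list of :class:`MotifMatch`, sorted by (chromosome, start).
    """
    fwd = _iupac_pattern(enzyme.recognition)
    scan_minus = enzyme.both_strands and not enzyme.is_palindromic()
    rev = _iupac_pattern(reverse_complement_iupac(enzyme.recognition)) if scan_minus else None

    matches: list[MotifMatch] = []
    for chrom in sequences:
        seq = sequences[chrom].upper()
        for m in fwd.finditer(seq):
            matches.append(MotifMatch(chrom, m.start(), "+"))
        if rev is not None:
            for m in rev.finditer(seq):
                matches.append(MotifMatch(chrom, m.start(), "-"))
    matches.sort(key=lambda x: (x.chromosome, x.start, x.strand))
    return matches


def cut_positions(
    matches: Iterable[MotifMatch],
    enzyme: EnzymeSpec,
    chromosome_lengths: Mapping[str, int],
) -> dict[str, np.ndarray]:
    """Cleavage coordinates implied by motif matches, per chromosome.

    A ``"+"``-strand match at start ``s`` with motif length ``m`` cleaves at
    ``s + cut_upstream`` and ``s + m + cut_downstream``.  A ``"-"``-strand
    match applies the mirrored geometry: ``s + m - cut_upstream`` and
    ``s - cut_downstream``.  Out-of-range coordinates are clipped to
    ``[0, L]`` (a warning totals the clipped count); duplicates collapse.

    Returns
    -------
    dict mapping chromosome name to a sorted, unique int array of cleavage
    coordinates.  Chromosomes present in ``chromosome_lengths`` but without
    matches map to an empty array.
    """
    m = enzyme.motif_length
    cu, cd = enzyme.cut_upstream, enzyme.cut_downstream
    raw: dict[str, list[int]] = {chrom: [] for chrom in chromosome_lengths}
    n_clipped = 0
    for match in matches:
        L = chromosome_lengths[match.chromosome]
        if match.strand == "+":
            points = (match.start + cu, match.start + m + cd)
        else:
            points = (match.start + m - cu, match.start - cd)
        for p in points:
            clipped = min(max(p, 0), L)
            if clipped != p:
                n_clipped += 1
            raw[match.chromosome].append(clipped)
    if n_clipped:
        logger.warning("clipped %d out-of-range cleavage coordinates", n_clipped)
    return {
        chrom: np.unique(np.asarray(points, dtype=np.int64))
        for chrom, points in raw.items()
    }


def digest_fragments(
    cuts: Sequence[int] | np.ndarray, chromosome_length: int, chromosome: str = "chr"
) -> list[Fragment]:
    """Fragments between consecutive cleavage points on one chromosome.

    The fragment boundaries are ``{0} ∪ cuts ∪ {L}``; fragments tile
    ``[0, L)`` exactly.  A fragment whose outer boundary is the chromosome
    end itself (no enzymatic cut at 0 or L) is flagged ``terminal``.
    """
    cuts = np.asarray(cuts, dtype=np.int64)
    if cuts.size and (cuts.min() < 0 or cuts.max() > chromosome_length):
        raise ValueError("cleavage coordinates outside [0, L]")
    cutset = set(int(c) for c in cuts)
    bounds = np.unique(np.concatenate([[0], cuts, [chromosome_length]]))
    fragments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        terminal = (a == 0 and 0 not in cutset) or (
            b == chromosome_length and chromosome_length not in cutset
        )
        fragments.append(Fragment(chromosome, int(a), int(b), terminal=terminal))
    return fragments


@dataclass
class SizeSelection:
    """Result of size-selecting a fragment population."""

    selected: list[Fragment]
    count: int
    total_bp: int
    genome_fraction: float | None = None
    window: SizeWindow | None = None


def size_select(
    fragments: Iterable[Fragment],
    window: SizeWindow,
    total_genome_bp: int | None = None,
    include_terminal: bool = False,
) -> SizeSelection:
    """Keep fragments with ``min_bp <= length <= max_bp``.

    Chromosome-end fragments are excluded by default: they have only one
    enzymatic end and would not amplify in the assay.  ``include_terminal``
    restores EMBOSS-like inclusion.  When ``total_genome_bp`` is given, the
    genome fraction captured by the window is reported.
    """
    selected = [
        f
        for f in fragments
        if (include_terminal or not f.terminal)
        and window.min_bp <= f.length <= window.max_bp
    ]
    total_bp = sum(f.length for f in selected)
    fraction = total_bp / total_genome_bp if total_genome_bp else None
    return SizeSelection(selected, len(selected), total_bp, fraction, window)


def fragment_histogram(
    fragments: Iterable[Fragment],
    bin_width: int,
    window: SizeWindow | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of fragment lengths in left-closed, right-open bins.

    Bins start at ``window.min_bp`` (or at the smallest length, floored to a
    bin boundary, when no window is given) and extend far enough to cover
    every input length; counts therefore sum to the number of fragments.

    Returns
    -------
    (edges, counts): ``edges`` has one more element than ``counts``; bin *i*
    covers ``[edges[i], edges[i+1])``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lengths = np.asarray([f.length for f in fragments], dtype=np.int64)
    if window is not None:
        start = window.min_bp
        stop = max(window.max_bp + 1, start + bin_width)
    elif lengths.size:
        start = (int(lengths.min()) // bin_width) * bin_width
        stop = int(lengths.max()) + 1
    else:
        start, stop = 0, bin_width
    n_bins = -(-(stop - start) // bin_width)
    edges = start + bin_width * np.arange(n_bins + 1, dtype=np.int64)
    counts = np.zeros(n_bins, dtype=np.int64)
    if lengths.size:
        idx = (lengths - start) // bin_width
        valid = (idx >= 0) & (idx < n_bins)
        np.add.at(counts, idx[valid], 1)
    return edges, counts


def digest_genome(
    sequences: Mapping[str, str], enzyme: EnzymeSpec
) -> tuple[list[Fragment], dict[str, np.ndarray]]:
    """Convenience: motif scan, cut mapping and fragmentation in one call."""
    lengths = {chrom: len(seq) for chrom, seq in sequences.items()}
    matches = find_recognition_sites(sequences, enzyme)
    cuts = cut_positions(matches, enzyme, lengths)
    fragments: list[Fragment] = []
    for chrom in sequences:
        fragments.extend(digest_fragments(cuts[chrom], lengths[chrom], chrom))
    return fragments, cuts
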