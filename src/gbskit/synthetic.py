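"""Synthetic-data generators with known ground truth for every pipeline stage.

Four generators emulate the inputs of a GBS study:

* :func:`simulate_genome` — toy chromosomes with recognition motifs planted
  at known positions and a background guaranteed free of incidental motif
  matches, so the ground-truth cut-site list is exhaustive;
* :func:`simulate_reference_panel` — K differentiated populations under the
  Balding–Nichols model: population frequencies are Beta-distributed around
  an ancestral frequency with variance governed by Fst, genotypes are
  binomial draws;
* :func:`simulate_admixed` — test individuals whose genotypes are binomial
  draws from ancestry-weighted mixtures of the panel frequencies, with
  independent per-call missingness;
* :func:`simulate_variant_file` — VCF-shaped records with per-site truth
  labels naming the single filter (if any) that should remove each site.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gbskit.digest import IUPAC_CODES, EnzymeSpec, MotifMatch, find_recognition_sites
from gbskit.variant_filter import MISSING, GenotypeMatrix, VariantRecord
from gbskit.ancestry import ReferencePanel

_BASES = np.array(list("ACGT"))


@dataclass
class SimGenomeConfig:
    """Toy-genome parameters: per-chromosome length, GC content, planted motif sites."""

    length: int = 100_000
    n_chromosomes: int = 1
    gc_content: float = 0.4
    planted_sites: list[tuple[int, int, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        per_chrom: dict[int, int] = {}
        for chrom_idx, pos, strand in self.planted_sites:
            if strand not in "+-":
                raise ValueError(f"strand must be '+' or '-', got {strand!r}")
            if not 0 <= chrom_idx < self.n_chromosomes:
                raise ValueError(f"planted site on unknown chromosome index {chrom_idx}")
            if chrom_idx in per_chrom and pos <= per_chrom[chrom_idx]:
                raise ValueError("planted positions must be strictly increasing per chromosome")
            per_chrom[chrom_idx] = pos


@dataclass
class SimPanelConfig:
    """Balding–Nichols reference-panel parameters."""

    K: int = 3
    n_loci: int = 1000
    n_per_pop: int = 20
    fst: float = 0.15
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("need at least K=2 populations")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie strictly in (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("ancestral frequencies must be bounded away from 0 and 1")


@dataclass
class SimAdmixedConfig:
    """Admixed-individual parameters: true ancestry matrix and missingness."""

    true_Q: np.ndarray = field(default_factory=lambda: np.array([[1.0]]))
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_Q = np.asarray(self.true_Q, dtype=np.float64)
        if self.true_Q.ndim != 2:
            raise ValueError("true_Q must be a samples x K matrix")
        if (self.true_Q < 0).any() or np.any(np.abs(self.true_Q.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each row of true_Q must be non-negative and sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def _resolve_motif(motif: str, rng: np.random.Generator) -> str:
    """Instantiate each IUPAC degeneracy uniformly at random."""
    return "".join(
        IUPAC_CODES[c][rng.integers(len(IUPAC_CODES[c]))] for c in motif
    )


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def simulate_genome(
    config: SimGenomeConfig, enzyme: EnzymeSpec
) -> tuple[dict[str, str], list[MotifMatch]]:
    """Toy genome with planted recognition sites and a motif-free background.

    Background bases are i.i.d. with the requested GC content.  At every
    planted (chromosome, position, strand) one concrete instance of the
    motif is placed (reverse-complemented for ``-`` sites).  The background
    is rejection-resampled until the only motif matches in the genome are
    the planted ones, so the returned ground truth is exhaustive.

    Returns
    -------
    ({chromosome name: sequence}, planted matches sorted by position).
    """
    rng = np.random.default_rng(config.seed)
    m = enzyme.motif_length
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    planted: dict[int, list[tuple[int, str]]] = {i: [] for i in range(config.n_chromosomes)}
    for chrom_idx, pos, strand in config.planted_sites:
        if pos < 0 or pos + m > config.length:
            raise ValueError(
                f"planted site (chrom {chrom_idx}, pos {pos}, {strand}) leaves no room "
                f"for the {m} bp motif in a {config.length} bp chromosome"
            )
        if planted[chrom_idx] and pos < planted[chrom_idx][-1][0] + m:
            raise ValueError(
                f"planted site at pos {pos} overlaps the previous motif footprint"
            )
        planted[chrom_idx].append((pos, strand))

    sequences: dict[str, np.ndarray] = {}
    protected: dict[str, np.ndarray] = {}
    truth: list[MotifMatch] = []
    for idx, name in enumerate(names):
        arr = _BASES[rng.choice(4, size=config.length, p=probs)]
        prot = np.zeros(config.length, dtype=bool)
        for pos, strand in planted[idx]:
            instance = _resolve_motif(enzyme.recognition, rng)
            if strand == "-":
                instance = instance.translate(_COMPLEMENT)[::-1]
            arr[pos : pos + m] = list(instance)
            prot[pos : pos + m] = True
            truth.append(MotifMatch(name, pos, strand))
        sequences[name] = arr
        protected[name] = prot

    expected = {(t.chromosome, t.start, t.strand) for t in truth}
    for _ in range(200):
        found = find_recognition_sites(
            {n: "".join(a) for n, a in sequences.items()}, enzyme
        )
        extras = [f for f in found if (f.chromosome, f.start, f.strand) not in expected]
        if not extras:
            break
        for f in extras:
            win = np.arange(f.start, f.start + m)
            redraw = win[~protected[f.chromosome][win]]
            if redraw.size == 0:
                raise RuntimeError(
                    "planted motifs themselves produce an unplanted match; "
                    "cannot construct a motif-free background"
                )
            sequences[f.chromosome][redraw] = _BASES[
                rng.choice(4, size=redraw.size, p=probs)
            ]
    else:
        raise RuntimeError("failed to build a motif-free background in 200 rounds")
    truth.sort(key=lambda t: (t.chromosome, t.start))
    return {n: "".join(a) for n, a in sequences.items()}, truth


def _locus_table(rng: np.random.Generator, n_loci: int) -> pd.DataFrame:
    ref_idx = rng.integers(0, 4, size=n_loci)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_loci)) % 4
    return pd.DataFrame(
        {
            "chromosome": ["1"] * n_loci,
            "pos": np.arange(1, n_loci + 1) * 10,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )


@dataclass
class SimulatedPanel:
    """A simulated structured panel plus its generating truth."""

    panel: ReferencePanel
    genotypes: GenotypeMatrix
    labels: dict[str, str]
    true_frequencies: np.ndarray  # (K, n_loci), pre-clamping
    ancestral_frequencies: np.ndarray  # (n_loci,)


def simulate_reference_panel(config: SimPanelConfig) -> SimulatedPanel:
    """Structured reference panel under the Balding–Nichols model.

    Per locus j the ancestral frequency p_j is uniform on
    ``ancestral_freq_range``; each population's frequency is

        f_kj ~ Beta(p_j (1 - F) / F, (1 - p_j)(1 - F) / F)

    so E[f] = p_j and Var[f] = F p_j (1 - p_j).  Genotypes are
    ``Binomial(2, f_kj)`` per diploid individual.  The returned
    :class:`~gbskit.ancestry.ReferencePanel` holds the *true* generating
    frequencies; estimate them from the genotypes with
    :func:`~gbskit.ancestry.panel_frequencies` to exercise the estimator.
    """
    rng = np.random.default_rng(config.seed)
    K, J, n = config.K, config.n_loci, config.n_per_pop
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=J)
    scale = (1.0 - config.fst) / config.fst
    f = rng.beta(p_anc * scale, (1.0 - p_anc) * scale, size=(K, J))
    doses = rng.binomial(2, f[:, None, :], size=(K, n, J)).astype(np.int8)
    pops = [f"POP{k + 1}" for k in range(K)]
    samples = [f"{pop}_{i + 1}" for pop in pops for i in range(n)]
    labels = {s: s.rsplit("_", 1)[0] for s in samples}
    loci = _locus_table(rng, J)
    genotypes = GenotypeMatrix(samples, loci, doses.reshape(K * n, J))
    panel = ReferencePanel(pops, f.copy(), loci.copy())
    return SimulatedPanel(panel, genotypes, labels, f, p_anc)


def dirichlet_q(n_samples: int, alpha: float | np.ndarray, K: int, seed: int = 0) -> np.ndarray:
    """Ancestry matrix with rows drawn from Dirichlet(alpha) on the K-simplex.

    A scalar ``alpha`` is symmetric: small values give near-pure
    individuals, large values give even mixtures.
    """
    rng = np.random.default_rng(seed)
    alpha_vec = np.broadcast_to(np.asarray(alpha, dtype=float), (K,))
    return rng.dirichlet(alpha_vec, size=n_samples)


@dataclass
class SimulatedAdmixed:
    """Simulated admixed samples plus their ground-truth ancestry."""

    genotypes: GenotypeMatrix
    true_Q: pd.DataFrame  # samples x populations


def simulate_admixed(panel: ReferencePanel, config: SimAdmixedConfig) -> SimulatedAdmixed:
    """Admixed individuals drawn from ancestry-weighted panel frequencies.

    Sample i's dose at locus j is ``Binomial(2, sum_k q_ik f_kj)``; calls
    are then masked to missing independently at ``missing_rate``.
    """
    if config.true_Q.shape[1] != panel.K:
        raise ValueError(
            f"true_Q has {config.true_Q.shape[1]} columns but the panel has K={panel.K}"
        )
    rng = np.random.default_rng(config.seed)
    mix = config.true_Q @ panel.frequencies  # (n_samples, n_loci)
    doses = rng.binomial(2, mix).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(doses.shape) < config.missing_rate
        doses[mask] = MISSING
    samples = [f"ADM_{i + 1}" for i in range(config.true_Q.shape[0])]
    genotypes = GenotypeMatrix(samples, panel.loci.copy(), doses)
    true_q = pd.DataFrame(config.true_Q, index=samples, columns=panel.populations)
    return SimulatedAdmixed(genotypes, true_q)


def _doses_with_counts(
    rng: np.random.Generator, n_samples: int, n_alt: int, n_missing: int
) -> np.ndarray:
    """Dose vector with exactly n_alt alt alleles among called samples."""
    n_called = n_samples - n_missing
    alleles = np.zeros(2 * n_called, dtype=np.int8)
    alleles[:n_alt] = 1
    rng.shuffle(alleles)
    doses = alleles.reshape(n_called, 2).sum(axis=1).astype(np.int8)
    out = np.full(n_samples, MISSING, dtype=np.int8)
    called_idx = rng.choice(n_samples, size=n_called, replace=False)
    out[np.sort(called_idx)] = doses
    return out


def simulate_variant_file(
    n_sites: int,
    n_samples: int = 30,
    frac_indel: float = 0.0,
    frac_multiallelic: float = 0.0,
    frac_low_maf: float = 0.0,
    frac_high_missing: float = 0.0,
    frac_hard_fail: float = 0.0,
    seed: int = 0,
) -> tuple[list[VariantRecord], list[str], list[str]]:
    """VCF-shaped records with per-site truth labels for the filter cascade.

    Each record carries QD, FS and MQ annotations and is constructed so
    that exactly one filter (or none) removes it.  Truth labels are one of
    ``clean, hard_filter, indel, multiallelic, low_maf, high_missing``.

    Sites labeled ``low_maf`` have a minor allele count of at most
    ``floor(0.05 * 2 * n_samples)`` with no missing calls; ``clean`` sites
    exceed that count; ``high_missing`` sites have strictly more than 20%
    missing genotypes but a passing MAF among called alleles.

    Returns
    -------
    (records, labels, sample names); records are ordered by position with
    labels aligned.
    """
    fracs = (frac_indel, frac_multiallelic, frac_low_maf, frac_high_missing, frac_hard_fail)
    if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
        raise ValueError("defect fractions must be non-negative and sum to at most 1")
    rng = np.random.default_rng(seed)
    n_alleles = 2 * n_samples
    mac_cut = int(np.floor(0.05 * n_alleles))  # MAF <= 0.05  <=>  mac <= mac_cut
    if frac_low_maf > 0 and mac_cut < 1:
        raise ValueError(
            f"with {n_samples} samples even a singleton exceeds MAF 0.05; "
            "low-MAF sites need at least 10 diploid samples"
        )
    miss_cut = int(np.floor(0.20 * n_samples))

    n_defect = [int(round(f * n_sites)) for f in fracs]
    while sum(n_defect) > n_sites:
        n_defect[int(np.argmax(n_defect))] -= 1
    kinds = ["indel", "multiallelic", "low_maf", "high_missing", "hard_filter"]
    labels = [k for k, c in zip(kinds, n_defect) for _ in range(c)]
    labels += ["clean"] * (n_sites - len(labels))
    labels = [labels[i] for i in rng.permutation(n_sites)]

    def clean_doses() -> np.ndarray:
        n_alt = int(rng.integers(mac_cut + 1, n_alleles - mac_cut))
        return _doses_with_counts(rng, n_samples, n_alt, 0)

    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    records: list[VariantRecord] = []
    for i, label in enumerate(labels):
        ref = str(_BASES[rng.integers(4)])
        others = [b for b in "ACGT" if b != ref]
        alt: tuple[str, ...] = (others[rng.integers(3)],)
        qd = float(rng.uniform(5.0, 30.0))
        fs = float(rng.uniform(0.0, 20.0))
        mq = float(rng.uniform(45.0, 60.0))
        if label == "clean":
            doses = clean_doses()
        elif label == "hard_filter":
            doses = clean_doses()
            which = rng.integers(3)
            if which == 0:
                qd = float(rng.uniform(0.0, 2.0))
            elif which == 1:
                fs = float(rng.uniform(60.0, 150.0))
            else:
                mq = float(rng.uniform(10.0, 39.0))
        elif label == "indel":
            doses = clean_doses()
            if rng.random() < 0.5:
                alt = (ref + str(_BASES[rng.integers(4)]),)  # insertion
            else:
                ref, alt = ref + str(_BASES[rng.integers(4)]), (ref,)  # deletion
        elif label == "multiallelic":
            doses = clean_doses()
            alt = (others[0], others[1])
        elif label == "low_maf":
            mac = int(rng.integers(1, mac_cut + 1))
            n_alt = mac if rng.random() < 0.5 else n_alleles - mac
            doses = _doses_with_counts(rng, n_samples, n_alt, 0)
        elif label == "high_missing":
            n_missing = int(rng.integers(miss_cut + 1, max(miss_cut + 2, n_samples // 2)))
            called_alleles = 2 * (n_samples - n_missing)
            low = int(np.floor(0.05 * called_alleles)) + 1
            n_alt = int(rng.integers(low, called_alleles - low + 1))
            doses = _doses_with_counts(rng, n_samples, n_alt, n_missing)
        else:  # pragma: no cover
            raise AssertionError(label)
        records.append(
            VariantRecord(
                chromosome="1",
                pos=100 * (i + 1),
                ref=ref,
                alt=alt,
                qd=qd,
                fs=fs,
                mq=mq,
                genotypes=doses,
            )
        )
    return records, labels, samples
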