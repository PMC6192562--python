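# Methods

This note records the models, conventions and design choices behind
`gbskit`, in the order the pipeline runs them.

## Coordinates and formats

All genomic intervals are 0-based, half-open (BED convention). VCF
positions are 1-based on input and output, converted at the format
boundary. Cleavage points are inter-base coordinates: a cut at `c`
separates bases `c−1` and `c`, so fragments between consecutive cuts tile
the chromosome exactly. Genotypes are stored as alternate-allele doses in
{0, 1, 2} with −1 for missing; phased separators and half-calls are
normalized on read (any missing allele makes the whole genotype missing).

## In-silico digestion

**Motif matching.** The recognition sequence is an IUPAC string; each code
denotes a set of concrete bases and matching is per-position set
membership. The scanner compiles the motif to a regular expression inside
a lookahead so overlapping occurrences are all reported, and scans the
reverse-complement motif separately, reporting minus-strand hits at
forward coordinates. A motif that equals its own reverse complement would
report every window twice; those are collapsed to a single `+` record.
Windows containing `N` (or any non-ACGT symbol) never match: reference
gaps must not create phantom fragments.

**Cut geometry.** A Type IIB enzyme cleaves on both sides of its site. The
enzyme spec makes both offsets explicit: a `+` match at start `s` with
motif length `m` cleaves at `s + cut_upstream` and `s + m + cut_downstream`;
a `−` match mirrors this to `s + m − cut_upstream` and `s − cut_downstream`
(derived by mapping the match to the reverse-complement genome and back).
The shipped *BsaXI* default places both cuts 14 bp outside the motif
boundaries; users can substitute exact REBASE geometry without code
changes. Top/bottom-strand stagger is ignored — fragment-length accounting
does not depend on overhangs. Out-of-range cuts are clipped to `[0, L]`
with a counted warning; duplicate cleavage coordinates (e.g. from nested
matches) collapse at the coordinate level.

**Fragments and size selection.** Fragment boundaries are
`{0} ∪ cuts ∪ {L}`. Chromosome-end fragments have only one enzymatic end
and would not amplify in the assay, so they are flagged `terminal` and
excluded from size-selection totals by default (a flag restores
EMBOSS-like inclusion). The selection window is inclusive on both bounds
(default 200–700 bp); the genome fraction is selected bp over total
genome bp. Histogram bins are left-closed, right-open, starting at the
window minimum, and always conserve the selected count.

## On-target intersection

Observed fragment spans (a BED of merged read-pair spans; BAM-to-span
conversion is upstream of this package) are intersected with the predicted
digest. Overlap of `[a,b)` and `[c,d)` is `max(0, min(b,d) − max(a,c))`;
an observed interval is a hit when it shares at least `min_overlap_bp`
(default 1, the common intersection default — configurable because
published analyses rarely state their threshold) with any predicted
interval on its chromosome. The implementation sweeps start-sorted
predicted intervals with a running maximum of interval ends, and is tested
for equality against an all-pairs brute force. Chromosome names absent
from the predicted set count as misses with a logged warning.

## SNP filter cascade

Stage 1, hard site filters on call annotations: retain QD > 2 (strict),
FS < 60 (strict), MQ ≥ 40. The MQ threshold is read as a floor, the
conventional direction for a minimum mapping quality; all three thresholds
are configurable. A record missing an annotation fails that filter —
conservative, since an unannotated site cannot demonstrate quality.
Removals are attributed to the first failing criterion in the order QD,
FS, MQ, so removal counts plus survivors always partition the input.

Stage 2, population filters, in order: biallelic-SNP restriction (one ALT,
both alleles single bases), per-site missingness ≤ 20% (strictly more is
removed, exactly 20% is retained), then MAF > 0.05. MAF uses called
alleles only (missing genotypes leave the denominator), and is computed
from integer minor-allele counts before dividing so boundary cases
(e.g. 3 of 60 alleles = 0.05 exactly) compare exactly. Because every
filter is a per-site predicate, the cascade equals a single conjunction;
the staged order only attributes removals.

Ti/Tv: the six unordered substitution classes with transitions A↔G and
C↔T. The ratio is always derived from the class counts actually tallied,
never quoted.

## Diversity statistics

Per site, with `p` the alternate-allele frequency over called alleles:
He = 2pq, Ho = heterozygotes / called genotypes, and Botstein's
PIC = 1 − p² − q² − 2p²q² (maximum 0.375 at p = 0.5, against He's maximum
of 0.5). Summary values are unweighted means over loci with at least one
called genotype.

Tajima's D is computed genome-wide on the complete-data site set: sites
with any missing call are dropped so the chromosome count n = 2 × samples
is constant and the variance normalization stays exact (per-site n would
make e₁, e₂ site-dependent). π is computed from allele counts with the
unbiased correction, π = Σⱼ 2pⱼqⱼ · n/(n−1), which equals the mean
pairwise difference over all chromosome pairs — the test suite verifies
this against explicit pair enumeration to 1e-10 and against neutral
coalescent simulations (msprime) where the mean D over 200 replicates must
sit near 0. With fewer than two segregating sites D is undefined and
reported as missing, not zero.

The folded SFS also uses complete-data sites only: the bin of a site is
min(alt count, n − alt count), monomorphic sites are excluded, and the
rare-allele proportion counts bins at or below the rare threshold
(default minor allele count 3; configurable).

All four statistics are invariant under swapping ref/alt labels at any
subset of loci; this is property-tested.

## Supervised ancestry estimation

**Model.** Each test individual's genotypes are independent binomial draws
from a mixture of K reference populations with fixed allele frequencies
fₖⱼ; the ancestry vector q lives on the K-simplex and maximizes

    L(q) = Σⱼ [ gⱼ ln(Σₖ qₖ fₖⱼ) + (2 − gⱼ) ln(Σₖ qₖ (1 − fₖⱼ)) ]

over non-missing loci. Holding the panel fixed is what "supervised" means
here; it also makes every sample's estimate independent and trivially
parallelizable.

**Optimization.** Plain EM from the uniform start:
qₖ ← qₖ/(2J′) Σⱼ [gⱼfₖⱼ/Σₘqₘfₘⱼ + (2−gⱼ)(1−fₖⱼ)/Σₘqₘ(1−fₘⱼ)], stopping at
max |Δq| < 1e-7 or 2000 iterations. EM was chosen over quasi-Newton
acceleration deliberately: convergence is slower but monotone, and the
implementation raises if the log-likelihood ever decreases, turning the
EM guarantee into a runtime check. Panel frequencies are clamped to
[1e-6, 1 − 1e-6] so fixed alleles cannot produce infinite log-likelihoods.

**Panel construction and harmonization.** fₖⱼ is the within-population
alternate-allele count over called chromosomes; a locus where any
population has no called genotype is dropped panel-wide. Test and
reference loci are matched on (chromosome, position); identical ref/alt
pairs pass through, swapped pairs flip the test doses (g → 2 − g), any
other mismatch is dropped and counted. No strand flipping is attempted:
A/T and C/G sites are ambiguous under strand flips and cannot be resolved
from alleles alone.

**Bootstrap.** Precision is per individual, so resampling is over *loci*
(with replacement, keeping J′ fixed), not over samples. Bias is the mean
replicate estimate minus the point estimate; SE the replicate standard
deviation. The default is B = 2000 pseudo-replicates; B is configurable
(the pipeline demo uses a small B for speed). Fixed seeds reproduce
bias/SE exactly.

**PCA.** Patterson normalization: per locus, center by the mean dose and
scale by √(p̂(1−p̂)) with p̂ = mean dose / 2; missing doses are mean-imputed
(zero after centering); zero-variance loci are dropped. The
eigendecomposition is of the sample covariance averaged over loci, and
variance fractions are eigenvalues over the trace. Reference and test
samples enter one joint decomposition by default, matching how such panels
are usually plotted together.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions used throughout the tests.

* **Genomes** — i.i.d. background at a requested GC content with motif
  instances planted at known positions (degeneracies resolved uniformly at
  random; minus-strand sites placed as reverse complements). The
  background is rejection-resampled until no unplanted motif match exists
  anywhere, so the ground-truth cut list is exhaustive — simpler and
  stricter than tolerating incidental matches. Real genomes have
  repeats, GC heterogeneity and N-gaps; none are modeled.
* **Reference panels** — the Balding–Nichols model: population frequencies
  Beta-distributed around a uniform ancestral frequency (default range
  0.1–0.9) with Var[f] = F·p(1−p). It is the standard analytically
  checkable structure model, and matches the supervised method's
  assumption of differentiated source populations with fixed frequencies.
  Default study conditions: K = 3, Fst = 0.15, 20 diploids per population
  — a moderate differentiation typical of crop germplasm groups.
* **Admixed individuals** — doses Binomial(2, Σₖ qₖfₖⱼ) at fixed true Q,
  with *independent per-call missingness*. Real GBS missingness clusters
  by sample depth and by locus; independence is a documented
  simplification. Allelic dropout — a recognized GBS artifact that
  depresses observed heterozygosity — is not modeled at all, since no
  quantified dropout rate was available to calibrate one; conclusions
  about Ho from synthetic data therefore transfer only qualitatively.
* **Variant files** — each record carries exactly one planted defect
  (indel, multi-allelic, MAF ≤ 0.05, > 20% missing, or one failing hard
  annotation) or none, constructed from integer allele counts so the truth
  labels are guaranteed, not merely likely.

Passing tests on these generators show the *computations* are correct
under known truth; they do not validate the sequencing-side assumptions
(read depth, mapping, calling) that real data would stress.

## Numerical choices and problem sizes

* Frequency clamp 1e-6 (ancestry), EM tolerance 1e-7 on max |Δq|,
  monotonicity tolerance 1e-8 relative — violations raise.
* MAF and missingness boundaries compared via integer counts where
  possible to make threshold cases exact.
* Tests run the oracles at the scale the checks need: the motif-scan
  oracle on 50 × 100 kb random sequences, interval sweep vs brute force on
  100 random sets, Tajima's D vs pair enumeration on 20 toy matrices,
  ancestry recovery at 5000 loci × 20 samples, bootstrap consistency at
  2000 loci × 200 replicates. The demo pipeline uses a 20 kb genome and a
  400-locus panel so a full end-to-end run stays interactive.

## Known limitations

* Double-digest (two-enzyme) protocols, methylation sensitivity and
  overhang chemistry are out of scope of the digestion model.
* The on-target module accepts any pre-filtered BED and deliberately does
  not define callability criteria for observed fragments.
* Tajima's D has no windowed mode enabled by default; the genome-wide
  value is what the pipeline reports.
* Ancestry assumes the panel's populations are the true sources; model
  misspecification (a missing source population) biases q toward the
  nearest available components and is not diagnosed.
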