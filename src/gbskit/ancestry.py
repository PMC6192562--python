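"""Supervised ancestry estimation, bootstrap precision and PCA.

The supervised admixture model: a test individual's genotypes are modeled
as binomial draws from a mixture of K fixed reference populations.  With
allele dose g_j at locus j and reference frequencies f_kj, the
log-likelihood of the ancestry vector q on the K-simplex is

    L(q) = sum_j [ g_j ln(sum_k q_k f_kj) + (2 - g_j) ln(sum_k q_k (1 - f_kj)) ],

maximized by an EM iteration that is monotone in L and preserves the
simplex.  Reference frequencies are held fixed (supervised semantics), so
each test sample's estimate is independent of the others.

Precision per individual is assessed by bootstrap over loci: resample loci
with replacement, re-estimate q, and report per-component bias and
standard error.

PCA uses Patterson normalization: each locus is centered by its mean dose
and scaled by sqrt(p(1-p)) with p the mean allele frequency; missing doses
are mean-imputed (zero after centering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gbskit.variant_filter import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: reference allele frequencies are clamped to [EPS, 1-EPS] so that fixed
#: alleles cannot produce infinite log-likelihoods
EPS = 1e-6


@dataclass
class ReferencePanel:
    """Per-population, per-locus alternate-allele frequencies.

    ``frequencies`` has shape (K, n_loci), clamped to ``[EPS, 1-EPS]``;
    ``loci`` carries (chromosome, pos, ref, alt) keys aligned with the
    frequency columns.
    """

    populations: list[str]
    frequencies: np.ndarray
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        self.frequencies = np.clip(
            np.asarray(self.frequencies, dtype=np.float64), EPS, 1.0 - EPS
        )
        if self.frequencies.shape != (len(self.populations), len(self.loci)):
            raise ValueError(
                f"frequency array shape {self.frequencies.shape} does not match "
                f"{len(self.populations)} populations x {len(self.loci)} loci"
            )

    @property
    def K(self) -> int:
        return len(self.populations)

    @property
    def n_loci(self) -> int:
        return len(self.loci)


@dataclass
class AncestryEstimate:
    """Ancestry proportions for one sample with convergence diagnostics."""

    q: np.ndarray
    log_likelihood: float
    iterations: int
    converged: bool


@dataclass
class BootstrapPrecision:
    """Per-component bootstrap bias and standard error for one sample."""

    bias: np.ndarray
    se: np.ndarray
    B: int
    seed: int | None


@dataclass
class PCAResult:
    """Eigenvalues (descending), variance fractions and sample coordinates."""

    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    coordinates: np.ndarray
    samples: list[str]


def panel_frequencies(
    reference: GenotypeMatrix, labels: dict[str, str]
) -> ReferencePanel:
    """Reference-panel allele frequencies from labeled genotypes.

    f_kj = alt allele count of population k at locus j over its called
    chromosomes, clamped to ``[EPS, 1-EPS]``.  A locus where any population
    has zero called genotypes is dropped panel-wide (logged).
    """
    missing_labels = [s for s in reference.samples if s not in labels]
    if missing_labels:
        raise ValueError(f"samples without population label: {missing_labels}")
    pops = sorted(set(labels[s] for s in reference.samples))
    freqs = np.empty((len(pops), reference.n_loci))
    keep = np.ones(reference.n_loci, dtype=bool)
    for k, pop in enumerate(pops):
        rows = [i for i, s in enumerate(reference.samples) if labels[s] == pop]
        doses = reference.doses[rows, :]
        called = doses != MISSING
        n_chrom = 2.0 * called.sum(axis=0)
        alt = np.where(called, doses, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[k] = np.where(n_chrom > 0, alt / n_chrom, np.nan)
        keep &= n_chrom > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "dropped %d loci with a population lacking called genotypes", n_dropped
        )
    return ReferencePanel(
        populations=pops,
        frequencies=freqs[:, keep],
        loci=reference.loci.loc[keep].reset_index(drop=True),
    )


def intersect_panels(
    test: GenotypeMatrix, reference: GenotypeMatrix, labels: dict[str, str]
) -> tuple[GenotypeMatrix, ReferencePanel]:
    """Harmonize a test matrix with a labeled reference on shared loci.

    Loci are matched on (chromosome, pos).  Identical ref/alt pairs are
    kept as-is; swapped pairs flip the test doses (g -> 2 - g, missing
    preserved); any other allele mismatch is dropped with a logged count.
    No strand flipping is attempted — A/T and C/G ambiguity cannot be
    resolved from alleles alone.
    """
    ref_index = {
        (c, p): i
        for i, (c, p) in enumerate(
            zip(reference.loci["chromosome"], reference.loci["pos"])
        )
    }
    test_idx: list[int] = []
    ref_idx: list[int] = []
    flip: list[bool] = []
    n_mismatch = 0
    for j, (c, p, a_ref, a_alt) in enumerate(
        zip(test.loci["chromosome"], test.loci["pos"], test.loci["ref"], test.loci["alt"])
    ):
        i = ref_index.get((c, p))
        if i is None:
            continue
        r_ref = reference.loci["ref"].iat[i]
        r_alt = reference.loci["alt"].iat[i]
        if (a_ref, a_alt) == (r_ref, r_alt):
            test_idx.append(j); ref_idx.append(i); flip.append(False)
        elif (a_ref, a_alt) == (r_alt, r_ref):
            test_idx.append(j); ref_idx.append(i); flip.append(True)
        else:
            n_mismatch += 1
    if n_mismatch:
        logger.warning("dropped %d shared-position loci with mismatched alleles", n_mismatch)
    if not test_idx:
        raise ValueError("no shared loci between test and reference sets")
    harmonized = test.subset_loci(np.asarray(test_idx))
    flip_arr = np.asarray(flip)
    if flip_arr.any():
        cols = harmonized.doses[:, flip_arr]
        harmonized.doses[:, flip_arr] = np.where(cols == MISSING, MISSING, 2 - cols)
        # harmonized loci now use the reference allele orientation
        harmonized.loci.loc[flip_arr, ["ref", "alt"]] = (
            harmonized.loci.loc[flip_arr, ["alt", "ref"]].to_numpy()
        )
    panel = panel_frequencies(reference.subset_loci(np.asarray(ref_idx)), labels)
    # panel_frequencies may drop loci; re-align the test matrix to survivors
    key = list(zip(panel.loci["chromosome"], panel.loci["pos"]))
    pos_of = {kp: i for i, kp in enumerate(
        zip(harmonized.loci["chromosome"], harmonized.loci["pos"]))}
    harmonized = harmonized.subset_loci(np.asarray([pos_of[kp] for kp in key]))
    return harmonized, panel


def estimate_q(
    doses: np.ndarray,
    panel: ReferencePanel,
    tol: float = 1e-7,
    max_iter: int = 2000,
) -> AncestryEstimate:
    """Maximize the supervised admixture likelihood for one sample by EM.

    Starting from the uniform vector, iterate

        q_k <- q_k / (2 J') * sum_j [ g_j f_kj / sum_m q_m f_mj
                                      + (2 - g_j)(1 - f_kj) / sum_m q_m (1 - f_mj) ]

    over the J' non-missing loci until ``max |dq| < tol`` or ``max_iter``.
    The log-likelihood is verified to be non-decreasing at every step.

    Raises
    ------
    ValueError
        If every locus is missing.
    RuntimeError
        If the monotonicity guarantee of EM is violated numerically.
    """
    doses = np.asarray(doses)
    obs = doses != MISSING
    if not obs.any():
        raise ValueError("cannot estimate ancestry: all loci missing")
    g = doses[obs].astype(np.float64)
    F = panel.frequencies[:, obs]  # (K, J')
    return _em(g, F, tol, max_iter)


def _em(g: np.ndarray, F: np.ndarray, tol: float, max_iter: int) -> AncestryEstimate:
    K, J = F.shape
    q = np.full(K, 1.0 / K)
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pf = q @ F          # P(alt allele) per locus
        pq = q @ (1.0 - F)  # P(ref allele) per locus
        ll = float(np.sum(g * np.log(pf) + (2.0 - g) * np.log(pq)))
        if ll < prev_ll - 1e-8 * (1.0 + abs(ll)):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: {prev_ll} -> {ll}"
            )
        prev_ll = ll
        new_q = (q / (2.0 * J)) * (F @ (g / pf) + (1.0 - F) @ ((2.0 - g) / pq))
        new_q = np.maximum(new_q, 0.0)
        new_q /= new_q.sum()
        delta = float(np.max(np.abs(new_q - q)))
        q = new_q
        if delta < tol:
            converged = True
            break
    pf = q @ F
    pq = q @ (1.0 - F)
    final_ll = float(np.sum(g * np.log(pf) + (2.0 - g) * np.log(pq)))
    return AncestryEstimate(q=q, log_likelihood=final_ll, iterations=it, converged=converged)


def estimate_q_matrix(
    matrix: GenotypeMatrix,
    panel: ReferencePanel,
    tol: float = 1e-7,
    max_iter: int = 2000,
) -> pd.DataFrame:
    """Per-sample ancestry estimates as a samples x K DataFrame."""
    rows = {}
    for i, sample in enumerate(matrix.samples):
        rows[sample] = estimate_q(matrix.doses[i], panel, tol=tol, max_iter=max_iter).q
    return pd.DataFrame.from_dict(rows, orient="index", columns=panel.populations)


def bootstrap_q(
    doses: np.ndarray,
    panel: ReferencePanel,
    B: int = 2000,
    seed: int | None = None,
    tol: float = 1e-7,
    max_iter: int = 2000,
) -> BootstrapPrecision:
    """Bootstrap bias and standard error of the ancestry vector for one sample.

    Each of the B pseudo-replicates resamples the non-missing loci with
    replacement (keeping J' fixed) and re-runs :func:`estimate_q`; bias is
    the mean replicate estimate minus the point estimate, SE the standard
    deviation over replicates.  Deterministic under a fixed seed.
    """
    if B < 2:
        raise ValueError("bootstrap requires B >= 2 replicates")
    doses = np.asarray(doses)
    obs_idx = np.flatnonzero(doses != MISSING)
    if obs_idx.size == 0:
        raise ValueError("cannot bootstrap: all loci missing")
    point = estimate_q(doses, panel, tol=tol, max_iter=max_iter).q
    rng = np.random.default_rng(seed)
    g_all = doses[obs_idx].astype(np.float64)
    F_all = panel.frequencies[:, obs_idx]
    reps = np.empty((B, panel.K))
    for b in range(B):
        take = rng.integers(0, obs_idx.size, size=obs_idx.size)
        reps[b] = _em(g_all[take], F_all[:, take], tol, max_iter).q
    return BootstrapPrecision(
        bias=reps.mean(axis=0) - point,
        se=reps.std(axis=0, ddof=1),
        B=B,
        seed=seed,
    )


def pca(matrix: GenotypeMatrix, n_components: int | None = None) -> PCAResult:
    """Principal components of a genotype matrix with Patterson normalization.

    Per locus, doses are centered by the mean dose and scaled by
    ``sqrt(p(1-p))`` with ``p = mean dose / 2`` over called genotypes;
    missing doses become 0 after centering (mean imputation).  Loci with
    zero variance (p in {0, 1}) or no called genotype are dropped.  The
    eigendecomposition is of the sample-by-sample covariance averaged over
    loci; variance fractions are eigenvalues over the trace.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    called = matrix.called_mask()
    n_called = called.sum(axis=0)
    alt = np.where(called, matrix.doses, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    keep = (n_called > 0) & (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("no polymorphic loci available for PCA")
    doses = matrix.doses[:, keep].astype(np.float64)
    mask = called[:, keep]
    pk = p[keep]
    centered = np.where(mask, doses - 2.0 * pk, 0.0)
    X = centered / np.sqrt(pk * (1.0 - pk))
    J = X.shape[1]
    cov = (X @ X.T) / J
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    eigvecs = eigvecs[:, order]
    trace = eigvals.sum()
    fractions = eigvals / trace if trace > 0 else np.zeros_like(eigvals)
    coords = eigvecs * np.sqrt(eigvals)
    if n_components is not None:
        eigvals = eigvals[:n_components]
        fractions = fractions[:n_components]
        coords = coords[:, :n_components]
    return PCAResult(
        eigenvalues=eigvals,
        variance_fractions=fractions,
        coordinates=coords,
        samples=list(matrix.samples),
    )


def pca_project(
    fit: GenotypeMatrix, project: GenotypeMatrix, n_components: int = 10
) -> tuple[PCAResult, np.ndarray]:
    """Projection-only PCA: axes from ``fit`` samples, ``project`` samples mapped on.

    Both matrices must share the same loci in the same order.  The
    projected samples use the *fit* set's per-locus centering and Patterson
    scaling, so they do not influence the axes — useful when reference and
    test cohorts should not be decomposed jointly.

    Returns the fit-set :class:`PCAResult` and the projected coordinates
    (n_project_samples x n_components).
    """
    if fit.n_loci != project.n_loci:
        raise ValueError("fit and project matrices must share the same loci")
    called = fit.called_mask()
    n_called = called.sum(axis=0)
    alt = np.where(called, fit.doses, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    keep = (n_called > 0) & (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("no polymorphic loci available for PCA")
    pk = p[keep]
    scale = np.sqrt(pk * (1.0 - pk))

    def _normalize(matrix: GenotypeMatrix) -> np.ndarray:
        doses = matrix.doses[:, keep].astype(np.float64)
        mask = matrix.called_mask()[:, keep]
        return np.where(mask, doses - 2.0 * pk, 0.0) / scale

    X = _normalize(fit)
    J = X.shape[1]
    cov = (X @ X.T) / J
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1][:n_components]
    eigvals = np.maximum(eigvals[order], 0.0)
    eigvecs = eigvecs[:, order]
    trace = np.trace(cov)
    result = PCAResult(
        eigenvalues=eigvals,
        variance_fractions=eigvals / trace if trace > 0 else np.zeros_like(eigvals),
        coordinates=eigvecs * np.sqrt(eigvals),
        samples=list(fit.samples),
    )
    # loadings of the fit decomposition: V = X^T U / (sqrt(lambda) * sqrt(J))
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_root = np.where(eigvals > 0, 1.0 / np.sqrt(eigvals), 0.0)
    loadings = (X.T @ eigvecs) * inv_root / J
    projected = _normalize(project) @ loadings
    return result, projected
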