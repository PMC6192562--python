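"""Supervised admixture EM, bootstrap precision and Patterson PCA."""

import numpy as np
import pandas as pd
import pytest

from gbskit.ancestry import (
    EPS,
    ReferencePanel,
    bootstrap_q,
    estimate_q,
    intersect_panels,
    panel_frequencies,
    pca,
)
from gbskit.synthetic import (
    SimAdmixedConfig,
    SimPanelConfig,
    simulate_admixed,
    simulate_reference_panel,
)
from gbskit.variant_filter import MISSING
from tests.conftest import make_matrix


def make_panel(freqs, pops=None):
    freqs = np.asarray(freqs, dtype=float)
    pops = pops or [f"P{k + 1}" for k in range(freqs.shape[0])]
    loci = pd.DataFrame(
        {
            "chromosome": ["1"] * freqs.shape[1],
            "pos": np.arange(1, freqs.shape[1] + 1) * 10,
            "ref": ["A"] * freqs.shape[1],
            "alt": ["G"] * freqs.shape[1],
        }
    )
    return ReferencePanel(pops, freqs, loci)


def supervised_loglik(q, g, F):
    pf = q @ F
    pq = q @ (1.0 - F)
    return float(np.sum(g * np.log(pf) + (2.0 - g) * np.log(pq)))


class TestPanelFrequencies:
    def test_allele_count_arithmetic(self):
        matrix = make_matrix(np.array([[1], [2]]))
        panel = panel_frequencies(matrix, {"s1": "P", "s2": "P"})
        assert panel.frequencies[0, 0] == pytest.approx(3 / 4)

    def test_monomorphic_population_clamped(self):
        matrix = make_matrix(np.zeros((3, 2)))
        panel = panel_frequencies(matrix, {s: "P" for s in matrix.samples})
        assert (panel.frequencies == EPS).all()

    def test_locus_dropped_when_population_uncalled(self):
        doses = np.array([[1, MISSING], [0, 1]], dtype=np.int8)
        matrix = make_matrix(doses)
        panel = panel_frequencies(matrix, {"s1": "A", "s2": "B"})
        assert panel.n_loci == 1

    def test_recovers_generating_frequencies(self, sim_panel):
        est = panel_frequencies(sim_panel.genotypes, sim_panel.labels)
        truth = np.clip(sim_panel.true_frequencies, EPS, 1 - EPS)
        mae = np.mean(np.abs(est.frequencies - truth))
        assert mae <= 0.08  # binomial error at 40 chromosomes per population


class TestIntersectPanels:
    def test_identical_sets_fully_shared(self, sim_panel):
        test = sim_panel.genotypes
        harmonized, panel = intersect_panels(test, sim_panel.genotypes, sim_panel.labels)
        assert harmonized.n_loci == panel.n_loci
        np.testing.assert_array_equal(
            harmonized.doses[:, :10], sim_panel.genotypes.doses[:, :10]
        )

    def test_swapped_alleles_flip_doses(self):
        ref = make_matrix(np.array([[0], [2]]), ref="A", alt="G")
        test = make_matrix(np.array([[2], [0]]), ref="G", alt="A")
        harmonized, _ = intersect_panels(test, ref, {"s1": "P", "s2": "P"})
        assert harmonized.doses[:, 0].tolist() == [0, 2]
        assert harmonized.loci.loc[0, "ref"] == "A"

    def test_shared_locus_count_by_construction(self):
        rng = np.random.default_rng(41)
        ref_doses = rng.integers(0, 3, size=(4, 800)).astype(np.int8)
        ref = make_matrix(ref_doses)
        test = make_matrix(rng.integers(0, 3, size=(3, 800)).astype(np.int8))
        test.loci.loc[500:, "pos"] = test.loci.loc[500:, "pos"] + 1_000_000
        harmonized, panel = intersect_panels(
            test, ref, {s: "P" for s in ref.samples}
        )
        assert harmonized.n_loci == 500 == panel.n_loci

    def test_mismatched_alleles_dropped(self):
        ref = make_matrix(np.array([[0], [2]]), ref="A", alt="G")
        test = make_matrix(np.array([[2], [0]]), ref="C", alt="T")
        with pytest.raises(ValueError, match="no shared loci"):
            intersect_panels(test, ref, {"s1": "P", "s2": "P"})


class TestEstimateQ:
    def test_perfectly_diagnostic_loci_force_corner(self):
        K, J = 3, 200
        F = np.full((K, J), EPS)
        F[0] = 1 - EPS
        panel = make_panel(F)
        est = estimate_q(np.full(J, 2, dtype=np.int8), panel)
        assert est.q[0] > 0.999 and est.converged

    def test_em_matches_grid_search_oracle(self):
        F = np.array([[0.9, 0.2, 0.7], [0.1, 0.8, 0.3]])
        g = np.array([2, 0, 1], dtype=np.int8)
        panel = make_panel(F)
        grid = np.arange(0.0, 1.0001, 0.001)
        lls = [supervised_loglik(np.array([q1, 1 - q1]), g, panel.frequencies) for q1 in grid]
        best = grid[int(np.argmax(lls))]
        est = estimate_q(g, panel)
        assert est.q[0] == pytest.approx(best, abs=2e-3)

    def test_loglik_nondecreasing_and_final_at_least_uniform(self, sim_panel, sim_admixed):
        # estimate_q raises internally if EM monotonicity is violated
        panel = sim_panel.panel
        for i in range(sim_admixed.genotypes.n_samples):
            g = sim_admixed.genotypes.doses[i]
            est = estimate_q(g, panel)
            uniform_ll = supervised_loglik(
                np.full(panel.K, 1 / panel.K), g.astype(float), panel.frequencies
            )
            assert est.log_likelihood >= uniform_ll - 1e-9
            assert est.q.min() >= 0
            assert est.q.sum() == pytest.approx(1.0, abs=1e-8)

    def test_recovery_improves_with_more_loci(self):
        maes = []
        for n_loci in (500, 5000):
            sim = simulate_reference_panel(
                SimPanelConfig(K=2, n_loci=n_loci, n_per_pop=20, fst=0.15, seed=42)
            )
            q_true = np.tile([0.7, 0.3], (10, 1))
            adm = simulate_admixed(sim.panel, SimAdmixedConfig(true_Q=q_true, seed=43))
            errs = [
                np.abs(estimate_q(adm.genotypes.doses[i], sim.panel).q - q_true[i]).mean()
                for i in range(10)
            ]
            maes.append(np.mean(errs))
        assert maes[1] < maes[0]

    def test_label_permutation_equivariance(self, sim_panel, sim_admixed):
        panel = sim_panel.panel
        perm = [2, 0, 1]
        permuted = ReferencePanel(
            [panel.populations[k] for k in perm],
            panel.frequencies[perm],
            panel.loci.copy(),
        )
        g = sim_admixed.genotypes.doses[0]
        q1 = estimate_q(g, panel).q
        q2 = estimate_q(g, permuted).q
        np.testing.assert_allclose(q2, q1[perm], atol=1e-6)

    def test_all_missing_is_an_error(self):
        panel = make_panel(np.array([[0.5, 0.5], [0.2, 0.8]]))
        with pytest.raises(ValueError, match="missing"):
            estimate_q(np.array([MISSING, MISSING], dtype=np.int8), panel)


class TestBootstrapQ:
    def test_fixed_seed_reproducible(self, sim_panel, sim_admixed):
        g = sim_admixed.genotypes.doses[0]
        b1 = bootstrap_q(g, sim_panel.panel, B=20, seed=7)
        b2 = bootstrap_q(g, sim_panel.panel, B=20, seed=7)
        np.testing.assert_array_equal(b1.bias, b2.bias)
        np.testing.assert_array_equal(b1.se, b2.se)

    def test_diagnostic_loci_give_vanishing_se(self):
        K, J = 2, 400
        F = np.full((K, J), EPS)
        F[0] = 1 - EPS
        panel = make_panel(F)
        boot = bootstrap_q(np.full(J, 2, dtype=np.int8), panel, B=30, seed=8)
        assert boot.se[0] < 1e-3

    def test_too_few_replicates_rejected(self, sim_panel, sim_admixed):
        with pytest.raises(ValueError):
            bootstrap_q(sim_admixed.genotypes.doses[0], sim_panel.panel, B=1, seed=1)


class TestPCA:
    def test_two_populations_separate_on_pc1(self):
        sim = simulate_reference_panel(
            SimPanelConfig(K=2, n_loci=300, n_per_pop=20, fst=0.3, seed=44)
        )
        res = pca(sim.genotypes)
        pc1 = res.coordinates[:, 0]
        a, b = pc1[:20], pc1[20:]
        # cluster ranges must not overlap
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_duplicated_sample_has_identical_coordinates(self, sim_panel):
        matrix = sim_panel.genotypes.subset_samples(list(range(10)) + [0])
        res = pca(matrix)
        np.testing.assert_allclose(
            res.coordinates[0, :5], res.coordinates[-1, :5], atol=1e-8
        )

    def test_spectral_properties(self, sim_panel):
        res = pca(sim_panel.genotypes)
        assert (res.eigenvalues >= 0).all()
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        assert res.variance_fractions.sum() <= 1 + 1e-9

    def test_fewer_than_two_samples_rejected(self, sim_panel):
        with pytest.raises(ValueError):
            pca(sim_panel.genotypes.subset_samples([0]))

    def test_projection_of_fit_samples_reproduces_their_coordinates(self, sim_panel):
        from gbskit.ancestry import pca_project

        matrix = sim_panel.genotypes.subset_samples(range(30))
        result, projected = pca_project(matrix, matrix, n_components=5)
        np.testing.assert_allclose(projected, result.coordinates, atol=1e-8)

    def test_projected_samples_do_not_move_the_axes(self, sim_panel):
        from gbskit.ancestry import pca_project

        fit = sim_panel.genotypes.subset_samples(range(40))
        test = sim_panel.genotypes.subset_samples(range(40, 60))
        result_alone = pca(fit, n_components=3)
        result_proj, projected = pca_project(fit, test, n_components=3)
        np.testing.assert_allclose(
            np.abs(result_proj.eigenvalues), np.abs(result_alone.eigenvalues), atol=1e-9
        )
        assert projected.shape == (20, 3)
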