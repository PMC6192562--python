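"""Ground-truth guarantees of the synthetic-data generators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gbskit.digest import BSAXI, digest_genome, find_recognition_sites
from gbskit.synthetic import (
    SimAdmixedConfig,
    SimGenomeConfig,
    SimPanelConfig,
    simulate_admixed,
    simulate_genome,
    simulate_reference_panel,
    simulate_variant_file,
)
from gbskit.variant_filter import MISSING


class TestSimulateGenome:
    def test_no_planted_sites_means_no_matches(self):
        cfg = SimGenomeConfig(length=1000, planted_sites=[], seed=1)
        sequences, truth = simulate_genome(cfg, BSAXI)
        assert truth == []
        assert find_recognition_sites(sequences, BSAXI) == []

    def test_digest_recovers_planted_cut_boundaries(self):
        cfg = SimGenomeConfig(
            length=5000,
            planted_sites=[(0, 1000, "+"), (0, 2500, "-"), (0, 4000, "+")],
            seed=2,
        )
        sequences, truth = simulate_genome(cfg, BSAXI)
        _, cuts = digest_genome(sequences, BSAXI)
        # BsaXI: 11 bp motif, cuts 14 bp either side -> {s-14, s+25} per site
        expected = sorted(
            p for s in (1000, 2500, 4000) for p in (s - 14, s + 11 + 14)
        )
        assert cuts["chr1"].tolist() == expected

    def test_background_gc_content(self):
        cfg = SimGenomeConfig(length=100_000, gc_content=0.5, seed=3)
        sequences, _ = simulate_genome(cfg, BSAXI)
        seq = sequences["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) <= 0.02

    def test_scan_finds_exactly_the_planted_sites(self):
        cfg = SimGenomeConfig(
            length=30_000,
            planted_sites=[(0, p, "+" if p % 2000 else "-") for p in range(1000, 29_000, 1000)],
            seed=4,
        )
        sequences, truth = simulate_genome(cfg, BSAXI)
        found = find_recognition_sites(sequences, BSAXI)
        assert {(m.chromosome, m.start, m.strand) for m in found} == {
            (t.chromosome, t.start, t.strand) for t in truth
        }

    def test_site_beyond_chromosome_end_rejected(self):
        cfg = SimGenomeConfig(length=100, planted_sites=[(0, 95, "+")], seed=5)
        with pytest.raises(ValueError, match="pos 95"):
            simulate_genome(cfg, BSAXI)

    def test_deterministic_under_fixed_seed(self):
        cfg = SimGenomeConfig(length=5000, planted_sites=[(0, 100, "+")], seed=6)
        a = simulate_genome(cfg, BSAXI)
        b = simulate_genome(cfg, BSAXI)
        assert a == b


class TestSimulateReferencePanel:
    def test_vanishing_fst_collapses_population_frequencies(self):
        sim = simulate_reference_panel(
            SimPanelConfig(K=3, n_loci=500, fst=1e-4, seed=7)
        )
        spread = sim.true_frequencies.std(axis=0)
        assert spread.mean() < 0.01

    def test_frequency_recovery_error_shrinks_with_panel_size(self):
        from gbskit.ancestry import panel_frequencies

        maes = []
        for n in (10, 40, 160):
            sim = simulate_reference_panel(
                SimPanelConfig(K=3, n_loci=800, n_per_pop=n, fst=0.15, seed=8)
            )
            est = panel_frequencies(sim.genotypes, sim.labels)
            maes.append(np.mean(np.abs(est.frequencies - np.clip(sim.true_frequencies, 1e-6, 1 - 1e-6))))
        assert maes[0] > maes[1] > maes[2]

    def test_deterministic_under_fixed_seed(self):
        cfg = SimPanelConfig(K=2, n_loci=100, n_per_pop=5, fst=0.2, seed=9)
        a = simulate_reference_panel(cfg)
        b = simulate_reference_panel(cfg)
        np.testing.assert_array_equal(a.genotypes.doses, b.genotypes.doses)
        np.testing.assert_array_equal(a.true_frequencies, b.true_frequencies)

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError):
            SimPanelConfig(fst=1.5)
        with pytest.raises(ValueError):
            SimPanelConfig(fst=0.0)


class TestSimulateAdmixed:
    def test_unit_ancestry_matches_source_population(self, sim_panel):
        q = np.zeros((40, 3))
        q[:, 1] = 1.0
        adm = simulate_admixed(sim_panel.panel, SimAdmixedConfig(true_Q=q, seed=10))
        mean_dose = adm.genotypes.doses.mean(axis=0)
        mad = np.mean(np.abs(mean_dose - 2 * sim_panel.panel.frequencies[1]))
        assert mad < 0.12  # binomial noise at 80 chromosomes per locus

    def test_zero_missing_rate_leaves_no_missing_calls(self, sim_panel):
        adm = simulate_admixed(
            sim_panel.panel,
            SimAdmixedConfig(true_Q=np.array([[0.5, 0.5, 0.0]]), missing_rate=0.0, seed=11),
        )
        assert not (adm.genotypes.doses == MISSING).any()

    def test_mean_dose_equals_mixture_expectation(self, sim_panel):
        # 10^4 replicate draws at one locus: E[g] = 2 sum_k q_k f_kj
        q = np.tile([0.6, 0.1, 0.3], (10_000, 1))
        adm = simulate_admixed(sim_panel.panel, SimAdmixedConfig(true_Q=q, seed=12))
        j = 5
        expected = 2 * float(q[0] @ sim_panel.panel.frequencies[:, j])
        observed = adm.genotypes.doses[:, j].mean()
        # binomial SE at n=10^4 draws of a dose in [0,2]
        assert observed == pytest.approx(expected, abs=0.05)

    def test_off_simplex_q_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimAdmixedConfig(true_Q=np.array([[0.5, 0.6]]))

    def test_dirichlet_q_rows_live_on_the_simplex(self):
        from gbskit.synthetic import dirichlet_q

        q = dirichlet_q(50, alpha=0.5, K=4, seed=13)
        assert q.shape == (50, 4)
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-12)
        # valid input for the admixture generator
        SimAdmixedConfig(true_Q=q)


class TestSimulateVariantFile:
    def test_all_fractions_zero_keeps_every_site(self):
        from gbskit.variant_filter import apply_hard_filters, filter_population

        records, labels, samples = simulate_variant_file(100, seed=13)
        assert labels.count("clean") == 100
        passing, _ = apply_hard_filters(records)
        matrix, _ = filter_population(passing, samples)
        assert matrix.n_loci == 100

    def test_each_defect_removed_by_exactly_its_filter(self):
        from gbskit.variant_filter import apply_hard_filters, filter_population

        records, labels, samples = simulate_variant_file(
            200, frac_indel=0.05, frac_multiallelic=0.05, frac_low_maf=0.10,
            frac_high_missing=0.10, frac_hard_fail=0.075, seed=14,
        )
        n_hard = labels.count("hard_filter")
        passing, removed = apply_hard_filters(records)
        assert sum(removed.values()) == n_hard
        matrix, counts = filter_population(passing, samples)
        assert matrix.n_loci == labels.count("clean")

    def test_indel_sites_removed_by_snp_restriction(self):
        records, labels, _ = simulate_variant_file(50, frac_indel=0.2, seed=15)
        snp_flags = [r.is_snp for r in records]
        assert sum(not f for f in snp_flags) == labels.count("indel") == 10

    def test_fractions_exceeding_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_variant_file(10, frac_indel=0.7, frac_low_maf=0.6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_truth_labels_consistent_for_any_seed(self, seed):
        records, labels, _ = simulate_variant_file(
            40, frac_low_maf=0.2, frac_high_missing=0.2, seed=seed
        )
        for rec, label in zip(records, labels):
            if label == "low_maf":
                assert rec.minor_allele_frequency() <= 0.05
                assert rec.missing_fraction() == 0.0
            elif label == "high_missing":
                assert rec.missing_fraction() > 0.20
                assert rec.minor_allele_frequency() > 0.05
            elif label == "clean":
                assert rec.is_snp
                assert rec.minor_allele_frequency() > 0.05
                assert rec.missing_fraction() <= 0.20
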