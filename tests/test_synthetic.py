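"""Generator correctness: frequency models, LD construction, mosaics,
phenotypes, relatives and determinism."""

import numpy as np
import pytest

from admixfine.association import trend_test
from admixfine.ld import pairwise_r2
from admixfine.synthetic import (
    CausalVariant,
    ConfigurationError,
    SimulationConfig,
    SimulationError,
    assign_phenotypes,
    balding_nichols_freqs,
    inject_relatives,
    panel_from_founders,
    simulate_admixed_cohort,
    simulate_ancestral_panels,
    simulate_case_control,
)


class TestAncestralPanels:
    def test_balding_nichols_moment(self):
        """Descendant frequencies have variance F p (1-p) around p."""
        rng = np.random.default_rng(0)
        draws = balding_nichols_freqs(np.full(20000, 0.5), 0.2, rng)
        assert abs(draws.mean() - 0.5) < 0.01
        assert abs(draws.var() - 0.2 * 0.25) < 0.003

    def test_zero_divergence_identical_distributions(self):
        cfg = SimulationConfig(n_variants=200, fst=0.0, pool_haplotypes=10000, seed=3)
        p1, p2 = simulate_ancestral_panels(cfg)
        diff = p1.empirical_freqs() - p2.empirical_freqs()
        se = np.std(diff) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 4 * se + 1e-9

    def test_pool_frequencies_match_declared(self):
        cfg = SimulationConfig(n_variants=150, pool_haplotypes=5000, seed=4)
        for panel in simulate_ancestral_panels(cfg):
            q = panel.freqs
            tol = 4 * np.sqrt(np.clip(q * (1 - q), 0, None) / panel.n_haplotypes) + 1e-9
            dev = np.abs(panel.empirical_freqs() - q)
            # allow a single 4-SD excursion over 150 variants
            assert (dev > tol).sum() <= 1

    def test_panel_frequency_variance_tracks_divergence(self):
        """Across many variants with a common ancestral frequency, panel
        frequencies scatter with variance close to F p (1-p)."""
        cfg = SimulationConfig(
            n_variants=3000,
            fst=0.2,
            ancestral_freq_range=(0.5, 0.5),
            n_founders_range=(8, 8),
            pool_haplotypes=2000,
            block_len_range=(1, 1),
            seed=5,
        )
        p1, _ = simulate_ancestral_panels(cfg)
        assert abs(p1.freqs.var() - 0.05) < 0.012

    def test_two_founder_block_complete_ld(self):
        founders = np.array([[1, 1, 1, 1, 1], [0, 0, 0, 0, 0]], dtype=np.int8)
        panel = panel_from_founders("X", founders, [0.4, 0.6], rng=1)
        pool = panel.pool.astype(float)
        for i in range(5):
            for j in range(i + 1, 5):
                assert pairwise_r2(pool[:, i], pool[:, j]) == pytest.approx(1.0)

    def test_every_variant_in_exactly_one_block(self):
        cfg = SimulationConfig(n_variants=57, seed=6)
        p1, _ = simulate_ancestral_panels(cfg)
        covered = np.zeros(57, dtype=int)
        for b0, b1 in p1.blocks:
            covered[b0:b1] += 1
        assert (covered == 1).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_ancestral_panels(SimulationConfig(fst=1.0))
        with pytest.raises(ConfigurationError):
            simulate_ancestral_panels(SimulationConfig(n_variants=0))
        with pytest.raises(ConfigurationError):
            SimulationConfig(theta=1.5).validate()


class TestAdmixedCohort:
    def test_single_ancestry_limit(self):
        cfg = SimulationConfig(n_variants=40, theta=1.0, seed=7)
        panels = simulate_ancestral_panels(cfg)
        _, track, _ = simulate_admixed_cohort(panels, cfg, n_samples=50, rng=7)
        assert (track.values == 2.0).all()

    def test_admixed_frequency_is_ancestry_mixture(self):
        """theta = 0.8 with p1 = 0.1, p2 = 0.5 gives frequency ~0.18."""
        f1 = panel_from_founders("P1", np.array([[1], [0]], np.int8), [0.1, 0.9],
                                 pool_size=20000, rng=1)
        f2 = panel_from_founders("P2", np.array([[1], [0]], np.int8), [0.5, 0.5],
                                 pool_size=20000, rng=2)
        cfg = SimulationConfig(
            n_variants=1, theta=0.8, theta_concentration=None, missing_rate=0.0,
            imputed_fraction=0.0, seed=8,
        )
        dm, _, _ = simulate_admixed_cohort((f1, f2), cfg, n_samples=5000, rng=8)
        expected = 0.8 * 0.1 + 0.2 * 0.5
        se = np.sqrt(expected * (1 - expected) / 10000) + np.sqrt(expected * (1 - expected) / 20000)
        assert abs(dm.allele_freq()[0] - expected) < 3 * se

    def test_switch_events_poisson(self):
        cfg = SimulationConfig(n_variants=100, switch_rate=2.0, theta=0.5, seed=9)
        panels = simulate_ancestral_panels(cfg)
        _, _, truth = simulate_admixed_cohort(panels, cfg, n_samples=1000, rng=9)
        counts = truth.switch_counts.ravel()
        se = np.sqrt(2.0 / counts.size)
        assert abs(counts.mean() - 2.0) < 3 * se

    def test_local_ancestry_matches_truth(self):
        cfg = SimulationConfig(n_variants=50, seed=10)
        panels = simulate_ancestral_panels(cfg)
        _, track, truth = simulate_admixed_cohort(panels, cfg, n_samples=40, rng=10)
        np.testing.assert_array_equal(track.values, truth.local_ancestry())

    @pytest.mark.parametrize("target", [0.5, 0.8, 0.95])
    def test_imputed_rsq_contract(self, target):
        """Realized dosage-genotype squared correlation hits target +/- 0.05."""
        cfg = SimulationConfig(
            n_variants=30, imputed_fraction=1.0, rsq_range=(target, target),
            missing_rate=0.0, seed=11,
        )
        panels = simulate_ancestral_panels(cfg)
        _, _, truth = simulate_admixed_cohort(panels, cfg, n_samples=4000, rng=11)
        dev = np.abs(truth.rsq_realized - target)
        assert np.nanmedian(dev) < 0.05
        assert np.nanmax(dev) < 0.1

    def test_dosages_in_range_or_missing(self, causal_dataset):
        d = causal_dataset.dosages.dosages
        ok = np.isnan(d) | ((d >= 0) & (d <= 2))
        assert ok.all()
        assert ((causal_dataset.local_ancestry.values >= 0)
                & (causal_dataset.local_ancestry.values <= 2)).all()


class TestPhenotypes:
    def test_pre_ascertainment_prevalence(self):
        cfg = SimulationConfig(
            n_variants=20, prevalence=0.1, age_beta=0.0, fh_log_or=0.0, seed=12
        )
        panels = simulate_ancestral_panels(cfg)
        dm, _, truth = simulate_admixed_cohort(panels, cfg, n_samples=5000, rng=12)
        pheno = assign_phenotypes(dm, truth, cfg, rng=12)
        frac = pheno["status"].mean()
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 5000)

    def test_effect_recovery_coverage(self):
        """CI for a planted OR of 1.3 covers the truth at ~nominal rate."""
        covered = 0
        reps = 50
        master = np.random.default_rng(13)
        for _ in range(reps):
            seed = int(master.integers(2**31))
            cfg = SimulationConfig(
                n_cases=600, n_controls=600, n_variants=12, block_len_range=(1, 1),
                causal=[CausalVariant("var00005", float(np.log(1.3)))],
                imputed_fraction=0.0, prevalence=0.25, seed=seed,
            )
            ds = simulate_case_control(cfg)
            r = trend_test(
                ds.dosages.dosage_of("var00005"), ds.samples["status"].to_numpy()
            )
            if r.ci_lo <= 1.3 <= r.ci_hi:
                covered += 1
        assert covered >= 43  # ~nominal 95% coverage over 50 replicates

    def test_unreachable_prevalence_errors(self):
        cfg = SimulationConfig(
            n_cases=500, n_controls=10, n_variants=10, prevalence=1e-4,
            max_attempts=2, seed=14,
        )
        with pytest.raises(SimulationError):
            simulate_case_control(cfg)


class TestRelatives:
    def test_mz_genotypes_identical(self, null_dataset):
        ds = null_dataset
        dm2, truth2 = inject_relatives(
            ds.dosages, ds.truth, [("MZ", 2)], ds.config, rng=15
        )
        for rec in truth2.relationships:
            i = dm2.sample_index(rec["members"][0])
            j = dm2.sample_index(rec["members"][1])
            np.testing.assert_array_equal(truth2.genotypes[i], truth2.genotypes[j])

    def test_parent_offspring_shares_allele_everywhere(self, null_dataset):
        ds = null_dataset
        dm2, truth2 = inject_relatives(
            ds.dosages, ds.truth, [("parent-offspring", 3)], ds.config, rng=16
        )
        for rec in truth2.relationships:
            gp = truth2.genotypes[dm2.sample_index(rec["members"][0])]
            gc = truth2.genotypes[dm2.sample_index(rec["members"][1])]
            # sharing one allele IBD bounds the genotype difference by 1
            assert np.abs(gp.astype(int) - gc.astype(int)).max() <= 1

    def test_full_sibling_ibd_fraction(self, null_dataset):
        """Genome-averaged sibling IBD sharing ~0.5, within 3 SD from an
        independent transmission-simulation oracle."""
        rate = 30.0
        V = null_dataset.dosages.n_variants

        def oracle_sd(reps=400, rng=np.random.default_rng(0)):
            fracs = []
            for _ in range(reps):
                share = []
                for _parent in range(2):
                    masks = []
                    for _child in range(2):
                        nx = rng.poisson(rate)
                        cuts = np.sort(rng.integers(1, V, size=nx)) if nx else []
                        m = np.zeros(V, dtype=int)
                        state = rng.integers(0, 2)
                        b = np.concatenate(([0], cuts, [V])).astype(int)
                        for s0, s1 in zip(b[:-1], b[1:]):
                            m[s0:s1] = state
                            state = 1 - state
                        masks.append(m)
                    share.append((masks[0] == masks[1]).mean())
                fracs.append(0.5 * (share[0] + share[1]))
            return np.std(fracs)

        sd = oracle_sd()
        import dataclasses
        cfg = dataclasses.replace(null_dataset.config, crossover_rate=rate)
        _, truth2 = inject_relatives(
            null_dataset.dosages, null_dataset.truth, [("full-sibling", 5)], cfg, rng=17
        )
        for rec in truth2.relationships:
            assert abs(rec["ibd_fraction"] - 0.5) < 3 * sd + 1e-9

    def test_unknown_relationship_rejected(self, null_dataset):
        with pytest.raises(ConfigurationError):
            inject_relatives(
                null_dataset.dosages, null_dataset.truth, [("cousin", 1)],
                null_dataset.config, rng=1,
            )


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = SimulationConfig(n_cases=80, n_controls=80, n_variants=40, seed=77)
        a = simulate_case_control(cfg)
        b = simulate_case_control(cfg)
        np.testing.assert_array_equal(
            np.nan_to_num(a.dosages.dosages, nan=-1),
            np.nan_to_num(b.dosages.dosages, nan=-1),
        )
        assert a.samples.equals(b.samples)
        np.testing.assert_array_equal(a.local_ancestry.values, b.local_ancestry.values)
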