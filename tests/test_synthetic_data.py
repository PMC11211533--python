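"""Wright–Fisher engine, study generator and epoch-recovery evaluation."""

import numpy as np
import pytest

from pvarch.errors import ConfigurationError
from pvarch.sharing_analysis import SharingPattern, classify_with_ancient
from pvarch.synthetic_data import (Lineage, SimulationParams, TruthRecord,
                                   classify_study, evaluate_epoch_recovery,
                                   simulate_study, wright_fisher_trajectory,
                                   write_study)
from pvarch.catalog_io import normalize_variant


FAST = dict(mutation_rate=0.5, ancestral_generations=200,
            t_split_years=15_000, n_ancestral=300, n_founders=60,
            african_sizes=((15_000, 300),), nonafrican_sizes=((15_000, 200),),
            african_cohort_size=300,
            nonafrican_cohorts=(("European", 400), ("EastAsian", 200)),
            ancient_sampling=((1000, 20, 0.2), (3000, 20, 0.2)))


class TestWrightFisher:
    def test_absorption_at_zero_and_one(self):
        rng = np.random.default_rng(0)
        assert (wright_fisher_trajectory(0.0, [10] * 5, rng) == 0.0).all()
        assert (wright_fisher_trajectory(1.0, [10] * 5, rng) == 1.0).all()

    def test_loss_probability_matches_exact_binomial(self):
        # one generation at N=2 from p=1/2: loss iff Binomial(4, 1/2)=0,
        # probability (1/2)^4 = 1/16
        rng = np.random.default_rng(123)
        n_rep = 100_000
        losses = sum(wright_fisher_trajectory(0.5, [2], rng)[1] == 0.0
                     for _ in range(n_rep))
        p_hat = losses / n_rep
        se = np.sqrt((1 / 16) * (15 / 16) / n_rep)
        assert abs(p_hat - 1 / 16) < 3 * se

    def test_expected_frequency_is_conserved(self):
        # neutral drift is a martingale: mean terminal freq approximates p0
        rng = np.random.default_rng(5)
        terminals = [wright_fisher_trajectory(0.3, [20] * 10, rng)[-1]
                     for _ in range(4000)]
        assert np.mean(terminals) == pytest.approx(0.3, abs=0.02)

    def test_invalid_inputs(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            wright_fisher_trajectory(1.5, [10], rng)
        with pytest.raises(ValueError):
            wright_fisher_trajectory(0.5, [0], rng)


class TestSimulateStudy:
    def test_zero_mutation_rate_gives_empty_study(self):
        study = simulate_study(SimulationParams(seed=0, mutation_rate=0.0,
                                                **{k: v for k, v in FAST.items()
                                                   if k != "mutation_rate"}))
        assert study.truth == []
        assert study.african_cohort.rows == []
        assert all(not s.observed_variants for s in study.ancient_samples)

    def test_full_missingness_blinds_ancient_samples(self):
        params = SimulationParams(seed=1, **{**FAST, "ancient_sampling":
                                             ((1000, 20, 1.0), (3000, 20, 1.0))})
        study = simulate_study(params)
        assert all(not s.observed_variants for s in study.ancient_samples)

    def test_same_seed_reproduces_identical_files(self, tmp_path):
        p1, p2 = tmp_path / "a", tmp_path / "b"
        write_study(simulate_study(SimulationParams(seed=7, **FAST)), p1)
        write_study(simulate_study(SimulationParams(seed=7, **FAST)), p2)
        for f1 in sorted(p1.iterdir()):
            assert f1.read_bytes() == (p2 / f1.name).read_bytes()

    def test_sampling_before_split_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_study(SimulationParams(
                seed=0, **{**FAST, "ancient_sampling": ((20_000, 5, 0.0),)}))

    def test_every_observed_variant_has_truth(self):
        study = simulate_study(SimulationParams(seed=2, **FAST))
        truth_keys = {t.variant for t in study.truth}
        observed = (study.african_keys() | study.nonafrican_keys()
                    | study.ancient_keys())
        assert observed <= truth_keys

    def test_allele_counts_bounded_by_cohort_alleles(self):
        study = simulate_study(SimulationParams(seed=2, **FAST))
        for table in [study.african_cohort, *study.nonafrican_cohorts]:
            for _, ac, an, _ in table.rows:
                assert 0 < ac <= an == 2 * table.sample_size

    def test_founder_effect_leaves_african_private_variants(self):
        # high ancestral diversity + narrow founder bottleneck: some ancestral
        # variants survive in the African branch but were never carried out
        study = simulate_study(SimulationParams(
            seed=3, **{**FAST, "mutation_rate": 2.0, "n_founders": 10}))
        afr_only = study.african_keys() - study.nonafrican_keys()
        assert afr_only

    def test_branch_frequencies_conditionally_independent_after_split(self):
        # post-split increments on the two branches must be uncorrelated
        rng_seeds = range(30)
        d_afr, d_non = [], []
        for seed in rng_seeds:
            study = simulate_study(SimulationParams(
                seed=seed, **{**FAST, "mutation_rate": 1.0}))
            afr = {v: ac / an for v, ac, an, _ in study.african_cohort.rows}
            non = {}
            for t in study.nonafrican_cohorts:
                for v, ac, an, _ in t.rows:
                    non[v] = non.get(v, 0) + ac / an
            ancestral = [t.variant for t in study.truth
                         if t.arising_lineage is Lineage.ANCESTRAL]
            for v in ancestral:
                d_afr.append(afr.get(v, 0.0))
                d_non.append(non.get(v, 0.0))
        corr = np.corrcoef(d_afr, d_non)[0, 1]
        # split frequency is a shared ancestor, so modest positive correlation
        # is expected overall; it must not approach 1
        assert corr < 0.9


class TestEpochRecovery:
    def _truth(self, spec):
        out = []
        for i, lineage in enumerate(spec):
            v = normalize_variant("1", i + 1, "A", "G")
            out.append(TruthRecord(v, 100, lineage, 3000))
        return out

    def test_hand_built_confusion_matrix(self):
        lineages = [Lineage.NONAFRICAN_BRANCH, Lineage.NONAFRICAN_BRANCH,
                    Lineage.ANCESTRAL, Lineage.ANCESTRAL,
                    Lineage.ANCESTRAL, Lineage.NONAFRICAN_BRANCH]
        truth = self._truth(lineages)
        v = [t.variant for t in truth]
        patterns = {v[0]: SharingPattern.NONAFRICAN_ONLY,
                    v[1]: SharingPattern.UNSHARED,
                    v[2]: SharingPattern.BOTH,
                    v[3]: SharingPattern.AFRICAN_ONLY,
                    v[4]: SharingPattern.NONAFRICAN_ONLY,
                    v[5]: SharingPattern.NONAFRICAN_ONLY}
        confusion, accuracy = evaluate_epoch_recovery(truth, patterns)
        assert confusion[Lineage.NONAFRICAN_BRANCH][SharingPattern.NONAFRICAN_ONLY] == 2
        assert confusion[Lineage.NONAFRICAN_BRANCH][SharingPattern.UNSHARED] == 1
        assert confusion[Lineage.ANCESTRAL][SharingPattern.BOTH] == 1
        assert confusion[Lineage.ANCESTRAL][SharingPattern.AFRICAN_ONLY] == 1
        assert confusion[Lineage.ANCESTRAL][SharingPattern.NONAFRICAN_ONLY] == 1
        # correct: v0, v5 (non-African), v2, v3 (ancestral) -> 4 of 6
        assert accuracy == pytest.approx(4 / 6)

    def test_single_ancestral_variant_in_both_cohorts(self):
        truth = self._truth([Lineage.ANCESTRAL])
        v = truth[0].variant
        patterns = classify_with_ancient([v], {v}, {v})
        _, accuracy = evaluate_epoch_recovery(truth, patterns)
        assert accuracy == 1.0

    def test_unknown_variant_is_consistency_error(self):
        with pytest.raises(ConfigurationError):
            evaluate_epoch_recovery([], {normalize_variant("1", 1, "A", "G"):
                                         SharingPattern.BOTH})

    def test_idealized_regime_recovers_every_epoch(self):
        # entry frequency held high and sizes huge: drift loss negligible,
        # cohorts exhaustive, so classification equals true epoch
        params = SimulationParams(
            seed=11, mutation_rate=0.05, init_frequency=0.2,
            n_ancestral=200_000, n_founders=200_000, ancestral_generations=200,
            african_sizes=((60_000, 200_000),),
            nonafrican_sizes=((60_000, 200_000),),
            ancient_sampling=((1000, 10, 0.0), (5000, 10, 0.0)))
        study = simulate_study(params)
        patterns = classify_study(study)
        assert len(patterns) > 50
        _, accuracy = evaluate_epoch_recovery(study.truth, patterns)
        assert accuracy == 1.0

    def test_accuracy_improves_with_cohort_size_on_average(self):
        def mean_accuracy(scale: float) -> float:
            accs = []
            for seed in range(12):
                params = SimulationParams(
                    seed=seed,
                    african_cohort_size=max(int(2000 * scale), 2),
                    nonafrican_cohorts=(
                        ("European", max(int(5000 * scale), 2)),
                        ("EastAsian", max(int(3000 * scale), 2)),
                        ("SouthAsian", max(int(1200 * scale), 2))))
                study = simulate_study(params)
                _, acc = evaluate_epoch_recovery(study.truth, classify_study(study))
                accs.append(acc)
            return float(np.mean(accs))

        assert mean_accuracy(1.0) >= mean_accuracy(0.002)
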