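"""Duplication spectra, headline statistics, profiles, and two-sample tests."""

import numpy as np
import pytest

from rdnasim import (Locus, SimConfig, duplication_spectrum, initialize_population,
                     ks_two_sample, largest_block_by_activity, run_replicate,
                     segment_profiles, spearman, summarize_final_state,
                     summarize_population, unequal_crossover)
from rdnasim.fixtures import (EMPIRICAL_TRUNCATION_SPECTRUM,
                              empirical_truncation_spectrum)
from rdnasim.summaries import DuplicationSpectrum, population_records


def brute_force_ks(x, y):
    grid = np.unique(np.concatenate([x, y]))
    best = 0.0
    for g in grid:
        d = abs(np.mean(x <= g) - np.mean(y <= g))
        best = max(best, d)
    return best


def brute_force_spearman(x, y):
    def average_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = np.asarray(v)[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2 + 1
            i = j
        return ranks
    rx, ry = average_ranks(x), average_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestDuplicationSpectrum:
    def test_packaged_empirical_spectrum(self):
        spec = DuplicationSpectrum(EMPIRICAL_TRUNCATION_SPECTRUM)
        assert spec.n_lineages == 386
        assert spec.fraction_single == pytest.approx(0.868, abs=5e-4)
        assert empirical_truncation_spectrum().counts == spec.counts

    def test_unique_labels_all_single(self, rng):
        loci = [Locus(np.arange(i * 20 + 1, i * 20 + 11, dtype=np.int64))
                for i in range(5)]
        spec = duplication_spectrum(loci)
        assert spec.fraction_single == 1.0
        assert spec.counts == {1: 50}

    def test_forced_crossover_duplication_hand_count(self):
        # duplicate the two lineages inside a 2-unit offset window
        codes = np.zeros(10, dtype=np.int64)
        codes[3], codes[4] = 7, 8
        codes[0], codes[8] = 1, 2
        A = Locus(codes)
        _, long_product = unequal_crossover(A, A, 3, 5)
        spec = duplication_spectrum([long_product])
        assert spec.counts == {1: 2, 2: 2}

    def test_copy_total_invariant(self, rng):
        from conftest import random_locus

        loci = []
        for i in range(8):
            base = random_locus(rng, 30, frac=0.4, label_start=100 * i)
            loci.append(unequal_crossover(base, base, 5, 9)[1])
        spec = duplication_spectrum(loci)
        total = sum(k * v for k, v in spec.counts.items())
        assert total == sum(loc.n_inserted for loc in loci)

    def test_truncated_only_restriction(self):
        loc = Locus(np.array([5, -6, 0, -7, 0], dtype=np.int64))
        spec = duplication_spectrum([loc], restrict="truncated_only")
        assert spec.counts == {1: 2}

    def test_sample_loci_mirrors_line_panel(self, rng):
        loci = [Locus(np.arange(i * 10 + 1, i * 10 + 6, dtype=np.int64))
                for i in range(30)]
        spec = duplication_spectrum(loci, sample_loci=18, rng=0)
        assert spec.n_lineages == 18 * 5


class TestSummarizeFinalState:
    def test_hand_built_population(self, rng):
        cfg = SimConfig(n_individuals=4, generations=5,
                        initial_locus_size=60, initial_insertion_fraction=0.2)
        pop = initialize_population(cfg, rng)
        stats = summarize_population(pop, domain_size=40)
        assert stats["mean_locus_size"] == 60.0
        assert stats["mean_r2_per_locus"] == 12.0
        assert stats["n_loci"] == 6
        assert stats["fraction_single_copy"] == 1.0

    def test_r2_free_population(self, rng):
        cfg = SimConfig(n_individuals=4, generations=5,
                        initial_insertion_fraction=0.0)
        pop = initialize_population(cfg, rng)
        stats = summarize_population(pop, domain_size=40)
        assert stats["fraction_active"] == 0.0
        assert stats["mean_r2_per_locus"] == 0.0

    def test_replicate_result_summary(self, small_config):
        res = run_replicate(small_config, 0)
        stats = summarize_final_state(res)
        assert stats["n_loci"] == 150
        assert 0 <= stats["fraction_active_males"] <= 1
        assert stats["mean_locus_size"] == pytest.approx(
            res.records["locus_size"].mean())


class TestLargestBlockByActivity:
    def test_uninserted_population_all_inactive(self, rng):
        cfg = SimConfig(n_individuals=6, generations=5,
                        initial_locus_size=80, initial_insertion_fraction=0.0)
        pop = initialize_population(cfg, rng)
        records = population_records(pop, domain_size=40)
        active, inactive = largest_block_by_activity(records)
        assert active.size == 0
        assert (inactive == 80).all()

    def test_constructed_active_locus_listed_active(self, rng):
        cfg = SimConfig(n_individuals=4, generations=5,
                        initial_locus_size=50, initial_insertion_fraction=0.4)
        pop = initialize_population(cfg, rng)
        records = population_records(pop, domain_size=40)
        active, inactive = largest_block_by_activity(records)
        assert active.size + inactive.size == 6
        # dense random loci: largest block far below the domain size
        assert records["largest_free_block"].max() < 40


class TestSegmentProfiles:
    def test_location_profile_sums_to_one_and_centers(self, rng):
        cfg = SimConfig(n_individuals=10, generations=5,
                        initial_insertion_fraction=0.0)
        pop = initialize_population(cfg, rng)
        records = population_records(pop, domain_size=40)
        profiles = segment_profiles(records)
        loc = profiles["domain_location"].values
        assert loc.sum() == pytest.approx(1.0, abs=1e-9)
        # uninserted loci center their domain: all mass in the middle bins
        assert loc[9] + loc[10] == pytest.approx(1.0)

    def test_insertion_profile_levels(self, rng):
        cfg = SimConfig(n_individuals=10, generations=5,
                        initial_insertion_fraction=0.2)
        pop = initialize_population(cfg, rng)
        records = population_records(pop, domain_size=40)
        loci = [pop.units[r, :pop.lengths[r]] for r in range(pop.n_chromosomes)]
        profiles = segment_profiles(records, loci)
        for key in ("insertion_active", "insertion_inactive"):
            vals = profiles[key].values
            assert ((vals >= 0) & (vals <= 1)).all()


class TestTwoSampleTests:
    def test_ks_identical_and_disjoint(self):
        x = np.arange(10.0)
        d, p = ks_two_sample(x, x)
        assert d == 0.0
        d, _ = ks_two_sample(x, x + 100.0)
        assert d == 1.0

    def test_ks_matches_brute_force_and_symmetry(self, rng):
        for _ in range(20):
            x = rng.normal(size=17)
            y = rng.normal(0.5, 1.3, size=23)
            d, _ = ks_two_sample(x, y)
            assert d == pytest.approx(brute_force_ks(x, y))
            assert d == pytest.approx(ks_two_sample(y, x)[0])

    def test_ks_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_spearman_perfect_and_reversed(self, rng):
        x = rng.normal(size=12)
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_spearman_matches_brute_force_with_ties(self, rng):
        x = np.array([3, 1, 4, 1, 5, 9, 2, 6, 5, 3], dtype=float)
        y = np.array([2, 7, 1, 8, 2, 8, 1, 8, 2, 8], dtype=float)
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(brute_force_spearman(x, y))

    def test_spearman_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])
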