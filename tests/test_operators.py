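"""Stochastic operators: samplers, crossovers, deletions, retrotransposition."""

import collections
import math

import numpy as np
import pytest
from scipy import stats

from rdnasim import (CrossoverSpec, DeletionSpec, InvalidCutError, LabelSource,
                     LocalizationSpec, Locus, RetroSpec, apply_ice,
                     apply_loop_deletion, apply_sce, place_domain,
                     retrotranspose, sample_position, sample_signed_offset,
                     unequal_crossover)

from conftest import random_locus


def label_multiset(*loci):
    out = collections.Counter()
    for loc in loci:
        out.update(loc.labels.tolist())
    return out


class TestSamplePosition:
    def test_degenerate_sigma_returns_rounded_center(self, rng):
        spec = LocalizationSpec(s=1e-12)
        for center in (3.0, 7.4, 12.6):
            got = sample_position(center, spec, 200, 0, 199, rng)
            assert got == int(math.floor(center + 0.5))

    def test_monte_carlo_spread_matches_locus_scaling(self, rng):
        spec = LocalizationSpec(s=0.1, scale="locus")
        draws = np.array([sample_position(0.0, spec, 200, -10_000, 10_000, rng)
                          for _ in range(30_000)])
        assert abs(draws.std() - 20.0) / 20.0 < 0.05

    def test_domain_scaled_spread(self, rng):
        spec = LocalizationSpec(s=0.4, scale="domain")
        draws = np.array([sample_position(0.0, spec, 500, -10_000, 10_000, rng,
                                          domain_size=40)
                          for _ in range(20_000)])
        assert abs(draws.std() - 16.0) / 16.0 < 0.05

    def test_always_within_bounds(self, rng):
        spec = LocalizationSpec(s=0.05)
        for _ in range(500):
            lo = int(rng.integers(0, 50))
            hi = lo + int(rng.integers(0, 50))
            got = sample_position(200.0, spec, 100, lo, hi, rng)
            assert lo <= got <= hi

    def test_tight_localization_stays_near_center(self, rng):
        spec = LocalizationSpec(s=0.05)
        L = 200
        sigma = 0.05 * L
        draws = [sample_position(100.0, spec, L, -10_000, 10_000, rng)
                 for _ in range(10_000)]
        within = np.mean([abs(d - 100.0) <= 3 * sigma for d in draws])
        assert within >= 0.985


class TestSignedOffset:
    def test_unit_offset_sign_balance(self, rng):
        draws = [sample_signed_offset(1, rng) for _ in range(10_000)]
        assert set(draws) == {-1, 1}
        assert abs(np.mean([d > 0 for d in draws]) - 0.5) < 0.02

    def test_magnitude_uniform_on_1_to_11(self, rng):
        draws = np.abs([sample_signed_offset(11, rng) for _ in range(100_000)])
        counts = np.bincount(draws, minlength=12)[1:]
        assert stats.chisquare(counts).pvalue > 0.001

    def test_zero_never_returned(self, rng):
        assert all(sample_signed_offset(3, rng) != 0 for _ in range(1000))


class TestUnequalCrossover:
    def test_three_unit_offset_duplicates_and_deletes_one_lineage(self):
        # sister chromatids offset by three units; the lineage wholly inside
        # the offset window is absent from the short product and doubled in
        # the long one
        L = 12
        codes = np.zeros(L, dtype=np.int64)
        codes[5] = 77  # element "c" inside the window [4, 7)
        A = Locus(codes)
        p_short, p_long = unequal_crossover(A, A, 4, 7)
        assert len(p_short) == L - 3 and len(p_long) == L + 3
        assert label_multiset(p_short)[77] == 0
        assert label_multiset(p_long)[77] == 2

    def test_zero_cuts_swap_inputs(self, rng):
        A = random_locus(rng, 9, frac=0.4)
        B = random_locus(rng, 6, frac=0.4, label_start=100)
        p1, p2 = unequal_crossover(A, B, 0, 0)
        assert p1 == B and p2 == A

    def test_exhaustive_conservation_small_loci(self, rng):
        """Total units and per-lineage copy totals conserved for all cuts."""
        for _ in range(20):
            La = int(rng.integers(1, 9))
            Lb = int(rng.integers(1, 9))
            A = random_locus(rng, La, frac=0.5)
            B = random_locus(rng, Lb, frac=0.5, label_start=50)
            before = label_multiset(A, B)
            for ca in range(La + 1):
                for cb in range(Lb + 1):
                    l1 = ca + (Lb - cb)
                    l2 = cb + (La - ca)
                    if l1 < 1 or l2 < 1:
                        with pytest.raises(InvalidCutError):
                            unequal_crossover(A, B, ca, cb)
                        continue
                    p1, p2 = unequal_crossover(A, B, ca, cb)
                    assert len(p1) + len(p2) == La + Lb
                    assert label_multiset(p1, p2) == before

    def test_invalid_cut_rejected(self):
        A = Locus.from_string("UU")
        with pytest.raises(InvalidCutError):
            unequal_crossover(A, A, 0, 2)  # first product would be empty


class TestApplySCE:
    def test_rate_zero_is_identity(self, rng):
        loc = random_locus(rng, 30, frac=0.3)
        spec = CrossoverSpec(sce_rate=0.0)
        pl = place_domain(loc, 10)
        assert apply_sce(loc, spec, pl, rng) == loc

    def test_forced_event_changes_length_symmetrically(self, rng):
        loc = random_locus(rng, 40, frac=0.2)
        spec = CrossoverSpec(sce_rate=1.0, max_offset=1)
        pl = place_domain(loc, 10)
        lengths = [len(apply_sce(loc, spec, pl, rng, force=True))
                   for _ in range(4000)]
        counts = collections.Counter(lengths)
        assert set(counts) == {39, 41}
        assert abs(counts[41] / 4000 - 0.5) < 0.04

    def test_mean_length_preserved_over_offsets(self, rng):
        loc = random_locus(rng, 60, frac=0.2)
        spec = CrossoverSpec(sce_rate=1.0, max_offset=11)
        pl = place_domain(loc, 20)
        lengths = [len(apply_sce(loc, spec, pl, rng, force=True))
                   for _ in range(6000)]
        assert abs(np.mean(lengths) - 60) < 0.35


class TestApplyICE:
    def test_rate_zero_is_identity(self, rng):
        A = random_locus(rng, 25, frac=0.3)
        B = random_locus(rng, 30, frac=0.3, label_start=60)
        spec = CrossoverSpec(ice_rate=0.0)
        pls = (place_domain(A, 20), place_domain(B, 20))
        assert apply_ice(A, B, spec, pls, rng) == (A, B)

    def test_forced_event_conserves_units_and_labels(self, rng):
        for _ in range(200):
            A = random_locus(rng, int(rng.integers(5, 40)), frac=0.4)
            B = random_locus(rng, int(rng.integers(5, 40)), frac=0.4,
                             label_start=500)
            spec = CrossoverSpec(ice_rate=1.0, max_offset=5)
            pls = (place_domain(A, 20), place_domain(B, 20))
            before = label_multiset(A, B)
            p1, p2 = apply_ice(A, B, spec, pls, rng, force=True)
            assert len(p1) + len(p2) == len(A) + len(B)
            assert label_multiset(p1, p2) == before
            assert len(p1) >= 1 and len(p2) >= 1


class TestLoopDeletion:
    def test_forced_fixed_size_deletion(self, rng):
        loc = random_locus(rng, 225, frac=0.2)
        spec = DeletionSpec()
        pl = place_domain(loc, 40)
        out = apply_loop_deletion(loc, spec, 0, pl, rng, force=True, size=3)
        assert len(out) == 222

    def test_mean_drawn_size_matches_uniform_1_to_30(self, rng):
        # large locus, domain-scaled midpoint far from the ends: no clipping
        loc = random_locus(rng, 500, frac=0.0)
        spec = DeletionSpec(max_size=30)
        pl = place_domain(loc, 40)
        removed = [500 - len(apply_loop_deletion(loc, spec, 0, pl, rng,
                                                 force=True))
                   for _ in range(20_000)]
        assert abs(np.mean(removed) - 15.5) < 0.3

    def test_single_unit_locus_never_deleted(self, rng):
        loc = Locus.from_string("U")
        spec = DeletionSpec(base_rate_per_unit=1.0)
        pl = place_domain(loc, 40)
        for _ in range(100):
            assert len(apply_loop_deletion(loc, spec, 0, pl, rng, force=True)) == 1


class TestRetrotranspose:
    def _one_fl_locus(self):
        codes = np.zeros(41, dtype=np.int64)
        codes[20] = 1  # one full-length element at the domain center
        loc = Locus(codes)
        return loc, place_domain(loc, 40)

    def test_inactive_individuals_never_transpose(self, rng):
        loc = Locus.from_string("U" * 50)
        pl = place_domain(loc, 40)
        out, = retrotranspose([(loc, pl)], RetroSpec(), rng, LabelSource())
        assert out == loc

    def test_event_rate_single_element(self, rng):
        loc, pl = self._one_fl_locus()
        spec = RetroSpec(probability=0.18)
        labels = LabelSource()
        total = 0
        n = 30_000
        for _ in range(n):
            out, = retrotranspose([(loc, pl)], spec, rng, labels)
            total += out.n_inserted - 1
        mean = total / n
        assert abs(mean - 0.18) / 0.18 < 0.05

    def test_truncation_fraction_of_new_copies(self, rng):
        loc, pl = self._one_fl_locus()
        spec = RetroSpec(truncation_fraction=0.5)
        labels = LabelSource()
        trunc = total = 0
        for _ in range(10_000):
            out, = retrotranspose([(loc, pl)], spec, rng, labels, n_events=1)
            trunc += out.n_truncated
            total += out.n_inserted - 1
        assert total == 10_000
        assert abs(trunc / total - 0.5) < 0.02

    def test_never_overwrites_existing_insertion(self, rng):
        loc = random_locus(rng, 12, frac=0.5)
        pl = place_domain(loc, 10)
        before = label_multiset(loc)
        out, = retrotranspose([(loc, pl)], RetroSpec(), rng, LabelSource(1000),
                              n_events=40)
        after = label_multiset(out)
        for lab, k in before.items():
            assert after[lab] == k
        assert out.n_inserted <= 12

    def test_female_pooling_targets_both_chromosomes(self, rng):
        locA, plA = self._one_fl_locus()
        locB = Locus.from_string("U" * 41)
        plB = place_domain(locB, 40)
        spec = RetroSpec()
        hits_b = 0
        for _ in range(2000):
            outs = retrotranspose([(locA, plA), (locB, plB)], spec, rng,
                                  LabelSource(10), n_events=1)
            hits_b += outs[1].n_inserted
        frac = hits_b / 2000
        assert abs(frac - 0.5) < 0.05
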