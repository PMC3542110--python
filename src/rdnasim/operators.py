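"""Stochastic operators on rDNA loci.

Unequal crossovers (sister-chromatid and interchromosomal), loop deletions,
retrotransposition, and the localized position sampling they share.  All
operators take an explicit :class:`numpy.random.Generator`; identical seeds
give identical trajectories.

Crossover geometry: cut positions are between-unit boundaries in ``[0, L]``.
Two arrays aligned with a signed offset of ``k`` units and cut at boundary
``cut_A`` (so ``cut_B = cut_A + k``) recombine into products of length
``L_A - k + (L_B - L_A)``-style sums; for identical sister chromatids the two
products are ``L - |k|`` and ``L + |k|`` units long, with any lineage lying
wholly inside the offset window deleted from the short product and duplicated
in the long one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import crossover_fill
from .locus import DomainPlacement, Locus, place_domain

_MAX_TRIES = 1000


class InvalidCutError(ValueError):
    """A crossover cut pair would produce an empty locus."""


@dataclass(frozen=True)
class LocalizationSpec:
    """Where within a locus an event lands.

    ``domain_centered``: Normal around the transcription-domain midpoint.
    ``locus_centered``: same kernel around ``L/2``.  ``uniform``: uniform
    over the allowed range.

    ``s`` is the dimensionless localization parameter; ``scale`` sets the
    length that multiplies it into a standard deviation in units.  Crossover
    cuts use ``scale='locus'`` (sigma = s * L: the s range spans cuts mostly
    within the domain up to cuts across the whole locus).  Insertions and
    loop deletions are domain-proximal events and use ``scale='domain'``
    (sigma = s * domain size), which keeps them anchored to the transcribed
    region whatever the locus length.
    """

    mode: str = "domain_centered"
    s: float = 0.05
    scale: str = "locus"

    def __post_init__(self):
        if self.mode not in ("domain_centered", "locus_centered", "uniform"):
            raise ValueError(f"unknown localization mode {self.mode!r}")
        if self.scale not in ("locus", "domain"):
            raise ValueError(f"unknown localization scale {self.scale!r}")
        if self.mode != "uniform" and not self.s > 0:
            raise ValueError("localization s must be > 0")

    def sigma(self, L: int, domain_size: int | None = None) -> float:
        """Standard deviation in units for a locus of length ``L``."""
        if self.scale == "domain" and domain_size is not None:
            return self.s * domain_size
        return self.s * L


@dataclass(frozen=True)
class CrossoverSpec:
    """Unequal-crossover rates and geometry (events/chromosome/generation)."""

    sce_rate: float = 0.2
    ice_rate: float = 0.0001
    max_offset: int = 11
    localization: LocalizationSpec = field(default_factory=LocalizationSpec)

    def __post_init__(self):
        if not (0.0 <= self.sce_rate <= 1.0 and 0.0 <= self.ice_rate <= 1.0):
            raise ValueError("crossover rates must be in [0, 1]")
        if self.max_offset < 1:
            raise ValueError("max_offset must be >= 1")


@dataclass(frozen=True)
class DeletionSpec:
    """Loop-deletion parameters.

    Per-chromosome event probability is ``base_rate_per_unit * L`` plus
    ``element_induced_rate`` per full-length R2 inside the transcription
    domain (R2 activity raises the deletion rate), capped at 1.  Deletion
    size is uniform on ``1..max_size`` units.
    """

    base_rate_per_unit: float = 0.00007
    element_induced_rate: float = 0.0065
    max_size: int = 30
    localization: LocalizationSpec = field(
        default_factory=lambda: LocalizationSpec(s=0.2, scale="domain"))

    def __post_init__(self):
        if self.base_rate_per_unit < 0 or self.element_induced_rate < 0:
            raise ValueError("deletion rates must be >= 0")
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")


@dataclass(frozen=True)
class RetroSpec:
    """Retrotransposition parameters.

    Per individual per generation the expected number of new insertions is
    ``probability * sqrt(n_full_length_in_domain)``; each new copy is
    dead-on-arrival (truncated) with ``truncation_fraction``.
    """

    probability: float = 0.18
    truncation_fraction: float = 0.5
    localization: LocalizationSpec = field(
        default_factory=lambda: LocalizationSpec(s=0.4, scale="domain"))

    def __post_init__(self):
        if self.probability < 0:
            raise ValueError("probability must be >= 0")
        if not 0.0 <= self.truncation_fraction <= 1.0:
            raise ValueError("truncation_fraction must be in [0, 1]")


class LabelSource:
    """Monotonic source of unique lineage labels."""

    def __init__(self, start: int = 0):
        self._next = int(start)

    def next_label(self) -> int:
        self._next += 1
        return self._next

    @property
    def last(self) -> int:
        return self._next


def sample_position(center, spec: LocalizationSpec, L, lo, hi, rng,
                    domain_size: int | None = None) -> int:
    """Sample an integer position in ``[lo, hi]`` localized around ``center``.

    Normal modes draw from Normal(center, sigma) with sigma = ``s * L`` for
    locus-scaled specs or ``s * domain_size`` for domain-scaled ones, round
    to the nearest integer, and resample out-of-range draws up to 1000 times
    before clamping the rounded center into range; uniform mode draws
    uniformly on ``[lo, hi]``.
    """
    if lo > hi:
        raise ValueError("empty position range")
    if spec.mode == "uniform":
        return int(rng.integers(lo, hi + 1))
    if spec.mode == "locus_centered":
        center = L / 2.0
    sigma = spec.sigma(L, domain_size)
    for _ in range(_MAX_TRIES):
        p = int(math.floor(rng.normal(center, sigma) + 0.5))
        if lo <= p <= hi:
            return p
    p = int(math.floor(center + 0.5))
    return min(max(p, lo), hi)


def sample_signed_offset(max_offset: int, rng) -> int:
    """Signed crossover offset: |k| uniform on 1..max_offset, sign fair."""
    if max_offset < 1:
        raise ValueError("max_offset must be >= 1")
    k = int(rng.integers(1, max_offset + 1))
    return k if rng.random() < 0.5 else -k


def unequal_crossover(A: Locus, B: Locus, cut_A: int, cut_B: int) -> tuple[Locus, Locus]:
    """Recombine two aligned arrays at boundary cuts ``cut_A`` / ``cut_B``.

    Returns ``(A[:cut_A] + B[cut_B:], B[:cut_B] + A[cut_A:])``.  The unit
    multiset (lineage labels included) of the two products equals that of the
    two inputs.  Raises :class:`InvalidCutError` if a product would be empty.
    """
    La, Lb = len(A), len(B)
    if not (0 <= cut_A <= La and 0 <= cut_B <= Lb):
        raise InvalidCutError("cut outside locus")
    l1 = cut_A + (Lb - cut_B)
    l2 = cut_B + (La - cut_A)
    if l1 < 1 or l2 < 1:
        raise InvalidCutError("crossover product would be empty")
    out1 = np.empty(l1, dtype=np.int64)
    out2 = np.empty(l2, dtype=np.int64)
    crossover_fill(A.codes, La, B.codes, Lb, cut_A, cut_B, out1, out2)
    return Locus(out1), Locus(out2)


def _crossover_center(spec: CrossoverSpec, placement: DomainPlacement, L: int) -> float:
    if spec.localization.mode == "locus_centered":
        return L / 2.0
    return placement.center


def apply_sce(locus: Locus, spec: CrossoverSpec, placement: DomainPlacement, rng,
              force: bool = False) -> Locus:
    """Sister-chromatid exchange: unequal crossover between identical copies.

    With probability ``sce_rate`` the locus is duplicated, the copies are
    aligned with a random signed offset ``k``, cut at a localized boundary,
    and one of the two products (lengths ``L - |k|`` and ``L + |k|``) is
    transmitted with probability 1/2.  Otherwise the locus is returned
    unchanged.  ``force=True`` makes the event certain (for testing).

    In the population lifecycle this operator is applied per transmitted
    gamete: each meiosis is an independent post-replication exchange
    opportunity, so two gametes copied from the same chromosome may carry
    different products.
    """
    if not force and rng.random() >= spec.sce_rate:
        return locus
    L = len(locus)
    k = sample_signed_offset(spec.max_offset, rng)
    if abs(k) >= L:
        return locus  # offset cannot fit; event skipped
    # cut_B = cut_A + k must lie in [0, L]
    lo, hi = max(0, -k), min(L, L - k)
    center = _crossover_center(spec, placement, L)
    cut_a = sample_position(center, spec.localization, L, lo, hi, rng)
    p1, p2 = unequal_crossover(locus, locus, cut_a, cut_a + k)
    return p1 if rng.random() < 0.5 else p2


def apply_ice(locusA: Locus, locusB: Locus, spec: CrossoverSpec,
              placements: tuple[DomainPlacement, DomainPlacement], rng,
              force: bool = False) -> tuple[Locus, Locus]:
    """Interchromosomal exchange between the two X-linked loci of a female.

    With probability ``ice_rate`` the loci are aligned at their domain
    midpoints, shifted by a random signed offset, cut at a localized
    boundary, and both crossover products replace the pair.
    """
    if not force and rng.random() >= spec.ice_rate:
        return locusA, locusB
    La, Lb = len(locusA), len(locusB)
    pa, pb = placements
    for _ in range(_MAX_TRIES):
        k = sample_signed_offset(spec.max_offset, rng)
        shift = int(math.floor(pb.center - pa.center + 0.5)) + k
        if 1 - La < shift < Lb:  # both products nonempty
            break
    else:
        return locusA, locusB  # no valid alignment found; event skipped
    lo, hi = max(0, -shift), min(La, Lb - shift)
    center = _crossover_center(spec, pa, La)
    cut_a = sample_position(center, spec.localization, La, lo, hi, rng)
    return unequal_crossover(locusA, locusB, cut_a, cut_a + shift)


def apply_loop_deletion(locus: Locus, spec: DeletionSpec, n_full_in_domain: int,
                        placement: DomainPlacement, rng, force: bool = False,
                        size: int | None = None) -> Locus:
    """Intrachromosomal loop deletion of a contiguous block of units.

    Event probability is ``min(1, base_rate_per_unit * L +
    element_induced_rate * n_full_in_domain)``.  On an event the size is
    uniform on ``1..max_size``, the segment midpoint is localized around the
    domain center, the segment is clipped to the locus, and the deletion is
    applied only if at least one unit would remain.
    """
    L = len(locus)
    if not force:
        p = min(1.0, spec.base_rate_per_unit * L + spec.element_induced_rate * n_full_in_domain)
        if rng.random() >= p:
            return locus
    if size is None:
        size = int(rng.integers(1, spec.max_size + 1))
    mid = sample_position(placement.center, spec.localization, L, 0, L - 1,
                          rng, domain_size=placement.size)
    start = max(0, mid - size // 2)
    end = min(L, start + size)
    if L - (end - start) < 1:
        return locus
    return Locus(np.concatenate([locus.codes[:start], locus.codes[end:]]))


def retrotranspose(individual_loci, spec: RetroSpec, rng, label_source: LabelSource,
                   n_events: int | None = None):
    """Insert new R2 copies into an individual's locus/loci.

    ``individual_loci`` is a list of ``(Locus, DomainPlacement)`` pairs (one
    for a male, two for a female).  The number of events is Poisson with mean
    ``probability * sqrt(n_FL)`` where ``n_FL`` is the individual's total
    full-length count inside its domain(s); each event targets a uniformly
    chosen chromosome, is truncated with ``truncation_fraction``, and lands
    on a localized uninserted unit (up to 1000 tries, else the event is
    dropped — an existing insertion is never overwritten).

    Returns the updated list of loci (placements unchanged).
    """
    from ._kernels import domain_counts

    loci = [loc.copy() for loc, _ in individual_loci]
    placements = [pl for _, pl in individual_loci]
    if n_events is None:
        n_fl = 0
        for loc, pl in zip(loci, placements):
            n_fl += domain_counts(loc.codes, pl.start, pl.size)[0]
        n_events = int(rng.poisson(spec.probability * math.sqrt(n_fl))) if n_fl > 0 else 0
    for _ in range(n_events):
        c = int(rng.integers(0, len(loci)))
        loc, pl = loci[c], placements[c]
        L = len(loc)
        for _ in range(_MAX_TRIES):
            pos = sample_position(pl.center, spec.localization, L, 0, L - 1,
                                  rng, domain_size=pl.size)
            if loc.codes[pos] == 0:
                label = label_source.next_label()
                truncated = rng.random() < spec.truncation_fraction
                loc.codes[pos] = -label if truncated else label
                break
    return loci


def place_all(loci, domain_size: int):
    """Convenience: place the domain on each locus; returns placement list."""
    return [place_domain(loc, domain_size) for loc in loci]
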