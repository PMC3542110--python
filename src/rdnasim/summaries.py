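"""End-state and comparative statistics.

Duplication spectra (within-locus copy number of each R2 lineage), the four
headline equilibrium statistics, activity-stratified largest-free-block
lists, 20-segment domain-location and insertion profiles, and the two-sample
tests (Kolmogorov-Smirnov, Spearman) used for empirical comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .locus import Locus


@dataclass(frozen=True)
class DuplicationSpectrum:
    """Within-locus copy-number spectrum of R2 lineages, pooled over loci.

    ``counts[k]`` is the number of (locus, lineage) groups in which the
    lineage is present in ``k`` copies in that locus.  A lineage present in
    more than one copy within a locus was duplicated by unequal crossover.
    """

    counts: dict

    @property
    def n_lineages(self) -> int:
        return sum(self.counts.values())

    @property
    def n_elements(self) -> int:
        return sum(k * v for k, v in self.counts.items())

    @property
    def fraction_single(self) -> float:
        n = self.n_lineages
        return self.counts.get(1, 0) / n if n else float("nan")

    def fraction_at_least(self, copies: int) -> float:
        """Fraction of lineages at within-locus copy number >= ``copies``."""
        n = self.n_lineages
        if not n:
            return float("nan")
        return sum(v for k, v in self.counts.items() if k >= copies) / n


def _iter_code_rows(loci):
    for loc in loci:
        if isinstance(loc, Locus):
            yield loc.codes
        else:
            yield np.asarray(loc, dtype=np.int64)


def duplication_spectrum(loci, restrict: str = "all",
                         sample_loci: int | None = None,
                         rng=None) -> DuplicationSpectrum:
    """Tabulate within-locus copy numbers of R2 lineages over a locus pool.

    ``restrict='truncated_only'`` scores only 5'-truncated copies, mirroring
    the PCR truncation assay used on fly lines; ``sample_loci`` optionally
    subsamples that many loci (e.g. 18) to match an empirical line panel.
    """
    if restrict not in ("all", "truncated_only"):
        raise ValueError("restrict must be 'all' or 'truncated_only'")
    rows = list(_iter_code_rows(loci))
    if not rows:
        raise ValueError("need at least one locus")
    if sample_loci is not None and sample_loci < len(rows):
        rng = np.random.default_rng(rng)
        idx = rng.choice(len(rows), size=sample_loci, replace=False)
        rows = [rows[i] for i in idx]
    counts: dict[int, int] = {}
    for codes in rows:
        if restrict == "truncated_only":
            labels = -codes[codes < 0]
        else:
            labels = np.abs(codes[codes != 0])
        if labels.size == 0:
            continue
        _, mult = np.unique(labels, return_counts=True)
        for m in mult:
            counts[int(m)] = counts.get(int(m), 0) + 1
    return DuplicationSpectrum(counts)


def summarize_final_state(source) -> dict:
    """The headline equilibrium statistics from a final population.

    ``source`` is a :class:`~rdnasim.population.ReplicateResult` or a
    :class:`~rdnasim.population.Population`.  R2 activity uses the
    full-length-in-domain definition (a truncated-only domain does not make
    an individual retrotransposition-competent); female activity pools her
    two half-size domains.
    """
    records, loci = _records_and_loci(source)
    spec = duplication_spectrum(loci)
    by_ind = records.groupby("individual").agg(
        sex=("sex", "first"), active=("active", "any"))
    frac_by_sex = by_ind.groupby("sex")["active"].mean()
    return {
        "mean_locus_size": float(records["locus_size"].mean()),
        "mean_r2_per_locus": float(records["n_r2"].mean()),
        "mean_full_length_per_locus": float(records["n_full"].mean()),
        "fraction_single_copy": spec.fraction_single,
        "fraction_active": float(by_ind["active"].mean()),
        "fraction_active_males": float(frac_by_sex.get("male", float("nan"))),
        "fraction_active_females": float(frac_by_sex.get("female", float("nan"))),
        "n_loci": int(len(records)),
        "spectrum": spec.counts,
        "locus_size_values": records["locus_size"].to_numpy(),
        "r2_number_values": records["n_r2"].to_numpy(),
    }


def _records_and_loci(source):
    from .population import ReplicateResult

    if isinstance(source, ReplicateResult):
        loci = [source.final_units[r, :source.final_lengths[r]]
                for r in range(len(source.final_lengths))]
        return source.records, loci
    raise TypeError(
        "pass a ReplicateResult (use summarize_population() for a live "
        f"Population), got {type(source).__name__}")


def population_records(population, domain_size: int) -> pd.DataFrame:
    """Per-locus end-state records for a live population."""
    from . import engine
    from .population import _records_frame

    mat = engine.final_state_records(
        population.units, population.lengths, population.n_females,
        population.n_males, domain_size, max(1, domain_size // 2))
    return _records_frame(mat)


def summarize_population(population, domain_size: int) -> dict:
    """As :func:`summarize_final_state`, from a live population."""
    records = population_records(population, domain_size)
    loci = [population.units[r, :population.lengths[r]]
            for r in range(population.n_chromosomes)]
    spec = duplication_spectrum(loci)
    by_ind = records.groupby("individual").agg(
        sex=("sex", "first"), active=("active", "any"))
    frac_by_sex = by_ind.groupby("sex")["active"].mean()
    return {
        "mean_locus_size": float(records["locus_size"].mean()),
        "mean_r2_per_locus": float(records["n_r2"].mean()),
        "mean_full_length_per_locus": float(records["n_full"].mean()),
        "fraction_single_copy": spec.fraction_single,
        "fraction_active": float(by_ind["active"].mean()),
        "fraction_active_males": float(frac_by_sex.get("male", float("nan"))),
        "fraction_active_females": float(frac_by_sex.get("female", float("nan"))),
        "n_loci": int(len(records)),
        "spectrum": spec.counts,
        "locus_size_values": records["locus_size"].to_numpy(),
        "r2_number_values": records["n_r2"].to_numpy(),
    }


def largest_block_by_activity(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Largest R2-free block per locus, split by R2 activity.

    Returns ``(active, inactive)`` arrays of block sizes.  With a 40-unit
    male domain, inactive loci cluster at blocks >= the domain size (the
    boundary is soft because truncated copies and the pooled female domains
    blur it).
    """
    active = records.loc[records["active"], "largest_free_block"].to_numpy()
    inactive = records.loc[~records["active"], "largest_free_block"].to_numpy()
    return active, inactive


@dataclass(frozen=True)
class SegmentProfile:
    """Per-bin values over 20 equal-size segments of each locus."""

    values: np.ndarray

    def __post_init__(self):
        if np.asarray(self.values).shape != (20,):
            raise ValueError("a segment profile has exactly 20 bins")


def segment_profiles(records: pd.DataFrame, loci=None) -> dict:
    """Twenty-segment profiles of domain location and insertion frequency.

    Each locus is divided into 20 equal segments (the last absorbs the
    remainder).  The location profile is the fraction of transcription
    domains whose midpoint falls in each segment (sums to 1).  When raw
    ``loci`` are given, per-segment insertion frequencies are also computed,
    stratified by activity.
    """
    loc_hist = np.zeros(20, dtype=float)
    sizes = records["locus_size"].to_numpy()
    mids = records["domain_start"].to_numpy() + (records["domain_size"].to_numpy() - 1) / 2.0
    bins = np.minimum((20 * mids / sizes).astype(int), 19)
    for b in bins:
        loc_hist[b] += 1
    out = {"domain_location": SegmentProfile(loc_hist / loc_hist.sum())}

    if loci is not None:
        rows = list(_iter_code_rows(loci))
        active_mask = records["active"].to_numpy()
        for name, keep in (("insertion_active", active_mask),
                           ("insertion_inactive", ~active_mask)):
            acc = np.zeros(20)
            n = 0
            for r, use in zip(rows, keep):
                if not use:
                    continue
                L = r.size
                seg = np.minimum((20 * np.arange(L) / L).astype(int), 19)
                ins = (r != 0).astype(float)
                frac = np.zeros(20)
                for b in range(20):
                    m = seg == b
                    frac[b] = ins[m].mean() if m.any() else 0.0
                acc += frac
                n += 1
            out[name] = SegmentProfile(acc / n if n else acc)
    return out


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (D statistic, asymptotic p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = _sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    res = _sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
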