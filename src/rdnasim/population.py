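"""Population lifecycle: initialization, generation stepping, replicates, sweeps.

The population is sexed with X-linked rDNA: every female carries two rDNA
loci, every male one, at a fixed even sex ratio.  Females place a half-size
transcription domain on each of their two loci and pool both domains for
fitness and retrotransposition.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import engine
from .config import ConfigurationError, SimConfig
from .locus import Locus, place_domain


@dataclass
class Individual:
    """A sexed carrier of one (male) or two (female) X-linked rDNA loci."""

    sex: str
    loci: list

    def __post_init__(self):
        need = 2 if self.sex == "female" else 1
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        if len(self.loci) != need:
            raise ValueError(f"a {self.sex} must carry {need} loci")


class Population:
    """All chromosomes of one generation, in the padded engine layout.

    Rows ``2i`` and ``2i+1`` are the two loci of female ``i``; row
    ``2*n_females + j`` is the single locus of male ``j``.
    """

    def __init__(self, units: np.ndarray, lengths: np.ndarray, n_females: int,
                 n_males: int, label_counter: int):
        self.units = units
        self.lengths = lengths
        self.n_females = n_females
        self.n_males = n_males
        self.label_counter = label_counter

    @property
    def n_individuals(self) -> int:
        return self.n_females + self.n_males

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_females + self.n_males

    def locus(self, row: int) -> Locus:
        return Locus(self.units[row, :self.lengths[row]].copy())

    def loci(self) -> list:
        return [self.locus(r) for r in range(self.n_chromosomes)]

    def individual(self, i: int) -> Individual:
        if i < self.n_females:
            return Individual("female", [self.locus(2 * i), self.locus(2 * i + 1)])
        j = i - self.n_females
        return Individual("male", [self.locus(2 * self.n_females + j)])

    def individuals(self):
        return [self.individual(i) for i in range(self.n_individuals)]

    def total_r2(self) -> int:
        n = 0
        for r in range(self.n_chromosomes):
            n += int(np.count_nonzero(self.units[r, :self.lengths[r]]))
        return n

    def ensure_capacity(self, headroom: int = 64) -> None:
        """Grow the padded matrix so crossovers cannot overflow it."""
        need = 2 * int(self.lengths.max()) + headroom
        if need > self.units.shape[1]:
            cap = max(need, int(self.units.shape[1] * 1.5))
            grown = np.zeros((self.units.shape[0], cap), dtype=np.int64)
            for r in range(self.n_chromosomes):
                grown[r, :self.lengths[r]] = self.units[r, :self.lengths[r]]
            self.units = grown


@dataclass
class GenerationSummary:
    """Thinned per-generation summary row."""

    generation: int
    mean_locus_size: float
    mean_r2_per_locus: float
    mean_full_length_per_locus: float
    fraction_active_males: float
    fraction_active_females: float
    r2_extinct: bool


@dataclass
class ReplicateResult:
    """End state and time series of one replicate."""

    config: SimConfig
    replicate_index: int
    seed: int
    series: pd.DataFrame
    records: pd.DataFrame
    final_units: np.ndarray
    final_lengths: np.ndarray
    r2_extinct: bool
    bottlenecks: int = 0
    skipped_crossovers: int = 0

    def final_loci(self) -> list:
        return [Locus(self.final_units[r, :self.final_lengths[r]].copy())
                for r in range(len(self.final_lengths))]


class PopulationExtinctError(RuntimeError):
    """The gamete pool was empty: no individual produced any gametes."""


def initialize_population(config: SimConfig, rng) -> Population:
    """Found the population: equal sexes, identical-size random loci.

    Every locus starts at ``initial_locus_size`` units with
    ``floor(initial_insertion_fraction * L)`` units inserted at distinct
    uniformly random positions; each founder insertion gets a unique lineage
    label and is truncated with ``initial_truncation_fraction``.
    """
    config.validate()
    n_f = config.n_individuals // 2
    n_m = config.n_individuals - n_f
    R = 2 * n_f + n_m
    L0 = config.initial_locus_size
    n_ins = int(math.floor(config.initial_insertion_fraction * L0))
    cap = max(256, 2 * L0 + 64)
    units = np.zeros((R, cap), dtype=np.int64)
    lengths = np.full(R, L0, dtype=np.int64)
    label = 0
    for r in range(R):
        if n_ins:
            pos = rng.choice(L0, size=n_ins, replace=False)
            for p in pos:
                label += 1
                trunc = rng.random() < config.initial_truncation_fraction
                units[r, p] = -label if trunc else label
    return Population(units, lengths, n_f, n_m, label)


def gamete_count(individual: Individual, config: SimConfig, placements=None) -> int:
    """Gametes contributed by one individual (fecundity as linear fitness).

    Domain mode: ``u`` uninserted units summed over the individual's placed
    domain(s); gametes = ``round(max_gametes * min(1, u / required))`` with
    halves rounded away from zero.  Legacy modes use total uninserted units
    in the individual's loci against the whole-locus requirement.
    """
    if config.mode == "domain":
        if placements is None:
            D = config.female_domain_size if individual.sex == "female" else config.domain_size
            placements = [place_domain(loc, D) for loc in individual.loci]
        u = 0
        for loc, pl in zip(individual.loci, placements):
            window = loc.codes[pl.start:pl.start + pl.size]
            u += int(np.count_nonzero(window == 0))
        req = config.fitness_units_required
    else:
        u = sum(int(np.count_nonzero(loc.codes == 0)) for loc in individual.loci)
        req = config.legacy_fitness_units_required
    frac = 1.0 if req == 0 else min(1.0, u / req)
    return int(math.floor(config.max_gametes * frac + 0.5))


def _series_frame(rows: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=list(engine.SERIES_COLUMNS))
    df["generation"] = df["generation"].astype(int)
    df["r2_extinct"] = df["r2_extinct"] > 0.5
    return df


def _records_frame(mat: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(mat, columns=list(engine.RECORD_COLUMNS))
    df["sex"] = np.where(df["sex_code"] == 0, "female", "male")
    df["active"] = df["n_full_in_domain"] > 0
    df["n_r2"] = df["n_full"] + df["n_trunc"]
    return df.drop(columns=["sex_code"])


def _advance(pop: Population, config: SimConfig, n_gen: int, gen0: int,
             total_gens: int):
    """Run the kernel for one chunk; returns (series_rows, bottlenecks, skipped)."""
    pop.ensure_capacity()
    cap = pop.units.shape[1]
    buf_units = np.zeros_like(pop.units)
    buf_lengths = np.zeros_like(pop.lengths)
    max_rec = n_gen // config.record_every + 2
    out_series = np.zeros((max_rec, len(engine.SERIES_COLUMNS)), dtype=np.float64)
    label, status, n_rec, bn, sk = engine.run_generations(
        pop.units, pop.lengths, buf_units, buf_lengths,
        pop.n_females, pop.n_males, n_gen, gen0, total_gens,
        engine.MODE_CODES[config.mode],
        config.domain_size, config.female_domain_size,
        config.fitness_units_required, config.max_gametes,
        config.sce_rate, config.ice_rate, config.crossover_max_offset,
        config.crossover_s,
        config.deletion_rate_per_unit, config.element_deletion_rate,
        config.deletion_max_size, config.deletion_s,
        config.retro_probability, config.truncation_fraction, config.retro_s,
        config.legacy_retro_probability, config.legacy_fitness_units_required,
        pop.label_counter, config.record_every, out_series)
    pop.label_counter = int(label)
    if status == engine.STATUS_POP_EXTINCT:
        raise PopulationExtinctError(
            "gamete pool empty: every individual had zero fitness")
    return out_series[:n_rec], int(bn), int(sk)


def step_generation(population: Population, config: SimConfig, rng) -> Population:
    """Advance the population by exactly one generation (in place).

    A 31-bit engine seed is drawn from ``rng``, so an identical generator
    state reproduces the generation exactly.
    """
    engine.seed_engine(int(rng.integers(0, 2**31)))
    _advance(population, config, 1, 0, config.generations)
    return population


def replicate_seed(master_seed: int, replicate_index: int) -> int:
    """Deterministic 31-bit engine seed for (master seed, replicate index)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate_index,))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


_CHUNK = 200  # generations per kernel call (capacity re-checked between calls)


def run_replicate(config: SimConfig, replicate_index: int = 0) -> ReplicateResult:
    """Run one full replicate: G generations from a fresh founder population.

    The replicate's random stream is derived from ``(config.seed,
    replicate_index)``; identical inputs give bit-identical trajectories.
    """
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(replicate_index,))
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    pop = initialize_population(config, init_rng)
    eng_seed = replicate_seed(config.seed, replicate_index)
    engine.seed_engine(eng_seed)

    series_parts = []
    bottlenecks = 0
    skipped = 0
    done = 0
    G = config.generations
    while done < G:
        step = min(_CHUNK, G - done)
        rows, bn, sk = _advance(pop, config, step, done, G)
        series_parts.append(rows)
        bottlenecks += bn
        skipped += sk
        done += step
    series = _series_frame(np.concatenate(series_parts, axis=0))
    rec_mat = engine.final_state_records(
        pop.units, pop.lengths, pop.n_females, pop.n_males,
        config.domain_size, config.female_domain_size)
    records = _records_frame(rec_mat)
    records.insert(0, "replicate", replicate_index)
    max_len = int(pop.lengths.max())
    return ReplicateResult(
        config=config,
        replicate_index=replicate_index,
        seed=eng_seed,
        series=series,
        records=records,
        final_units=pop.units[:, :max_len].copy(),
        final_lengths=pop.lengths.copy(),
        r2_extinct=bool(series["r2_extinct"].iloc[-1]),
        bottlenecks=bottlenecks,
        skipped_crossovers=skipped,
    )


def run_replicates(config: SimConfig, replicates: int | None = None) -> list:
    n = config.replicates if replicates is None else replicates
    return [run_replicate(config, i) for i in range(n)]


def run_sweep(base_config: SimConfig, parameter_name: str, values,
              replicates: int = 5) -> pd.DataFrame:
    """Vary one parameter, holding all others constant.

    For each value the four headline end-state statistics (mean locus size,
    mean R2 number, fraction of lineages single-copy, fraction of R2-active
    individuals) are averaged over replicates, with standard errors.
    """
    from .summaries import summarize_final_state

    if parameter_name not in {f.name for f in dataclasses.fields(SimConfig)}:
        raise ConfigurationError(f"unknown parameter {parameter_name!r}")
    rows = []
    for v in values:
        cfg = base_config.replace(**{parameter_name: v})
        stats = [summarize_final_state(run_replicate(cfg, i))
                 for i in range(replicates)]
        row = {parameter_name: v, "replicates": replicates}
        for key in ("mean_locus_size", "mean_r2_per_locus", "fraction_single_copy",
                    "fraction_active", "fraction_active_males",
                    "fraction_active_females"):
            vals = np.array([s[key] for s in stats], dtype=float)
            row[key] = float(vals.mean())
            row[key + "_se"] = float(vals.std(ddof=1) / math.sqrt(len(vals))) \
                if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
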