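"""Simulation configuration: schema, defaults, validation, YAML round-trip.

The default parameter set is the transcription-domain reference
parameterization: population of 5000, domain of 40 units (female per-locus
domains of 20), 34 uninserted domain units for peak fitness, fecundity 6,
SCE rate 0.2 localized at s = 0.05, ICE rate 1e-4, crossover offset 1-11,
retrotransposition probability 0.18 (s = 0.4) with 50% dead-on-arrival
copies, loop deletions at 7e-5 per unit plus 6.5e-3 per full-length domain
element (sizes 1-30, s = 0.2), starting from 250-unit loci with 20% of units
inserted.

``legacy_uniform`` mode reproduces the earlier uniform-crossover model:
fitness from total uninserted units against a whole-locus requirement,
constant per-locus retrotransposition probability, and crossover, deletion
and insertion positions uniform over the locus.  ``legacy_centered`` is the
same model with crossovers localized at the locus center.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass

import yaml

MODES = ("domain", "legacy_uniform", "legacy_centered")


class ConfigurationError(ValueError):
    """Invalid or unknown configuration value."""


@dataclass
class SimConfig:
    """Complete parameterization of one simulation."""

    mode: str = "domain"
    n_individuals: int = 5000
    generations: int = 50000
    replicates: int = 50
    seed: int = 1

    # transcription domain & fitness
    domain_size: int = 40
    fitness_units_required: int = 34
    max_gametes: int = 6

    # crossovers
    sce_rate: float = 0.2
    ice_rate: float = 0.0001
    crossover_max_offset: int = 11
    crossover_s: float = 0.05

    # loop deletions
    deletion_rate_per_unit: float = 0.00007
    element_deletion_rate: float = 0.0065
    deletion_max_size: int = 30
    deletion_s: float = 0.2

    # retrotransposition
    retro_probability: float = 0.18
    truncation_fraction: float = 0.5
    retro_s: float = 0.4

    # legacy-mode fields
    legacy_fitness_units_required: int = 100
    legacy_retro_probability: float = 0.009

    # initial state
    initial_locus_size: int = 250
    initial_insertion_fraction: float = 0.2
    initial_truncation_fraction: float = 0.5

    # output plumbing
    record_every: int = 10

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        c = self
        if c.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {c.mode!r}")
        if c.n_individuals < 2 or c.n_individuals % 2:
            raise ConfigurationError("n_individuals must be even and >= 2")
        if c.generations < 1:
            raise ConfigurationError("generations must be >= 1")
        if c.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if c.domain_size < 1:
            raise ConfigurationError("domain_size must be >= 1")
        if not 0 <= c.fitness_units_required <= c.domain_size:
            raise ConfigurationError("fitness_units_required must be in [0, domain_size]")
        if c.max_gametes < 1:
            raise ConfigurationError("max_gametes must be >= 1")
        for key in ("sce_rate", "ice_rate", "truncation_fraction",
                    "initial_insertion_fraction", "initial_truncation_fraction"):
            v = getattr(c, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{key} must be in [0, 1], got {v}")
        for key in ("deletion_rate_per_unit", "element_deletion_rate",
                    "retro_probability", "legacy_retro_probability"):
            if getattr(c, key) < 0:
                raise ConfigurationError(f"{key} must be >= 0")
        for key in ("crossover_s", "deletion_s", "retro_s"):
            if not getattr(c, key) > 0:
                raise ConfigurationError(f"{key} must be > 0")
        if c.crossover_max_offset < 1 or c.deletion_max_size < 1:
            raise ConfigurationError("offset/deletion sizes must be >= 1")
        if c.initial_locus_size < 1:
            raise ConfigurationError("initial_locus_size must be >= 1")
        if c.legacy_fitness_units_required < 0:
            raise ConfigurationError("legacy_fitness_units_required must be >= 0")
        if c.record_every < 1:
            raise ConfigurationError("record_every must be >= 1")
        if c.seed < 0:
            raise ConfigurationError("seed must be >= 0")

    @property
    def female_domain_size(self) -> int:
        """Per-locus domain size in females (half the male domain)."""
        return max(1, self.domain_size // 2)

    def replace(self, **overrides) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path_or_stream) -> None:
        """Write the config as a flat YAML key-value document."""
        if isinstance(path_or_stream, (str, bytes)) or hasattr(path_or_stream, "__fspath__"):
            with open(path_or_stream, "w") as fh:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        else:
            yaml.safe_dump(self.to_dict(), path_or_stream, sort_keys=False)


def legacy_defaults(mode: str = "legacy_uniform") -> SimConfig:
    """Reference parameterization of the legacy uniform-crossover model.

    Population 4000 for 10000 generations; whole-locus fitness requirement of
    100 uninserted units; SCE rate 0.3 with offsets 1-8; constant
    retrotransposition probability 0.009 per R2-bearing locus; loop deletions
    at 5e-5 per unit with sizes 1-15; positions uniform over the locus
    (``legacy_centered``: crossovers Normal around the locus center).
    """
    return SimConfig(
        mode=mode,
        n_individuals=4000,
        generations=10000,
        replicates=60,
        sce_rate=0.3,
        crossover_max_offset=8,
        deletion_rate_per_unit=0.00005,
        element_deletion_rate=0.0,
        deletion_max_size=15,
        legacy_retro_probability=0.009,
        legacy_fitness_units_required=100,
    )


def load_config(path=None, overrides: dict | None = None) -> SimConfig:
    """Load a flat YAML config; missing keys fall back to the defaults.

    ``overrides`` (e.g. from CLI flags) are applied after the file.  Unknown
    keys or out-of-range values raise :class:`ConfigurationError` naming the
    key.
    """
    data: dict = {}
    if path is not None:
        if hasattr(path, "read"):
            loaded = yaml.safe_load(path.read())
        else:
            with open(path) as fh:
                loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("config file must be a flat key-value mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    try:
        return SimConfig(**data)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigurationError(str(exc)) from exc


def dumps_config(config: SimConfig) -> str:
    buf = io.StringIO()
    yaml.safe_dump(config.to_dict(), buf, sort_keys=False)
    return buf.getvalue()
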