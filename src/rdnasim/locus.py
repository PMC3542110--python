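"""The rDNA tandem array: unit states, domain placement, R2-activity logic.

An rDNA locus is modeled as an ordered array of categorical units.  Each unit
is either uninserted, carries a full-length R2 retrotransposon, or carries a
5'-truncated (dead-on-arrival) copy.  Every insertion event is tagged with a
lineage label so that later duplication by unequal crossover can be scored.

Each generation the host activates a single contiguous block of units for
transcription (the transcription domain), centered on the largest contiguous
block of units free of R2 insertions.  If that free block is at least as
large as the domain, no R2-inserted unit is transcribed and the locus is
R2-silent; otherwise R2-inserted units fall inside the domain and R2 is
transcribed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from ._kernels import domain_counts, largest_run, place_domain_kernel


class UnitState(IntEnum):
    """State of a single rDNA unit."""

    UNINSERTED = 0
    FULL_LENGTH = 1
    TRUNCATED = 2


_STATE_CHARS = {UnitState.UNINSERTED: "U", UnitState.FULL_LENGTH: "F", UnitState.TRUNCATED: "T"}
_CHAR_STATES = {v: k for k, v in _STATE_CHARS.items()}


class Locus:
    """Ordered rDNA array, stored as an int64 code vector.

    Codes: ``0`` uninserted, ``+k`` full-length R2 of lineage ``k``, ``-k``
    truncated copy of lineage ``k``.  Lineage labels are positive integers,
    unique per insertion event; a label occurring more than once in a locus
    means the copy was duplicated by a crossover.
    """

    __slots__ = ("codes",)

    def __init__(self, codes: np.ndarray):
        codes = np.ascontiguousarray(codes, dtype=np.int64)
        if codes.ndim != 1 or codes.size < 1:
            raise ValueError("a locus needs at least one unit")
        self.codes = codes

    @classmethod
    def from_states(cls, states, labels=None) -> "Locus":
        """Build a locus from per-unit states and per-inserted-unit labels.

        ``labels`` lists one positive integer per inserted unit, in locus
        order.  If omitted, inserted units are labeled 1, 2, ... left to
        right (each treated as its own lineage).
        """
        states = [UnitState(s) for s in states]
        n_ins = sum(s != UnitState.UNINSERTED for s in states)
        if labels is None:
            labels = list(range(1, n_ins + 1))
        if len(labels) != n_ins:
            raise ValueError("need exactly one label per inserted unit")
        codes = np.zeros(len(states), dtype=np.int64)
        it = iter(labels)
        for i, s in enumerate(states):
            if s == UnitState.FULL_LENGTH:
                codes[i] = next(it)
            elif s == UnitState.TRUNCATED:
                codes[i] = -next(it)
        return cls(codes)

    @classmethod
    def from_string(cls, text: str, labels: str | list | None = None) -> "Locus":
        """Parse the compact serialization: a {U,F,T} string plus labels.

        ``labels`` may be a comma-separated string or a list, one entry per
        inserted unit in locus order.
        """
        states = [_CHAR_STATES[c] for c in text.strip()]
        if isinstance(labels, str):
            labels = [int(x) for x in labels.split(",")] if labels.strip() else []
        return cls.from_states(states, labels)

    def to_string(self) -> tuple[str, str]:
        """Serialize to the ({U,F,T} string, comma-separated labels) pair."""
        chars = []
        labels = []
        for c in self.codes:
            if c > 0:
                chars.append("F")
                labels.append(str(c))
            elif c < 0:
                chars.append("T")
                labels.append(str(-c))
            else:
                chars.append("U")
        return "".join(chars), ",".join(labels)

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return self.codes.size

    def __eq__(self, other) -> bool:
        return isinstance(other, Locus) and np.array_equal(self.codes, other.codes)

    def __repr__(self) -> str:
        s, _ = self.to_string()
        if len(s) > 60:
            s = s[:57] + "..."
        return f"Locus(L={len(self)}, '{s}')"

    def copy(self) -> "Locus":
        return Locus(self.codes.copy())

    @property
    def states(self) -> np.ndarray:
        out = np.zeros(self.codes.size, dtype=np.int8)
        out[self.codes > 0] = UnitState.FULL_LENGTH
        out[self.codes < 0] = UnitState.TRUNCATED
        return out

    @property
    def labels(self) -> np.ndarray:
        """Lineage labels of inserted units, in locus order."""
        return np.abs(self.codes[self.codes != 0])

    @property
    def n_inserted(self) -> int:
        return int(np.count_nonzero(self.codes))

    @property
    def n_full_length(self) -> int:
        return int(np.count_nonzero(self.codes > 0))

    @property
    def n_truncated(self) -> int:
        return int(np.count_nonzero(self.codes < 0))


@dataclass(frozen=True)
class DomainPlacement:
    """A placed transcription domain: half-open unit window [start, start+size)."""

    start: int
    size: int

    @property
    def center(self) -> float:
        """Real-valued midpoint of the domain, in unit coordinates."""
        return self.start + (self.size - 1) / 2.0


@dataclass(frozen=True)
class ActivityReport:
    """Unit-state census of a placed domain.

    ``active`` is the transcription-level flag: any inserted unit (full-length
    or truncated) inside the domain means R2-containing units are transcribed.
    The retrotransposition-competence statistic reported population-wide uses
    the stricter full-length-only definition, available as
    ``full_length_active``.
    """

    active: bool
    n_full_in_domain: int
    n_trunc_in_domain: int
    n_uninserted_in_domain: int
    largest_free_block: int

    @property
    def full_length_active(self) -> bool:
        """True when a full-length (retrotransposition-competent) R2 is in the domain."""
        return self.n_full_in_domain > 0


def largest_uninserted_run(locus: Locus) -> tuple[int, int]:
    """Leftmost maximal run of consecutive uninserted units, as (start, length).

    Returns ``(0, 0)`` for a fully inserted locus.
    """
    s, l = largest_run(locus.codes, locus.codes.size)
    return int(s), int(l)


def place_domain(locus: Locus, per_locus_domain_size: int) -> DomainPlacement:
    """Center the transcription domain on the largest R2-free block.

    The effective domain size is ``min(per_locus_domain_size, L)``.  The
    domain midpoint is aligned with the free-block midpoint, rounded to the
    nearest unit (exact halves toward the lower index), then clamped inside
    the locus.  Ties between equal largest blocks go to the leftmost block.
    """
    if per_locus_domain_size < 1:
        raise ValueError("domain size must be >= 1")
    start, size = place_domain_kernel(locus.codes, locus.codes.size, per_locus_domain_size)
    return DomainPlacement(int(start), int(size))


def classify_activity(locus: Locus, placement: DomainPlacement) -> ActivityReport:
    """Census the domain window and classify R2 transcriptional activity."""
    L = locus.codes.size
    if placement.start < 0 or placement.start + placement.size > L:
        raise ValueError("placement does not fit the locus")
    n_full, n_trunc, n_un = domain_counts(locus.codes, placement.start, placement.size)
    _, block = largest_run(locus.codes, L)
    return ActivityReport(
        active=(n_full + n_trunc) > 0,
        n_full_in_domain=int(n_full),
        n_trunc_in_domain=int(n_trunc),
        n_uninserted_in_domain=int(n_un),
        largest_free_block=int(block),
    )
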