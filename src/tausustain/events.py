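"""Event sets and event sequences for the linear z-score progression model.

An *event* is a (region, threshold index) pair: the region's z-score crossing
one of its severity thresholds.  An :class:`EventSet` fixes the regions, their
ascending threshold vectors and a per-region maximum z; an event *sequence* is
a permutation of all N events that respects, within each region, the ascending
threshold order (a region cannot cross its second threshold before its first).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "EventSet",
    "build_event_set",
    "is_valid_sequence",
    "random_valid_sequence",
    "canonical_sequence",
    "all_valid_sequences",
    "valid_positions",
]


@dataclass(frozen=True)
class EventSet:
    """Regions, per-region ascending z thresholds, and per-region maximum z.

    Parameters
    ----------
    regions
        Region names, in canonical order.
    thresholds
        One strictly ascending tuple of z thresholds per region.
    z_max
        Per-region trajectory ceiling, strictly above the last threshold.
    """

    regions: tuple[str, ...]
    thresholds: tuple[tuple[float, ...], ...]
    z_max: tuple[float, ...]
    # events[e] = (region_index, threshold_index), canonical order:
    # region order, then ascending threshold.
    events: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        if not (len(self.regions) == len(self.thresholds) == len(self.z_max)):
            raise ValueError("regions, thresholds and z_max must have equal length")
        if len(self.regions) == 0:
            raise ValueError("at least one region required")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("duplicate region names")
        for name, thr, zm in zip(self.regions, self.thresholds, self.z_max):
            if len(thr) == 0:
                raise ValueError(f"region {name!r} has no thresholds")
            if any(b <= a for a, b in zip(thr, thr[1:])):
                raise ValueError(f"thresholds for region {name!r} not strictly ascending: {thr}")
            if not zm > thr[-1]:
                raise ValueError(
                    f"z_max for region {name!r} ({zm}) must exceed its last threshold ({thr[-1]})"
                )
        events = tuple(
            (i, r) for i in range(len(self.regions)) for r in range(len(self.thresholds[i]))
        )
        object.__setattr__(self, "events", events)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def event_id(self, region: int, thr: int) -> int:
        """Canonical event index of (region, threshold) — region-major layout."""
        return int(sum(len(t) for t in self.thresholds[:region]) + thr)

    def event_labels(self) -> list[str]:
        """Human-readable labels, e.g. ``"frontal_l:z1"``."""
        return [f"{self.regions[i]}:z{r + 1}" for i, r in self.events]

    def to_dict(self) -> dict:
        return {
            "regions": list(self.regions),
            "thresholds": [list(t) for t in self.thresholds],
            "z_max": list(self.z_max),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventSet":
        return cls(
            regions=tuple(d["regions"]),
            thresholds=tuple(tuple(t) for t in d["thresholds"]),
            z_max=tuple(d["z_max"]),
        )


def build_event_set(
    regions: Sequence[str],
    thresholds: Sequence[Sequence[float]],
    z_max: Sequence[float],
) -> EventSet:
    """Assemble an :class:`EventSet`, validating ascending thresholds."""
    return EventSet(
        regions=tuple(regions),
        thresholds=tuple(tuple(t) for t in thresholds),
        z_max=tuple(z_max),
    )


def is_valid_sequence(seq: np.ndarray, es: EventSet) -> bool:
    """True iff ``seq`` permutes all events with within-region ascending order."""
    seq = np.asarray(seq)
    if sorted(seq.tolist()) != list(range(es.n_events)):
        return False
    pos = np.empty(es.n_events, dtype=int)
    pos[seq] = np.arange(es.n_events)
    for i in range(es.n_regions):
        ids = [es.events.index((i, r)) for r in range(len(es.thresholds[i]))]
        p = pos[ids]
        if np.any(np.diff(p) <= 0):
            return False
    return True


def canonical_sequence(es: EventSet) -> np.ndarray:
    """The identity sequence (region order, ascending thresholds)."""
    return np.arange(es.n_events)


def random_valid_sequence(es: EventSet, rng: np.random.Generator) -> np.ndarray:
    """Draw uniformly from the valid sequences.

    A uniformly random permutation of the events, with each region's events
    then stably reordered into ascending threshold order, is uniform over the
    valid permutations (valid sequences are in bijection with the orderings of
    the multiset of region labels).
    """
    perm = rng.permutation(es.n_events)
    return _repair_within_region(perm, es)


def _repair_within_region(seq: np.ndarray, es: EventSet) -> np.ndarray:
    regions_of = np.array([i for i, _ in es.events])
    out = np.array(seq, dtype=int)
    for i in range(es.n_regions):
        slots = np.nonzero(regions_of[out] == i)[0]
        ids = sorted(out[slots].tolist())  # canonical ids are threshold-ascending
        out[slots] = ids
    return out


def all_valid_sequences(es: EventSet) -> Iterator[np.ndarray]:
    """Enumerate every valid sequence in lexicographic (canonical) order.

    Intended for brute-force oracles at small N; the count is the multinomial
    N! / prod(R_i!).
    """
    n = es.n_events
    counts = [len(t) for t in es.thresholds]
    first_event = np.cumsum([0] + counts[:-1])

    def rec(prefix: list[int], used: list[int]) -> Iterator[np.ndarray]:
        if len(prefix) == n:
            yield np.array(prefix, dtype=int)
            return
        for i in range(es.n_regions):
            if used[i] < counts[i]:
                used[i] += 1
                prefix.append(int(first_event[i]) + used[i] - 1)
                yield from rec(prefix, used)
                prefix.pop()
                used[i] -= 1

    yield from rec([], [0] * es.n_regions)


def valid_positions(seq_without: np.ndarray, event: int, es: EventSet) -> np.ndarray:
    """Insertion slots for ``event`` into ``seq_without`` that keep validity.

    ``seq_without`` is a valid-ordered array of the other N-1 events.  The slot
    must lie strictly after the region's lower-threshold event and strictly
    before its higher-threshold event (where those exist).
    """
    i, r = es.events[event]
    lo, hi = 0, len(seq_without)
    if r > 0:
        below = es.events.index((i, r - 1))
        lo = int(np.nonzero(seq_without == below)[0][0]) + 1
    if r + 1 < len(es.thresholds[i]):
        above = es.events.index((i, r + 1))
        hi = int(np.nonzero(seq_without == above)[0][0])
    return np.arange(lo, hi + 1)
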