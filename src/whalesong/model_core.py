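"""Domain types and song-copying micro-operations.

A humpback whale song is modelled as a fixed-capacity container of 11 slots,
each holding a theme identifier or left empty.  Themes are atomic cultural
units that are only ever the same or different; every invented theme receives
a globally fresh identifier, so identity of theme ids across individuals or
populations always means common cultural descent.

The operations here are the micro-level learning rules: the novelty test
that gates which tutor songs may be learned, the count-dependent retention
probability for each theme of a copied song, the invention of new themes by
insertion into empty slots, and theme substitution.  The population-level
scheduler in :mod:`whalesong.simulator` applies these rules synchronously
over a metapopulation; this module keeps a direct, object-level reference
implementation that the vectorized engine is tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

SONG_SLOTS = 11
EMPTY = 0  # sentinel for an unoccupied slot; real theme ids are >= 1


class ThemeCounter:
    """Global monotone source of fresh theme identifiers.

    Every invented theme (by insertion or substitution) draws from this
    counter, so an id issued later is strictly greater than every id issued
    earlier and no id is ever reused.
    """

    def __init__(self, start: int = 1):
        self._next = int(start)

    def fresh(self) -> int:
        tid = self._next
        self._next += 1
        return tid

    def reserve(self, n: int) -> int:
        """Reserve ``n`` consecutive ids, returning the first."""
        first = self._next
        self._next += int(n)
        return first


@dataclass(frozen=True)
class Song:
    """An 11-slot song: a tuple of theme ids with ``EMPTY`` (0) for absent themes."""

    slots: tuple[int, ...]

    def __post_init__(self):
        if len(self.slots) != SONG_SLOTS:
            raise ValueError(f"a song has exactly {SONG_SLOTS} slots")
        occupied = [s for s in self.slots if s != EMPTY]
        if len(occupied) != len(set(occupied)):
            raise ValueError("a theme may not appear twice within one song")

    @classmethod
    def from_themes(cls, themes) -> "Song":
        themes = list(themes)
        if len(themes) > SONG_SLOTS:
            raise ValueError("too many themes for one song")
        return cls(tuple(themes) + (EMPTY,) * (SONG_SLOTS - len(themes)))

    def __len__(self) -> int:
        return sum(1 for s in self.slots if s != EMPTY)


def theme_set(song: Song) -> frozenset[int]:
    """Ids of the occupied slots of ``song`` (set semantics, no duplicates)."""
    return frozenset(s for s in song.slots if s != EMPTY)


def is_different(tutor_song: Song, focal_song: Song) -> bool:
    """True iff the tutor's song contains at least one theme absent from ``focal_song``."""
    return bool(theme_set(tutor_song) - theme_set(focal_song))


def is_novel(tutor_song: Song, memory) -> bool:
    """True iff the tutor's song differs from *every* song in the focal memory.

    An empty memory makes any tutor song vacuously novel.  Equivalently, the
    tutor song is novel unless some remembered song is a superset of it.
    Callers pass the *live* memory (entries within the ``round(L_sm)``-epoch
    window, see :meth:`Agent.live_memory`); forgotten songs no longer block.
    """
    return all(is_different(tutor_song, entry.song) for entry in memory)


@dataclass
class MemoryEntry:
    song: Song
    learned_epoch: int


@dataclass
class Agent:
    """One male whale: a current song plus a time-bounded memory of learned songs.

    The current song is always the most recently learned (newest) memory
    entry.  The memory spans ``round(L_sm)`` learning epochs: entries older
    than that window are forgotten and no longer block novelty.  Since at
    most one song is learned per epoch, a buffer of ``round(L_sm)`` entries
    (oldest replaced on overflow) holds every song still within the window.
    """

    memory: list[MemoryEntry] = field(default_factory=list)

    @property
    def current(self) -> Song:
        return self.memory[-1].song

    def learn(self, song: Song, epoch: int, memory_bound: int) -> None:
        self.memory.append(MemoryEntry(song, epoch))
        while len(self.memory) > memory_bound:
            self.memory.pop(0)

    def live_memory(self, epoch: int, memory_bound: int) -> list[MemoryEntry]:
        """Entries still remembered at ``epoch`` (learned within the window)."""
        return [m for m in self.memory if m.learned_epoch > epoch - memory_bound]

    def mutate_in_place(self, song: Song) -> None:
        """Replace the newest memory entry's song without a new timestamp."""
        self.memory[-1] = MemoryEntry(song, self.memory[-1].learned_epoch)


@dataclass(frozen=True)
class LearningParams:
    """The six fitted learning parameters.

    N_t
        tutors sampled per learning epoch (continuous; used as a
        round-half-up integer with floor 1).
    P_n
        probability, in the single migration/feeding epoch each year, that a
        given tutor is drawn from a neighbouring population.
    mu
        per-theme substitution rate per learning event.
    L_sm
        song-memory length (number of remembered songs; continuous, used
        rounded).
    P_d
        deletion-shape parameter of the retention probability.
    P_i
        insertion-scale parameter of the invention probability.
    """

    N_t: float
    P_n: float
    mu: float
    L_sm: float
    P_d: float
    P_i: float
    insert_rule: str = "scaled"  # "scaled": e^-Pd * Pi; "joint": e^-(Pd*Pi)

    PRIOR_BOUNDS = {
        "N_t": (1.0, 20.0),
        "P_n": (1e-7, 0.25),
        "mu": (1e-10, 1e-3),
        "L_sm": (1.0, 100.0),
        "P_d": (1.0, 20.0),
        "P_i": (0.2, 6.0),
    }

    @property
    def n_tutors(self) -> int:
        return max(1, round_half_up(self.N_t))

    @property
    def memory_bound(self) -> int:
        return max(1, round_half_up(self.L_sm))


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def p_learn(k, P_d):
    """Probability that a theme heard ``k`` times this epoch is retained when copying.

    ``P_learn = 1 / (1 + 0.5**(k + P_d))``; strictly increasing in both
    arguments, so rarer themes are deleted more often.  ``k`` counts the
    tutor songs (among all heard this epoch) containing the theme and must
    be at least 1: the theme occurs in the chosen song, which was heard.
    """
    k = np.asarray(k)
    if np.any(k < 1):
        raise ValueError("k counts occurrences of a heard theme and must be >= 1")
    out = 1.0 / (1.0 + 0.5 ** (k + P_d))
    return float(out) if out.ndim == 0 else out


def p_insert(P_d, P_i, rule: str = "scaled") -> float:
    """Probability that an empty slot is filled with a freshly invented theme.

    Two readings of the invention probability are supported: ``"scaled"``
    (default), ``e**(-P_d) * P_i`` clamped to [0, 1], which at typical fitted
    values is of the same order as the per-theme deletion probability and so
    permits song-length equilibrium; and ``"joint"``, ``e**(-(P_d * P_i))``,
    which is vanishingly small there and lets songs only shrink.
    """
    if rule == "scaled":
        return float(min(1.0, math.exp(-P_d) * P_i))
    if rule == "joint":
        return float(math.exp(-P_d * P_i))
    raise ValueError(f"unknown insertion rule {rule!r}")


def copy_song(
    tutor_song: Song,
    theme_counts: dict[int, int],
    params: LearningParams,
    rng: np.random.Generator,
    counter: ThemeCounter,
) -> Song:
    """Copy a tutor song with deletions, insertions and substitutions.

    Stage 1: each theme of the tutor song is retained independently with
    probability ``p_learn(k, P_d)`` where ``k = theme_counts[theme]`` tallies
    its occurrences over all tutor songs heard this epoch; a deleted theme
    leaves its slot empty.  Stage 2: each empty slot is independently filled
    with a fresh theme with probability ``p_insert``.  Stage 3: each occupied
    slot (retained or inserted) is independently substituted by a fresh theme
    with probability ``mu``.  Inputs are not mutated; an all-empty result is
    legal.
    """
    if len(tutor_song) < 1:
        raise ValueError("a copied tutor song must contain at least one theme")
    slots = list(tutor_song.slots)
    for i, tid in enumerate(slots):
        if tid == EMPTY:
            continue
        if rng.random() >= p_learn(theme_counts[tid], params.P_d):
            slots[i] = EMPTY
    pi = p_insert(params.P_d, params.P_i, params.insert_rule)
    for i, tid in enumerate(slots):
        if tid == EMPTY and rng.random() < pi:
            slots[i] = counter.fresh()
    for i, tid in enumerate(slots):
        if tid != EMPTY and rng.random() < params.mu:
            slots[i] = counter.fresh()
    return Song(tuple(slots))


def mutate_current(
    song: Song, mu: float, rng: np.random.Generator, counter: ThemeCounter
) -> Song:
    """Substitute each occupied slot with probability ``mu``; no insertion or deletion.

    Applied when no novel tutor song was available this epoch: the whale
    keeps its old song, only substitutions creep in.
    """
    slots = list(song.slots)
    for i, tid in enumerate(slots):
        if tid != EMPTY and rng.random() < mu:
            slots[i] = counter.fresh()
    return Song(tuple(slots))


def song_to_json(song: Song) -> list:
    """JSON form: array of 11 entries, integer id or null for an empty slot."""
    return [None if s == EMPTY else int(s) for s in song.slots]


def song_from_json(arr) -> Song:
    if len(arr) != SONG_SLOTS:
        raise ValueError(f"serialized song must have {SONG_SLOTS} entries")
    return Song(tuple(EMPTY if s is None else int(s) for s in arr))
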