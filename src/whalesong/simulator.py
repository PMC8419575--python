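"""Metapopulation epoch scheduler for song learning.

Each simulated year consists of ten learning epochs: nine breeding-season
epochs in which tutors come only from the focal whale's own population, and
one migration/feeding epoch in which each tutor is, with probability
``P_n``, drawn from a uniformly chosen adjacent population.  Within an
epoch every whale samples ``round(N_t)`` tutors, screens the tutor songs
for novelty against its song memory, copies one uniformly chosen novel
song (with deletions, insertions and substitutions), or — if nothing novel
was heard — keeps its old song subject only to theme substitution.  The
song memory that gates novelty is a time window: songs learned more than
round(L_sm) epochs ago are forgotten, so a song circulating around the
ring of populations can be re-adopted once it has been out of a
population's memory long enough.  All new current songs are committed
simultaneously after every whale has decided, so the outcome is
independent of the order in which whales are processed.

Implementation notes
--------------------
Songs are interned: each distinct theme set maps to a small integer song
id, and agent state (current song, memory ring buffer) stores song ids.
The novelty test "tutor song s is different from every remembered song"
is equivalent to "no remembered song is a superset of s", so the engine
maintains a lazily extended superset index per song id and evaluates the
test with a compiled newest-first scan over each agent's live memory
entries (see :mod:`whalesong._kernels`).

All randomness within a (population, epoch) is drawn from a dedicated
generator seeded by ``(master seed, population, epoch)`` in agent-uid
order, and freshly invented theme ids are a deterministic injective
function of ``(epoch, population, agent uid, slot)``.  Together these make
the committed epoch state exactly invariant under permutations of agent
storage order, and every run bit-reproducible from its seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from ._kernels import build_contains, copy_retention, floyd_sample, novelty_scan
from .demography import PopulationDemography, population_size
from .model_core import SONG_SLOTS, LearningParams, p_insert

UID_STRIDE = 1 << 21  # fresh-id address space per (epoch, population)
SLOT_STRIDE = 2 * SONG_SLOTS  # insertion slots + substitution slots per agent
INITIAL_SONG_LENGTH = 7


@dataclass(frozen=True)
class Topology:
    """Which populations may exchange tutors during the migration epoch.

    ``kind`` is ``"ring"`` (circular west-to-east chain, every population
    has a western and an eastern neighbour) or ``"groups"`` (disjoint
    cliques, e.g. one per ocean basin, ordered west to east within each
    group; the endpoints of a group lack one directional neighbour).
    """

    populations: tuple[str, ...]
    adjacency: tuple[tuple[bool, ...], ...]
    kind: str = "custom"
    groups: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self):
        A = self.matrix()
        P = len(self.populations)
        if A.shape != (P, P):
            raise ValueError("adjacency shape must match population count")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if A.diagonal().any():
            raise ValueError("adjacency may not contain self-loops")

    def matrix(self) -> np.ndarray:
        return np.asarray(self.adjacency, dtype=bool)

    @classmethod
    def ring(cls, labels) -> "Topology":
        labels = tuple(labels)
        P = len(labels)
        A = np.zeros((P, P), dtype=bool)
        for i in range(P):
            A[i, (i - 1) % P] = A[i, (i + 1) % P] = True
        if P == 1:
            A[:] = False
        return cls(labels, tuple(map(tuple, A.tolist())), kind="ring")

    @classmethod
    def cliques(cls, groups) -> "Topology":
        groups = tuple(tuple(g) for g in groups)
        labels = tuple(l for g in groups for l in g)
        P = len(labels)
        pos = {l: i for i, l in enumerate(labels)}
        A = np.zeros((P, P), dtype=bool)
        for g in groups:
            for a in g:
                for b in g:
                    if a != b:
                        A[pos[a], pos[b]] = True
        return cls(labels, tuple(map(tuple, A.tolist())), kind="groups", groups=groups)

    def neighbours(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.matrix()[i])

    def west_east(self, i: int) -> tuple[int | None, int | None]:
        """Indices of the western and eastern neighbour of population ``i``.

        On the ring every population has both; in grouped topologies the
        westernmost/easternmost population of a group lacks one, reported
        as ``None`` (its directional sharing is then unavailable).
        """
        P = len(self.populations)
        if self.kind == "ring":
            return (i - 1) % P, (i + 1) % P
        if self.kind == "groups":
            label = self.populations[i]
            pos = {l: j for j, l in enumerate(self.populations)}
            for g in self.groups:
                if label in g:
                    k = g.index(label)
                    west = pos[g[k - 1]] if k > 0 else None
                    east = pos[g[k + 1]] if k < len(g) - 1 else None
                    return west, east
        return None, None

    def to_dict(self) -> dict:
        return {
            "populations": list(self.populations),
            "adjacency": [[bool(x) for x in row] for row in self.adjacency],
            "kind": self.kind,
            "groups": [list(g) for g in self.groups],
        }

    @classmethod
    def from_dict(cls, d) -> "Topology":
        return cls(
            tuple(d["populations"]),
            tuple(tuple(bool(x) for x in row) for row in d["adjacency"]),
            d.get("kind", "custom"),
            tuple(tuple(g) for g in d.get("groups", [])),
        )


@dataclass
class SimulationConfig:
    topology: Topology
    demography: tuple[PopulationDemography, ...]
    params: LearningParams
    years: int = 50
    seed: int = 0
    epochs_per_year: int = 10
    breeding_epochs: int = 9
    sample_size: int = 20
    sampling_plan: dict | None = None  # (year, population label) -> sample size

    def __post_init__(self):
        if self.epochs_per_year != self.breeding_epochs + 1:
            raise ValueError("epochs_per_year must equal breeding_epochs + 1")
        if len(self.demography) != len(self.topology.populations):
            raise ValueError("one demography entry per population required")
        for d, label in zip(self.demography, self.topology.populations):
            if d.name != label:
                raise ValueError(
                    f"demography order must match topology: {d.name!r} vs {label!r}"
                )

    def config_hash(self) -> str:
        payload = {
            "topology": self.topology.to_dict(),
            "demography": [
                [d.name, d.N_min, d.N_2015, d.N_K, d.calibration_years]
                for d in self.demography
            ],
            "params": [
                self.params.N_t, self.params.P_n, self.params.mu,
                self.params.L_sm, self.params.P_d, self.params.P_i,
                self.params.insert_rule,
            ],
            "years": self.years,
            "epochs_per_year": self.epochs_per_year,
            "sample_size": self.sample_size,
        }
        return hashlib.md5(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SimulationRecord:
    """Per-year, per-population samples of sung theme sets, plus run metadata."""

    populations: tuple[str, ...]
    topology: Topology
    years: int
    samples: dict  # (year, population label) -> list of sorted theme tuples
    seed: int
    config_hash: str
    final_sizes: dict = field(default_factory=dict)

    def sample(self, year: int, population: str):
        return self.samples.get((year, population))

    def to_json(self) -> dict:
        return {
            "populations": list(self.populations),
            "topology": self.topology.to_dict(),
            "years": self.years,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "final_sizes": {k: int(v) for k, v in self.final_sizes.items()},
            "samples": [
                {"year": y, "population": p, "songs": [list(s) for s in songs]}
                for (y, p), songs in sorted(self.samples.items())
            ],
        }

    @classmethod
    def from_json(cls, d) -> "SimulationRecord":
        samples = {
            (row["year"], row["population"]): [tuple(s) for s in row["songs"]]
            for row in d["samples"]
        }
        return cls(
            tuple(d["populations"]),
            Topology.from_dict(d["topology"]),
            d["years"],
            samples,
            d["seed"],
            d["config_hash"],
            dict(d.get("final_sizes", {})),
        )


class SongRegistry:
    """Interns theme sets to dense song ids and indexes superset relations.

    Song id 0 is reserved for the all-empty song.  ``supersets(sid)`` lists
    every known song id whose theme set contains that of ``sid`` — the only
    relation the novelty gate needs — and is cached incrementally: new song
    ids are only checked against the containing-list of the rarest theme of
    ``sid``, which for a song carrying a recently invented theme is short.
    """

    def __init__(self, capacity: int = 1024):
        self._map: dict[frozenset, int] = {}
        self.arr = np.zeros((capacity, SONG_SLOTS), dtype=np.int64)
        self.lens = np.zeros(capacity, dtype=np.int64)
        self.sets: list[frozenset] = []
        self.n = 0
        self._containing: dict[int, list[int]] = {}
        self._sup_cache: dict[int, tuple[list[int], int, int]] = {}
        self.intern(())

    def intern(self, themes) -> int:
        key = frozenset(int(t) for t in themes)
        sid = self._map.get(key)
        if sid is not None:
            return sid
        if len(key) > SONG_SLOTS:
            raise ValueError("more themes than song slots")
        sid = self.n
        if sid == len(self.arr):
            self.arr = np.vstack([self.arr, np.zeros_like(self.arr)])
            self.lens = np.concatenate([self.lens, np.zeros_like(self.lens)])
        srt = sorted(key)
        self.arr[sid, : len(srt)] = srt
        self.lens[sid] = len(srt)
        self.sets.append(key)
        self._map[key] = sid
        for t in srt:
            self._containing.setdefault(t, []).append(sid)
        self.n += 1
        return sid

    def themes(self, sid: int) -> tuple[int, ...]:
        return tuple(int(t) for t in self.arr[sid, : self.lens[sid]])

    def supersets(self, sid: int) -> list[int]:
        key = self.sets[sid]
        if not key:
            raise ValueError("the empty song has every song as a superset")
        cached = self._sup_cache.get(sid)
        if cached is None:
            ref = min(key, key=lambda t: len(self._containing[t]))
            sup: list[int] = []
            frontier = 0
        else:
            sup, ref, frontier = cached
        lst = self._containing[ref]
        if frontier < len(lst):
            for m in lst[frontier:]:
                if key <= self.sets[m]:
                    sup.append(m)
            frontier = len(lst)
            self._sup_cache[sid] = (sup, ref, frontier)
        return sup


class _PopState:
    def __init__(self, demog: PopulationDemography, memory_bound: int, capacity: int):
        self.demog = demog
        self.capacity = capacity
        self.n = 0
        self.next_uid = 0
        self.uid = np.zeros(capacity, dtype=np.int64)
        self.cur = np.zeros(capacity, dtype=np.int64)
        self.mem = np.full((capacity, memory_bound), -1, dtype=np.int64)
        self.mem_epoch = np.full((capacity, memory_bound), -(10**9), dtype=np.int64)
        self.mem_pos = np.zeros(capacity, dtype=np.int64)
        self.mem_len = np.zeros(capacity, dtype=np.int64)

    def add_agents(self, count: int, sids, epoch: int) -> None:
        if self.n + count > self.capacity:
            extra = self.n + count - self.capacity
            self.uid = np.concatenate([self.uid, np.zeros(extra, np.int64)])
            self.cur = np.concatenate([self.cur, np.zeros(extra, np.int64)])
            self.mem = np.vstack(
                [self.mem, np.full((extra, self.mem.shape[1]), -1, np.int64)]
            )
            self.mem_epoch = np.vstack(
                [self.mem_epoch, np.full((extra, self.mem.shape[1]), -(10**9), np.int64)]
            )
            self.mem_pos = np.concatenate([self.mem_pos, np.zeros(extra, np.int64)])
            self.mem_len = np.concatenate([self.mem_len, np.zeros(extra, np.int64)])
            self.capacity += extra
        sl = slice(self.n, self.n + count)
        self.uid[sl] = np.arange(self.next_uid, self.next_uid + count)
        self.cur[sl] = sids
        self.mem[sl, :] = -1
        self.mem[sl, 0] = sids
        self.mem_epoch[sl, :] = -(10**9)
        self.mem_epoch[sl, 0] = epoch
        self.mem_pos[sl] = 1 % self.mem.shape[1]
        self.mem_len[sl] = 1
        self.n += count
        self.next_uid += count


class Metapopulation:
    """Mutable simulation state: one :class:`_PopState` per population."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.params = config.params
        self.topology = config.topology
        self.registry = SongRegistry()
        P = len(config.topology.populations)
        self._P = P
        self._fresh_offset = INITIAL_SONG_LENGTH * P + 1
        M = self.params.memory_bound
        self.pops: list[_PopState] = []
        for i, demog in enumerate(config.demography):
            cap = population_size(demog, config.years)
            st = _PopState(demog, M, cap)
            themes = range(
                INITIAL_SONG_LENGTH * i + 1, INITIAL_SONG_LENGTH * (i + 1) + 1
            )
            sid = self.registry.intern(themes)
            st.add_agents(population_size(demog, 0), sid, epoch=0)
            self.pops.append(st)

    # -- randomness ----------------------------------------------------
    def _rng(self, stream: int, a: int, b: int) -> np.random.Generator:
        """Generator for one (stream, index, index) triple of this run.

        Philox keyed by a collision-free packing of (seed, stream, a, b):
        streams are small tags, a is an epoch or year (< 2^36) and b packs
        a population index and optionally an agent uid (< 2^26).
        """
        key = (
            (int(self.config.seed) & ((1 << 63) - 1)) << 65
            | int(stream) << 62
            | int(a) << 26
            | int(b)
        )
        return np.random.Generator(np.random.Philox(key=key))

    def _fresh_base(self, epoch: int, pop: int, uid: int) -> int:
        if uid >= UID_STRIDE:
            raise OverflowError("population exceeds fresh-id address space")
        return (
            ((epoch + 1) * self._P + pop) * UID_STRIDE + uid
        ) * SLOT_STRIDE + self._fresh_offset

    # -- demography ----------------------------------------------------
    def grow_to_year(self, year: int) -> None:
        """Recruit each population up to its logistic size for ``year``.

        Each recruit copies the current song of a uniformly chosen
        incumbent; its memory holds that one song.
        """
        epoch = (year - 1) * self.config.epochs_per_year
        for p, st in enumerate(self.pops):
            target = population_size(st.demog, year)
            if target < st.n:
                raise ValueError("no mortality is modelled; target below current size")
            if target == st.n:
                continue
            if st.n == 0:
                raise ValueError("an empty population cannot recruit")
            rng = self._rng(2, year, p)
            sorter = np.argsort(st.uid[: st.n], kind="stable")
            count = target - st.n
            src_rank = np.minimum(
                (rng.random(count) * st.n).astype(np.int64), st.n - 1
            )
            sids = st.cur[sorter[src_rank]]
            st.add_agents(count, sids, epoch)

    # -- tutor selection -----------------------------------------------
    def _uid_order(self, st: _PopState):
        sorter = np.argsort(st.uid[: st.n], kind="stable")
        rank = np.empty(st.n, dtype=np.int64)
        rank[sorter] = np.arange(st.n)
        return sorter, rank

    def _tutor_draws(self, p: int, epoch: int, migration: bool, rng, rank):
        """Fixed-schedule tutor-selection uniforms, drawn in uid order.

        Row r of each raw draw belongs to the agent of uid-rank r; the
        returned arrays are re-indexed so row j belongs to the agent
        stored at position j.  All agent-conditional draws later in the
        epoch are likewise made in uid order, which makes the committed
        epoch outcome invariant under agent storage permutations.
        """
        n = self.pops[p].n
        T = self.params.n_tutors
        draws = {"floyd": rng.random((n, T))}
        if migration:
            draws["flag"] = rng.random((n, T))
            draws["side"] = rng.random((n, T))
            draws["nidx"] = rng.random((n, T))
        return {k: v[rank] for k, v in draws.items()}

    @staticmethod
    def _floyd(u: np.ndarray, c: int) -> np.ndarray:
        """Row-wise sample of T distinct integers from [0, c), T fixed draws each."""
        return floyd_sample(u, c)

    def select_tutors(self, p: int, epoch: int, migration: bool):
        """Tutor sources for every agent of population ``p`` at ``epoch``.

        Returns ``(src_pop, src_idx, valid)`` arrays of shape ``(n, T)``:
        the population index and storage index of each tutor.  Breeding
        epochs draw tutors uniformly without replacement from the focal
        population excluding the focal whale (with replacement only when
        fewer candidates than tutors exist); in the migration epoch each
        tutor is independently, with probability ``P_n``, drawn instead
        from a uniformly chosen adjacent population.  Isolated populations
        behave as in a breeding epoch.
        """
        rng = self._rng(1, epoch, p)
        sorter, rank = self._uid_order(self.pops[p])
        draws = self._tutor_draws(p, epoch, migration, rng, rank)
        return self._select_tutors_from(p, epoch, migration, draws, rank, sorter)

    def _select_tutors_from(self, p, epoch, migration, draws, rank, sorter):
        st = self.pops[p]
        n = st.n
        T = self.params.n_tutors
        c = n - 1
        if c >= T:
            own_rank = self._floyd(draws["floyd"], c)
        elif c >= 1:
            own_rank = np.minimum((draws["floyd"] * c).astype(np.int64), c - 1)
        else:
            own_rank = np.zeros((n, T), dtype=np.int64)
        own_rank = own_rank + (own_rank >= rank[:, None])
        src_idx = sorter[np.minimum(own_rank, n - 1)]
        src_pop = np.full((n, T), p, dtype=np.int64)
        valid = np.full((n, T), c >= 1, dtype=bool)

        nbrs = self.topology.neighbours(p) if migration else np.empty(0, np.int64)
        nbrs = np.asarray([q for q in nbrs if self.pops[q].n > 0], dtype=np.int64)
        if migration and nbrs.size and self.params.P_n > 0:
            flag = draws["flag"] < self.params.P_n
            d = len(nbrs)
            side = np.minimum((draws["side"] * d).astype(np.int64), d - 1)
            qsorters = {}
            for si, q in enumerate(nbrs):
                qn = self.pops[q].n
                sel = flag & (side == si)
                if not sel.any():
                    continue
                qsorters[q] = np.argsort(self.pops[q].uid[:qn], kind="stable")
                qrank = np.minimum((draws["nidx"] * qn).astype(np.int64), qn - 1)
                src_pop[sel] = q
                src_idx[sel] = qsorters[q][qrank[sel]]
                valid[sel] = True
            self._dedupe_neighbour_tutors(
                p, epoch, flag, src_pop, src_idx, qsorters, st
            )
        return src_pop, src_idx, valid

    def _dedupe_neighbour_tutors(self, p, epoch, flag, src_pop, src_idx, qsorters, st):
        """Redraw neighbour tutors that collided within one source population."""
        multi = np.flatnonzero(flag.sum(axis=1) >= 2)
        for j in multi:
            cols = np.flatnonzero(flag[j])
            seen: set[tuple[int, int]] = set()
            arng = None
            for t in cols:
                key = (int(src_pop[j, t]), int(src_idx[j, t]))
                tries = 0
                while key in seen and tries < 64:
                    if arng is None:
                        arng = self._rng(4, epoch, (p << 22) | int(st.uid[j]))
                    q = key[0]
                    qn = self.pops[q].n
                    if sum(1 for s in seen if s[0] == q) >= qn:
                        break
                    src_idx[j, t] = qsorters[q][int(arng.integers(qn))]
                    key = (q, int(src_idx[j, t]))
                    tries += 1
                seen.add(key)

    # -- learning epoch ------------------------------------------------
    def learning_epoch(self, epoch: int, migration: bool | None = None) -> None:
        """Run one synchronous learning epoch over all populations.

        Every agent decides on its new current song from the pre-epoch
        state; all decisions are then committed simultaneously.
        """
        if migration is None:
            migration = (
                epoch % self.config.epochs_per_year == self.config.epochs_per_year - 1
            )
        plans = [self._decide(p, epoch, migration) for p in range(self._P)]
        M = self.params.memory_bound
        for st, plan in zip(self.pops, plans):
            if plan is None:
                continue
            learners, learned_sids, mutants, mutant_sids = plan
            if learners.size:
                pos = st.mem_pos[learners]
                st.mem[learners, pos] = learned_sids
                st.mem_epoch[learners, pos] = epoch
                st.mem_pos[learners] = (pos + 1) % M
                st.mem_len[learners] = np.minimum(st.mem_len[learners] + 1, M)
                st.cur[learners] = learned_sids
            if mutants.size:
                pos = (st.mem_pos[mutants] - 1) % M
                st.mem[mutants, pos] = mutant_sids
                st.cur[mutants] = mutant_sids

    def _decide(self, p: int, epoch: int, migration: bool):
        st = self.pops[p]
        n = st.n
        if n == 0:
            return None
        rng = self._rng(1, epoch, p)
        sorter, rank = self._uid_order(st)
        cur = st.cur[:n]
        M = self.params.memory_bound
        if not migration and bool((cur == cur[0]).all()):
            # the newest memory entry always holds the current song; if it
            # has not expired, a tutor singing that same song is not novel
            newest = st.mem_epoch[np.arange(n), (st.mem_pos[:n] - 1) % M]
            if bool((newest > epoch - M).all()):
                # monomorphic breeding epoch with live memories: nothing
                # novel can be heard, only substitutions can occur
                empty = np.empty(0, dtype=np.int64)
                mutants, mutant_sids = self._substitution_batch(
                    st, p, epoch, rng, sorter, np.ones(n, dtype=bool)
                )
                return empty, empty, mutants, mutant_sids
        draws = self._tutor_draws(p, epoch, migration, rng, rank)
        src_pop, src_idx, valid = self._select_tutors_from(
            p, epoch, migration, draws, rank, sorter
        )

        tsid = np.full(src_pop.shape, -1, dtype=np.int64)
        if not migration:
            tsid[valid] = st.cur[src_idx[valid]]
        else:
            for q in np.unique(src_pop[valid]) if valid.any() else ():
                mask = valid & (src_pop == q)
                tsid[mask] = self.pops[q].cur[src_idx[mask]]

        novel, V, code = self._novelty(st, tsid, valid, epoch)

        cnt = novel.sum(axis=1)
        learn_mask = cnt > 0
        # learner-conditional draws happen in uid order, so keep the
        # learner list uid-ordered
        learners = sorter[learn_mask[sorter]]
        learned_sids = self._copy_batch(
            st, p, epoch, learners, valid, novel, cnt, rng, V, code
        )
        mutants, mutant_sids = self._substitution_batch(
            st, p, epoch, rng, sorter, ~learn_mask
        )
        return learners, learned_sids, mutants, mutant_sids

    def _substitution_batch(self, st, p, epoch, rng, sorter, eligible_mask):
        """Theme substitution on the current songs of the eligible agents.

        Per-slot Bernoulli(mu) substitution is sampled as a binomial count
        per agent followed by a uniform choice of which occupied slots flip
        (slots are exchangeable), which is equivalent and avoids drawing a
        per-slot uniform matrix for the whole population every epoch.
        """
        params = self.params
        reg = self.registry
        elig = sorter[eligible_mask[sorter]]  # storage indices, uid order
        empty = np.empty(0, dtype=np.int64)
        if elig.size == 0 or params.mu <= 0:
            return empty, empty
        plen = reg.lens[st.cur[elig]]
        nsub = rng.binomial(plen, params.mu)
        hit = nsub > 0
        mutants = elig[hit]
        nsub = nsub[hit]
        mutant_sids = np.empty(len(mutants), dtype=np.int64)
        for i, j in enumerate(mutants):
            uid = int(st.uid[j])
            L0 = int(reg.lens[st.cur[j]])
            arng = self._rng(5, epoch, (p << 22) | uid)
            slots = set(arng.choice(L0, size=int(nsub[i]), replace=False).tolist())
            base = self._fresh_base(epoch, p, uid)
            themes = [
                base + SONG_SLOTS + s if s in slots else int(t)
                for s, t in enumerate(reg.arr[st.cur[j], :L0])
            ]
            mutant_sids[i] = reg.intern(themes)
        return mutants, mutant_sids

    def _novelty(self, st: _PopState, tsid: np.ndarray, valid: np.ndarray, epoch: int):
        """Boolean (n, T): is each heard tutor song novel for its hearer?

        A tutor song is novel iff no *remembered* song is a superset of
        it, where the memory covers only the songs learned within the
        last round(L_sm) epochs — older entries have been forgotten.
        All-empty tutor songs are never novel.
        """
        reg = self.registry
        n = st.n
        novel = np.zeros(tsid.shape, dtype=bool)
        vals = tsid[valid]
        if vals.size == 0:
            return novel, np.empty(0, np.int64), None
        V = np.unique(vals)
        V = V[reg.lens[V] > 0]
        if V.size == 0:
            return novel, V, None
        sups = [reg.supersets(int(s)) for s in V]
        sup_start = np.zeros(len(V) + 1, dtype=np.int64)
        sup_start[1:] = np.cumsum([len(s) for s in sups])
        sup_flat = (
            np.concatenate([np.asarray(s, dtype=np.int64) for s in sups])
            if sup_start[-1]
            else np.empty(0, np.int64)
        )
        code = np.searchsorted(V, tsid)
        inV = valid & (code < len(V))
        inV[inV] = V[code[inV]] == tsid[inV]
        code = np.where(inV, code, -1)
        novel = novelty_scan(
            st.mem[:n],
            st.mem_epoch[:n],
            st.mem_pos[:n],
            st.mem_len[:n],
            sup_flat,
            sup_start,
            code,
            len(V),
            epoch - self.params.memory_bound + 1,
        )
        return novel, V, code

    def _copy_batch(self, st, p, epoch, learners, valid, novel, cnt, rng, V, code):
        """Batched copy_song for all learning agents of one population.

        ``learners`` must be uid-ordered.  Theme occurrence counts k are
        tallied over all tutor songs heard this epoch via a contains-table
        over the (few) distinct heard song ids (dense codes over ``V``,
        shared with the novelty stage).  Insertion and substitution events
        are sampled as binomial counts plus a uniform slot choice (slots
        are exchangeable), equivalent to per-slot Bernoulli draws.
        """
        reg = self.registry
        params = self.params
        if learners.size == 0:
            return np.empty(0, dtype=np.int64)
        u_pick = rng.random(learners.size)
        cum = novel[learners].cumsum(axis=1)
        k = np.minimum((u_pick * cnt[learners]).astype(np.int64), cnt[learners] - 1)
        pos = (cum > k[:, None]).argmax(axis=1)
        arrV = reg.arr[V]  # (v, 11) sorted themes, zero-padded
        contains = build_contains(arrV, reg.lens[V])
        ccode = code[learners, pos]
        hcode = np.where(code[learners] >= 0, code[learners], len(V))
        chosen = V[ccode]
        C = arrV[ccode]
        u_ret = rng.random((learners.size, SONG_SLOTS))
        keep, kept_count = copy_retention(contains, ccode, hcode, u_ret, params.P_d)
        pi = p_insert(params.P_d, params.P_i, params.insert_rule)
        n_ins = rng.binomial(SONG_SLOTS - kept_count, pi)
        if params.mu > 0:
            n_sub = rng.binomial(kept_count, params.mu)
        else:
            n_sub = np.zeros(learners.size, dtype=np.int64)
        clen = reg.lens[chosen]
        changed = (kept_count < clen) | (n_ins > 0) | (n_sub > 0)
        new_sids = chosen.copy()
        for i in np.flatnonzero(changed):
            j = learners[i]
            uid = int(st.uid[j])
            base = self._fresh_base(epoch, p, uid)
            kept_slots = np.flatnonzero(keep[i])
            if n_sub[i]:
                arng = self._rng(5, epoch, (p << 22) | uid)
                sel = arng.choice(len(kept_slots), size=int(n_sub[i]), replace=False)
                sub_slots = set(kept_slots[sel].tolist())
            else:
                sub_slots = ()
            themes = [int(C[i, s]) for s in kept_slots if s not in sub_slots]
            themes += [base + e for e in range(int(n_ins[i]))]
            themes += [base + SONG_SLOTS + int(s) for s in sub_slots]
            new_sids[i] = reg.intern(themes)
        return new_sids

    # -- sampling ------------------------------------------------------
    def sample_population(self, p: int, year: int, size: int):
        """Theme sets of ``size`` singers drawn without replacement."""
        st = self.pops[p]
        size = min(size, st.n)
        if size <= 0:
            return []
        rng = self._rng(3, year, p)
        sorter = np.argsort(st.uid[: st.n], kind="stable")
        picked = sorter[rng.permutation(st.n)[:size]]
        return [self.registry.themes(int(s)) for s in st.cur[picked]]

    def permute_agents(self, p: int, perm) -> None:
        """Scramble the storage order of population ``p`` (testing hook)."""
        st = self.pops[p]
        perm = np.asarray(perm)
        sl = slice(0, st.n)
        st.uid[sl] = st.uid[sl][perm]
        st.cur[sl] = st.cur[sl][perm]
        st.mem[sl] = st.mem[sl][perm]
        st.mem_epoch[sl] = st.mem_epoch[sl][perm]
        st.mem_pos[sl] = st.mem_pos[sl][perm]
        st.mem_len[sl] = st.mem_len[sl][perm]


def run_simulation(config: SimulationConfig) -> SimulationRecord:
    """Run the full multi-year simulation and return the sampled record.

    Year ``y`` (1-based): populations grow to their logistic size for ``y``,
    then nine breeding epochs and one migration epoch run, then per-
    population singer samples are recorded.  Year 0 holds the initial
    (bottleneck) state.  Fully reproducible from ``config.seed``.
    """
    mp = Metapopulation(config)
    labels = config.topology.populations
    samples: dict = {}
    plan = config.sampling_plan

    def record(year: int):
        for p, label in enumerate(labels):
            size = config.sample_size if plan is None else plan.get((year, label), 0)
            if size <= 0:
                continue
            songs = mp.sample_population(p, year, size)
            if songs:
                samples[(year, label)] = songs

    record(0)
    E = config.epochs_per_year
    for year in range(1, config.years + 1):
        mp.grow_to_year(year)
        for e in range(E):
            mp.learning_epoch((year - 1) * E + e)
        record(year)
    return SimulationRecord(
        populations=labels,
        topology=config.topology,
        years=config.years,
        samples=samples,
        seed=config.seed,
        config_hash=config.config_hash(),
        final_sizes={label: mp.pops[p].n for p, label in enumerate(labels)},
    )
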