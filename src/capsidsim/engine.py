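"""Discrete-event stochastic simulation of capsid self-assembly.

The simulator follows next-reaction semantics over a rule set: every
possible bond-formation (association) and bond-breaking (dissociation) event
carries an exponentially distributed tentative firing time sampled from its
propensity; the minimum-time event fires, the system state is updated, and
only events whose participants changed are re-sampled — untouched events
keep their scheduled times.

Assemblies are rigid fragments embedded in the target lattice: an assembly
occupies a set of lattice nodes and holds bonds on a subset of the lattice
edges induced by those nodes.  Association places one fragment relative to
another through a lattice automorphism such that the fragments do not
overlap and at least one lattice edge joins them; all open lattice contacts
inside the merged footprint close in the same event (implied ring closure).
Geometrically equivalent placements are collapsed to a single event, so the
propensity of an association is the base on-rate of its contact class
converted to a stochastic rate through the simulation volume, not multiplied
by placement multiplicity.  Dissociation is per bond; an assembly whose bond
graph disconnects splits into two fragments.

Free subunits are size-1 assemblies without a committed lattice position
(the lattice is generally not node-transitive, so a free subunit must be
allowed to enter at any slot); they acquire a placement on first binding.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .corrections import AVOGADRO, EffectFactors, IDENTITY_FACTORS
from .ruleset import RuleSet

__all__ = [
    "NEVER",
    "SimConfig",
    "Assembly",
    "ReactionEvent",
    "EventRecord",
    "EventLog",
    "Simulation",
    "exponential_time",
    "draw_event_time",
    "steric_join_check",
    "run_trajectory",
    "run_ensemble",
]

NEVER = math.inf

ASSOCIATION = "association"
DISSOCIATION = "dissociation"
CLOSURE = "closure"  # intra-fragment re-formation of an open ring contact


def exponential_time(rate: float, u: float) -> float:
    """Inverse-CDF exponential waiting time: ``-ln(u)/rate`` for ``u`` in (0, 1].

    A zero rate returns the never-fires sentinel (infinity); negative rates
    are an error.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if not 0 < u <= 1:
        raise ValueError("u must lie in (0, 1]")
    if rate == 0:
        return NEVER
    return -math.log(u) / rate


def draw_event_time(rate: float, rng: np.random.Generator) -> float:
    """Sample an exponential waiting time for the given rate (s)."""
    return exponential_time(rate, 1.0 - rng.random())


@dataclass(frozen=True)
class SimConfig:
    """Protocol constants for a trajectory.

    Defaults follow the single-capsid protocol: exactly enough subunits for
    one complete CCMV capsid (90 dimers) at 15.6 µM, stopping at completion
    or after 100 simulated seconds.
    """

    n_subunits: int = 90
    concentration_uM: float = 15.6
    time_limit: float = 100.0
    seed: int = 0
    stop_on_completion: bool = True

    def __post_init__(self) -> None:
        if self.n_subunits < 0:
            raise ValueError("n_subunits must be non-negative")
        if self.concentration_uM <= 0:
            raise ValueError("concentration_uM must be strictly positive")
        if self.time_limit < 0:
            raise ValueError("time_limit must be non-negative")

    @property
    def volume_L(self) -> float:
        """Simulation volume fixed by subunit count and bulk concentration."""
        n = max(self.n_subunits, 1)
        return n / (self.concentration_uM * 1e-6 * AVOGADRO)


@dataclass(frozen=True)
class Assembly:
    """A rigid lattice-embedded fragment (or an unplaced free subunit)."""

    id: int
    nodes: frozenset[int]
    bonds: frozenset[tuple[int, int]]

    @property
    def size(self) -> int:
        return len(self.nodes) or 1

    @property
    def placed(self) -> bool:
        return bool(self.nodes)


@dataclass(frozen=True)
class ReactionEvent:
    """A scheduled association or dissociation with its sampled firing time."""

    kind: str
    scheduled_time: float
    rate: float
    ids: tuple[int, ...]
    # association: lattice nodes the second participant will occupy
    placement: frozenset[int] | None = None
    # dissociation: the bond to break
    bond: tuple[int, int] | None = None


@dataclass(frozen=True)
class EventRecord:
    """One executed event.

    For associations ``size_i``/``size_j`` are the reactant sizes and
    ``product_size`` their sum.  For dissociations ``size_i``/``size_j`` are
    the fragment sizes (``size_j`` = 0 when a ring bond breaks without
    splitting the fragment) and ``product_size`` is the parent size.
    """

    time: float
    kind: str
    size_i: int
    size_j: int
    product_size: int
    n_assemblies_after: int


@dataclass
class EventLog:
    """Time-ordered record of one trajectory."""

    n_subunits: int
    capsid_size: int
    time_limit: float
    final_time: float
    completed: bool
    seed: int | None
    records: list[EventRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def steric_join_check(lattice, a: Assembly, b: Assembly, bond: tuple[int, int]):
    """Can ``b`` be rigidly placed so that ``bond`` joins it to ``a``?

    ``bond`` is a lattice edge ``(x, y)`` with ``x`` occupied by ``a`` and
    ``y`` the slot ``b`` would enter.  Searches lattice automorphisms for an
    overlap-free placement of ``b`` covering ``y``; returns
    ``(ok, merged_nodes)``.
    """
    x, y = bond
    if x not in a.nodes or y in a.nodes:
        return False, None
    if y not in lattice.neighbors[x]:
        return False, None
    if not b.placed:
        return True, a.nodes | {y}
    for sigma in lattice.automorphisms:
        q = frozenset(sigma[n] for n in b.nodes)
        if y in q and not (q & a.nodes):
            return True, a.nodes | q
    return False, None


class Simulation:
    """One stochastic assembly trajectory over a rule set.

    Rate scalings enter in two interchangeable ways: an
    :class:`~capsidsim.corrections.EffectFactors` triple (an RNA effect
    combination) or manual ``kon_scale``/``koff_scale`` multipliers for grid
    scans.  Bimolecular on-rates (M^-1 s^-1) are converted to stochastic
    propensities by dividing by Avogadro's number times the simulation
    volume; the volume itself never changes with the effect factors.
    """

    def __init__(
        self,
        ruleset: RuleSet,
        factors: EffectFactors | None = None,
        config: SimConfig | None = None,
        kon_scale: float = 1.0,
        koff_scale: float = 1.0,
        assemblies: list[Assembly] | None = None,
    ):
        if factors is None:
            factors = IDENTITY_FACTORS
        if config is None:
            config = SimConfig()
        if kon_scale < 0 or koff_scale < 0:
            raise ValueError("rate scalings must be non-negative")
        self.ruleset = ruleset
        self.lattice = ruleset.lattice
        self.config = config
        self.factors = factors
        vol = config.volume_L
        self.kon_eff = {
            cls: r.kon * factors.kon_factor * kon_scale / (AVOGADRO * vol)
            for cls, r in ruleset.bond_classes.items()
        }
        self.koff_eff = {
            cls: r.koff * factors.koff_factor * koff_scale
            for cls, r in ruleset.bond_classes.items()
        }
        self.rng = np.random.default_rng(config.seed)
        self.time = 0.0
        self._seq = 0
        # heap entries: (time, seq, kind, ids, payload, rate); payload is the
        # placement frozenset for associations, the bond tuple for dissociations
        self._heap: list[tuple] = []
        self._batch: list[tuple] = []
        if assemblies is None:
            assemblies = [
                Assembly(i, frozenset(), frozenset()) for i in range(config.n_subunits)
            ]
        self.assemblies: dict[int, Assembly] = {a.id: a for a in assemblies}
        self._dead: set[int] = set()
        self._next_id = 1 + max((a.id for a in assemblies), default=-1)
        # per-assembly canonicalization: id -> (shape key, inverse automorphism)
        self._canon: dict[int, tuple[tuple[int, ...], tuple[int, ...]]] = {}
        # shape-keyed mode caches shared across trajectories via the lattice
        if not hasattr(self.lattice, "_mode_cache"):
            self.lattice._mode_cache = {}
        self._cache = self.lattice._mode_cache
        self.closure_rate = ruleset.ring_closure_rate
        for aid in sorted(self.assemblies):
            for bid in sorted(self.assemblies):
                if bid <= aid:
                    continue
                self._schedule_association(aid, bid)
            self._schedule_dissociations(aid)
            a = self.assemblies[aid]
            if a.placed:
                for edge in sorted(self.lattice.induced_edges(a.nodes) - a.bonds):
                    self._emit(CLOSURE, (aid,), edge, self.closure_rate)
        self._flush()

    # ------------------------------------------------------------------ caches
    #
    # All symmetry work happens once per fragment *shape* (automorphism orbit
    # of node sets) in a canonical frame and is cached on the lattice, shared
    # across trajectories.  Each live assembly stores the inverse
    # automorphism taking the canonical representative onto its concrete
    # placement, so cached canonical placements translate in O(|placement|).

    def _canonical(self, a: Assembly):
        """(shape key, inverse automorphism) for a placed assembly."""
        entry = self._canon.get(a.id)
        if entry is None:
            best = None
            best_sigma = None
            for sigma in self.lattice.automorphisms:
                key = tuple(sorted(sigma[n] for n in a.nodes))
                if best is None or key < best:
                    best, best_sigma = key, sigma
            inv = [0] * len(best_sigma)
            for i, p in enumerate(best_sigma):
                inv[p] = i
            entry = (best, tuple(inv))
            self._canon[a.id] = entry
        return entry

    def _shape_stabilizer(self, shape: tuple[int, ...]):
        key = ("stab", shape)
        stab = self._cache.get(key)
        if stab is None:
            nodes = frozenset(shape)
            stab = tuple(
                s
                for s in self.lattice.automorphisms
                if frozenset(s[n] for n in nodes) == nodes
            )
            self._cache[key] = stab
        return stab

    def _free_neighbor_modes(self, shape: tuple[int, ...]):
        """Orbit reps of free slots adjacent to the canonical shape: (slot, class)."""
        key = ("mono", shape)
        modes = self._cache.get(key)
        if modes is not None:
            return modes
        nbrs = self.lattice.neighbors
        nodes = frozenset(shape)
        free = sorted({m for n in nodes for m in nbrs[n]} - nodes)
        stab = self._shape_stabilizer(shape)
        seen: set[int] = set()
        modes = []
        for y in free:
            if y in seen:
                continue
            seen.update(sigma[y] for sigma in stab)
            cross = [(min(x, y), max(x, y)) for x in nbrs[y] if x in nodes]
            modes.append((y, _class_counts(self.lattice, cross)))
        self._cache[key] = modes
        return modes

    def _placement_modes(self, shape_a: tuple[int, ...], shape_b: tuple[int, ...]):
        """Canonical overlap-free adjacent placements of shape_b against shape_a."""
        key = ("pair", shape_a, shape_b)
        modes = self._cache.get(key)
        if modes is not None:
            return modes
        nbrs = self.lattice.neighbors
        nodes_a = frozenset(shape_a)
        nodes_b = frozenset(shape_b)
        stab = self._shape_stabilizer(shape_a)
        tried: set[frozenset[int]] = set()
        canon_seen: set[tuple[int, ...]] = set()
        modes = []
        for sigma in self.lattice.automorphisms:
            q = frozenset(sigma[n] for n in nodes_b)
            if q in tried:
                continue
            tried.add(q)
            if q & nodes_a:
                continue
            if len(stab) == 1:
                canon = tuple(sorted(q))
            else:
                canon = min(tuple(sorted(tau[n] for n in q)) for tau in stab)
            if canon in canon_seen:
                continue
            canon_seen.add(canon)
            cross = [
                (min(u, v), max(u, v)) for u in canon for v in nbrs[u] if v in nodes_a
            ]
            if not cross:
                continue
            modes.append((canon, _class_counts(self.lattice, cross)))
        self._cache[key] = modes
        return modes

    # -------------------------------------------------------------- scheduling

    def _emit(self, kind: str, ids: tuple[int, ...], payload, rate: float) -> None:
        if rate > 0:
            self._batch.append((kind, ids, payload, rate))

    def _flush(self) -> None:
        """Sample firing times for the emitted batch and push onto the heap."""
        if not self._batch:
            return
        us = self.rng.random(len(self._batch))
        for (kind, ids, payload, rate), u in zip(self._batch, us):
            t = self.time - math.log1p(-u) / rate
            self._seq += 1
            heapq.heappush(self._heap, (t, self._seq, kind, ids, payload, rate))
        self._batch.clear()

    def _schedule_association(self, aid: int, bid: int) -> None:
        a, b = self.assemblies[aid], self.assemblies[bid]
        if a.size + b.size > self.lattice.n_nodes:
            return
        if not a.placed and not b.placed:
            for u, v in self.lattice.edge_orbits:
                cls = self.lattice.bond_class(u, v)
                self._emit(
                    ASSOCIATION, (aid, bid), frozenset((u, v)), self.kon_eff[cls]
                )
            return
        # fall through: at least one participant has a committed placement
        if a.placed and not b.placed:
            anchor, other = a, b
        elif b.placed and not a.placed:
            anchor, other = b, a
        elif (a.size, -a.id) >= (b.size, -b.id):
            anchor, other = a, b
        else:
            anchor, other = b, a
        shape_a, inv = self._canonical(anchor)
        if not other.placed:
            for y, classes in self._free_neighbor_modes(shape_a):
                self._emit(
                    ASSOCIATION, (anchor.id, other.id), frozenset((inv[y],)),
                    self._mode_rate(classes),
                )
            return
        shape_b, _ = self._canonical(other)
        for q, classes in self._placement_modes(shape_a, shape_b):
            self._emit(
                ASSOCIATION, (anchor.id, other.id),
                frozenset(inv[n] for n in q), self._mode_rate(classes),
            )

    def _mode_rate(self, classes: tuple[tuple[str, int], ...]) -> float:
        """Association propensity: each contact the event forms is a distinct
        site pairing and contributes its own base on-rate."""
        return sum(self.kon_eff[cls] * n for cls, n in classes)

    def _schedule_dissociations(self, aid: int) -> None:
        a = self.assemblies[aid]
        for bond in sorted(a.bonds):
            cls = self.lattice.bond_class(*bond)
            self._emit(DISSOCIATION, (aid,), bond, self.koff_eff[cls])

    def _schedule_new(self, new_ids: list[int]) -> None:
        for nid in new_ids:
            for oid in sorted(self.assemblies):
                if oid == nid or (oid in new_ids and oid < nid):
                    continue
                self._schedule_association(min(nid, oid), max(nid, oid))
            self._schedule_dissociations(nid)
        self._flush()

    # --------------------------------------------------------------- execution

    def pending_events(self) -> list[ReactionEvent]:
        """The currently valid scheduled events (for inspection/testing)."""
        out = []
        for t, _, kind, ids, payload, rate in sorted(self._heap):
            if any(i not in self.assemblies for i in ids):
                continue
            if kind == ASSOCIATION:
                out.append(ReactionEvent(kind, t, rate, ids, placement=payload))
            else:
                out.append(ReactionEvent(kind, t, rate, ids, bond=payload))
        return out

    def _event_valid(self, kind, ids, payload) -> bool:
        if kind == DISSOCIATION:
            return payload in self.assemblies[ids[0]].bonds
        if kind == CLOSURE:
            return payload not in self.assemblies[ids[0]].bonds
        # defensive steric re-check; participants unchanged implies still valid
        return not (payload & self.assemblies[ids[0]].nodes)

    def _new_assembly(self, nodes: frozenset[int], bonds: frozenset) -> Assembly:
        a = Assembly(self._next_id, nodes, bonds)
        self._next_id += 1
        self.assemblies[a.id] = a
        return a

    def _remove(self, aid: int) -> None:
        del self.assemblies[aid]
        self._dead.add(aid)
        self._canon.pop(aid, None)

    def run(self) -> EventLog:
        """Execute the trajectory to completion or the time limit."""
        cfg = self.config
        capsid = self.lattice.n_nodes
        log = EventLog(
            n_subunits=cfg.n_subunits,
            capsid_size=capsid,
            time_limit=cfg.time_limit,
            final_time=cfg.time_limit,
            completed=False,
            seed=cfg.seed,
        )
        while self._heap:
            t, _, kind, ids, payload, _rate = heapq.heappop(self._heap)
            if any(i in self._dead for i in ids):
                continue
            if t > cfg.time_limit:
                break
            if not self._event_valid(kind, ids, payload):
                # sterically rejected: the event consumes its time slot
                self.time = t
                continue
            self.time = t
            if kind == ASSOCIATION:
                a, b = (self.assemblies[i] for i in ids)
                merged_nodes = a.nodes | payload
                merged = self._new_assembly(
                    merged_nodes, self.lattice.induced_edges(merged_nodes)
                )
                si, sj = sorted((a.size, b.size), reverse=True)
                self._remove(a.id)
                self._remove(b.id)
                log.records.append(
                    EventRecord(t, ASSOCIATION, si, sj, merged.size, len(self.assemblies))
                )
                if cfg.stop_on_completion and merged.size == capsid:
                    log.final_time = t
                    log.completed = True
                    return log
                self._schedule_new([merged.id])
            elif kind == DISSOCIATION:
                parent = self.assemblies[ids[0]]
                bonds = parent.bonds - {payload}
                comps = _components(parent.nodes, bonds)
                if len(comps) == 1:
                    # a ring bond opened; the fragment keeps its identity and
                    # the open contact may re-close as a fast closure event
                    self.assemblies[parent.id] = Assembly(
                        parent.id, parent.nodes, bonds
                    )
                    log.records.append(
                        EventRecord(
                            t, DISSOCIATION, parent.size, 0, parent.size,
                            len(self.assemblies),
                        )
                    )
                    self._emit(CLOSURE, ids, payload, self.closure_rate)
                    self._flush()
                else:
                    self._remove(parent.id)
                    comps = sorted(comps, key=lambda c: (-len(c), sorted(c)))
                    new_ids = []
                    for comp in comps:
                        if len(comp) == 1:
                            child = self._new_assembly(frozenset(), frozenset())
                        else:
                            nodes = frozenset(comp)
                            child = self._new_assembly(
                                nodes, frozenset(b for b in bonds if b[0] in nodes)
                            )
                            for edge in sorted(
                                self.lattice.induced_edges(nodes) - child.bonds
                            ):
                                self._emit(CLOSURE, (child.id,), edge, self.closure_rate)
                        new_ids.append(child.id)
                    log.records.append(
                        EventRecord(
                            t, DISSOCIATION, len(comps[0]), len(comps[1]),
                            parent.size, len(self.assemblies),
                        )
                    )
                    self._schedule_new(new_ids)
            else:  # CLOSURE: an open intra-fragment contact re-forms
                a = self.assemblies[ids[0]]
                self.assemblies[a.id] = Assembly(a.id, a.nodes, a.bonds | {payload})
                log.records.append(
                    EventRecord(t, CLOSURE, a.size, 0, a.size, len(self.assemblies))
                )
                cls = self.lattice.bond_class(*payload)
                self._emit(DISSOCIATION, ids, payload, self.koff_eff[cls])
                self._flush()
        log.final_time = cfg.time_limit
        log.completed = False
        return log


def _class_counts(lattice, edges) -> tuple[tuple[str, int], ...]:
    counts: dict[str, int] = {}
    for e in edges:
        cls = lattice.bond_class(*e)
        counts[cls] = counts.get(cls, 0) + 1
    return tuple(sorted(counts.items()))


def _components(nodes: frozenset[int], bonds) -> list[set[int]]:
    """Connected components of the bond graph over ``nodes``."""
    adj: dict[int, list[int]] = {n: [] for n in nodes}
    for u, v in bonds:
        adj[u].append(v)
        adj[v].append(u)
    seen: set[int] = set()
    comps = []
    for start in sorted(nodes):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            n = stack.pop()
            if n in comp:
                continue
            comp.add(n)
            stack.extend(m for m in adj[n] if m not in comp)
        seen |= comp
        comps.append(comp)
    return comps


def run_trajectory(
    ruleset: RuleSet,
    factors: EffectFactors | None = None,
    config: SimConfig | None = None,
    kon_scale: float = 1.0,
    koff_scale: float = 1.0,
) -> EventLog:
    """Run one trajectory; identical config (incl. seed) gives identical logs."""
    return Simulation(
        ruleset, factors=factors, config=config, kon_scale=kon_scale,
        koff_scale=koff_scale,
    ).run()


def run_ensemble(
    ruleset: RuleSet,
    factors: EffectFactors | None = None,
    config: SimConfig | None = None,
    reps: int = 100,
    base_seed: int = 0,
    kon_scale: float = 1.0,
    koff_scale: float = 1.0,
) -> list[EventLog]:
    """Independent trajectories with per-rep seeds ``base_seed + rep`` (mod 2^31)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if config is None:
        config = SimConfig()
    logs = []
    for rep in range(reps):
        cfg = replace(config, seed=(base_seed + rep) % 2**31)
        logs.append(
            run_trajectory(
                ruleset, factors=factors, config=cfg,
                kon_scale=kon_scale, koff_scale=koff_scale,
            )
        )
    return logs
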