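"""Target capsid lattice graphs and their symmetry groups.

A complete capsid is modelled as a fixed *lattice graph*: one node per
subunit slot in the finished shell, one edge per inter-subunit contact.  For
the CCMV-scale model the shell is a T=3 icosahedral capsid built from 90
coat-protein dimers.  Its lattice is the line graph of the truncated
icosahedron: nodes are the 90 edges of the truncated icosahedron (dimer
slots) and two slots are in contact when their edges share a vertex.  The 12
pentagonal faces become 5-rings of slots (pentamers of dimers) and the 20
hexagonal faces become 6-rings (hexamer motifs); every contact lies on
exactly one face ring, which assigns it a ``pentagon`` or ``hexagon`` bond
class, and every slot lies on exactly two rings.

The construction inherits the T=3 asymmetry of the real virus: under the
120-element icosahedral symmetry group the 90 slots split into an orbit of 60
(edges between a pentagon and a hexagon; the A/B-type dimers) and an orbit of
30 (edges between two hexagons; the C/C-type dimers).

Smaller toy lattices (triangle, tetrahedron, dodecahedron) are provided for
testing and for fast parameter scans.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import cached_property

import networkx as nx

__all__ = [
    "Ring",
    "LatticeGraph",
    "build_ccmv_lattice",
    "build_toy_lattice",
    "TOY_KINDS",
]

PENTAGON = "pentagon"
HEXAGON = "hexagon"

TOY_KINDS = ("triangle", "tetrahedron", "dodecahedron")


@dataclass(frozen=True)
class Ring:
    """A chordless face cycle of the lattice, in cyclic node order."""

    kind: str
    nodes: tuple[int, ...]


@dataclass
class LatticeGraph:
    """A capsid contact graph with ring-labelled bond classes.

    ``graph`` nodes are consecutive integers; every edge carries a
    ``bond_class`` attribute.  ``rings`` lists the face cycles (may be empty
    for toy lattices).  ``automorphisms`` — the full automorphism group as
    node-permutation tuples — is supplied by the builders where it is known
    analytically and enumerated generically otherwise.
    """

    name: str
    graph: nx.Graph
    rings: tuple[Ring, ...] = ()
    _automorphisms: tuple[tuple[int, ...], ...] | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def bond_class(self, u: int, v: int) -> str:
        return self.graph.edges[u, v]["bond_class"]

    def bond_classes_present(self) -> tuple[str, ...]:
        return tuple(sorted({d["bond_class"] for _, _, d in self.graph.edges(data=True)}))

    @cached_property
    def neighbors(self) -> dict[int, frozenset[int]]:
        return {n: frozenset(self.graph.neighbors(n)) for n in self.graph.nodes}

    @property
    def automorphisms(self) -> tuple[tuple[int, ...], ...]:
        if self._automorphisms is None:
            self._automorphisms = _enumerate_automorphisms(self.graph)
        return self._automorphisms

    @cached_property
    def edge_orbits(self) -> tuple[tuple[int, int], ...]:
        """One canonical representative edge per automorphism orbit."""
        seen: set[tuple[int, int]] = set()
        reps: list[tuple[int, int]] = []
        for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
            if (u, v) in seen:
                continue
            reps.append((u, v))
            for sigma in self.automorphisms:
                seen.add(tuple(sorted((sigma[u], sigma[v]))))
        return tuple(reps)

    def induced_edges(self, nodes: frozenset[int]) -> frozenset[tuple[int, int]]:
        """All lattice edges with both endpoints in ``nodes``."""
        return frozenset(
            (min(n, m), max(n, m))
            for n in nodes
            for m in self.neighbors[n]
            if m in nodes and n < m
        )


def _enumerate_automorphisms(graph: nx.Graph) -> tuple[tuple[int, ...], ...]:
    """All automorphisms preserving the ``bond_class`` edge attribute."""
    em = nx.isomorphism.categorical_edge_match("bond_class", None)
    gm = nx.isomorphism.GraphMatcher(graph, graph, edge_match=em)
    autos = []
    for mapping in gm.isomorphisms_iter():
        autos.append(tuple(mapping[i] for i in range(graph.number_of_nodes())))
    return tuple(sorted(autos))


def _icosahedron_faces(g: nx.Graph) -> list[frozenset[int]]:
    """The 20 triangular faces of the icosahedral graph (its 3-cliques)."""
    faces = set()
    for u in g.nodes:
        for v, w in itertools.combinations(sorted(g.neighbors(u)), 2):
            if g.has_edge(v, w):
                faces.add(frozenset((u, v, w)))
    return sorted(faces, key=sorted)


def build_ccmv_lattice() -> LatticeGraph:
    """The 90-dimer CCMV-scale lattice (line graph of the truncated icosahedron).

    Nodes of the truncated icosahedron are flags (vertex, incident edge) of
    the icosahedron.  Its edges — our dimer slots — come in two kinds:

    * ``("e", (u, v))`` for each icosahedron edge (the slot crossing that
      edge; lies between two hexagonal faces), and
    * ``("vf", v, face)`` for each vertex/face incidence (the slot on the
      pentagon at ``v``, between that pentagon and the hexagon at ``face``).

    Two slots are in contact when the corresponding truncated-icosahedron
    edges share an endpoint.  Contacts around a pentagonal face are class
    ``pentagon``; contacts around a hexagonal face are class ``hexagon``.
    """
    ico = nx.icosahedral_graph()
    faces = _icosahedron_faces(ico)
    face_key = {f: tuple(sorted(f)) for f in faces}

    labels: list[tuple] = []
    for u, v in sorted(tuple(sorted(e)) for e in ico.edges):
        labels.append(("e", (u, v)))
    for v in sorted(ico.nodes):
        for f in faces:
            if v in f:
                labels.append(("vf", v, face_key[f]))
    labels.sort()
    index = {lab: i for i, lab in enumerate(labels)}

    g = nx.Graph()
    g.add_nodes_from(range(len(labels)))

    # pentagon-class contacts: two pentagon slots at the same vertex whose
    # faces share an edge through that vertex (consecutive around the vertex)
    for v in sorted(ico.nodes):
        at_v = [f for f in faces if v in f]
        for f1, f2 in itertools.combinations(at_v, 2):
            shared = f1 & f2
            if len(shared) == 2 and v in shared:
                g.add_edge(
                    index[("vf", v, face_key[f1])],
                    index[("vf", v, face_key[f2])],
                    bond_class=PENTAGON,
                )

    # hexagon-class contacts: an edge slot with a pentagon slot of a face
    # containing that edge, at either endpoint
    for u, v in sorted(tuple(sorted(e)) for e in ico.edges):
        for f in faces:
            if u in f and v in f:
                g.add_edge(index[("e", (u, v))], index[("vf", u, face_key[f])],
                           bond_class=HEXAGON)
                g.add_edge(index[("e", (u, v))], index[("vf", v, face_key[f])],
                           bond_class=HEXAGON)

    rings: list[Ring] = []
    # 12 pentagon rings: the five pentagon slots around each vertex in cyclic order
    for v in sorted(ico.nodes):
        at_v = [f for f in faces if v in f]
        adj = {
            f: [h for h in at_v if h is not f and len(f & h) == 2 and v in (f & h)]
            for f in at_v
        }
        start = min(at_v, key=sorted)
        cycle = [start]
        prev = None
        while len(cycle) < 5:
            nxts = [h for h in adj[cycle[-1]] if h is not prev]
            nxt = min(nxts, key=sorted)
            prev = cycle[-1]
            cycle.append(nxt)
        rings.append(
            Ring(PENTAGON, tuple(index[("vf", v, face_key[f])] for f in cycle))
        )
    # 20 hexagon rings: alternating edge and pentagon slots around each face
    for f in faces:
        u, v, w = sorted(f)
        seq = [
            ("e", (u, v)),
            ("vf", v, face_key[f]),
            ("e", (min(v, w), max(v, w))),
            ("vf", w, face_key[f]),
            ("e", (min(u, w), max(u, w))),
            ("vf", u, face_key[f]),
        ]
        rings.append(Ring(HEXAGON, tuple(index[s] for s in seq)))

    autos = _lift_icosahedral_automorphisms(ico, faces, face_key, index)
    return LatticeGraph("ccmv", g, tuple(rings), autos)


def _lift_icosahedral_automorphisms(ico, faces, face_key, index):
    """Lift the 120 automorphisms of the icosahedron to slot permutations."""
    gm = nx.isomorphism.GraphMatcher(ico, ico)
    lifted = []
    for sigma in gm.isomorphisms_iter():
        perm = [0] * len(index)
        for lab, i in index.items():
            if lab[0] == "e":
                u, v = lab[1]
                target = ("e", tuple(sorted((sigma[u], sigma[v]))))
            else:
                _, v, f = lab
                target = ("vf", sigma[v], tuple(sorted(sigma[x] for x in f)))
            perm[i] = index[target]
        lifted.append(tuple(perm))
    return tuple(sorted(lifted))


def build_toy_lattice(kind: str) -> LatticeGraph:
    """Small test lattices: ``triangle``, ``tetrahedron`` or ``dodecahedron``.

    The dodecahedron toy is the adjacency graph of the 12 pentagonal faces of
    a dodecahedron (equivalently the icosahedron skeleton): 12 nodes of
    degree 5, complete capsid = 12 subunits.  All toy bonds share one class.
    """
    kind = kind.lower()
    if kind == "triangle":
        g = nx.cycle_graph(3)
        rings: tuple[Ring, ...] = (Ring(PENTAGON, (0, 1, 2)),)
    elif kind == "tetrahedron":
        g = nx.complete_graph(4)
        rings = ()
    elif kind == "dodecahedron":
        g = nx.icosahedral_graph()
        rings = ()
    else:
        raise ValueError(f"unknown toy lattice kind {kind!r}; expected one of {TOY_KINDS}")
    nx.set_edge_attributes(g, PENTAGON, "bond_class")
    return LatticeGraph(kind, g, rings)
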