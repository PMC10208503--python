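"""Structural causal models as directed acyclic graphs.

A :class:`CausalDAG` holds named variables, each flagged observed or latent,
plus directed cause -> effect edges.  On top of it this module provides the
three graphical queries the analysis needs:

* d-separation (``d_separated``) — does the graph imply that two variables
  are conditionally independent given a set?
* testable implications (``implied_independencies``) — one conditional
  independence statement per non-adjacent pair of observed variables, used
  to check the model against data.
* backdoor adjustment (``minimal_adjustment_sets``) — the minimal sets of
  observed covariates that remove confounding when estimating the *total*
  effect of an exposure on an outcome.

The study's own graph (brain injury, impairments, demographics, walking
speed, gait deviation index, net metabolic power) ships as an edge-list data
file and is returned by :func:`study_dag`.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "CausalDAG",
    "IndependenceStatement",
    "DAGParseError",
    "parse_dag",
    "d_separated",
    "implied_independencies",
    "minimal_adjustment_sets",
    "study_dag",
]


class DAGParseError(ValueError):
    """Raised when an edge-list text does not describe a valid DAG."""


@dataclass(frozen=True)
class IndependenceStatement:
    """A testable implication: ``x`` independent of ``y`` given ``given``."""

    x: str
    y: str
    given: frozenset[str]

    def __str__(self) -> str:  # e.g.  "Sex _||_ Age | {}"
        cond = ", ".join(sorted(self.given)) if self.given else "{}"
        return f"{self.x} _||_ {self.y} | {cond}"


@dataclass
class CausalDAG:
    """A validated directed acyclic graph with observed/latent flags.

    Parameters
    ----------
    nodes
        Mapping-friendly iterable of node names.
    edges
        ``(parent, child)`` pairs.
    latent
        Subset of ``nodes`` that are unmeasured.  Latent nodes take part in
        paths but are never admissible as conditioning variables for the
        data-facing queries.
    """

    nodes: frozenset[str]
    edges: tuple[tuple[str, str], ...]
    latent: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.nodes = frozenset(self.nodes)
        self.latent = frozenset(self.latent)
        self.edges = tuple(self.edges)
        if not self.latent <= self.nodes:
            missing = sorted(self.latent - self.nodes)
            raise DAGParseError(f"latent declaration for undeclared node(s): {missing}")
        seen: set[tuple[str, str]] = set()
        for a, b in self.edges:
            if a == b:
                raise DAGParseError(f"self-loop on node {a!r}")
            if a not in self.nodes or b not in self.nodes:
                raise DAGParseError(f"edge {a!r} -> {b!r} uses an undeclared node")
            if (a, b) in seen:
                raise DAGParseError(f"duplicate edge {a!r} -> {b!r}")
            seen.add((a, b))
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[0][0]}"
            raise DAGParseError(f"cycle detected: {path}")
        if not self.observed:
            raise DAGParseError("graph has no observed node")
        self._g = g
        self._parents = {n: frozenset(g.predecessors(n)) for n in self.nodes}
        self._children = {n: frozenset(g.successors(n)) for n in self.nodes}

    # -- basic structure ---------------------------------------------------
    @property
    def observed(self) -> frozenset[str]:
        return self.nodes - self.latent

    @property
    def graph(self) -> nx.DiGraph:
        """The underlying :class:`networkx.DiGraph` (do not mutate)."""
        return self._g

    def parents(self, node: str) -> frozenset[str]:
        return self._parents[node]

    def children(self, node: str) -> frozenset[str]:
        return self._children[node]

    def ancestors(self, node: str) -> frozenset[str]:
        return frozenset(nx.ancestors(self._g, node))

    def descendants(self, node: str) -> frozenset[str]:
        return frozenset(nx.descendants(self._g, node))

    def is_adjacent(self, a: str, b: str) -> bool:
        return b in self._children[a] or a in self._children[b]

    def _require(self, *names: str) -> None:
        for name in names:
            if name not in self.nodes:
                raise KeyError(f"unknown variable {name!r}")


def parse_dag(text: str) -> CausalDAG:
    """Parse an edge-list text into a validated :class:`CausalDAG`.

    Format: one ``Parent -> Child`` per line; ``latent: Name`` declarations;
    ``#`` starts a comment; blank lines ignored.  Node declarations are
    implicit in the edges, so a latent declaration may name a node that only
    appears in edges.
    """
    edges: list[tuple[str, str]] = []
    latent: set[str] = set()
    nodes: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("latent:"):
            name = line.split(":", 1)[1].strip()
            if not name:
                raise DAGParseError(f"line {lineno}: empty latent declaration")
            latent.add(name)
            nodes.add(name)
            continue
        if "->" not in line:
            raise DAGParseError(f"line {lineno}: expected 'A -> B', got {raw!r}")
        a, _, b = line.partition("->")
        a, b = a.strip(), b.strip()
        if not a or not b:
            raise DAGParseError(f"line {lineno}: malformed edge {raw!r}")
        if a == b:
            raise DAGParseError(f"line {lineno}: self-loop on {a!r}")
        if (a, b) in edges:
            raise DAGParseError(f"line {lineno}: duplicate edge {raw.strip()!r}")
        edges.append((a, b))
        nodes.update((a, b))
    return CausalDAG(nodes=frozenset(nodes), edges=tuple(edges), latent=frozenset(latent))


# ---------------------------------------------------------------------------
# d-separation via the moralized ancestral graph
# ---------------------------------------------------------------------------

def d_separated(dag: CausalDAG, x: str, y: str, given: Iterable[str] = ()) -> bool:
    """True iff ``x`` and ``y`` are d-separated by ``given`` in ``dag``.

    Implemented as reachability in the moralized subgraph induced by the
    ancestors of ``{x, y} | given`` (Lauritzen's criterion, equivalent to
    path blocking).  Latent nodes participate like any other node; callers
    enforcing observability do so at a higher level.
    """
    z = frozenset(given)
    dag._require(x, y, *z)
    if x == y:
        raise ValueError("x and y must differ")
    if x in z or y in z:
        raise ValueError("x and y must not be in the conditioning set")

    # ancestral node set of {x, y} ∪ z
    relevant = {x, y, *z}
    anc: set[str] = set(relevant)
    stack = list(relevant)
    parents = dag._parents
    while stack:
        for p in parents[stack.pop()]:
            if p not in anc:
                anc.add(p)
                stack.append(p)

    # moralize: undirected adjacency = edges within anc + married parents
    adj: dict[str, set[str]] = {n: set() for n in anc}
    for n in anc:
        ps = [p for p in parents[n] if p in anc]
        for p in ps:
            adj[n].add(p)
            adj[p].add(n)
        for p, q in itertools.combinations(ps, 2):
            adj[p].add(q)
            adj[q].add(p)

    # BFS from x avoiding z
    if x in z or y in z:  # pragma: no cover - guarded above
        return True
    seen = {x}
    queue = deque([x])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v == y:
                return False
            if v not in seen and v not in z:
                seen.add(v)
                queue.append(v)
    return True


# ---------------------------------------------------------------------------
# testable implications
# ---------------------------------------------------------------------------

def _minimal_separator(
    dag: CausalDAG,
    x: str,
    y: str,
    candidates: Sequence[str],
    max_size: int,
) -> frozenset[str] | None:
    """Smallest (then lexicographically first) separating subset of candidates."""
    for size in range(min(max_size, len(candidates)) + 1):
        for combo in itertools.combinations(candidates, size):
            if d_separated(dag, x, y, combo):
                return frozenset(combo)
    return None


def implied_independencies(
    dag: CausalDAG, max_conditioning: int = 8
) -> list[IndependenceStatement]:
    """Basis set of testable conditional independencies.

    For every non-adjacent pair of observed variables, one statement with a
    minimal separating set of *observed* variables, searched smallest-first
    over observed ancestors of the pair (minimal separators always lie in
    the ancestral set).  Pairs separable only through latent variables are
    omitted: they carry no data-testable implication.
    """
    out: list[IndependenceStatement] = []
    obs = sorted(dag.observed)
    for x, y in itertools.combinations(obs, 2):
        if dag.is_adjacent(x, y):
            continue
        anc = (dag.ancestors(x) | dag.ancestors(y)) & dag.observed - {x, y}
        candidates = sorted(anc)
        sep = _minimal_separator(dag, x, y, candidates, max_conditioning)
        if sep is None:
            if len(candidates) > max_conditioning and d_separated(dag, x, y, candidates):
                raise ValueError(
                    f"minimal separator search for ({x}, {y}) exceeded the "
                    f"conditioning-set cap of {max_conditioning}"
                )
            continue
        out.append(IndependenceStatement(x=x, y=y, given=sep))
    return out


# ---------------------------------------------------------------------------
# backdoor adjustment
# ---------------------------------------------------------------------------

def _backdoor_graph(dag: CausalDAG, exposure: str) -> CausalDAG:
    """Graph with the exposure's outgoing edges removed."""
    edges = tuple(e for e in dag.edges if e[0] != exposure)
    return CausalDAG(nodes=dag.nodes, edges=edges, latent=dag.latent)


def satisfies_backdoor(
    dag: CausalDAG, exposure: str, outcome: str, adjustment: Iterable[str]
) -> bool:
    """Check the backdoor criterion for a total effect.

    ``adjustment`` must contain only observed non-descendants of the
    exposure; it is valid iff exposure and outcome are d-separated by it in
    the graph with the exposure's outgoing edges removed.
    """
    z = frozenset(adjustment)
    dag._require(exposure, outcome, *z)
    if z & dag.latent:
        return False
    if z & (dag.descendants(exposure) | {exposure, outcome}):
        return False
    return d_separated(_backdoor_graph(dag, exposure), exposure, outcome, z)


def minimal_adjustment_sets(
    dag: CausalDAG, exposure: str, outcome: str
) -> list[frozenset[str]]:
    """All minimal observed backdoor adjustment sets for the total effect.

    Total-effect semantics: no descendant of the exposure may be adjusted
    for (that would block mediated paths), and latent nodes are never
    admissible.  Returns every minimal valid set, ordered by size then
    lexicographically.  An empty *list* means the effect is not identifiable
    by covariate adjustment; a valid empty set is returned as
    ``[frozenset()]``.
    """
    dag._require(exposure, outcome)
    if exposure == outcome:
        raise ValueError("exposure and outcome must differ")
    if exposure in dag.latent or outcome in dag.latent:
        raise ValueError("exposure and outcome must be observed")

    forbidden = dag.descendants(exposure) | {exposure, outcome}
    candidates = sorted(dag.observed - forbidden)
    bd = _backdoor_graph(dag, exposure)

    minimal: list[frozenset[str]] = []
    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            s = frozenset(combo)
            if any(m <= s for m in minimal):
                continue
            if d_separated(bd, exposure, outcome, s):
                minimal.append(s)
    return sorted(minimal, key=lambda s: (len(s), sorted(s)))


def study_dag() -> CausalDAG:
    """The pinned study graph: 11 observed variables plus latent BrainInjury.

    Loaded from the bundled edge-list file so alternative reconstructions
    can be swapped in by editing or replacing the file.
    """
    text = (
        resources.files("gaitcausal.data").joinpath("study_dag.txt").read_text("utf-8")
    )
    return parse_dag(text)
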