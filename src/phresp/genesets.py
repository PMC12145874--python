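"""Multi-type gene-set collections, GMT I/O, and ontology ancestor propagation.

Gene sets of several annotation types (GO, InterPro, KEGG KO / BRITE / MODULE,
orthogroups) are kept in one collection together with the gene universe they
are scored against.  GO-style annotations are closed under the parent relation
of an ontology DAG before enrichment, so a gene annotated to a term is also
counted for every ancestor of that term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

SET_TYPES = ("GO", "IPR", "KO", "BRITE", "MODULE", "OG")

__all__ = [
    "SET_TYPES",
    "GeneSetCollection",
    "OntologyDAG",
    "propagate_ancestors",
    "restrict_to_universe",
    "read_gmt",
    "write_gmt",
    "read_edge_tsv",
    "read_obo",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with per-set type tags over a gene universe.

    Invariants: every member gene belongs to ``universe``; no set is empty.
    """

    sets: dict[str, frozenset[str]]
    set_type: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}
        if not self.universe:
            self.universe = frozenset().union(*self.sets.values()) if self.sets else frozenset()
        else:
            self.universe = frozenset(self.universe)
        stray = {
            sid for sid, members in self.sets.items() if not members <= self.universe
        }
        if stray:
            raise ValueError(f"sets with members outside the universe: {sorted(stray)[:5]}")
        empty = [sid for sid, members in self.sets.items() if not members]
        if empty:
            raise ValueError(f"empty gene sets not allowed: {empty[:5]}")
        for sid in self.sets:
            self.set_type.setdefault(sid, "OG")

    def __len__(self) -> int:
        return len(self.sets)

    def of_type(self, *types: str) -> "GeneSetCollection":
        """Sub-collection containing only sets of the given types."""
        keep = {sid: s for sid, s in self.sets.items() if self.set_type[sid] in types}
        return GeneSetCollection(
            sets=keep,
            set_type={sid: self.set_type[sid] for sid in keep},
            universe=self.universe,
        )


@dataclass
class OntologyDAG:
    """Child -> parents edges of a rooted, acyclic term hierarchy."""

    parents: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.parents = {c: frozenset(p) for c, p in self.parents.items()}
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology edges contain a cycle: {cycle}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for child, parents in self.parents.items():
            g.add_node(child)
            for p in parents:
                g.add_edge(child, p)
        return g

    @property
    def terms(self) -> frozenset[str]:
        out = set(self.parents)
        for ps in self.parents.values():
            out |= ps
        return frozenset(out)

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self.parents.get(t))

    def ancestors(self, term: str) -> frozenset[str]:
        """All strict ancestors of ``term`` (transitive closure of the parent relation)."""
        if term not in self.terms:
            raise KeyError(term)
        seen: set[str] = set()
        frontier = [term]
        while frontier:
            current = frontier.pop()
            for parent in self.parents.get(current, ()):
                if parent not in seen:
                    seen.add(parent)
                    frontier.append(parent)
        return frozenset(seen)


def propagate_ancestors(
    annotations: Mapping[str, Iterable[str]], dag: OntologyDAG
) -> dict[str, frozenset[str]]:
    """Close each gene's term annotations under the parent relation.

    Every annotated term must exist in the DAG; unknown terms raise with the
    offending list.  Idempotent: propagating an already-closed annotation map
    returns it unchanged.
    """
    known = dag.terms
    unknown = sorted({t for ts in annotations.values() for t in ts} - known)
    if unknown:
        raise ValueError(f"terms absent from the ontology: {unknown}")
    closure_cache: dict[str, frozenset[str]] = {}

    def closure(term: str) -> frozenset[str]:
        if term not in closure_cache:
            closure_cache[term] = dag.ancestors(term) | {term}
        return closure_cache[term]

    return {
        gene: frozenset().union(*(closure(t) for t in terms)) if terms else frozenset()
        for gene, terms in annotations.items()
    }


def restrict_to_universe(
    collection: GeneSetCollection, universe: Iterable[str]
) -> GeneSetCollection:
    """Intersect memberships with ``universe``; drop (and log) sets that become empty."""
    universe = frozenset(universe)
    kept: dict[str, frozenset[str]] = {}
    dropped = 0
    for sid, members in collection.sets.items():
        inter = members & universe
        if inter:
            kept[sid] = inter
        else:
            dropped += 1
    if dropped:
        logger.info("restrict_to_universe: dropped %d sets emptied by restriction", dropped)
    return GeneSetCollection(
        sets=kept,
        set_type={sid: collection.set_type[sid] for sid in kept},
        universe=universe,
    )


def read_gmt(path, set_type: str | Mapping[str, str] = "auto") -> GeneSetCollection:
    """Read a GMT file (set_id <tab> description <tab> gene...) into a collection.

    ``set_type`` is one tag for every set, a per-set mapping, or ``"auto"``:
    use the description field as the type tag when it is a recognized tag
    (the convention :func:`write_gmt` emits), else fall back to ``"OG"``.
    Duplicate genes within one line are deduplicated with a warning.
    """
    sets: dict[str, frozenset[str]] = {}
    types: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            sid, desc, *genes = fields
            genes = [g for g in genes if g]
            members = frozenset(genes)
            if len(members) < len(genes):
                logger.warning("%s:%d: duplicate gene ids in set %s deduplicated", path, lineno, sid)
            if sid in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {sid!r}")
            sets[sid] = members
            if set_type == "auto":
                types[sid] = desc if desc in SET_TYPES else "OG"
            elif isinstance(set_type, str):
                types[sid] = set_type
            else:
                types[sid] = set_type.get(sid, "OG")
    return GeneSetCollection(sets=sets, set_type=types)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection as GMT with sorted set ids and members (canonical form)."""
    path = Path(path)
    with open(path, "w") as fh:
        for sid in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[sid]))
            fh.write(f"{sid}\t{collection.set_type[sid]}\t{members}\n")


def read_obo(path) -> OntologyDAG:
    """Reduce an OBO ontology to the child->parent edge table (is_a edges only).

    Other relations (part_of, regulates, ...) are deliberately not traversed;
    the edge table is the propagation contract.
    """
    import obonet

    graph = obonet.read_obo(path)
    parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    return OntologyDAG(parents={c: frozenset(p) for c, p in parents.items()})


def read_edge_tsv(path) -> OntologyDAG:
    """Read a two-column child->parent edge table into an ontology DAG."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns child_id, parent_id")
    child_col, parent_col = frame.columns[:2]
    parents: dict[str, set[str]] = {}
    for child, parent in zip(frame[child_col], frame[parent_col]):
        parents.setdefault(child, set()).add(parent)
        parents.setdefault(parent, set())
    return OntologyDAG(parents={c: frozenset(p) for c, p in parents.items()})
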