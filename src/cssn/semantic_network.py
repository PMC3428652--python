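"""Semantic-type inventory and IS-A hierarchy.

The UMLS Semantic Network (SN) is a small upper-level categorization:
~135 *semantic types* (STs), each with a type unique identifier (TUI,
e.g. ``T109``), a display name, and a dotted tree number encoding its
place in the SN's two-tree IS-A hierarchy.  This module parses the SN
distribution files (SRDEF for type definitions, SRSTR for the IS-A
structure), and exposes the queries the rest of the package needs:
subtree membership, ancestor chains, and the structural/functional axis
split that the chemical subtree is organised around.

Chemicals in the SN are described from two perspectives at once: what a
substance *is* (descendants of **Chemical Viewed Structurally**) and
what it *does* (descendants of **Chemical Viewed Functionally**).  The
axis of an ST drives both the relaxation order and the naming engine.

A 25-type chemical-subtree fixture matching the 2009AA release is
bundled so everything is testable without the licensed UMLS download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import IO, Iterable

import networkx as nx

from .errors import DomainError, IntegrityError, ParseError, UnknownSemanticTypeError

__all__ = [
    "AxisLabel",
    "SemanticType",
    "SemanticNetwork",
    "parse_srdef",
    "parse_srstr",
    "load_bundled_network",
    "BUNDLED_FIXTURE",
]

BUNDLED_FIXTURE = "2009aa-chem"

STRUCTURAL_ROOT = "Chemical Viewed Structurally"
FUNCTIONAL_ROOT = "Chemical Viewed Functionally"
CHEMICAL_ROOT = "Chemical"


class AxisLabel(str, Enum):
    """Which side of the chemical subtree an ST belongs to."""

    STRUCTURAL = "structural"
    FUNCTIONAL = "functional"
    ROOT = "root"


@dataclass(frozen=True)
class SemanticType:
    """One SN semantic type."""

    tui: str
    name: str
    tree_number: str = ""
    definition: str = ""


class SemanticNetwork:
    """An ST inventory plus its IS-A edge set.

    STs may be identified anywhere by TUI or by exact display name; the
    canonical internal key is the TUI.  Within the chemical subtree the
    IS-A relation is a tree (one parent per non-root node), matching the
    SN's design; the class enforces acyclicity globally.
    """

    def __init__(self, types: Iterable[SemanticType], isa_edges: Iterable[tuple[str, str]]):
        self._types: dict[str, SemanticType] = {}
        self._by_name: dict[str, str] = {}
        for st in types:
            if st.tui in self._types:
                raise IntegrityError(f"duplicate TUI {st.tui}")
            if st.name in self._by_name:
                raise IntegrityError(f"duplicate semantic-type name {st.name!r}")
            self._types[st.tui] = st
            self._by_name[st.name] = st.tui
        self._graph = nx.DiGraph()  # edge child -> parent
        self._graph.add_nodes_from(self._types)
        for child, parent in isa_edges:
            child, parent = self.resolve(child), self.resolve(parent)
            self._graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self._graph):
            raise IntegrityError("IS-A edge set contains a cycle")

    # -- identification -------------------------------------------------
    def resolve(self, st: str) -> str:
        """Canonical TUI for an ST given by TUI or display name."""
        if st in self._types:
            return st
        if st in self._by_name:
            return self._by_name[st]
        raise UnknownSemanticTypeError(f"unknown semantic type {st!r}")

    def __contains__(self, st: str) -> bool:
        return st in self._types or st in self._by_name

    def __getitem__(self, st: str) -> SemanticType:
        return self._types[self.resolve(st)]

    def __len__(self) -> int:
        return len(self._types)

    @property
    def types(self) -> frozenset[SemanticType]:
        return frozenset(self._types.values())

    @property
    def isa_edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._graph.edges())

    def name_of(self, st: str) -> str:
        return self[st].name

    # -- hierarchy queries ----------------------------------------------
    def parent_of(self, st: str) -> str | None:
        """The unique IS-A parent TUI, or None for a root."""
        tui = self.resolve(st)
        parents = list(self._graph.successors(tui))
        if not parents:
            return None
        if len(parents) > 1:
            raise IntegrityError(f"{self.name_of(tui)} has multiple IS-A parents")
        return parents[0]

    def children_of(self, st: str) -> list[str]:
        """Direct IS-A children, in tree-number order."""
        tui = self.resolve(st)
        kids = list(self._graph.predecessors(tui))
        kids.sort(key=lambda t: _tree_key(self._types[t].tree_number, t))
        return kids

    def subtree(self, root: str) -> frozenset[str]:
        """TUIs of *root* and all of its IS-A descendants."""
        tui = self.resolve(root)
        # edges point child -> parent, so descendants are graph ancestors
        return frozenset(nx.ancestors(self._graph, tui)) | {tui}

    def ancestors(self, st: str) -> list[str]:
        """Parent chain from *st*'s parent up to the root, in order."""
        chain: list[str] = []
        cur = self.parent_of(st)
        while cur is not None:
            chain.append(cur)
            cur = self.parent_of(cur)
        return chain

    def depth(self, st: str) -> int:
        """Distance to the root of the IS-A tree (root has depth 0)."""
        return len(self.ancestors(st))

    def tree_order(self, root: str) -> list[str]:
        """Depth-first pre-order of subtree(root), children by tree number."""
        out: list[str] = []

        def walk(tui: str) -> None:
            out.append(tui)
            for child in self.children_of(tui):
                walk(child)

        walk(self.resolve(root))
        return out

    def axis_of(self, st: str) -> AxisLabel:
        """Structural/functional axis of a chemical ST.

        The two axis roots classify as their own axis (descendant-or-self);
        the subtree root **Chemical** is ``root``.
        """
        tui = self.resolve(st)
        if tui not in self.subtree(CHEMICAL_ROOT):
            raise DomainError(f"{self.name_of(tui)} is not in the chemical subtree")
        if tui == self.resolve(CHEMICAL_ROOT):
            return AxisLabel.ROOT
        lineage = {tui, *self.ancestors(tui)}
        if self.resolve(STRUCTURAL_ROOT) in lineage:
            return AxisLabel.STRUCTURAL
        if self.resolve(FUNCTIONAL_ROOT) in lineage:
            return AxisLabel.FUNCTIONAL
        raise DomainError(f"{self.name_of(tui)} is on neither chemical axis")


def _tree_key(tree_number: str, tui: str) -> tuple:
    if not tree_number:
        return (1, tui)
    parts: list[object] = []
    for piece in tree_number.split("."):
        parts.append(int(piece) if piece.isdigit() else piece)
    return (0, parts)


# -- file parsing --------------------------------------------------------

def _lines(stream: IO[str] | Iterable[str]) -> Iterable[tuple[int, str]]:
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if line.strip():
            yield lineno, line


def parse_srdef(stream: IO[str] | Iterable[str]) -> set[SemanticType]:
    """Parse an SRDEF-dialect stream into semantic types.

    SRDEF is pipe-delimited with a trailing pipe:
    ``RT|UI|STY/RL|STN/RTN|DEF|EX|UN|NH|ABR|RIN|``.  Only ``STY``
    records (semantic types) are kept; ``RL`` relation records are
    dropped.
    """
    seen: dict[str, int] = {}
    out: set[SemanticType] = set()
    for lineno, line in _lines(stream):
        fields = line.split("|")
        if fields and fields[-1] == "":
            fields = fields[:-1]
        if len(fields) < 10:
            raise ParseError(
                f"expected >= 10 pipe-delimited fields, got {len(fields)}", line=lineno
            )
        rtype, ui, name, tree_number, definition = fields[0], fields[1], fields[2], fields[3], fields[4]
        if rtype != "STY":
            continue
        if ui in seen:
            raise IntegrityError(f"duplicate UI {ui} at lines {seen[ui]} and {lineno}")
        seen[ui] = lineno
        out.add(SemanticType(ui, name, tree_number, definition))
    return out


def parse_srstr(
    stream: IO[str] | Iterable[str], types: Iterable[SemanticType]
) -> set[tuple[str, str]]:
    """Parse an SRSTR-dialect stream into (child_tui, parent_tui) IS-A edges.

    Records are ``STY1|RL|STY2|LS|``.  Only ``isa`` relations with link
    status ``D`` (defined) are kept: the SN also distributes blocked and
    inherited links, which do not build the tree.  ST names are resolved
    against *types*; an unresolvable name is an integrity error.
    """
    by_name = {st.name: st.tui for st in types}
    by_tui = {st.tui for st in types}

    def resolve(name: str, lineno: int) -> str:
        if name in by_name:
            return by_name[name]
        if name in by_tui:
            return name
        raise IntegrityError(f"line {lineno}: unresolvable semantic-type name {name!r}")

    edges: set[tuple[str, str]] = set()
    for lineno, line in _lines(stream):
        fields = line.split("|")
        if fields and fields[-1] == "":
            fields = fields[:-1]
        if len(fields) < 4:
            raise ParseError(
                f"expected STY1|RL|STY2|LS record, got {len(fields)} fields", line=lineno
            )
        sty1, rel, sty2, status = fields[0], fields[1], fields[2], fields[3]
        if rel != "isa" or status != "D":
            continue
        edges.add((resolve(sty1, lineno), resolve(sty2, lineno)))
    return edges


def load_bundled_network(name: str = BUNDLED_FIXTURE) -> SemanticNetwork:
    """Load the bundled 2009AA chemical-subtree network (25 STs, 24 edges)."""
    if name != BUNDLED_FIXTURE:
        raise UnknownSemanticTypeError(f"unknown bundled fixture {name!r}")
    doc = json.loads(
        resources.files("cssn.data").joinpath("sn2009aa_chemical.json").read_text("utf-8")
    )
    return network_from_json(doc)


def network_from_json(doc: dict) -> SemanticNetwork:
    """Build a network from the versioned JSON fixture document."""
    types = [
        SemanticType(
            t["tui"], t["name"], t.get("tree_number", ""), t.get("definition", "")
        )
        for t in doc["types"]
    ]
    return SemanticNetwork(types, [tuple(e) for e in doc["edges"]])


def network_to_json(net: SemanticNetwork, release: str = "custom") -> dict:
    """Serialise a network to the JSON fixture layout."""
    types = sorted(net.types, key=lambda st: st.tui)
    return {
        "release": release,
        "types": [
            {
                "tui": st.tui,
                "name": st.name,
                "tree_number": st.tree_number,
                "definition": st.definition,
            }
            for st in types
        ],
        "edges": sorted([list(e) for e in net.isa_edges]),
    }
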