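"""Derivation of a chemical specialty semantic network (CSSN).

The CSSN refines the SN's chemical subtree into *mutually exclusive*
types, derived automatically from the existing ST assignments:

* one **pure semantic type** (PST) per ST of the subtree — always
  present, even with an empty exact extent, so parent derivation always
  has singleton fallbacks;
* one **intersection semantic type** (IST) per multi-ST signature whose
  exact extent has at least N concepts.  The threshold N applies to
  ISTs only and trades network size against concept coverage: at N = 1
  every observed combination is a type and coverage is total.

The hierarchy is a DAG rather than a tree.  PSTs mirror the SN's IS-A
edges exactly.  An IST's parents are the *maximal* available proper
sub-signatures, recomputed after threshold filtering — dropping an IST
can promote a smaller IST or a PST into the parent set, which is what
produces the different 3-IST parent configurations (three 2-ISTs; two
2-ISTs; a 2-IST and a PST; three PSTs).  Every IST ends up with at
least two parents, and the union of a type's parent signatures always
equals its own signature.

Concepts of dropped ISTs either stay uncovered (strategy ``none``) or
are reassigned through the relaxation module.  Reassigned concepts are
recorded in the assignment map but not in the target's printed extent,
so listings keep exact-signature counts; a separate assigned count
includes them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .assignments import Signature, SignatureIndex
from .errors import CssnError, DomainError
from .naming import Namer
from .relaxation import RelaxationTrace, reassign_largest, reassign_relax
from .semantic_network import SemanticNetwork

__all__ = [
    "STRATEGIES",
    "RefinedType",
    "BuildConfig",
    "CSSN",
    "derive_types",
    "derive_parents",
    "build",
    "coverage",
    "sweep",
]

STRATEGIES = ("none", "largest_extent", "relax")


@dataclass(frozen=True)
class RefinedType:
    """A pure (singleton signature) or intersection (>= 2) type."""

    signature: Signature
    extent: frozenset[str] = frozenset()
    display_name: str = ""

    @property
    def kind(self) -> str:
        return "PST" if len(self.signature) == 1 else "IST"

    @property
    def extent_size(self) -> int:
        return len(self.extent)


@dataclass(frozen=True)
class BuildConfig:
    """Build parameters: threshold N (ISTs only), relaxation strategy, root."""

    threshold: int = 300
    strategy: str = "none"
    root: str = "Chemical"

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise DomainError("threshold must be a positive integer")
        if self.strategy not in STRATEGIES:
            raise DomainError(
                f"strategy must be one of {STRATEGIES}, got {self.strategy!r}"
            )


@dataclass
class CSSN:
    """A derived specialty network plus its concept assignment map."""

    net: SemanticNetwork
    config: BuildConfig
    types: dict[Signature, RefinedType]
    isa_edges: frozenset[tuple[Signature, Signature]]
    assignment: dict[str, Signature]
    uncovered: frozenset[str]
    traces: dict[Signature, RelaxationTrace] = field(default_factory=dict)

    @property
    def signatures(self) -> frozenset[Signature]:
        return frozenset(self.types)

    @property
    def psts(self) -> list[RefinedType]:
        return [t for t in self.types.values() if t.kind == "PST"]

    @property
    def ists(self) -> list[RefinedType]:
        return [t for t in self.types.values() if t.kind == "IST"]

    @property
    def type_count(self) -> int:
        return len(self.types)

    @property
    def covered_count(self) -> int:
        """Concepts whose exact signature exists as a type."""
        return sum(t.extent_size for t in self.types.values())

    @property
    def concept_count(self) -> int:
        return len(self.assignment) + len(self.uncovered)

    def assigned_count(self, sig: Signature) -> int:
        """Concepts assigned to *sig* including relaxed-in ones."""
        return sum(1 for s in self.assignment.values() if s == sig)

    def parents_of(self, sig: Signature) -> set[Signature]:
        return {p for c, p in self.isa_edges if c == sig}

    def coverage(self) -> float:
        """Fraction of concepts keeping exact-signature coverage (pre-relaxation)."""
        total = self.concept_count
        return 1.0 if total == 0 else self.covered_count / total

    # -- export ----------------------------------------------------------
    def to_json(self) -> dict:
        namer = Namer(self.net)

        def key(sig: Signature) -> list[str]:
            return sorted(sig)

        types = sorted(
            self.types.values(), key=lambda t: (len(t.signature), key(t.signature))
        )
        return {
            "config": {
                "threshold": self.config.threshold,
                "strategy": self.config.strategy,
                "root": self.config.root,
            },
            "types": [
                {
                    "signature": key(t.signature),
                    "kind": t.kind,
                    "name": t.display_name,
                    "label": namer.intersection_label(t.signature),
                    "extent_size": t.extent_size,
                    "assigned_size": self.assigned_count(t.signature),
                }
                for t in types
            ],
            "isa_edges": sorted(
                [key(c), key(p)] for c, p in self.isa_edges
            ),
            "concepts": self.concept_count,
            "covered": self.covered_count,
            "uncovered": sorted(self.uncovered),
        }

    def to_json_str(self, **kwargs) -> str:
        return json.dumps(self.to_json(), ensure_ascii=False, **kwargs)

    def edges_tsv(self) -> str:
        """Flat child/parent edge list using display names."""
        rows = sorted(
            (self.types[c].display_name, self.types[p].display_name)
            for c, p in self.isa_edges
        )
        return "".join(f"{c}\t{p}\n" for c, p in rows)


def derive_types(
    index: SignatureIndex, net: SemanticNetwork, config: BuildConfig
) -> set[RefinedType]:
    """The CSSN's type set: all PSTs plus ISTs meeting the threshold."""
    subtree = net.subtree(config.root)
    for sig in index.signatures:
        if not sig <= subtree:
            raise CssnError(
                f"index signature {sorted(sig)} escapes the {config.root!r} subtree"
            )
    out: set[RefinedType] = set()
    for tui in subtree:
        sig = Signature([tui])
        out.add(RefinedType(sig, index.extents.get(sig, frozenset())))
    for sig, extent in index.extents.items():
        if len(sig) >= 2 and len(extent) >= config.threshold:
            out.add(RefinedType(sig, extent))
    return out


def derive_parents(
    sig: Signature,
    available: set[Signature] | frozenset[Signature],
    net: SemanticNetwork,
) -> set[Signature]:
    """Parent signatures of one type.

    PSTs mirror the SN: the parent is the SN parent's singleton (empty
    for the subtree root).  ISTs get the maximal available proper
    sub-signatures; since all singletons are available, the union of the
    parents always reconstitutes the child's signature and there are
    always at least two of them.
    """
    if len(sig) == 1:
        (tui,) = sig
        parent = net.parent_of(tui)
        return set() if parent is None else {Signature([parent])}
    from .relaxation import maximal_proper_subsignatures

    return maximal_proper_subsignatures(sig, available)


def build(
    index: SignatureIndex,
    net: SemanticNetwork,
    config: BuildConfig | None = None,
    namer: Namer | None = None,
) -> CSSN:
    """Assemble the full CSSN: types, IS-A edges, and concept assignments."""
    config = config or BuildConfig()
    namer = namer or Namer(net)

    typeset = derive_types(index, net, config)
    types: dict[Signature, RefinedType] = {
        t.signature: replace(t, display_name=namer.render(t.signature)) for t in typeset
    }
    available = frozenset(types)

    edges: set[tuple[Signature, Signature]] = set()
    for sig in available:
        for parent in derive_parents(sig, available, net):
            edges.add((sig, parent))

    assignment: dict[str, Signature] = {}
    uncovered: set[str] = set()
    traces: dict[Signature, RelaxationTrace] = {}
    extent_size = {sig: t.extent_size for sig, t in types.items()}

    for sig, extent in index.extents.items():
        if sig in types:
            for cui in extent:
                assignment[cui] = sig
            continue
        # exact IST dropped by the threshold
        if config.strategy == "none":
            uncovered.update(extent)
            continue
        if config.strategy == "largest_extent":
            target = reassign_largest(sig, available, extent_size)
        else:
            trace = reassign_relax(sig, available, net)
            traces[sig] = trace
            target = trace.result
        for cui in extent:
            assignment[cui] = target

    return CSSN(
        net=net,
        config=config,
        types=types,
        isa_edges=frozenset(edges),
        assignment=assignment,
        uncovered=frozenset(uncovered),
        traces=traces,
    )


def coverage(cssn: CSSN) -> float:
    """Fraction of concepts whose exact signature exists as a CSSN type.

    Defined pre-relaxation, so it is independent of the strategy; at
    N = 1 it is exactly 1.0.
    """
    return cssn.coverage()


def sweep(
    index: SignatureIndex,
    net: SemanticNetwork,
    thresholds: Iterable[int],
    root: str = "Chemical",
) -> list[tuple[int, int, float]]:
    """(N, type count, coverage fraction) rows, one per requested threshold."""
    rows = []
    for n in thresholds:
        cssn = build(index, net, BuildConfig(threshold=n, strategy="none", root=root))
        rows.append((n, cssn.type_count, cssn.coverage()))
    return rows
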