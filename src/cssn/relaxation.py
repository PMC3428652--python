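"""Reassignment of concepts whose intersection type fell below threshold.

When a threshold N > 1 drops an intersection type (IST), its concepts
lose exact type coverage.  Two strategies restore it:

``largest_extent``
    Among the maximal proper sub-signatures that exist as types, pick
    the one with the largest extent.  Example: a concept carrying
    {Organic Chemical, Hormone, Immunologic Factor} moves to
    Organic Chemical ∩ Immunologic Factor when that pair's extent (136)
    beats Organic Chemical ∩ Hormone's (62).

``relax``
    Step-wise generalisation: repeatedly replace one member ST by its
    SN parent (merging duplicates) until the resulting signature exists
    as a type.  Members are relaxed within the functional group first,
    then the structural group, deepest ST first — the deeper type has
    an intermediate ancestor to visit before the common one, so
    specificity is surrendered as slowly as possible.  After every
    single step availability is re-checked, so e.g.
    {Organic Chemical, Pharmacologic Substance, Immunologic Factor}
    stops at {Organic Chemical, Pharmacologic Substance,
    Biologically Active Substance} as soon as that triple is a valid
    type, without touching Pharmacologic Substance.

Both strategies are total: singleton signatures (pure types) always
exist, and every ST relaxes eventually to the subtree root, so a valid
target is always reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .assignments import Signature
from .errors import DomainError
from .semantic_network import AxisLabel, SemanticNetwork, _tree_key

__all__ = [
    "RelaxStep",
    "RelaxationTrace",
    "candidates",
    "maximal_proper_subsignatures",
    "reassign_largest",
    "relax_step",
    "reassign_relax",
]


@dataclass(frozen=True)
class RelaxStep:
    """One generalisation step: *relaxed* was replaced by *replacement*."""

    relaxed: str
    replacement: str
    result: Signature


@dataclass
class RelaxationTrace:
    """Audit record of a relax-strategy reassignment."""

    start: Signature
    steps: list[RelaxStep] = field(default_factory=list)

    @property
    def result(self) -> Signature:
        return self.steps[-1].result if self.steps else self.start

    def to_json(self, name_of=lambda t: t) -> dict:
        return {
            "start": sorted(name_of(t) for t in self.start),
            "steps": [
                {
                    "relaxed": name_of(s.relaxed),
                    "replacement": name_of(s.replacement),
                    "result": sorted(name_of(t) for t in s.result),
                }
                for s in self.steps
            ],
            "result": sorted(name_of(t) for t in self.result),
        }


def maximal_proper_subsignatures(
    sig: Signature, available: set[Signature] | frozenset[Signature]
) -> set[Signature]:
    """Maximal elements (under set inclusion) of the available proper subsets."""
    subs = [s for s in available if s < sig]
    return {s for s in subs if not any(s < t for t in subs)}


def candidates(
    sig: Signature, available: set[Signature] | frozenset[Signature]
) -> set[Signature]:
    """Candidate reassignment targets for a dropped signature.

    The maximal available proper sub-signatures; never empty as long as
    *available* contains the singletons of *sig*'s members.
    """
    return maximal_proper_subsignatures(sig, available)


def reassign_largest(
    sig: Signature,
    available: set[Signature] | frozenset[Signature],
    extent_size,
) -> Signature:
    """Largest-extent strategy: the candidate with the biggest extent.

    *extent_size* maps signature -> exact extent count (a mapping or a
    callable).  Ties break toward the larger signature, then the
    lexicographically smaller tuple of sorted member TUIs, for
    determinism.
    """
    size = extent_size if callable(extent_size) else lambda s: extent_size.get(s, 0)
    cands = candidates(sig, available)
    if not cands:
        raise DomainError(f"no reassignment candidates for {sorted(sig)}")
    return min(cands, key=lambda s: (-size(s), -len(s), tuple(sorted(s))))


def _phase_pool(sig: Signature, net: SemanticNetwork) -> list[str]:
    axes = {t: net.axis_of(t) for t in sig}
    functional = [t for t, a in axes.items() if a is AxisLabel.FUNCTIONAL]
    if functional:
        return functional
    return [t for t, a in axes.items() if a is AxisLabel.STRUCTURAL]


def relax_step(sig: Signature, net: SemanticNetwork) -> tuple[Signature, RelaxStep]:
    """Replace one member ST by its SN parent, merging duplicates.

    Functional members relax before structural ones; within the active
    group the deepest ST (greatest distance to the subtree root) goes
    first, ties broken toward the greater tree number.  The subtree
    root itself is not relaxable.
    """
    pool = _phase_pool(sig, net)
    if not pool:
        raise DomainError("signature contains only the subtree root; nothing to relax")
    target = max(
        pool, key=lambda t: (net.depth(t), _tree_key(net[t].tree_number, t))
    )
    parent = net.parent_of(target)
    assert parent is not None  # pool excludes the root
    new_sig = Signature(sig - {target}) | {parent}
    step = RelaxStep(relaxed=target, replacement=parent, result=Signature(new_sig))
    return step.result, step


def reassign_relax(
    sig: Signature,
    available: set[Signature] | frozenset[Signature],
    net: SemanticNetwork,
) -> RelaxationTrace:
    """Relax strategy: generalise step by step until a valid type is reached.

    *available* is the set of signatures that exist as types in the
    target network (all singletons, plus the intersections that
    survived the threshold).  Availability is re-checked after every
    single step.  Terminates because the total member depth strictly
    decreases; the subtree-root singleton is the absorbing fallback.
    """
    trace = RelaxationTrace(start=Signature(sig))
    current = Signature(sig)
    while current not in available:
        current, step = relax_step(current, net)
        trace.steps.append(step)
    return trace
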