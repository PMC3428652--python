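"""Display names for pure and intersection types.

Formally an intersection type is named "A ∩ B", but readable names are
built by concatenating words drawn from the member STs' names, dropping
filler words like "Substance" or "Chemical" from modifier positions
("Pharmacologic Substance" contributes just "Pharmacologic").  Members
are ordered left-to-right by ascending priority so that the most
defining aspect lands rightmost as the head: general-purpose functional
aspects first, then structural aspects, then specific functional
aspects — "Pharmacologic Steroid" is first and foremost a steroid, and
"Pharmacologic Steroid Hormone" first and foremost a hormone.

The per-ST forms and priority classes ship as an editable TSV
(``data/name_rules.tsv``), so curators can adjust wording without code
changes.  One known wrinkle: the published examples are not perfectly
consistent about whether a couple of functional types outrank
structural heads; the shipped table follows the majority pattern and
documents the exception (see docs/methods.md).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import IO, Iterable, Mapping

from .assignments import Signature
from .errors import DomainError, IntegrityError
from .semantic_network import SemanticNetwork, _tree_key

__all__ = ["NameRule", "Namer", "load_name_rules", "PRIORITY_CLASSES"]

# ascending priority: the rightmost (head) component has the highest class
PRIORITY_CLASSES = ("root", "general_functional", "structural", "specific_functional")
_CLASS_RANK = {c: i for i, c in enumerate(PRIORITY_CLASSES)}


@dataclass(frozen=True)
class NameRule:
    """Naming behaviour of one semantic type.

    ``head_form`` is used when the ST is the rightmost component of an
    intersection name; ``modifier_form`` otherwise.
    """

    tui: str
    name: str
    head_form: str
    modifier_form: str
    priority_class: str

    def __post_init__(self) -> None:
        if self.priority_class not in _CLASS_RANK:
            raise IntegrityError(
                f"unknown priority class {self.priority_class!r} for {self.tui}"
            )


def load_name_rules(stream: IO[str] | Iterable[str] | None = None) -> dict[str, NameRule]:
    """Load the name-rule table (the packaged default when *stream* is None)."""
    if stream is None:
        text = resources.files("cssn.data").joinpath("name_rules.tsv").read_text("utf-8")
        stream = text.splitlines()
    rules: dict[str, NameRule] = {}
    for row in csv.DictReader(stream, delimiter="\t"):
        rule = NameRule(
            row["tui"], row["name"], row["head_form"], row["modifier_form"],
            row["priority_class"],
        )
        if rule.tui in rules:
            raise IntegrityError(f"duplicate name rule for {rule.tui}")
        rules[rule.tui] = rule
    return rules


class Namer:
    """Renders signatures into display names against one network + rule table."""

    def __init__(self, net: SemanticNetwork, rules: Mapping[str, NameRule] | None = None):
        self.net = net
        self.rules = dict(rules) if rules is not None else load_name_rules()

    def _rule(self, st: str) -> NameRule:
        tui = self.net.resolve(st)
        if tui not in self.rules:
            raise DomainError(f"no name rule for {self.net.name_of(tui)} ({tui})")
        return self.rules[tui]

    def priority_class(self, st: str) -> str:
        """Priority class of one chemical ST."""
        return self._rule(st).priority_class

    def order(self, sig: Signature) -> list[str]:
        """Members of *sig* in left-to-right display order.

        Ascending priority class; ties within a class break by SN tree
        number (which reproduces the published structural-pair orderings
        where alphabetical order would not).
        """
        def key(tui: str) -> tuple:
            return (
                _CLASS_RANK[self._rule(tui).priority_class],
                _tree_key(self.net[tui].tree_number, tui),
            )

        return sorted((self.net.resolve(t) for t in sig), key=key)

    def render(self, sig: Signature) -> str:
        """Display name for a signature.

        Singletons keep the ST name unchanged; intersections use
        modifier forms with the rightmost member in head form.
        """
        if not sig:
            raise DomainError("cannot render an empty signature")
        if len(sig) == 1:
            (tui,) = sig
            return self.net.name_of(tui)
        ordered = self.order(sig)
        words = [self._rule(t).modifier_form for t in ordered[:-1]]
        words.append(self._rule(ordered[-1]).head_form)
        return " ".join(words)

    def intersection_label(self, sig: Signature) -> str:
        """Formal "A ∩ B" label, members in TUI order (the published style)."""
        names = [self.net.name_of(t) for t in sorted(sig, key=self.net.resolve)]
        return " ∩ ".join(names)

    def placement_parent(
        self, sig: Signature, parents: Iterable[Signature]
    ) -> Signature:
        """The parent a type is indented under in listings.

        That is the parent holding the highest-priority (rightmost)
        components of the child's name — equivalently the parent whose
        own rendered name is the longest suffix of the child's rendered
        name.
        """
        parents = list(parents)
        if not parents:
            raise DomainError("type has no parents to place under")
        ordered = self.order(sig)
        # suffix sets of the child's display order, longest first
        for k in range(len(ordered) - 1, 0, -1):
            suffix = frozenset(ordered[-k:])
            for p in parents:
                if frozenset(p) == suffix:
                    return p
        # fallback: parent containing the head component, largest first
        head = ordered[-1]
        with_head = [p for p in parents if head in p]
        pool = with_head or parents
        return max(pool, key=lambda p: (len(p), sorted(p)))
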