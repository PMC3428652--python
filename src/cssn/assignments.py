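"""Concept-to-semantic-type assignment tables.

The Metathesaurus assigns each concept (CUI) one or more semantic
types; the distribution file is MRSTY.RRF, pipe-delimited
``CUI|TUI|STN|STY|ATUI|CVF|``.  The chemical specialty network is
scoped to the chemical subtree: a concept carrying both chemical and
non-chemical STs keeps only its chemical ones (the classic example is
*Soap*, a **Lipid** that is also a **Manufactured Object** — the
non-chemical assignment is ignored), and a concept with no chemical ST
is excluded.

The *signature* of a concept is the exact set of chemical TUIs it
carries; grouping concepts by signature yields the extents from which
pure and intersection types are derived.  Signatures are plain
``frozenset`` values — order-free by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from .errors import ParseError

__all__ = [
    "Signature",
    "AssignmentTable",
    "SignatureIndex",
    "read_mrsty",
    "restrict_to_chemical",
    "build_index",
]

Signature = frozenset  # of TUI strings


def read_mrsty(stream: IO[str] | Iterable[str]) -> Iterator[tuple[str, str]]:
    """Yield (CUI, TUI) pairs from an MRSTY.RRF-dialect stream.

    Two dialects are auto-detected per line: the 6-field pipe-delimited
    RRF layout with trailing pipe, and a minimal two-column TSV
    (``cui<TAB>tui``, optional header row).  Pairs are yielded in file
    order with duplicates preserved; deduplication happens at table
    construction.
    """
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if "|" in line:
            fields = line.split("|")
        else:
            fields = line.split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            if lineno == 1 and fields[0].lower() == "cui":
                continue  # TSV header row
            raise ParseError("expected at least CUI and TUI fields", line=lineno)
        if lineno == 1 and fields[0].lower() == "cui" and fields[1].lower() == "tui":
            continue
        yield fields[0], fields[1]


@dataclass
class AssignmentTable:
    """Concept -> chemical-signature map after subtree restriction.

    ``mixed_count`` records how many concepts carried both a chemical
    and a non-chemical ST before restriction (their non-chemical STs
    were dropped, not the concepts).
    """

    entries: dict[str, Signature] = field(default_factory=dict)
    mixed_count: int = 0

    def __len__(self) -> int:
        return len(self.entries)


def restrict_to_chemical(
    pairs: Iterable[tuple[str, str]], chemical_set: frozenset[str] | set[str]
) -> AssignmentTable:
    """Restrict raw (CUI, TUI) pairs to the chemical subtree.

    Concepts keep only TUIs inside *chemical_set*; any TUI outside it is
    treated as non-chemical.  Concepts left with no chemical TUI are
    excluded entirely.  Duplicate pairs are deduplicated silently (RRF
    files may repeat a pair across ATUIs).  Idempotent: restricting an
    already-restricted table changes nothing.
    """
    chemical_set = frozenset(chemical_set)
    chem: dict[str, set[str]] = {}
    had_nonchem: set[str] = set()
    for cui, tui in pairs:
        if tui in chemical_set:
            chem.setdefault(cui, set()).add(tui)
        else:
            had_nonchem.add(cui)
    entries = {cui: Signature(tuis) for cui, tuis in chem.items()}
    mixed = sum(1 for cui in entries if cui in had_nonchem)
    return AssignmentTable(entries=entries, mixed_count=mixed)


@dataclass
class SignatureIndex:
    """Concepts grouped by exact signature.

    The extents form a partition of the restricted table's concepts:
    pairwise disjoint (a concept has exactly one exact signature), and
    their union is the whole concept set.
    """

    extents: dict[Signature, frozenset[str]] = field(default_factory=dict)

    @property
    def signatures(self) -> frozenset[Signature]:
        return frozenset(self.extents)

    @property
    def concept_count(self) -> int:
        return sum(len(v) for v in self.extents.values())

    def extent_size(self, sig: Signature) -> int:
        return len(self.extents.get(sig, ()))


def build_index(table: AssignmentTable) -> SignatureIndex:
    """Group a restricted table's concepts by exact signature."""
    groups: dict[Signature, set[str]] = {}
    for cui, sig in table.entries.items():
        groups.setdefault(sig, set()).add(cui)
    return SignatureIndex({sig: frozenset(cuis) for sig, cuis in groups.items()})
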