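"""Tabular views of a derived network.

Three report shapes:

* the hierarchically indented type listing (formal "A ∩ B" label, exact
  extent size, display name indented under the placement parent, one
  asterisk per parent beyond the placement one);
* the SN-versus-pure-type comparison (a concept counts once per
  chemical ST in the SN column, but only exact singletons count in the
  pure-type column);
* the audit listing: at threshold 1, intersection types with very small
  extents (six or fewer concepts by default) are prime suspects for
  inconsistent ST assignments and are handed to a human auditor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .assignments import AssignmentTable, Signature
from .builder import CSSN
from .naming import Namer

__all__ = ["ListingRow", "render_listing", "format_listing", "compare_sn", "audit_candidates"]

INDENT = "  "


@dataclass(frozen=True)
class ListingRow:
    """One row of the indented type listing."""

    signature: Signature
    rst_label: str
    extent_size: int
    display_name: str
    depth: int
    n_parents: int

    @property
    def asterisks(self) -> int:
        # each asterisk marks a parent besides the placement parent
        return max(0, self.n_parents - 1)

    @property
    def indented_name(self) -> str:
        return f"{INDENT * self.depth}{'*' * self.asterisks}{self.display_name}"


def render_listing(cssn: CSSN, namer: Namer | None = None) -> list[ListingRow]:
    """Ordered listing rows for a built network.

    Pure types appear in SN tree order (depth-first by tree number).
    Each intersection type is indented under its placement parent — the
    parent carrying the rightmost components of its name — inside the
    block of the pure type its placement chain roots at.  Within a
    block, intersections are ordered by signature size then descending
    extent, which reproduces the published listing order.
    """
    namer = namer or Namer(cssn.net)
    parents = {sig: cssn.parents_of(sig) for sig in cssn.types}
    placement: dict[Signature, Signature] = {}
    for sig in cssn.types:
        if len(sig) >= 2:
            placement[sig] = namer.placement_parent(sig, parents[sig])

    def block_root(sig: Signature) -> Signature:
        while len(sig) >= 2:
            sig = placement[sig]
        return sig

    blocks: dict[Signature, list[Signature]] = {}
    for sig in placement:
        blocks.setdefault(block_root(sig), []).append(sig)

    depth_cache: dict[Signature, int] = {}

    def depth_of(sig: Signature) -> int:
        if sig not in depth_cache:
            if len(sig) == 1:
                (tui,) = sig
                depth_cache[sig] = cssn.net.depth(tui)
            else:
                depth_cache[sig] = depth_of(placement[sig]) + 1
        return depth_cache[sig]

    def row(sig: Signature) -> ListingRow:
        t = cssn.types[sig]
        return ListingRow(
            signature=sig,
            rst_label=namer.intersection_label(sig),
            extent_size=t.extent_size,
            display_name=t.display_name,
            depth=depth_of(sig),
            n_parents=len(parents[sig]),
        )

    rows: list[ListingRow] = []
    for tui in cssn.net.tree_order(cssn.config.root):
        pst = Signature([tui])
        rows.append(row(pst))
        members = blocks.get(pst, [])
        members.sort(key=lambda s: (len(s), -cssn.types[s].extent_size, sorted(s)))
        rows.extend(row(s) for s in members)
    return rows


def format_listing(rows: list[ListingRow]) -> str:
    """The indented text rendering (label, extent, indented name)."""
    return "".join(
        f"{r.rst_label}\t{r.extent_size:,}\t{r.indented_name}\n" for r in rows
    )


def compare_sn(table: AssignmentTable, cssn: CSSN) -> list[tuple[str, int, int]]:
    """(ST name, SN-style count, pure-type count) rows in tree order.

    The SN column counts a concept once for *each* chemical ST it
    carries; the pure-type column counts only concepts whose exact
    signature is that singleton.
    """
    sn_counts: dict[str, int] = {}
    for sig in table.entries.values():
        for tui in sig:
            sn_counts[tui] = sn_counts.get(tui, 0) + 1
    rows = []
    for tui in cssn.net.tree_order(cssn.config.root):
        pst = cssn.types.get(Signature([tui]))
        rows.append(
            (
                cssn.net.name_of(tui),
                sn_counts.get(tui, 0),
                pst.extent_size if pst else 0,
            )
        )
    return rows


def audit_candidates(
    cssn: CSSN, max_extent: int = 6
) -> list[tuple[Signature, int, frozenset[str]]]:
    """Small intersection types worth an auditor's review.

    Expects a network built with threshold 1 (warns otherwise, since
    higher thresholds have already discarded the suspects).  Returns
    (signature, extent size, member CUIs) sorted by ascending extent.
    """
    if cssn.config.threshold != 1:
        warnings.warn(
            f"audit expects a threshold-1 network, got N={cssn.config.threshold}",
            stacklevel=2,
        )
    out = [
        (t.signature, t.extent_size, t.extent)
        for t in cssn.ists
        if 1 <= t.extent_size <= max_extent
    ]
    out.sort(key=lambda r: (r[1], sorted(r[0])))
    return out
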