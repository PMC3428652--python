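# Methods

## The model

The package operates on two inputs: a semantic network — an inventory
of semantic types (STs), each with a TUI, a display name and a dotted
tree number, plus a defined-`isa` edge set — and an assignment table
mapping concepts (CUIs) to one or more STs.  Within the chemical
subtree the IS-A relation is required to be a tree (every non-root ST
has exactly one parent), which the loader enforces; tree numbers, when
present, must be dotted-prefix-consistent with the edges.  The subtree
splits into a *structural* axis (descendants of **Chemical Viewed
Structurally**) and a *functional* axis (descendants of **Chemical
Viewed Functionally**); the root **Chemical** belongs to neither.

Restriction to the chemical subtree follows a single rule: a concept
keeps exactly its chemical STs.  Concepts with only non-chemical STs
are dropped silently (the network scopes chemicals only, so this is
not an error); concepts with both keep their chemical STs and are
tallied in `mixed_count`.  Duplicate (CUI, TUI) rows — which occur in
real RRF files across ATUIs — are deduplicated at table construction.

The *signature* of a concept is the exact set of its chemical TUIs,
represented as a plain `frozenset`.  Grouping by signature yields
extents that partition the concept set by construction; the partition
and totality properties asserted in the tests follow from this
representation rather than from any bookkeeping.

## Type derivation and the threshold

A build instantiates one pure type (PST) per subtree ST — always,
even with an empty exact extent — and one intersection type (IST) per
multi-ST signature whose extent has at least `threshold` concepts.
Instantiating all PSTs is deliberate: parent derivation and both
relaxation strategies rely on singleton signatures always being
available as fallbacks, and it keeps the type count definition uniform
(25 PSTs + surviving ISTs for the chemical subtree).  The threshold
never applies to PSTs.

*Coverage* is the fraction of concepts whose exact signature exists as
a type.  It is defined before any relaxation, so it is independent of
the strategy and equals 1.0 exactly at N = 1; this is the quantity the
threshold sweep reports, as a percentage printed to one decimal.

## Parent derivation

PST IS-A edges mirror the source network's subtree edges one-for-one.
An IST's parents are the *maximal* elements, under set inclusion, of
the available proper sub-signatures — recomputed after threshold
filtering, so dropping an IST promotes smaller ISTs or PSTs into the
parent set.  Because every singleton is available, each IST has at
least two parents and the union of its parents' signatures equals its
own; both facts are asserted as invariants and checked against a
brute-force subset-enumeration oracle in the tests.  Signatures of any
size are handled uniformly; 2- and 3-member intersections are only
special in display.

## Relaxation of dropped intersections

Two reassignment strategies restore coverage for concepts of dropped
ISTs:

* `largest_extent` — among the maximal available sub-signatures,
  choose the one with the largest exact extent.  Ties break toward the
  larger signature, then the lexicographically smaller tuple of sorted
  TUIs; the tie rule is a determinism choice, not a semantic one.
* `relax` — repeatedly replace one member ST with its SN parent
  (merging duplicates) until the current signature exists as a type,
  re-checking availability after every single step.

Step order for `relax`: members on the functional axis relax before
structural ones, and within the active group the deepest ST (greatest
distance to the root) goes first; the deeper type has an intermediate
ancestor to pass through, so specificity is surrendered gradually
rather than jumping to a common ancestor.  Between equally deep
members the one with the greater tree number (the later sibling in SN
order) relaxes first — a pure determinism choice.  The functional-first
phase order itself is a design choice the published worked examples
are consistent with but do not force; it is configurable only by
editing the phase pool in `relaxation._phase_pool`.  Termination is
guaranteed because total member depth strictly decreases each step and
the root singleton is always an available absorbing state; both
strategies are therefore total, which is property-tested.

Reassigned concepts are recorded in the assignment map of the target
type but *not* added to its printed extent, so listings show exact
extents; `CSSN.assigned_count` includes the relaxed-in concepts.

## Naming

Each ST carries a head form, a modifier form (filler words such as
"Substance"/"Chemical" dropped), and one of three priority classes:
`general_functional` < `structural` < `specific_functional`.  An
intersection name concatenates the members in ascending priority with
the last member in head form; ties within a class order by tree
number, which reproduces the published structural pairs
("Nucleic Acid, Nucleoside, or Nucleotide Carbohydrate") where
alphabetical order would not.  Singleton types keep the ST name.

The class memberships are inferred from the published names, which are
not fully consistent.  Two judgement calls:

* **Neuroreactive Substance or Biogenic Amine** is classified
  `general_functional`, following the published sample-categorization
  name "Neuroreactive or Biogenic Amine Amino Acid, Peptide, or
  Protein" (as a specific functional head it would instead have
  produced "… Neuroreactive Substance or Biogenic Amine").
* **Indicator, Reagent, or Diagnostic Aid** stays
  `specific_functional` (forced by "Organic Indicator, Reagent, or
  Diagnostic Aid"); the one published row "Indicator, Reagent, or
  Diagnostic Aid Amino Acid, Peptide, or Protein" contradicts that
  classification and is the single printed name the default rule table
  does not reproduce.

The table ships as data (`data/name_rules.tsv`) so curators can change
either decision without touching code.

For listings, a type is indented under its *placement parent*: the
parent holding the rightmost (highest-priority) components of its
name, found as the parent whose own rendered name is the longest
suffix of the child's.  One asterisk marks each parent beyond the
placement one.  Within a pure type's block, intersections are ordered
by signature size then descending extent — this matches the published
partial listing, whose 3-member row follows both 2-member rows even
though it is indented under the first of them.

## Synthetic data

The generator emits MRSTY-dialect text from a spec of (signature,
count) rows, with optional mixed rows that attach one non-chemical TUI
per concept (default placeholder T073), emulating mixed concepts like
*Soap*.  Synthetic CUIs use an `S` prefix (never colliding with real
`C…` CUIs), output row order is shuffled deterministically by the spec
seed, and `iter_pairs` provides an unshuffled streaming path for large
extents.  What it does *not* emulate: concept names, source
vocabularies, assignment errors, or any correlation structure between
signatures — so green tests demonstrate the derivation machinery, not
robustness to real-world assignment noise.

`paper_extent_spec()` encodes the published 2009AA extent sizes: the
25 pure-type exact counts and the twelve intersection extents printed
with the method's worked examples (including the single-concept
{Organic Chemical, Hormone, Immunologic Factor} combination).  It is
*not* the full 2009AA signature distribution — that exists only in the
study's supplementary listing — so full-scale published figures (68
types at N = 300, 97.3% coverage, the published sweep column) are
reproducible only with the licensed UMLS files, for which the CLI's
`--srdef/--srstr/--mrsty` path is the intended route.  A `divisor`
scales every count by integer division with a floor of one, preserving
the signature structure for fast tests.

`random_spec(seed, …)` draws a seed-deterministic random distribution
(default: 1,000 concepts over ~30 signatures of size 1–3, 2% mixed)
used by the property tests and the acceptance script.

## Problem sizes and numerical notes

The property suites run 200 random 1,000-concept tables for the
partition/totality check and 30 for threshold monotonicity; the parent
derivation oracle enumerates all 57 multi-member signatures over a
fixed 6-ST universe under four random availability sets each.  The
full `paper_extent_spec` fixture (~236,000 concepts) is built once per
test session.  All computation is exact set arithmetic; the only
floating-point quantity is the coverage ratio.

## Known limitations

* The bundled network targets the 2009AA chemical subtree; later
  releases changed the ST inventory and are untested.
* The fixture's tree numbers follow the convention implied by its own
  edge set (functional axis at `A1.4.1.1`); only prefix-consistency,
  not equality with any particular release's numbering, is relied on.
* `parse_srstr` requires every name in a defined-`isa` row to resolve;
  loading a full SRSTR therefore requires the full SRDEF, not just the
  chemical subset.
* Creating provisional ISTs for newly added concepts (letting a
  too-small intersection exist "for a time") is an editorial workflow
  outside this package's scope.
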