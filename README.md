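# cssn — chemical specialty semantic networks

`cssn` derives a *Chemical Specialty Semantic Network* (CSSN): a
finer-grained, mutually exclusive type system for the chemical subtree
of a UMLS-style Semantic Network, computed automatically from the
existing semantic-type (ST) assignments of a concept table.

It is aimed at terminology engineers and auditors working with the
UMLS Metathesaurus (or any table of concept → semantic-type
assignments in the MRSTY.RRF format), and at ontology developers who
want a compact upper-level categorization for chemical ontologies such
as ChEBI.

## The method

In the Semantic Network, almost every chemical concept carries two or
more STs — typically one *structural* perspective (what the substance
is, e.g. **Organic Chemical**) and one or more *functional*
perspectives (what it does, e.g. **Pharmacologic Substance**).  The
extent of a single ST therefore mixes concepts with quite different
semantics.  The CSSN fixes this by reifying exact combinations:

* each ST *X* of the chemical subtree yields a **pure semantic type**
  (PST) whose extent holds the concepts assigned exactly {*X*};
* each observed combination {*A*, *B*, …} of two or more chemical STs
  yields a candidate **intersection semantic type** (IST)
  *A* ∩ *B* ∩ …, whose extent holds the concepts assigned exactly that
  combination.

Extents are pairwise disjoint by construction, so every concept has
exactly one type.  A threshold *N* (applying to ISTs only) keeps the
network compact: an IST with fewer than *N* concepts is omitted.  Its
concepts are either left uncovered, or reassigned by one of two
strategies — `largest_extent` (move to the maximal existing
sub-combination with the most concepts) or `relax` (generalise one
member ST at a time toward its ancestors, functional members first,
deepest first, until an existing type is reached).

The surviving types are renamed for readability (*Amino Acid, Peptide,
or Protein* ∩ *Immunologic Factor* becomes **Immunologic Amino Acid,
Peptide, or Protein**) and arranged into an IS-A DAG: PSTs mirror the
Semantic Network's edges, and an IST's parents are the maximal
existing sub-combinations of its signature — so every IST has at least
two parents whose signatures union back to its own.

A 25-type chemical-subtree fixture (2009AA release) is bundled; the
licensed UMLS distribution files (SRDEF, SRSTR, MRSTY.RRF) can be
supplied for full-scale runs.  A synthetic-table generator produces
MRSTY-dialect files with any chosen signature distribution, so the
whole pipeline is testable without a UMLS license.

## Worked example

Build a network from the bundled fixture of published per-signature
extent sizes, at threshold 300:

```python
import cssn

net = cssn.load_bundled_network()
pairs = cssn.iter_pairs(cssn.paper_extent_spec(), net)
table = cssn.restrict_to_chemical(pairs, net.subtree("Chemical"))
index = cssn.build_index(table)
built = cssn.build(index, net, cssn.BuildConfig(threshold=300))
print(cssn.format_listing(cssn.render_listing(built)))
```

An excerpt of what it prints (label, extent, indented display name):

```
Organic Chemical	58,347	    Organic Chemical
Organic Chemical ∩ Pharmacologic Substance	76,832	      *Pharmacologic Organic Chemical
...
Amino Acid, Peptide, or Protein	16,973	      Amino Acid, Peptide, or Protein
Amino Acid, Peptide, or Protein ∩ Immunologic Factor	12,662	        *Immunologic Amino Acid, Peptide, or Protein
Amino Acid, Peptide, or Protein ∩ Pharmacologic Substance	6,537	        *Pharmacologic Amino Acid, Peptide, or Protein
Amino Acid, Peptide, or Protein ∩ Pharmacologic Substance ∩ Immunologic Factor	1,940	          **Pharmacologic Immunologic Amino Acid, Peptide, or Protein
```

12,662 concepts carry exactly the protein + immunologic combination;
the asterisks mark parents beyond the one the row is indented under
(a 3-IST with three parents gets two asterisks).

The same pipeline from the shell, with the threshold sweep:

```sh
cssn synth --paper-extents --out mrsty.rrf
cssn sweep --mrsty mrsty.rrf --thresholds 500,300,100,50,1
```

```
N	types	coverage
500	32	99.6%
300	33	99.8%
100	35	100.0%
50	36	100.0%
1	37	100.0%
```

Coverage is the percentage of concepts whose exact combination exists
as a type; raising N shrinks the network at the cost of coverage, and
N = 1 always covers everything.  (The bundled fixture contains only
the published per-signature extents, so its sweep is denser than a
full Metathesaurus run.)  Reassignment of a dropped combination:

```sh
cssn assign --signature "Organic Chemical;Hormone;Immunologic Factor" \
            --mrsty mrsty.rrf --threshold 50 --strategy relax --explain
# relaxed Immunologic Factor -> Biologically Active Substance: ...
# relaxed Hormone -> Biologically Active Substance: ...
# Organic Chemical ∩ Biologically Active Substance
```

`cssn build`, `cssn listing`, `cssn compare`, `cssn audit` and
`cssn synth` cover the remaining operations; see `cssn --help` and the
`examples/` scripts.

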