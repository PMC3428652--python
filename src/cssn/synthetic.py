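"""Synthetic MRSTY-style assignment tables.

The licensed Metathesaurus cannot be bundled, so every pipeline stage
is exercised against generated assignment tables with a controlled
distribution over exact signature combinations.  A spec lists, per
signature, how many concepts carry exactly that combination; mixed rows
additionally attach one non-chemical TUI to each concept, emulating
concepts like *Soap* (a **Lipid** that is also a **Manufactured
Object**).  Synthetic CUIs use a reserved ``S`` prefix so they can
never collide with real ``C``-prefixed CUIs.

``paper_extent_spec`` encodes the published 2009AA extent sizes (the
pure-type counts and every intersection extent printed alongside the
method's worked examples) as a reusable fixture; a ``divisor`` scales
it down for fast tests while keeping every signature present.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .assignments import Signature
from .errors import SpecError
from .semantic_network import SemanticNetwork, load_bundled_network

__all__ = [
    "SignatureSpec",
    "generate",
    "iter_pairs",
    "paper_extent_spec",
    "random_spec",
    "NONCHEMICAL_PLACEHOLDER",
]

#: stand-in non-chemical TUI (Manufactured Object) for mixed concepts
NONCHEMICAL_PLACEHOLDER = "T073"

CUI_PREFIX = "S"


@dataclass
class SignatureSpec:
    """A generation plan: (signature, count) rows plus mixed rows.

    Signature members may be ST names or TUIs; they are resolved at
    generation time.  ``mixed_rows`` entries are (chemical signature,
    non-chemical TUI, count).
    """

    rows: list[tuple[frozenset, int]] = field(default_factory=list)
    mixed_rows: list[tuple[frozenset, str, int]] = field(default_factory=list)
    seed: int = 0

    def scaled(self, divisor: int) -> "SignatureSpec":
        """Integer-divide every count by *divisor*, keeping each
        non-empty signature present (minimum count 1)."""
        if divisor < 1:
            raise SpecError("divisor must be a positive integer")
        scale = lambda c: max(1, c // divisor) if c > 0 else 0
        return SignatureSpec(
            rows=[(sig, scale(c)) for sig, c in self.rows],
            mixed_rows=[(sig, t, scale(c)) for sig, t, c in self.mixed_rows],
            seed=self.seed,
        )

    @property
    def concept_count(self) -> int:
        return sum(c for _, c in self.rows) + sum(c for _, _, c in self.mixed_rows)


def _resolve_rows(
    spec: SignatureSpec, net: SemanticNetwork
) -> list[tuple[Signature, str | None, int]]:
    out: list[tuple[Signature, str | None, int]] = []
    for entry in [(sig, None, count) for sig, count in spec.rows] + list(
        spec.mixed_rows
    ):
        sig, extra, count = entry
        if count < 0:
            raise SpecError(f"negative count {count} for {sorted(sig)}")
        if not sig:
            raise SpecError("empty signature in spec")
        try:
            resolved = Signature(net.resolve(st) for st in sig)
        except KeyError as exc:
            raise SpecError(f"unknown semantic type in spec: {exc}") from exc
        out.append((resolved, extra, count))
    return out


def iter_pairs(
    spec: SignatureSpec, net: SemanticNetwork | None = None
) -> Iterator[tuple[str, str]]:
    """Stream (CUI, TUI) pairs in spec order, without shuffling.

    Lazy: large extents never materialise in memory.  CUIs are
    sequential within the spec, so output is deterministic.
    """
    net = net or load_bundled_network()
    serial = 0
    for sig, extra, count in _resolve_rows(spec, net):
        for _ in range(count):
            serial += 1
            cui = f"{CUI_PREFIX}{serial:07d}"
            for tui in sorted(sig):
                yield cui, tui
            if extra is not None:
                yield cui, extra


def generate(spec: SignatureSpec, net: SemanticNetwork | None = None) -> str:
    """Render a spec as MRSTY-dialect text (CUI|TUI|STN|STY|ATUI|CVF|).

    Exactly ``count`` fresh concepts per signature; mixed rows carry one
    extra non-chemical line per concept.  Row order is shuffled
    deterministically by ``spec.seed``, so identical spec+seed gives
    byte-identical output.
    """
    net = net or load_bundled_network()

    def line(cui: str, tui: str) -> str:
        if tui in net:
            st = net[tui]
            stn, sty = st.tree_number, st.name
        else:
            stn, sty = "", ""
        return f"{cui}|{tui}|{stn}|{sty}|||"

    lines = [line(cui, tui) for cui, tui in iter_pairs(spec, net)]
    random.Random(spec.seed).shuffle(lines)
    return "".join(l + "\n" for l in lines)


# -- fixtures -------------------------------------------------------------

# Pure-type exact extents as published for 2009AA (concepts whose only
# chemical assignment is that single ST).
_PST_EXTENTS = {
    "Chemical": 26,
    "Chemical Viewed Structurally": 248,
    "Organic Chemical": 58347,
    "Steroid": 4883,
    "Eicosanoid": 537,
    "Nucleic Acid, Nucleoside, or Nucleotide": 4727,
    "Organophosphorus Compound": 919,
    "Amino Acid, Peptide, or Protein": 16973,
    "Carbohydrate": 6077,
    "Lipid": 3494,
    "Chemical Viewed Functionally": 174,
    "Pharmacologic Substance": 14168,
    "Biomedical or Dental Material": 3408,
    "Biologically Active Substance": 1026,
    "Neuroreactive Substance or Biogenic Amine": 20,
    "Hormone": 147,
    "Enzyme": 233,
    "Vitamin": 117,
    "Immunologic Factor": 7181,
    "Indicator, Reagent, or Diagnostic Aid": 4350,
    "Hazardous or Poisonous Substance": 422,
    "Receptor": 125,
    "Antibiotic": 546,
    "Element, Ion, or Isotope": 1004,
    "Inorganic Chemical": 2490,
}

# Intersection extents printed for 2009AA.
_IST_EXTENTS = [
    ({"Amino Acid, Peptide, or Protein", "Immunologic Factor"}, 12662),
    ({"Amino Acid, Peptide, or Protein", "Pharmacologic Substance"}, 6537),
    (
        {
            "Amino Acid, Peptide, or Protein",
            "Pharmacologic Substance",
            "Immunologic Factor",
        },
        1940,
    ),
    ({"Amino Acid, Peptide, or Protein", "Antibiotic"}, 490),
    ({"Organic Chemical", "Pharmacologic Substance"}, 76832),
    ({"Organic Chemical", "Hormone"}, 62),
    ({"Organic Chemical", "Immunologic Factor"}, 136),
    ({"Organic Chemical", "Biologically Active Substance"}, 4151),
    (
        {
            "Organic Chemical",
            "Pharmacologic Substance",
            "Biologically Active Substance",
        },
        507,
    ),
    ({"Organic Chemical", "Pharmacologic Substance", "Immunologic Factor"}, 249),
    ({"Pharmacologic Substance", "Immunologic Factor"}, 1065),
    # the single concept carrying exactly this triple (Adrenal cortex agent)
    ({"Organic Chemical", "Hormone", "Immunologic Factor"}, 1),
]


def paper_extent_spec(divisor: int = 1, seed: int = 0) -> SignatureSpec:
    """The published 2009AA extent sizes as a generation spec.

    With ``divisor`` > 1 every count is integer-divided (minimum 1), so
    reduced fixtures keep the same signature structure.
    """
    rows = [(frozenset([name]), count) for name, count in _PST_EXTENTS.items()]
    rows += [(frozenset(sig), count) for sig, count in _IST_EXTENTS]
    spec = SignatureSpec(rows=rows, seed=seed)
    return spec.scaled(divisor) if divisor != 1 else spec


def random_spec(
    seed: int,
    n_concepts: int = 1000,
    net: SemanticNetwork | None = None,
    n_signatures: int = 30,
    max_size: int = 3,
    mixed_fraction: float = 0.02,
    sts: Sequence[str] | None = None,
) -> SignatureSpec:
    """A random but seed-deterministic assignment-table spec.

    Draws *n_signatures* distinct signatures (sizes 1..max_size) over
    the chemical subtree, distributes *n_concepts* among them, and
    marks roughly *mixed_fraction* of concepts as mixed
    chemical/non-chemical.
    """
    net = net or load_bundled_network()
    rng = random.Random(seed)
    universe = sorted(sts) if sts is not None else sorted(net.subtree("Chemical"))
    sigs: set[frozenset] = set()
    attempts = 0
    while len(sigs) < n_signatures and attempts < n_signatures * 50:
        attempts += 1
        size = rng.randint(1, max_size)
        sigs.add(frozenset(rng.sample(universe, min(size, len(universe)))))
    ordered = sorted(sigs, key=lambda s: tuple(sorted(s)))
    counts = {sig: 0 for sig in ordered}
    for _ in range(n_concepts):
        counts[rng.choice(ordered)] += 1
    rows, mixed_rows = [], []
    for sig in ordered:
        count = counts[sig]
        if count == 0:
            continue
        n_mixed = int(round(count * mixed_fraction))
        if count - n_mixed:
            rows.append((sig, count - n_mixed))
        if n_mixed:
            mixed_rows.append((sig, NONCHEMICAL_PLACEHOLDER, n_mixed))
    return SignatureSpec(rows=rows, mixed_rows=mixed_rows, seed=seed)
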