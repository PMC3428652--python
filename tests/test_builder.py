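import itertools

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cssn
from cssn import BuildConfig, DomainError, Signature, build, coverage, derive_parents, derive_types, sweep
from cssn.assignments import SignatureIndex

from conftest import index_for


def make_index(rows):
    """rows: {signature: extent size} -> SignatureIndex with synthetic CUIs."""
    extents, n = {}, 0
    for sig, count in rows.items():
        extents[Signature(sig)] = frozenset(f"X{n + i:06d}" for i in range(count))
        n += count
    return SignatureIndex(extents)


def subset_oracle(sig, available):
    """Independent maximal-proper-subset filter by full enumeration."""
    proper = []
    for r in range(1, len(sig)):
        for combo in itertools.combinations(sorted(sig), r):
            s = frozenset(combo)
            if s in available:
                proper.append(s)
    return {s for s in proper if not any(s < t for t in proper)}


class TestDeriveTypes:
    def test_ist_meeting_threshold_retained(self, net, sig):
        index = make_index({sig("Amino Acid, Peptide, or Protein", "Antibiotic"): 490})
        types = derive_types(index, net, BuildConfig(threshold=300))
        assert sig("Amino Acid, Peptide, or Protein", "Antibiotic") in {
            t.signature for t in types
        }

    def test_small_ist_omitted_and_concepts_uncovered(self, net, sig):
        triple = sig("Organic Chemical", "Hormone", "Immunologic Factor")
        index = make_index({triple: 1})
        types = derive_types(index, net, BuildConfig(threshold=300))
        assert triple not in {t.signature for t in types}
        c = build(index, net, BuildConfig(threshold=300, strategy="none"))
        assert c.uncovered == next(iter(index.extents.values()))

    def test_threshold_one_keeps_every_observed_signature(self, net, sig):
        index = make_index({sig("Lipid"): 3, sig("Lipid", "Hormone"): 1})
        c = build(index, net, BuildConfig(threshold=1))
        assert index.signatures <= c.signatures
        assert c.uncovered == frozenset()

    def test_all_psts_present_even_with_empty_extents(self, net, chem):
        types = derive_types(SignatureIndex({}), net, BuildConfig(threshold=300))
        assert {t.signature for t in types} == {Signature([t]) for t in chem}
        assert all(t.extent_size == 0 for t in types)

    def test_threshold_applies_to_ists_only(self, net, sig):
        index = make_index({sig("Eicosanoid"): 2})
        types = derive_types(index, net, BuildConfig(threshold=300))
        by_sig = {t.signature: t for t in types}
        assert by_sig[sig("Eicosanoid")].extent_size == 2


class TestDeriveParents:
    def singletons(self, chem):
        return {Signature([t]) for t in chem}

    def test_config_a_three_two_ist_parents(self, net, chem, sig):
        child = sig("Pharmacologic Substance", "Immunologic Factor",
                    "Amino Acid, Peptide, or Protein")
        pairs = {frozenset(c) for c in itertools.combinations(child, 2)}
        available = self.singletons(chem) | pairs | {child}
        assert derive_parents(child, available, net) == pairs

    def test_config_b_two_two_ist_parents(self, net, chem, sig):
        child = sig("Pharmacologic Substance", "Hazardous or Poisonous Substance",
                    "Organic Chemical")
        hoc = sig("Hazardous or Poisonous Substance", "Organic Chemical")
        poc = sig("Pharmacologic Substance", "Organic Chemical")
        available = self.singletons(chem) | {hoc, poc, child}
        assert derive_parents(child, available, net) == {hoc, poc}

    def test_config_c_two_ist_and_pst_parents(self, net, chem, sig):
        child = sig("Pharmacologic Substance", "Steroid", "Hormone")
        ps = sig("Pharmacologic Substance", "Steroid")
        available = self.singletons(chem) | {ps, child}
        assert derive_parents(child, available, net) == {ps, sig("Hormone")}

    def test_config_d_three_pst_parents(self, net, chem, sig):
        child = sig("Carbohydrate", "Vitamin", "Receptor")
        available = self.singletons(chem) | {child}
        assert derive_parents(child, available, net) == {
            sig("Carbohydrate"), sig("Vitamin"), sig("Receptor")
        }

    def test_two_ist_parents_are_its_singletons(self, net, chem, sig):
        child = sig("Organic Chemical", "Pharmacologic Substance")
        available = self.singletons(chem) | {child}
        assert derive_parents(child, available, net) == {
            sig("Organic Chemical"), sig("Pharmacologic Substance")
        }

    def test_pst_parents_mirror_sn(self, net, chem):
        available = self.singletons(chem)
        for tui in chem:
            parents = derive_parents(Signature([tui]), available, net)
            sn_parent = net.parent_of(tui)
            expected = set() if sn_parent is None else {Signature([sn_parent])}
            assert parents == expected

    @settings(derandomize=True, max_examples=150)
    @given(data=st.data())
    def test_matches_subset_enumeration_oracle(self, net, chem, data):
        universe = sorted(chem)
        members = data.draw(st.sets(st.sampled_from(universe), min_size=2, max_size=6))
        child = Signature(members)
        extra = data.draw(
            st.sets(
                st.sets(st.sampled_from(universe), min_size=2, max_size=5).map(frozenset),
                max_size=12,
            )
        )
        available = self.singletons(chem) | {frozenset(s) for s in extra} | {child}
        assert derive_parents(child, available, net) == subset_oracle(child, available)


def brute_force_build(index, net, threshold, strategy, chem):
    """Independent end-to-end reimplementation: enumeration, no library calls."""
    parent = dict(net.isa_edges)
    type_sigs = {frozenset([t]) for t in chem}
    type_sigs |= {
        s for s, e in index.extents.items() if len(s) >= 2 and len(e) >= threshold
    }

    def functional(t):
        chain = set()
        cur = t
        while cur is not None:
            chain.add(cur)
            cur = parent.get(cur)
        return net.resolve("Chemical Viewed Functionally") in chain

    def depth(t):
        d, cur = 0, t
        while cur in parent:
            cur = parent[cur]
            d += 1
        return d

    assignment, uncovered = {}, set()
    for s, extent in index.extents.items():
        if s in type_sigs:
            target = s
        elif strategy == "none":
            uncovered |= set(extent)
            continue
        elif strategy == "largest_extent":
            best = None
            for cand in subset_oracle(s, type_sigs):
                size = len(index.extents.get(cand, ()))
                key = (size, len(cand), [t for t in sorted(cand)])
                if best is None or (key[0], key[1]) > (best[0][0], best[0][1]) or (
                    (key[0], key[1]) == (best[0][0], best[0][1]) and key[2] < best[0][2]
                ):
                    best = (key, cand)
            target = best[1]
        else:  # relax
            cur = s
            while cur not in type_sigs:
                pool = [t for t in cur if functional(t)] or [
                    t for t in cur if t != net.resolve("Chemical")
                ]
                pick = max(pool, key=lambda t: (depth(t), net[t].tree_number))
                cur = (cur - {pick}) | {parent[pick]}
            target = cur
        for cui in extent:
            assignment[cui] = target
    return type_sigs, assignment, uncovered


class TestBuildEndToEnd:
    def test_paper_extents_at_n300_include_published_listing(self, net, sig, paper_index):
        c = build(paper_index, net, BuildConfig(threshold=300))
        names = {t.display_name: t.extent_size for t in c.ists}
        assert names["Immunologic Amino Acid, Peptide, or Protein"] == 12662
        assert names["Pharmacologic Amino Acid, Peptide, or Protein"] == 6537
        assert names["Pharmacologic Immunologic Amino Acid, Peptide, or Protein"] == 1940

    def test_threshold_one_gives_total_assignment(self, net, paper_index):
        c = build(paper_index, net, BuildConfig(threshold=1, strategy="none"))
        assert c.uncovered == frozenset()
        assert len(c.assignment) == paper_index.concept_count

    @pytest.mark.parametrize("strategy", ["none", "largest_extent", "relax"])
    def test_matches_brute_force_reimplementation(self, net, chem, strategy):
        index = index_for(seed=20240915, net=net, n_concepts=1000)
        c = build(index, net, BuildConfig(threshold=5, strategy=strategy))
        sigs, assignment, uncovered = brute_force_build(index, net, 5, strategy, chem)
        assert c.signatures == sigs
        assert c.assignment == assignment
        assert c.uncovered == frozenset(uncovered)

    def test_relaxed_concepts_counted_in_assignment_not_extent(self, net, sig):
        triple = sig("Organic Chemical", "Hormone", "Immunologic Factor")
        pair = sig("Organic Chemical", "Immunologic Factor")
        index = make_index({triple: 1, pair: 136, sig("Organic Chemical", "Hormone"): 62})
        c = build(index, net, BuildConfig(threshold=50, strategy="largest_extent"))
        assert c.types[pair].extent_size == 136
        assert c.assigned_count(pair) == 137

    def test_extents_pairwise_disjoint(self, net):
        index = index_for(seed=11, net=net)
        c = build(index, net, BuildConfig(threshold=3))
        seen = set()
        for t in c.types.values():
            assert not (seen & t.extent)
            seen |= t.extent


@pytest.fixture(scope="module")
def built(net, paper_index):
    return build(paper_index, net, BuildConfig(threshold=300))


class TestDag:
    def test_acyclic(self, built):
        g = nx.DiGraph(list(built.isa_edges))
        assert nx.is_directed_acyclic_graph(g)

    def test_every_ist_has_at_least_two_parents(self, built):
        for t in built.ists:
            assert len(built.parents_of(t.signature)) >= 2

    def test_parent_union_equals_child_signature(self, built):
        for t in built.ists:
            union = frozenset().union(*built.parents_of(t.signature))
            assert union == t.signature

    def test_parents_are_proper_subsets(self, built):
        for child, parent in built.isa_edges:
            if len(child) >= 2:
                assert parent < child

    def test_pst_edges_bijective_with_sn_subtree_edges(self, built, net, chem):
        pst_edges = {
            (next(iter(c)), next(iter(p)))
            for c, p in built.isa_edges
            if len(c) == 1 and len(p) == 1
        }
        sn_edges = {(c, p) for c, p in net.isa_edges if c in chem and p in chem}
        assert pst_edges == sn_edges

    def test_dropping_an_ist_promotes_fallback_parents(self, net, sig):
        # with the middle pair below threshold, the triple falls back to a PST
        triple = sig("Pharmacologic Substance", "Steroid", "Hormone")
        index = make_index({
            triple: 10,
            sig("Pharmacologic Substance", "Steroid"): 10,
            sig("Pharmacologic Substance", "Hormone"): 2,
        })
        c = build(index, net, BuildConfig(threshold=5))
        assert c.parents_of(triple) == {
            sig("Pharmacologic Substance", "Steroid"), sig("Hormone")
        }


class TestCoverageAndSweep:
    def test_coverage_is_one_at_threshold_one(self, net):
        index = index_for(seed=3, net=net)
        c = build(index, net, BuildConfig(threshold=1))
        assert coverage(c) == 1.0

    def test_coverage_matches_hand_count(self, net, sig):
        index = make_index({
            sig("Lipid"): 4,                      # covered (PST)
            sig("Lipid", "Hormone"): 3,           # covered IST at N=3
            sig("Lipid", "Vitamin"): 2,           # dropped at N=3
        })
        c = build(index, net, BuildConfig(threshold=3))
        assert coverage(c) == pytest.approx(7 / 9)

    def test_coverage_independent_of_strategy(self, net):
        index = index_for(seed=5, net=net)
        values = {
            coverage(build(index, net, BuildConfig(threshold=8, strategy=s)))
            for s in ("none", "largest_extent", "relax")
        }
        assert len(values) == 1

    def test_sweep_threshold_one_row(self, net):
        index = index_for(seed=9, net=net)
        ((n, count, cov),) = sweep(index, net, [1])
        assert n == 1 and cov == 1.0
        assert count == 25 + sum(1 for s in index.signatures if len(s) >= 2)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_type_count_and_coverage_non_increasing(self, net, seed):
        index = index_for(seed=seed, net=net)
        rows = sweep(index, net, [1, 2, 5, 10, 50])
        counts = [r[1] for r in rows]
        covs = [r[2] for r in rows]
        assert counts == sorted(counts, reverse=True)
        assert covs == sorted(covs, reverse=True)

    def test_rows_follow_requested_order(self, net):
        index = index_for(seed=4, net=net)
        rows = sweep(index, net, [50, 1, 10])
        assert [r[0] for r in rows] == [50, 1, 10]


class TestExport:
    def test_json_document_shape(self, net, sig):
        index = make_index({sig("Lipid"): 2, sig("Lipid", "Hormone"): 3})
        c = build(index, net, BuildConfig(threshold=1))
        doc = c.to_json()
        assert doc["concepts"] == 5 and doc["covered"] == 5
        by_name = {t["name"]: t for t in doc["types"]}
        row = by_name["Lipid Hormone"]
        assert row["kind"] == "IST" and row["extent_size"] == 3
        assert row["label"] == "Lipid ∩ Hormone"
        assert [sorted(sig("Lipid", "Hormone")), sorted(sig("Lipid"))] in doc["isa_edges"]

    def test_edge_tsv_uses_display_names(self, net, sig):
        index = make_index({sig("Lipid", "Hormone"): 3})
        c = build(index, net, BuildConfig(threshold=1))
        tsv = c.edges_tsv()
        assert "Lipid Hormone\tHormone\n" in tsv
        assert "Lipid Hormone\tLipid\n" in tsv
        assert "Steroid\tLipid\n" in tsv


class TestConfigValidation:
    def test_threshold_must_be_positive(self):
        with pytest.raises(DomainError):
            BuildConfig(threshold=0)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(DomainError):
            BuildConfig(strategy="bogus")
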