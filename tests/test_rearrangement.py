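"""Signed circular gene orders: boundaries, distances, events, clustering."""

import re
import warnings

import numpy as np
import pytest

import mitoglyph as mg
from mitoglyph.rearrange import GeneOrder, RearrangementEvent

BLOCK17 = ("atp8", "atp6", "trnE", "trnF", "nad5", "trnH", "nad4", "nad4L",
           "trnT", "trnP", "nad6", "cob", "trnS2", "nad1", "trnL1",
           "rrnL", "rrnS")


def brute_adjacencies(order):
    """Oracle: canonicalised oriented adjacency set by direct enumeration."""
    out = set()
    g = order.genes
    for i in range(len(g)):
        a, b = g[i], g[(i + 1) % len(g)]
        flip = ((b[0], -b[1]), (a[0], -a[1]))
        out.add(min((a, b), flip))
    return out


def random_order(rng, n=20):
    names = ["cox1"] + [f"g{i}" for i in range(n - 1)]
    rest = names[1:]
    rng.shuffle(rest)
    genes = [("cox1", 1)] + [(g, int(rng.choice([-1, 1]))) for g in rest]
    return GeneOrder(tuple(genes))


class TestSharedBoundaries:
    def test_identical_orders_share_everything(self, whitefly_orders):
        ac = whitefly_orders["A_camelliae"]
        n, _ = mg.shared_boundaries(ac, ac)
        assert n == len(ac)

    def test_singleton_transposition_on_ten_genes(self):
        base = GeneOrder.from_strings(
            "cox1,g1,g2,g3,g4,g5,g6,g7,g8,g9")
        moved = mg.apply_events(base, [RearrangementEvent(
            "transposition", ("g2",), destination="g7")])
        n, shared = mg.shared_boundaries(base, moved)
        assert n == 7
        # oracle: direct adjacency-set intersection
        assert n == len(brute_adjacencies(base) & brute_adjacencies(moved))

    def test_camelliae_acaciae_share_printed_block(self, whitefly_orders):
        """The 17-gene atp8..rrnS block contributes 16 internal boundaries."""
        n, shared = mg.shared_boundaries(whitefly_orders["A_camelliae"],
                                         whitefly_orders["T_acaciae"])
        internal = [b for b in shared
                    if b[0][0] in BLOCK17 and b[1][0] in BLOCK17]
        assert len(internal) == 16
        # and the trnQ-trnV block is shared too
        assert any({b[0][0], b[1][0]} == {"trnQ", "trnV"} for b in shared)


class TestBreakpointDistance:
    def test_identical_is_zero(self, whitefly_orders):
        ac = whitefly_orders["A_camelliae"]
        assert mg.breakpoint_distance(ac, ac) == 0

    def test_single_transposition_is_three(self):
        base = GeneOrder.from_strings("cox1,g1,g2,g3,g4,g5,g6,g7,g8,g9")
        moved = mg.apply_events(base, [RearrangementEvent(
            "transposition", ("g2", "g3"), destination="g7")])
        assert mg.breakpoint_distance(base, moved) == 3
        assert mg.breakpoint_distance(base, moved) == \
            len(brute_adjacencies(base) - brute_adjacencies(moved))

    def test_single_inversion_is_two(self):
        base = GeneOrder.from_strings("cox1,g1,g2,g3,g4,g5,g6,g7,g8,g9")
        flipped = mg.apply_events(base, [RearrangementEvent(
            "inversion", ("g3", "g4", "g5"))])
        assert mg.breakpoint_distance(base, flipped) == 2

    def test_small_common_set_rejected(self):
        a = GeneOrder.from_strings("cox1,g1,g2")
        b = GeneOrder.from_strings("cox1,h1,h2")
        with pytest.raises(ValueError, match="common gene set"):
            mg.breakpoint_distance(a, b)

    def test_pseudo_metric_on_random_pairs(self):
        """d(A,A)=0, symmetry, and shared+distance = common count, 500 pairs."""
        rng = np.random.default_rng(7)
        for _ in range(500):
            a, b = random_order(rng), random_order(rng)
            assert mg.breakpoint_distance(a, a) == 0
            dab = mg.breakpoint_distance(a, b)
            assert dab == mg.breakpoint_distance(b, a)
            n_shared, _ = mg.shared_boundaries(a, b)
            common = set(a.names()) & set(b.names())
            assert n_shared + dab == len(common)


class TestClassifyEvents:
    def test_reference_vs_itself_is_empty(self, whitefly_orders):
        dec = mg.classify_events(whitefly_orders["ancestral"],
                                 whitefly_orders["ancestral"])
        assert dec.events == []

    def test_tabaci_contains_inverse_transposed_block(self, whitefly_orders):
        dec = mg.classify_events(whitefly_orders["ancestral"],
                                 whitefly_orders["B_tabaci"])
        inv_trans = [e for e in dec.events
                     if e.type == "inverse_transposition"]
        assert any({"cox3", "trnG", "nad3"} <= set(e.block)
                   for e in inv_trans)

    def test_scripted_transposition_recovered(self, whitefly_orders):
        rng = np.random.default_rng(3)
        ref = whitefly_orders["ancestral"]
        ev = RearrangementEvent("transposition", ("trnD",),
                                destination="nad6")
        observed = mg.apply_events(ref, [ev])
        dec = mg.classify_events(ref, observed)
        assert [e.type for e in dec.events] == ["transposition"]
        assert dec.events[0].block == ("trnD",)

    @pytest.mark.parametrize("events", [
        [RearrangementEvent("inversion", ("trnS1",))],
        [RearrangementEvent("inverse_transposition",
                            ("cox3", "trnG", "nad3"), destination="rrnS")],
        [RearrangementEvent("gene_loss", ("trnI",)),
         RearrangementEvent("transposition", ("trnS1",),
                            destination="cox3")],
    ])
    def test_round_trip_reapplication(self, whitefly_orders, events):
        """Applying the classified events to the reference reproduces the
        observed order."""
        ref = whitefly_orders["ancestral"]
        observed = mg.apply_events(ref, events)
        dec = mg.classify_events(ref, observed)
        rebuilt = mg.apply_events(ref, dec.events)
        assert rebuilt.genes == observed.genes

    def test_losses_reported_for_absent_genes(self, whitefly_orders):
        dec = mg.classify_events(whitefly_orders["ancestral"],
                                 whitefly_orders["A_camelliae"])
        lost = {g for e in dec.events if e.type == "gene_loss"
                for g in e.block}
        assert lost == {"trnI"}


class TestApplyEvents:
    def test_identity_event_list(self, whitefly_orders):
        ref = whitefly_orders["ancestral"]
        assert mg.apply_events(ref, []).genes == ref.genes

    def test_inverse_transposition_flips_and_reverses(self):
        base = GeneOrder.from_strings("cox1,g1,g2,g3,g4,g5")
        out = mg.apply_events(base, [RearrangementEvent(
            "inverse_transposition", ("g1", "g2"), destination="g4")])
        names = [(g, s) for g, s in out.genes]
        i = names.index(("g2", -1))
        assert names[i + 1] == ("g1", -1)
        assert names[i - 1] == ("g4", 1)

    def test_absent_gene_raises(self):
        base = GeneOrder.from_strings("cox1,g1,g2,g3")
        with pytest.raises(ValueError, match="absent gene"):
            mg.apply_events(base, [RearrangementEvent(
                "transposition", ("nope",), destination="g1")])


class TestRemnantScan:
    def test_deleted_trnP_leaves_named_remnant(self, whitefly_orders):
        spec = mg.GenomeSpec.camelliae_like(seed=17)
        spec.deletions = [mg.Deletion("trnP", "remnant")]
        genome = mg.generate(spec, with_sequence=False)
        events = mg.remnant_scan(genome.annotation,
                                 whitefly_orders["A_camelliae"])
        assert len(events) == 1
        assert events[0].type == "remnant"
        assert events[0].block == ("trnP",)
        assert "trnT" in events[0].note and "nad6" in events[0].note

    def test_no_absences_no_remnants(self, whitefly_orders, camelliae):
        events = mg.remnant_scan(camelliae, whitefly_orders["A_camelliae"])
        assert events == []

    def test_flanks_not_adjacent_means_no_remnant(self, whitefly_orders,
                                                  camelliae):
        """trnI is absent, but its ancestral flanks are not adjacent in the
        observed order, so only gene_loss (not remnant) applies."""
        events = mg.remnant_scan(camelliae, whitefly_orders["ancestral"])
        assert all(e.block != ("trnI",) for e in events)


class TestDistanceMatrixAndTree:
    def test_identical_orders_zero_matrix_star_tree(self, whitefly_orders):
        ac = whitefly_orders["A_camelliae"]
        mat = mg.order_distance_matrix([ac, ac, ac])
        assert np.allclose(mat, 0)
        with pytest.warns(UserWarning, match="star"):
            tree = mg.order_tree(mat, ["a", "b", "c"])
        assert tree.count(",") == 2

    def test_camelliae_acaciae_mutual_nearest_and_sisters(self,
                                                          whitefly_orders):
        labels = sorted(whitefly_orders)
        mat = mg.order_distance_matrix([whitefly_orders[l] for l in labels])
        i = labels.index("A_camelliae")
        j = labels.index("T_acaciae")
        assert np.argmin(np.where(np.eye(len(labels), dtype=bool), np.inf,
                                  mat)[i]) == j
        assert np.argmin(np.where(np.eye(len(labels), dtype=bool), np.inf,
                                  mat)[j]) == i
        tree = mg.order_tree(mat, labels)
        assert re.search(r"\(A_camelliae:[\d.]+,T_acaciae:[\d.]+\)", tree)

    def test_scripted_hierarchy_recovered(self, whitefly_orders):
        """Orders 1/2/4 events from an ancestor cluster by event count."""
        ref = whitefly_orders["ancestral"]
        near1 = mg.apply_events(ref, [RearrangementEvent(
            "inversion", ("trnS1",))])
        near2 = mg.apply_events(near1, [RearrangementEvent(
            "inversion", ("trnE",))])
        far = mg.apply_events(ref, [
            RearrangementEvent("inverse_transposition",
                               ("cox3", "trnG", "nad3"), destination="rrnS"),
            RearrangementEvent("transposition", ("trnD",),
                               destination="nad6"),
            RearrangementEvent("inversion", ("trnT",)),
            RearrangementEvent("transposition", ("trnW",),
                               destination="trnV"),
        ])
        labels = ["near1", "near2", "far", "ref"]
        mat = mg.order_distance_matrix([near1, near2, far, ref])
        tree = mg.order_tree(mat, labels)
        assert re.search(r"\(near1:[\d.]+,near2:[\d.]+\)", tree)

    def test_upgma_heights_match_scipy_average_linkage(self):
        """Cross-check the deterministic UPGMA against scipy's."""
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(11)
        n = 6
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"t{i}" for i in range(n)]
        tree = mg.order_tree(m, labels)
        z = average(squareform(m))
        # the root height of UPGMA equals scipy's final merge height / 2
        heights = re.findall(r":([\d.e+-]+)", tree)
        root_depth = max(float(h) for h in heights)
        assert root_depth <= z[-1, 2]
        # every scipy merge height appears as twice a clade height sum;
        # compare the sets of cophenetic heights instead
        from scipy.cluster.hierarchy import cophenet
        coph = squareform(cophenet(z))
        # rebuild cophenetic distances from the newick by pairwise merge
        # heights: parse with a simple stack
        import dendropy
        t = dendropy.Tree.get(data=tree, schema="newick")
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        for i in range(n):
            for j in range(i + 1, n):
                assert pdm.distance(taxa[f"t{i}"], taxa[f"t{j}"]) == \
                    pytest.approx(coph[i, j], abs=1e-6)
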