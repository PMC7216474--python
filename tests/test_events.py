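"""Local AS events: one hand-built gene per type, oracle agreement, set algebra."""

import pytest

from sjkit.events import (
    EVENT_TYPES,
    build_catalog,
    compare_conditions,
    enumerate_events,
)
from sjkit.formats import IntegrityError
from _oracles import brute_force_events
from conftest import tm


def events_of(txs):
    return enumerate_events(txs)


def keyset(events):
    return {(e.event_type, e.coordinates) for e in events}


# two-isoform genes designed to yield exactly one event of each type
HAND_BUILT = {
    "SE": (
        tm("i", [(0, 100), (200, 300), (400, 500)]),
        tm("e", [(0, 100), (400, 500)]),
    ),
    "A5": (
        tm("i", [(0, 150), (200, 300)]),
        tm("e", [(0, 100), (200, 300)]),
    ),
    "A3": (
        tm("i", [(0, 100), (250, 300)]),
        tm("e", [(0, 100), (200, 300)]),
    ),
    "MX": (
        tm("i", [(0, 100), (200, 300), (600, 700)]),
        tm("e", [(0, 100), (400, 500), (600, 700)]),
    ),
    "RI": (
        tm("i", [(0, 300)]),
        tm("e", [(0, 100), (200, 300)]),
    ),
    "AF": (
        tm("i", [(0, 100), (500, 600)]),
        tm("e", [(200, 300), (500, 600)]),
    ),
    "AL": (
        tm("i", [(0, 100), (200, 300)]),
        tm("e", [(0, 100), (400, 500)]),
    ),
}


class TestHandBuiltGenes:
    @pytest.mark.parametrize("etype", list(HAND_BUILT))
    def test_exactly_one_event_of_expected_type(self, etype):
        evs = events_of(list(HAND_BUILT[etype]))
        assert [e.event_type for e in evs] == [etype]
        assert evs[0].inclusion_isoforms and evs[0].exclusion_isoforms

    @pytest.mark.parametrize("etype", list(HAND_BUILT))
    def test_strand_mirroring(self, etype):
        """On '-', A5<->A3 and AF<->AL swap; SE/MX/RI are symmetric."""
        mirror = {"A5": "A3", "A3": "A5", "AF": "AL", "AL": "AF"}
        txs = [
            tm(t.transcript_id, t.exon_coords, strand="-")
            for t in HAND_BUILT[etype]
        ]
        evs = events_of(txs)
        assert [e.event_type for e in evs] == [mirror.get(etype, etype)]

    def test_se_example_coordinates(self):
        evs = events_of(
            [
                tm("a", [(0, 100), (200, 300), (400, 500)]),
                tm("b", [(0, 100), (400, 500)]),
            ]
        )
        (e,) = evs
        assert e.event_type == "SE" and e.coordinates == (100, 200, 300, 400)
        assert e.inclusion_isoforms == ("a",) and e.exclusion_isoforms == ("b",)

    def test_ri_example(self):
        evs = events_of([tm("a", [(0, 100), (200, 300)]), tm("b", [(0, 300)])])
        (e,) = evs
        assert e.event_type == "RI" and e.coordinates == (0, 100, 200, 300)
        assert e.inclusion_isoforms == ("b",)  # retaining isoform

    def test_a5_variant_boundary_inside_partner_exon(self):
        evs = events_of(
            [tm("a", [(0, 100), (200, 300)]), tm("b", [(0, 150), (200, 300)])]
        )
        (e,) = evs
        assert e.event_type == "A5" and e.coordinates == (100, 200, 150, 200)


class TestEnumerate:
    def test_mixed_strand_rejected(self):
        with pytest.raises(IntegrityError):
            events_of(
                [tm("a", [(0, 100), (200, 300)]),
                 tm("b", [(0, 100), (200, 300)], strand="-")]
            )

    def test_single_transcript_no_events(self):
        assert events_of([tm("a", [(0, 100), (200, 300)])]) == []

    def test_witnesses_accumulate_and_dedupe(self):
        txs = [
            tm("a", [(0, 100), (200, 300), (400, 500)]),
            tm("a2", [(10, 100), (200, 300), (400, 490)]),
            tm("b", [(0, 100), (400, 500)]),
        ]
        evs = [e for e in events_of(txs) if e.event_type == "SE"]
        (e,) = evs
        assert e.inclusion_isoforms == ("a", "a2")
        assert e.exclusion_isoforms == ("b",)

    def test_monotone_under_transcript_addition(self):
        txs = list(HAND_BUILT["SE"])
        before = keyset(events_of(txs))
        extra = tm("x", [(0, 100), (250, 300), (400, 500)])
        after = keyset(events_of(txs + [extra]))
        assert before <= after

    def test_oracle_agreement_on_random_toy_genes(self, random_toy_genes):
        genes = random_toy_genes(seed=11, n_genes=120)
        for txs in genes:
            got = keyset(enumerate_events(txs))
            want = brute_force_events(txs)
            assert got == want, (txs[0].gene_id, got ^ want)


class TestCatalogAndComparison:
    def test_mono_isoform_genes_empty_catalog(self):
        cat = build_catalog(
            [tm("a", [(0, 100), (200, 300)], gene="g1"),
             tm("b", [(0, 50)], gene="g2")]
        )
        assert len(cat) == 0

    def test_counts_by_type(self):
        isoforms = [
            t.with_ids(gene_id="gSE") for t in HAND_BUILT["SE"]
        ] + [
            tm(f"ri_{t.transcript_id}", t.exon_coords, gene="gRI")
            for t in HAND_BUILT["RI"]
        ]
        cat = build_catalog(isoforms)
        assert cat.counts["SE"] == 1 and cat.counts["RI"] == 1
        assert sum(cat.counts.values()) == len(cat) == 2

    def test_gene_order_invariance(self):
        isoforms = [
            tm(f"{g}.{t.transcript_id}", t.exon_coords, gene=g)
            for g, pair in [("g1", HAND_BUILT["SE"]), ("g2", HAND_BUILT["A5"])]
            for t in pair
        ]
        assert (
            build_catalog(isoforms).keys == build_catalog(isoforms[::-1]).keys
        )

    def test_condition_specific_events_and_deg_partition(self):
        a_iso = [
            tm(f"g1.{t.transcript_id}", t.exon_coords, gene="g1")
            for t in HAND_BUILT["SE"]
        ]
        b_iso = a_iso + [
            tm(f"g2.{t.transcript_id}", t.exon_coords, gene="g2")
            for t in HAND_BUILT["RI"]
        ]
        cat_a, cat_b = build_catalog(a_iso, "A"), build_catalog(b_iso, "B")
        cmp = compare_conditions(cat_a, cat_b, deg_genes=set())
        assert {e.gene_id for e in cmp.events_only_in_b} == {"g2"}
        assert cmp.asg_b == {"g2"} == cmp.asg_b_non_deg
        cmp2 = compare_conditions(cat_a, cat_b, deg_genes={"g2"})
        assert cmp2.asg_b_deg == {"g2"} and cmp2.asg_b_non_deg == frozenset()

    def test_identical_catalogs_give_empty_comparison(self):
        iso = [
            tm(f"g1.{t.transcript_id}", t.exon_coords, gene="g1")
            for t in HAND_BUILT["SE"]
        ]
        cmp = compare_conditions(build_catalog(iso), build_catalog(iso), set())
        assert cmp.events_only_in_b == () and cmp.asg_b == frozenset()

    def test_symmetric_difference_partition(self, random_toy_genes):
        genes = random_toy_genes(seed=3, n_genes=20)
        iso_a = [t for txs in genes[:15] for t in txs]
        iso_b = [t for txs in genes[5:] for t in txs]
        cat_a, cat_b = build_catalog(iso_a), build_catalog(iso_b)
        ab = compare_conditions(cat_a, cat_b)
        ba = compare_conditions(cat_b, cat_a)
        only_b = {e.key for e in ab.events_only_in_b}
        only_a = {e.key for e in ba.events_only_in_b}
        assert only_a | only_b == cat_a.keys ^ cat_b.keys
        assert not only_a & only_b
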