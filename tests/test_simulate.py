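"""Synthetic-fixture generator: determinism, self-consistency, perturbation ops."""

import numpy as np
import pytest

from sjkit.classify import build_reference_index, classify_isoform
from sjkit.events import build_catalog
from sjkit.junctions import classify_junction_motif, filter_isoforms, junctions_of
from sjkit.simulate import (
    CONDITIONS,
    OPS,
    SimConfig,
    TREATED,
    UNTREATED,
    perturb_isoform,
    simulate_dataset,
)
from conftest import tm


SMALL = dict(n_genes=6, spurious_sj_rate=10)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        p1 = simulate_dataset(SimConfig(seed=5, **SMALL)).write(tmp_path / "a")
        p2 = simulate_dataset(SimConfig(seed=5, **SMALL)).write(tmp_path / "b")
        for key in p1:
            assert (
                open(p1[key], "rb").read() == open(p2[key], "rb").read()
            ), key

    def test_different_seed_differs(self):
        d1 = simulate_dataset(SimConfig(seed=1, **SMALL))
        d2 = simulate_dataset(SimConfig(seed=2, **SMALL))
        assert d1.sequence != d2.sequence

    def test_truth_covers_requested_genes(self):
        ds = simulate_dataset(SimConfig(seed=3, n_genes=5))
        real_genes = {
            t.gene_id
            for t in ds.truth.isoforms.values()
            if t.op not in ("antisense", "intergenic")
        }
        assert real_genes == {f"g{k:04d}" for k in range(1, 6)}


class TestSelfConsistency:
    @pytest.mark.parametrize("seed", range(20))
    def test_labels_rederivable_from_generated_data(self, seed):
        """Validation status, structural category and planted motifs are
        reproduced by running the toolkit's definitions on the outputs."""
        ds = simulate_dataset(
            SimConfig(seed=seed, n_genes=5, spurious_sj_rate=15,
                      noncanonical_fraction=0.2)
        )
        index = build_reference_index(ds.annotation)
        genome = ds.genome
        for cond in CONDITIONS:
            retained, report = filter_isoforms(
                ds.isoforms[cond], ds.sj_tables[cond]
            )
            for outcome in report:
                truth = ds.truth.isoforms[outcome.isoform_id]
                assert dict(truth.status)[cond] == outcome.status
            # no dropout: everything retained
            assert {t.transcript_id for t in retained} == ds.truth.valid_ids(cond)
        for t in ds.isoforms[TREATED]:
            call = classify_isoform(t, index)
            assert call.category == ds.truth.isoforms[t.transcript_id].category
        # planted motifs recovered exactly
        for ref in ds.annotation.transcripts():
            for sj in junctions_of(ref):
                donor, acceptor, canonical = ds.truth.junction_motifs[
                    (sj.start, sj.end)
                ]
                m = classify_junction_motif(sj, genome)
                assert (m.donor, m.acceptor, m.canonical) == (
                    donor, acceptor, canonical,
                )
        # events re-derivable from the isoform sets
        for cond in CONDITIONS:
            cat = build_catalog(ds.isoforms[cond], cond)
            assert cat.keys == ds.truth.catalogs[cond].keys

    def test_condition_b_has_specific_events(self):
        ds = simulate_dataset(SimConfig(seed=8, n_genes=10))
        only_b = ds.truth.catalogs[TREATED].keys - ds.truth.catalogs[UNTREATED].keys
        assert only_b

    def test_spurious_junctions_disjoint_from_truth(self):
        ds = simulate_dataset(SimConfig(seed=4, n_genes=5, spurious_sj_rate=50))
        true_coords = {
            (sj.start, sj.end)
            for cond in CONDITIONS
            for t in ds.isoforms[cond]
            for sj in junctions_of(t)
        }
        for cond in CONDITIONS:
            n_spurious = sum(
                1
                for rec in ds.sj_tables[cond]
                if (rec.junction.start, rec.junction.end) not in true_coords
            )
            assert n_spurious == 50


class TestDropout:
    def test_dropout_only_invalidates_hit_chains(self):
        ds = simulate_dataset(
            SimConfig(seed=9, n_genes=10, junction_dropout=0.3)
        )
        for cond in CONDITIONS:
            dropped = ds.truth.dropped[cond]
            assert dropped  # 0.3 over dozens of junctions
            _, report = filter_isoforms(ds.isoforms[cond], ds.sj_tables[cond])
            by_id = {t.transcript_id: t for t in ds.isoforms[cond]}
            for o in report:
                coords = {
                    (sj.start, sj.end)
                    for sj in junctions_of(by_id[o.isoform_id])
                }
                if o.status == "invalid":
                    assert coords & dropped
                elif o.status == "valid":
                    assert not (coords & dropped)

    def test_dropout_monotone_under_coupled_seeds(self):
        for seed in range(5):
            counts = []
            for rate in (0.0, 0.2, 0.5):
                ds = simulate_dataset(
                    SimConfig(seed=seed, n_genes=6, junction_dropout=rate)
                )
                retained, _ = filter_isoforms(
                    ds.isoforms[UNTREATED], ds.sj_tables[UNTREATED]
                )
                counts.append(len(retained))
            assert counts[0] >= counts[1] >= counts[2]


class TestPerturbIsoform:
    BASE = tm("g1.t1", [(0, 100), (200, 300), (400, 500), (600, 700)])

    @pytest.mark.parametrize("op", OPS)
    def test_labels_match_documented_table(self, op):
        rng = np.random.default_rng(0)
        model, category, event = perturb_isoform(self.BASE, op, rng)
        expected = {
            "skip_exon": ("NIC", "SE"),
            "retain_intron": ("NIC", "RI"),
            "shift_donor": ("NNC", "A5"),
            "shift_acceptor": ("NNC", "A3"),
            "novel_exon": ("NNC", "SE"),
            "truncate_5prime": ("ISM", None),
            "antisense": ("Antisense", None),
            "intergenic": ("Intergenic", None),
        }[op]
        assert (category, event) == expected

    @pytest.mark.parametrize("op", ("skip_exon", "retain_intron", "truncate_5prime"))
    def test_inapplicable_op_raises(self, op):
        mono = tm("m", [(0, 100), (200, 300)])
        if op == "truncate_5prime":
            mono = tm("m", [(0, 100), (200, 300)])
        with pytest.raises(ValueError):
            perturb_isoform(tm("m", [(0, 100)]) if op != "retain_intron" else mono,
                            op, np.random.default_rng(0))

    @pytest.mark.parametrize("strand", "+-")
    @pytest.mark.parametrize(
        "op", ("skip_exon", "retain_intron", "shift_donor", "shift_acceptor", "novel_exon")
    )
    def test_expected_event_realized_against_reference(self, op, strand):
        """The advertised event type appears when the perturbed isoform is
        enumerated together with its reference."""
        from sjkit.events import enumerate_events

        base = tm("g1.t1", [(0, 100), (200, 300), (400, 500), (600, 700)],
                  strand=strand)
        rng = np.random.default_rng(1)
        model, _, event = perturb_isoform(base, op, rng)
        evs = enumerate_events([base, model])
        assert event in {e.event_type for e in evs}

    def test_truncation_gives_contiguous_subchain_no_event(self):
        from sjkit.events import enumerate_events

        rng = np.random.default_rng(1)
        model, _, _ = perturb_isoform(self.BASE, "truncate_5prime", rng)
        assert enumerate_events([self.BASE, model]) == []
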