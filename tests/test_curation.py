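"""The five-rule annotation cleanup: per-rule behaviour, boundary cases,
planted-defect recovery, idempotence, and the global postcondition sweep."""

import pytest

from asmcurate import fixtures as fx
from asmcurate import io as aio
from asmcurate.curation import (
    AT_AC,
    GT_AG,
    CurationParams,
    curate,
    dedupe_identical_isoforms,
    dedupe_named_loci,
    filter_structural,
    intron_dinucleotides,
    resolve_locus_gene_names,
    strip_shared_exons,
)
from _builders import contig_with, locus, tx


class TestResolveGeneNames:
    def test_keeps_transcripts_matching_top_scorer_name(self):
        l = locus("g1", [
            tx("g1.t1", [(100, 200)], score=50, name="A"),
            tx("g1.t2", [(100, 250)], score=40, name="B"),
            tx("g1.t3", [(100, 300)], score=30, name="A"),
        ])
        out = resolve_locus_gene_names(l)
        assert [t.id for t in out.transcripts] == ["g1.t1", "g1.t3"]

    def test_single_transcript_unchanged(self):
        l = locus("g1", [tx("g1.t1", [(100, 200)], name="A")])
        assert resolve_locus_gene_names(l) is l

    def test_score_tie_keeps_first_in_input_order(self):
        l = locus("g1", [
            tx("g1.t1", [(100, 200)], score=50, name="B"),
            tx("g1.t2", [(100, 250)], score=50, name="A"),
        ])
        out = resolve_locus_gene_names(l)
        assert [t.gene_name for t in out.transcripts] == ["B"]


class TestDedupeNamedLoci:
    def test_lower_scoring_duplicate_removed(self):
        ann = [
            locus("g1", [tx("g1.t1", [(100, 200)], score=60, name="A")]),
            locus("g2", [tx("g2.t1", [(900, 999)], score=55, name="A")]),
        ]
        out = dedupe_named_loci(ann)
        assert [l.id for l in out] == ["g1"]

    def test_unique_names_unchanged(self):
        ann = [
            locus("g1", [tx("g1.t1", [(100, 200)], name="A")]),
            locus("g2", [tx("g2.t1", [(900, 999)], name="B")]),
        ]
        assert dedupe_named_loci(ann) == ann

    def test_unnamed_loci_exempt(self):
        ann = [
            locus("g1", [tx("g1.t1", [(100, 200)], name=None)]),
            locus("g2", [tx("g2.t1", [(900, 999)], name=None)]),
        ]
        assert len(dedupe_named_loci(ann)) == 2

    def test_tie_keeps_leftmost_then_smallest_id(self):
        ann = [
            locus("g2", [tx("g2.t1", [(900, 999)], score=60, name="A")]),
            locus("g1", [tx("g1.t1", [(100, 200)], score=60, name="A")]),
        ]
        assert [l.id for l in dedupe_named_loci(ann)] == ["g1"]
        ann = [
            locus("gB", [tx("gB.t1", [(100, 200)], score=60, name="A")]),
            locus("gA", [tx("gA.t1", [(100, 200)], score=60, name="A")]),
        ]
        assert [l.id for l in dedupe_named_loci(ann)] == ["gA"]


class TestStripSharedExons:
    def test_cross_gene_shared_exon_trimmed_from_both(self):
        shared = (5000, 5120)
        ann = [
            locus("g1", [tx("g1.t1", [(100, 200), shared], gene_id="g1")]),
            locus("g2", [tx("g2.t1", [shared, (8000, 8100)], gene_id="g2")]),
        ]
        out = strip_shared_exons(ann)
        assert out[0].transcripts[0].exon_boundaries() == ((100, 200),)
        assert out[1].transcripts[0].exon_boundaries() == ((8000, 8100),)
        assert out[0].span == (100, 200)

    def test_shared_within_same_gene_untouched(self):
        shared = (5000, 5120)
        ann = [
            locus("g1", [
                tx("g1.t1", [(100, 200), shared], gene_id="g1"),
                tx("g1.t2", [(100, 250), shared], gene_id="g1"),
            ]),
        ]
        out = strip_shared_exons(ann)
        assert out[0].transcripts[0].exon_boundaries() == ((100, 200), shared)

    def test_transcript_emptied_by_trim_is_dropped(self):
        shared = (5000, 5120)
        ann = [
            locus("g1", [tx("g1.t1", [shared], gene_id="g1")]),
            locus("g2", [tx("g2.t1", [shared, (8000, 8100)], gene_id="g2")]),
        ]
        out = strip_shared_exons(ann)
        assert [l.id for l in out] == ["g2"]

    def test_planted_shared_exons_counted(self, tmp_path):
        fix = fx.make_annotation(
            tmp_path, seed=21, n_genes=10,
            defects=fx.DefectSpec(shared_exons=2),
        )
        _, rep = curate(fix.annotation, fix.contigs)
        assert rep.exons_trimmed["strip_shared_exons"] == 4  # 2 exons x 2 owners


class TestFilterStructural:
    def make_genome(self, plants=()):
        return [contig_with(20_000, plants)]

    def test_14bp_exon_eliminates_transcript(self):
        genome = self.make_genome()
        ann = [locus("g1", [tx("g1.t1", [(100, 113)])])]
        assert filter_structural(ann, genome) == []

    def test_15bp_exon_retained(self):
        genome = self.make_genome()
        ann = [locus("g1", [tx("g1.t1", [(100, 114)])])]
        assert len(filter_structural(ann, genome)) == 1

    def test_plus_strand_gt_ag_retained(self):
        # exons 100-200, 301-400; intron 201-300 with GT..AG
        genome = self.make_genome([(201, "GT"), (299, "AG")])
        ann = [locus("g1", [tx("g1.t1", [(100, 200), (301, 400)])])]
        assert len(filter_structural(ann, genome)) == 1

    def test_minus_strand_ct_ac_is_canonical(self):
        # genomic CT..AC reads GT..AG in transcript orientation on '-'
        genome = self.make_genome([(201, "CT"), (299, "AC")])
        ann = [locus("g1", [tx("g1.t1", [(100, 200), (301, 400)], strand="-")],
                     strand="-")]
        assert len(filter_structural(ann, genome)) == 1

    def test_minus_strand_at_cc_eliminated(self):
        genome = self.make_genome([(201, "AT"), (299, "CC")])
        ann = [locus("g1", [tx("g1.t1", [(100, 200), (301, 400)], strand="-")],
                     strand="-")]
        assert filter_structural(ann, genome) == []

    def test_configurable_canonical_set(self):
        genome = self.make_genome([(201, "AT"), (299, "AC")])
        ann = [locus("g1", [tx("g1.t1", [(100, 200), (301, 400)])])]
        assert filter_structural(ann, genome) == []
        params = CurationParams(splice_canon=(GT_AG, AT_AC))
        assert len(filter_structural(ann, genome, params)) == 1

    def test_intron_dinucleotides_orientation(self):
        contig = contig_with(1000, [(201, "CT"), (299, "AC")])
        t = tx("t", [(100, 200), (301, 400)], strand="-")
        assert intron_dinucleotides(t, contig.sequence) == [("GT", "AG")]


class TestDedupeIdenticalIsoforms:
    def test_longest_cds_survives(self):
        l = locus("g1", [
            tx("g1.t1", [(100, 200), (300, 400)], cds=[(110, 200), (300, 390)]),
            tx("g1.t2", [(100, 200), (300, 400)], cds=[(150, 200), (300, 360)]),
        ])
        out = dedupe_identical_isoforms(l)
        assert [t.id for t in out.transcripts] == ["g1.t1"]

    def test_equal_cds_keeps_smallest_id(self):
        l = locus("g1", [
            tx("g1.t2", [(100, 200)], cds=[(110, 190)]),
            tx("g1.t1", [(100, 200)], cds=[(120, 200)]),
        ])
        out = dedupe_identical_isoforms(l)
        assert [t.id for t in out.transcripts] == ["g1.t1"]

    def test_different_boundaries_both_kept(self):
        l = locus("g1", [
            tx("g1.t1", [(100, 200)]),
            tx("g1.t2", [(100, 201)]),
        ])
        assert len(dedupe_identical_isoforms(l).transcripts) == 2


# --- the full pipeline ------------------------------------------------------

ALL_DEFECTS = fx.DefectSpec(
    name_conflicts=1, duplicate_named_loci=1, shared_exons=1,
    short_exons=1, noncanonical_introns=1, identical_isoforms=1,
)


def assert_postconditions(annotation, genome, params=CurationParams()):
    """Global postcondition sweep after curation."""
    genome_by_id = {c.id: c for c in genome}
    seen_names = {}
    exon_owner = {}
    for l in annotation:
        names = {t.gene_name for t in l.transcripts}
        assert len(names) == 1, f"{l.id}: multiple gene names"
        (name,) = names
        if name is not None:
            assert name not in seen_names, f"name {name} on two loci"
            seen_names[name] = l.id
        boundaries = set()
        for t in l.transcripts:
            b = t.exon_boundaries()
            assert b not in boundaries, f"{l.id}: identical-boundary isoforms"
            boundaries.add(b)
            for ex in t.exons:
                assert ex.length >= params.min_exon_len
                key = (l.seqid, ex.start, ex.end, l.strand)
                assert exon_owner.setdefault(key, l.id) == l.id, (
                    f"exon {key} shared across genes"
                )
            seq = genome_by_id[l.seqid].sequence
            for pair in intron_dinucleotides(t, seq):
                assert pair in params.splice_canon, f"{t.id}: noncanonical {pair}"


class TestCuratePipeline:
    def test_defect_free_fixture_unchanged(self, tmp_path):
        fix = fx.make_annotation(tmp_path, seed=2, n_genes=8)
        out, rep = curate(fix.annotation, fix.contigs)
        assert len(rep.log) == 0
        assert rep.transcripts_in == rep.transcripts_out
        assert [l.id for l in out] == [l.id for l in fix.annotation]

    def test_one_defect_of_each_kind_one_action_per_rule(self, tmp_path):
        fix = fx.make_annotation(tmp_path, seed=4, n_genes=10, defects=ALL_DEFECTS)
        out, rep = curate(fix.annotation, fix.contigs)
        assert rep.transcripts_removed["resolve_gene_names"] == 1
        assert rep.loci_removed["dedupe_named_loci"] == 1
        assert rep.exons_trimmed["strip_shared_exons"] == 2
        assert rep.transcripts_removed["filter_structural"] == 2
        assert rep.transcripts_removed["dedupe_identical_isoforms"] == 1

    @pytest.mark.parametrize("seed", range(22))
    def test_planted_defects_recovered_no_spurious_actions(self, seed, tmp_path):
        fix = fx.make_annotation(
            tmp_path, seed=seed, n_genes=12, defects=ALL_DEFECTS
        )
        out, rep = curate(fix.annotation, fix.contigs)
        exp = fix.ledger.expected
        assert rep.total_transcripts_removed() == exp["transcripts_removed"]
        assert sum(rep.loci_removed.values()) == exp["loci_removed"]
        assert sum(rep.exons_trimmed.values()) == exp["exon_trims"]
        # every action targets a planted entity: no spurious removals
        planted = {e for d in fix.ledger.planted_defects for e in d["entities"]}
        for action in rep.log:
            if action.action == "transcript_removed":
                assert action.entity_id in planted, (
                    f"spurious removal of {action.entity_id}"
                )
        # all surviving clean genes intact
        out_ids = {l.id for l in out}
        assert set(exp["clean_genes"]) <= out_ids
        assert_postconditions(out, fix.contigs)

    @pytest.mark.parametrize("seed", range(22))
    def test_curate_is_idempotent(self, seed, tmp_path):
        fix = fx.make_annotation(
            tmp_path, seed=100 + seed, n_genes=12, defects=ALL_DEFECTS
        )
        once, rep1 = curate(fix.annotation, fix.contigs)
        twice, rep2 = curate(once, fix.contigs)
        assert len(rep2.log) == 0

        def flat(ann):
            return [
                (l.id, t.id, t.exon_boundaries(),
                 tuple((c.start, c.end) for c in t.cds))
                for l in ann for t in l.transcripts
            ]

        assert flat(once) == flat(twice)

    @pytest.mark.parametrize("seed", range(5))
    def test_transcript_count_conservation(self, seed, tmp_path):
        fix = fx.make_annotation(
            tmp_path, seed=200 + seed, n_genes=12, defects=ALL_DEFECTS
        )
        _, rep = curate(fix.annotation, fix.contigs)
        assert rep.transcripts_in == (
            rep.transcripts_out + rep.total_transcripts_removed()
        )

    def test_pipeline_through_files(self, tmp_path):
        fix = fx.make_annotation(
            tmp_path, seed=8, n_genes=10, defects=ALL_DEFECTS
        )
        ann = aio.read_annotation(fix.gff3)
        genome = aio.read_fasta(fix.genome)
        out, rep = curate(ann, genome)
        assert rep.total_transcripts_removed() == (
            fix.ledger.expected["transcripts_removed"]
        )
        assert_postconditions(out, genome)
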