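"""Deletion-length arithmetic, consequence classes, PCR bands, final report."""

import itertools

import numpy as np
import pytest

from recmap.consequence import (
    ConsequenceCall,
    GeneModel,
    GenotypingAssay,
    classify_consequence,
    deletion_length,
    downstream_start_rescue,
    final_report,
    hgvs_to_vcf_anchor,
    load_gene_models,
    predict_genotyping_bands,
    read_fasta_sequence,
    render_report_text,
    vcf_anchor_to_hgvs,
)

# mirrored on the real lesion: exon 1 carries a 321 nt 5'UTR, the start
# codon and 79 coding bases in total; the deletion removes >900 bp of
# upstream sequence, the whole exon and ~1.1 kb of intron 1
GENE = GeneModel(
    gene_id="LAMC2L", transcript_id="TX1", chrom="16", strand="+",
    exons=((10_933, 11_332), (14_000, 15_599), (16_400, 18_570)),
    cds_start=11_254, cds_end=18_320,
)
DELETION = ("16", 10_000, 12_432)          # 2,433 bp


class TestDeletionLength:
    def test_printed_worked_example(self):
        assert deletion_length(65_704_617, 65_707_049) == 2_433

    def test_single_base(self):
        assert deletion_length(7, 7) == 1

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            deletion_length(10, 9)

    def test_matches_integer_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            s = int(rng.integers(1, 10**8))
            e = s + int(rng.integers(0, 10**5))
            assert deletion_length(s, e) == len(range(s, e + 1))

    def test_vcf_anchor_round_trip(self):
        pos, end = hgvs_to_vcf_anchor(65_704_617, 65_707_049)
        assert (pos, end) == (65_704_616, 65_707_049)
        assert vcf_anchor_to_hgvs(pos, end) == (65_704_617, 65_707_049)


def _reflect_model(model, c=10_000_000):
    """Mirror-image a model: x -> c - x, strand flipped."""
    exons = tuple(sorted((c - e, c - s) for s, e in model.exons))
    return GeneModel(
        gene_id=model.gene_id, transcript_id=model.transcript_id,
        chrom=model.chrom, strand="-" if model.strand == "+" else "+",
        exons=exons, cds_start=c - model.cds_end, cds_end=c - model.cds_start,
    )


class TestClassifyConsequence:
    def test_exon1_loss_is_start_lost_with_79_coding_bases(self):
        call = classify_consequence(DELETION, GENE)
        assert call.consequence == "start_lost"
        assert call.deleted_coding_bases == 79
        assert call.whole_exons_deleted == 1

    def test_intronic_deletion(self):
        call = classify_consequence(("16", 12_500, 13_000), GENE)
        assert call.consequence == "intronic"
        assert call.deleted_coding_bases == 0

    def test_cds_truncation(self):
        call = classify_consequence(("16", 15_000, 15_100), GENE)
        assert call.consequence == "cds_truncation"
        assert call.deleted_coding_bases == 101

    def test_whole_internal_exon_loss(self):
        call = classify_consequence(("16", 13_900, 15_700), GENE)
        assert call.consequence == "exon_loss"
        assert call.whole_exons_deleted == 1

    def test_upstream_within_window(self):
        call = classify_consequence(("16", 9_500, 9_900), GENE)
        assert call.consequence == "upstream"

    def test_intergenic_beyond_window(self):
        call = classify_consequence(("16", 1_000, 2_000), GENE)
        assert call.consequence == "intergenic"

    def test_chromosome_mismatch_intergenic_with_note(self):
        call = classify_consequence(("3", 10_000, 12_432), GENE)
        assert call.consequence == "intergenic"
        assert any("mismatch" in n for n in call.notes)

    def test_minus_strand_start_lost(self):
        minus = _reflect_model(GENE)
        refl = ("16", 10_000_000 - DELETION[2], 10_000_000 - DELETION[1])
        call = classify_consequence(refl, minus)
        assert call.consequence == "start_lost"
        assert call.deleted_coding_bases == 79

    @pytest.mark.parametrize("interval", [
        (10_000, 12_432), (12_500, 13_000), (15_000, 15_100),
        (13_900, 15_700), (9_500, 9_900), (1_000, 2_000), (18_400, 18_800),
    ])
    def test_strand_reflection_preserves_class(self, interval):
        fwd = classify_consequence(("16", *interval), GENE)
        minus = _reflect_model(GENE)
        refl = ("16", 10_000_000 - interval[1], 10_000_000 - interval[0])
        rev = classify_consequence(refl, minus)
        assert fwd.consequence == rev.consequence
        assert fwd.deleted_coding_bases == rev.deleted_coding_bases

    def test_deleted_coding_bases_bounded(self):
        rng = np.random.default_rng(4)
        total_cds = GENE.cds_length()
        for _ in range(100):
            s = int(rng.integers(9_000, 19_000))
            e = s + int(rng.integers(0, 6_000))
            call = classify_consequence(("16", s, e), GENE)
            assert call.deleted_coding_bases <= min(e - s + 1, total_cds)

    def test_invalid_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            GeneModel(gene_id="X", transcript_id="T", chrom="1", strand="*",
                      exons=((1, 10),), cds_start=2, cds_end=8)


def _cds_with_atg_at(offsets, length=3_600):
    codons = ["GCT"] * (length // 3)
    for off in offsets:
        codons[off // 3] = "ATG"
    return "".join(codons)


class TestDownstreamStartRescue:
    def test_second_start_at_900_gives_quarter_loss(self):
        seq = _cds_with_atg_at([0, 900])
        off, frac = downstream_start_rescue(GENE, seq, DELETION)
        assert off == 900
        assert frac == pytest.approx(0.25)

    def test_first_intact_codon_is_found(self):
        # deletion removes the first 79 coding bases; an ATG in the first
        # intact in-frame codon (offset 81) is picked up immediately
        seq = _cds_with_atg_at([0, 81, 900])
        off, frac = downstream_start_rescue(GENE, seq, DELETION)
        assert off == 81
        assert frac == pytest.approx(81 / 3_600)

    def test_no_downstream_atg_total_loss(self):
        seq = _cds_with_atg_at([0])
        off, frac = downstream_start_rescue(GENE, seq, DELETION)
        assert off is None
        assert frac == 1.0

    def test_deleted_inframe_atg_skipped(self):
        # an ATG whose codon lost a base to the deletion cannot rescue
        seq = _cds_with_atg_at([0, 78, 900])
        off, _ = downstream_start_rescue(GENE, seq, DELETION)
        assert off == 900

    def test_non_start_lost_rejected(self):
        seq = _cds_with_atg_at([0])
        with pytest.raises(ValueError):
            downstream_start_rescue(GENE, seq, ("16", 12_500, 13_000))


ASSAY = GenotypingAssay(forward_pos=9_800, rev1_pos=11_000, rev2_pos=12_600,
                        deletion=(10_000, 12_432))


class TestGenotypingBands:
    @pytest.mark.parametrize("genotype,bands", [
        ("wt/wt", {"F+Rev1"}),
        ("wt/del", {"F+Rev1", "F+Rev2"}),
        ("del/wt", {"F+Rev1", "F+Rev2"}),
        ("del/del", {"F+Rev2"}),
    ])
    def test_band_patterns(self, genotype, bands):
        assert predict_genotyping_bands(ASSAY, genotype) == bands

    def test_determined_solely_by_allele_pair(self):
        for a1, a2 in itertools.product(("wt", "del"), repeat=2):
            bands = predict_genotyping_bands(ASSAY, f"{a1}/{a2}")
            expected = {{"wt": "F+Rev1", "del": "F+Rev2"}[a] for a in (a1, a2)}
            assert bands == expected

    def test_bad_genotype_rejected(self):
        with pytest.raises(ValueError):
            predict_genotyping_bands(ASSAY, "wt")

    @pytest.mark.parametrize("kw", [
        dict(forward_pos=10_500),    # forward inside the deletion
        dict(rev1_pos=9_999),        # Rev1 outside
        dict(rev2_pos=12_000),       # Rev2 not downstream
    ])
    def test_assay_invariants_enforced(self, kw):
        base = dict(forward_pos=9_800, rev1_pos=11_000, rev2_pos=12_600,
                    deletion=(10_000, 12_432))
        with pytest.raises(ValueError):
            GenotypingAssay(**{**base, **kw})


class TestFinalReport:
    def _deletion_call(self, gene="LAMC2L", consequence="start_lost"):
        from recmap.svcall import DeletionCall

        call = DeletionCall(chrom="16", start=10_000, end=12_432, support=20,
                            estimated_size=2_433.0, genotype="hom_del")
        cons = ConsequenceCall(deletion=("16", 10_000, 12_432), gene=gene,
                               consequence=consequence,
                               deleted_coding_bases=79)
        return call, cons

    def test_unique_nomination(self):
        report = final_report([], [self._deletion_call()], ["LAMC2L", "G2"],
                              {"stage": 1})
        assert report["unique_nomination"]
        assert report["nominations"][0]["gene"] == "LAMC2L"
        assert report["cascade"] == {"stage": 1}

    def test_no_event_empty_nomination_with_counts(self):
        report = final_report([], [], ["LAMC2L"], {"a": 2, "b": 0})
        assert report["n_candidate_events"] == 0
        assert not report["unique_nomination"]
        assert report["cascade"] == {"a": 2, "b": 0}

    def test_two_events_flagged_non_unique(self):
        pairs = [self._deletion_call(), self._deletion_call(gene="G2")]
        report = final_report([], pairs, ["LAMC2L", "G2"], {})
        assert report["n_candidate_events"] == 2
        assert not report["unique_nomination"]

    def test_intronic_deletion_not_nominated(self):
        report = final_report([], [self._deletion_call(consequence="intronic")],
                              ["LAMC2L"], {})
        assert report["n_candidate_events"] == 0

    def test_text_rendering(self):
        report = final_report([], [self._deletion_call()], ["LAMC2L"], {"n": 3})
        text = render_report_text(report)
        assert "start_lost" in text and "LAMC2L" in text and "n: 3" in text


class TestModelIO:
    def test_gene_model_json_round_trip(self, small_cohort, tmp_path):
        from recmap.cohort import write_cohort

        paths = write_cohort(small_cohort, str(tmp_path))
        models = load_gene_models(paths["gene_models"])
        assert len(models) == 18
        hit = models[0]
        assert hit.gene_id == "LAMC2L"
        assert hit.cds_length() == 3_600

    def test_fasta_reader(self, small_cohort, tmp_path):
        from recmap.cohort import write_cohort

        paths = write_cohort(small_cohort, str(tmp_path))
        seq = read_fasta_sequence(paths["transcript_fasta"])
        assert seq == small_cohort.transcript_cds
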