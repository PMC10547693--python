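"""Protein-consequence prediction: worked examples, oracle spot checks,
strand symmetry and the duplication rule."""

import numpy as np
import pytest

from madw import (
    ProteinChange,
    ValidationError,
    Variant,
    apply_variant_to_cds,
    detect_duplication,
    plant_variant,
    predict_consequence,
    random_gene_model,
    translate_cds,
)
from madw.consequence import TranscriptContext
from madw.gene_models import GenomicInterval, revcomp
from madw.synthetic import PlantTarget
from genutil import explicit_gene, random_coding_variant
from oracle import oracle_consequence


class TestTranslate:
    def test_stops_at_first_stop(self):
        assert translate_cds("ATGTAA") == ("M", True)

    def test_flags_missing_stop(self):
        assert translate_cds("ATGTGG") == ("MW", False)

    def test_trp_codon(self):
        assert translate_cds("TGGTAA") == ("W", True)

    def test_ambiguous_base_translates_to_x_with_warning(self):
        with pytest.warns(UserWarning):
            assert translate_cds("ATGANGTAA")[0] == "MX"

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            translate_cds("AT")


class TestApplyVariant:
    def test_snp_preserves_length(self):
        assert apply_variant_to_cds("ATGCCC", 4, "C", "G") == "ATGGCC"

    def test_two_base_deletion(self):
        out = apply_variant_to_cds("ATGCCCAAA", 4, "CCC", "C")
        assert out == "ATGCAAA"

    def test_five_base_insertion(self):
        out = apply_variant_to_cds("ATGCCC", 3, "G", "GGTCGA")
        assert len(out) == 6 + 5
        assert "GTCGA" in out

    def test_cds_ref_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            apply_variant_to_cds("ATGCCC", 4, "G", "T")


def _gene_with(codons_at: dict[int, str], length: int = 120, strand: str = "+"):
    """Deterministic gene: Ala codons everywhere except the given overrides."""
    codons = ["ATG"] + ["GCT"] * (length - 1) + ["TAA"]
    for pos, codon in codons_at.items():
        codons[pos - 1] = codon
    return explicit_gene(codons, strand=strand)


class TestWorkedExamples:
    def test_nonsense_at_gln_codon(self):
        """C->T in CAA at codon 100 creates a premature stop: p.(Gln100Ter)."""
        model, seq = _gene_with({100: "CAA"})
        g = model.cds_to_genomic(3 * 99 + 1)
        v = Variant(model.chrom, g, seq[g - 1], "T")
        rec = predict_consequence(model, seq, v)
        assert rec.hgvs_p == "p.(Gln100Ter)"

    def test_five_base_insertion_causes_frameshift(self):
        """A GTCGA insertion inside codon 94 shifts the frame at Glu94."""
        model, seq = _gene_with({94: "GAA"})
        v, rec = plant_variant(
            model,
            seq,
            PlantTarget(
                protein_change=ProteinChange("frameshift", 94, ref_aa="E", no_stop=True),
                insertion="GTCGA",
            ),
            np.random.default_rng(0),
        )
        assert v.indel_length == 5
        assert rec.protein_change.kind == "frameshift"
        # the first shifted residue is at (or immediately after) Glu94,
        # depending on whether the insertion junction re-creates Glu
        assert rec.protein_change.start in (94, 95)
        assert "fsTer" in rec.hgvs_p

    def test_six_base_deletion_removes_gln_arg_pair(self):
        """In-frame 6-bp deletion of Gln74-Arg75: p.(Gln74_Arg75del)."""
        model, seq = _gene_with({74: "CAA", 75: "AGA"})
        v, rec = plant_variant(
            model,
            seq,
            PlantTarget(
                protein_change=ProteinChange(
                    "inframe_del", 74, end=75, ref_aa="QR"
                )
            ),
            np.random.default_rng(0),
        )
        assert v.indel_length == 6
        assert rec.hgvs_p == "p.(Gln74_Arg75del)"

    def test_missense_formats_with_three_letter_codes(self):
        model, seq = _gene_with({50: "AAA"})  # Lys50
        g = model.cds_to_genomic(3 * 49 + 3)
        v = Variant(model.chrom, g, seq[g - 1], "T")  # AAA -> AAT = Asn
        rec = predict_consequence(model, seq, v)
        assert rec.hgvs_p == "p.(Lys50Asn)"

    def test_intronic_offset_plus4_is_splice_region_without_protein(self):
        rng = np.random.default_rng(8)
        model, seq = random_gene_model(rng, exon_count=2, strand="+")
        intron = model.introns[0]
        pos = intron.start + 3  # offset +4
        old = seq[pos - 1]
        v = Variant(model.chrom, pos, old, "ACGT".replace(old, "")[0])
        rec = predict_consequence(model, seq, v)
        assert rec.noncoding_label == "splice_region"
        assert rec.hgvs_p is None

    def test_donor_dinucleotide_variant_is_splice_donor(self):
        rng = np.random.default_rng(8)
        model, seq = random_gene_model(rng, exon_count=2, strand="+")
        pos = model.introns[0].start  # +1 (the G of GT)
        v = Variant(model.chrom, pos, seq[pos - 1], "C")
        rec = predict_consequence(model, seq, v)
        assert rec.noncoding_label == "splice_donor"

    def test_deletion_spanning_exon_intron_boundary_is_splice_disrupting(self):
        rng = np.random.default_rng(8)
        model, seq = random_gene_model(rng, exon_count=2, strand="+")
        end1 = model.exons[0].end
        v = Variant(model.chrom, end1 - 2, seq[end1 - 3 : end1 + 2], seq[end1 - 3])
        rec = predict_consequence(model, seq, v)
        assert rec.noncoding_label == "splice_disrupting"
        assert rec.protein_change is None

    def test_start_codon_disruption_reported_as_met1_unknown(self):
        model, seq = _gene_with({})
        g = model.cds_to_genomic(2)  # the T of ATG
        v = Variant(model.chrom, g, seq[g - 1], "C")
        rec = predict_consequence(model, seq, v)
        assert rec.hgvs_p == "p.(Met1?)"

    def test_stop_codon_loss_reported_as_extension(self):
        model, seq = _gene_with({}, length=60)
        g = model.cds_to_genomic(model.cds_length - 2)  # T of final TAA
        v = Variant(model.chrom, g, seq[g - 1], "C")
        rec = predict_consequence(model, seq, v)
        assert rec.protein_change.kind == "stop_loss"
        assert rec.hgvs_p.startswith("p.(Ter61") and rec.hgvs_p.endswith("extTer?)")

    def test_variant_outside_span_is_an_error(self):
        model, seq = _gene_with({})
        with pytest.raises(Exception):
            predict_consequence(model, seq, Variant(model.chrom, 1, seq[0], "A" if seq[0] != "A" else "C"))


class TestDuplicationRule:
    def test_insertion_of_codon_copy_after_matching_codon_is_dup(self):
        """CAT inserted right after a His(CAT) codon duplicates His31."""
        model, seq = _gene_with({31: "CAT"})
        v, rec = plant_variant(
            model,
            seq,
            PlantTarget(protein_change=ProteinChange("inframe_dup", 31, ref_aa="H")),
            np.random.default_rng(0),
        )
        assert rec.hgvs_p == "p.(His31dup)"

    def test_insertion_after_non_matching_codon_is_plain_insertion(self):
        cds = "ATG" + "GGA" * 40 + "CAT" + "GGA" * 10 + "TAA"
        # direct CDS-level check, no gene needed
        assert detect_duplication("ATG" + "GGA" * 5 + "TAA", 6, "CAT") == "inframe_ins"

    def test_duplication_detected_at_three_prime_most_placement(self):
        """Inserting a repeat unit anywhere inside a tandem repeat names the
        3'-most copy, matching an enumeration of equivalent placements."""
        base = ["ATG"] + ["GCT"] * 10 + ["CAT", "CAT", "CAT"] + ["GGA"] * 10 + ["TAA"]
        cds = "".join(base)
        kind = detect_duplication(cds, 3 * 12, "CAT")  # insert inside the repeat
        assert kind == "inframe_dup"
        from madw.consequence import compare_proteins, translate_cds as tr

        mutant = cds[: 3 * 12] + "CAT" + cds[3 * 12 :]
        ref_p, rs = tr(cds)
        mut_p, ms = tr(mutant)
        pc = compare_proteins(ref_p, mut_p, rs, ms, frame_preserved=True)
        # equivalent placements are codons 12..14; the 3'-most is 14
        assert pc.start == 14


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(5))
    def test_predictions_match_full_retranslation_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        checked = 0
        for _ in range(40):
            model, seq = random_gene_model(rng)
            ctx = TranscriptContext(model, seq)
            for _ in range(10):
                v = random_coding_variant(rng, model, seq)
                if v is None:
                    continue
                rec = predict_consequence(model, seq, v, ctx)
                if rec.protein_change is None:
                    continue
                assert rec.protein_change == oracle_consequence(model, seq, v), v.key
                checked += 1
        assert checked > 200

    def test_synonymous_iff_mutant_protein_identical(self):
        rng = np.random.default_rng(77)
        from Bio.Seq import Seq

        for _ in range(100):
            model, seq = random_gene_model(rng)
            ctx = TranscriptContext(model, seq)
            v = random_coding_variant(rng, model, seq)
            if v is None:
                continue
            rec = predict_consequence(model, seq, v, ctx)
            if rec.protein_change is None:
                continue
            from oracle import mutate_chromosome, shifted_model, biopython_translate

            mut_p, _ = biopython_translate(
                shifted_model(model, v).cds_sequence(mutate_chromosome(seq, v))
            )
            ref_p, _ = biopython_translate(model.cds_sequence(seq))
            assert (rec.protein_change.kind == "synonymous") == (mut_p == ref_p)


class TestStrandSymmetry:
    def test_mirrored_minus_strand_gene_gives_identical_protein_change(self):
        rng = np.random.default_rng(31)
        for _ in range(40):
            model, seq = random_gene_model(rng, strand="+")
            v = random_coding_variant(rng, model, seq)
            if v is None or v.is_indel:
                continue  # SNP/MNP mirrors are exact; indel anchors re-align
            L = len(seq)
            mseq = revcomp(seq)
            mirrored = type(model)(
                gene_id="mir",
                chrom=model.chrom,
                strand="-",
                span=GenomicInterval(
                    model.chrom, L - model.span.end + 1, L - model.span.start + 1
                ),
                exons=sorted(
                    (
                        GenomicInterval(model.chrom, L - e.end + 1, L - e.start + 1)
                        for e in model.exons
                    ),
                    key=lambda iv: iv.start,
                ),
                cds_start=L - model.cds_end + 1,
                cds_end=L - model.cds_start + 1,
            )
            mv = Variant(
                model.chrom, L - v.end + 1, revcomp(v.ref), revcomp(v.alt)
            )
            rec = predict_consequence(model, seq, v)
            mrec = predict_consequence(mirrored, mseq, mv)
            assert rec.protein_change == mrec.protein_change
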