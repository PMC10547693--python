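"""Independent brute-force oracle for consequence prediction.

Deliberately takes a different route from the library: the variant is
applied to the *chromosome* string, every gene-model coordinate at or past
the edit is shifted, the mutant spliced transcript is re-extracted from the
mutant chromosome with Bio.Seq machinery, and the mutant protein is
obtained by full re-translation.  Only then are reference and mutant
proteins compared end-to-end and named under the package's documented
conventions.  Shares nothing with the implementation except the standard
codon table.
"""

from __future__ import annotations

from dataclasses import replace

from Bio.Seq import Seq

from madw.gene_models import GeneModel, GenomicInterval
from madw.hgvs import ProteinChange
from madw.variant_io import Variant


def mutate_chromosome(chrom_seq: str, v: Variant) -> str:
    return chrom_seq[: v.pos - 1] + v.alt + chrom_seq[v.pos + len(v.ref) - 1 :]


def _coordinate_map(v: Variant):
    """Old-coordinate -> new-coordinate mapping for the edit.

    Handles the three shapes the random generator emits: length-preserving
    substitutions, anchored pure insertions, and anchored pure deletions.
    A deleted boundary base maps to the last surviving base at or before it.
    """
    delta = len(v.alt) - len(v.ref)
    if delta == 0:
        return lambda x: x
    if delta > 0:  # insertion after v.pos
        return lambda x: x + delta if x > v.pos else x
    deleted = set(range(v.pos + len(v.alt), v.end + 1))

    def shift(x: int) -> int:
        return x - sum(1 for d in deleted if d <= x)

    return shift


def shifted_model(model: GeneModel, v: Variant) -> GeneModel:
    """Gene model with coordinates adjusted for the indel length change."""
    s = _coordinate_map(v)
    exons = [
        GenomicInterval(iv.chrom, s(iv.start), s(iv.end)) for iv in model.exons
    ]
    return GeneModel(
        gene_id=model.gene_id,
        synonyms=list(model.synonyms),
        chrom=model.chrom,
        strand=model.strand,
        span=GenomicInterval(model.chrom, s(model.span.start), s(model.span.end)),
        exons=exons,
        cds_start=s(model.cds_start),
        cds_end=s(model.cds_end),
        exon_count=model.exon_count,
    )


def biopython_translate(seq: str) -> tuple[str, bool]:
    """Full translation with Biopython, cut at the first stop."""
    usable = seq[: len(seq) - len(seq) % 3]
    aa = str(Seq(usable).translate())
    if "*" in aa:
        return aa[: aa.index("*")], True
    return aa, False


def name_change(
    ref_p: str, ref_stop: bool, mut_p: str, mut_stop: bool, frame_preserved: bool
) -> ProteinChange:
    """Name the protein difference under the documented HGVS conventions."""
    r = ref_p + ("*" if ref_stop else "")
    m = mut_p + ("*" if mut_stop else "")
    if r == m:
        return ProteinChange("synonymous", 1)

    # maximal common prefix
    a = 0
    while a < min(len(r), len(m)) and r[a] == m[a]:
        a += 1

    if a == 0 and ref_p.startswith("M"):
        return ProteinChange("start_loss", 1, ref_aa="M")

    if not frame_preserved:
        n_real_ref = len(ref_p)
        if a >= n_real_ref:  # only the stop region differs
            alt = m[a] if a < len(m) and m[a] != "*" else ""
            return ProteinChange("stop_loss", n_real_ref + 1, ref_aa="*", alt_aa=alt)
        if a >= len(m):
            return ProteinChange("frameshift", a + 1, ref_aa=r[a], no_stop=True)
        if m[a] == "*":
            return ProteinChange("nonsense", a + 1, ref_aa=r[a])
        if not mut_stop:
            return ProteinChange(
                "frameshift", a + 1, ref_aa=r[a], alt_aa=m[a], no_stop=True
            )
        return ProteinChange(
            "frameshift",
            a + 1,
            ref_aa=r[a],
            alt_aa=m[a],
            ter_offset=len(mut_p) + 1 - a,
        )

    # in-frame: clean truncation is nonsense
    if mut_stop and len(m) < len(r) and a == len(m) - 1:
        return ProteinChange("nonsense", len(m), ref_aa=r[len(m) - 1])
    # all real residues intact: the change begins at the stop codon
    if ref_stop and a == len(ref_p):
        alt = m[a] if a < len(m) and m[a] != "*" else ""
        return ProteinChange("stop_loss", len(ref_p) + 1, ref_aa="*", alt_aa=alt)

    # maximal common suffix of the remainders
    b = 0
    while (
        b < min(len(r), len(m)) - a
        and r[len(r) - 1 - b] == m[len(m) - 1 - b]
    ):
        b += 1
    r_seg = r[a : len(r) - b]
    m_seg = m[a : len(m) - b]

    if "*" in r_seg:
        alt = m_seg[0] if m_seg and m_seg[0] != "*" else ""
        return ProteinChange("stop_loss", len(ref_p) + 1, ref_aa="*", alt_aa=alt)
    if "*" in m_seg:
        end = len(ref_p)
        return ProteinChange(
            "inframe_delins",
            a + 1,
            end=end if end != a + 1 else None,
            ref_aa=(r_seg[0] + r_seg[-1]) if len(r_seg) > 1 else r_seg,
            alt_aa=m_seg,
        )
    if m_seg == "":
        end = a + len(r_seg)
        return ProteinChange(
            "inframe_del",
            a + 1,
            end=end if end != a + 1 else None,
            ref_aa=(r_seg[0] + r_seg[-1]) if len(r_seg) > 1 else r_seg,
        )
    if r_seg == "":
        k = len(m_seg)
        if a >= k and r[a - k : a] == m_seg:
            start = a - k + 1
            return ProteinChange(
                "inframe_dup",
                start,
                end=a if a != start else None,
                ref_aa=(m_seg[0] + m_seg[-1]) if k > 1 else m_seg,
            )
        return ProteinChange(
            "inframe_ins", a, end=a + 1, ref_aa=r[a - 1] + r[a], alt_aa=m_seg
        )
    if len(r_seg) == 1 and len(m_seg) == 1:
        return ProteinChange("missense", a + 1, ref_aa=r_seg, alt_aa=m_seg)
    end = a + len(r_seg)
    return ProteinChange(
        "inframe_delins",
        a + 1,
        end=end if end != a + 1 else None,
        ref_aa=(r_seg[0] + r_seg[-1]) if len(r_seg) > 1 else r_seg,
        alt_aa=m_seg,
    )


def oracle_consequence(model: GeneModel, chrom_seq: str, v: Variant) -> ProteinChange:
    """Full re-translation oracle for a coding variant."""
    mut_chrom = mutate_chromosome(chrom_seq, v)
    mut_model = shifted_model(model, v)

    ref_ext = model.cds_sequence(chrom_seq) + model.utr3_sequence(chrom_seq)
    mut_ext = mut_model.cds_sequence(mut_chrom) + mut_model.utr3_sequence(mut_chrom)

    ref_p, ref_stop = biopython_translate(ref_ext)
    mut_p, mut_stop = biopython_translate(mut_ext)
    frame_preserved = (len(v.alt) - len(v.ref)) % 3 == 0
    pc = name_change(ref_p, ref_stop, mut_p, mut_stop, frame_preserved)
    if pc.kind == "synonymous":
        # recover the codon index from the edit site for position-labelled output
        cds_coords = []
        for p in range(v.pos, v.end + 1):
            try:
                cds_coords.append(model.genomic_to_cds(p))
            except Exception:
                continue
        if cds_coords:
            codon = (min(cds_coords) + 2) // 3
            if codon <= len(ref_p):
                return ProteinChange("synonymous", codon, ref_aa=ref_p[codon - 1])
    return pc
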