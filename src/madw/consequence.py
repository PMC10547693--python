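"""First-principles protein-consequence prediction.

Given a gene model with reference sequence and a normalized variant, the
predictor mutates the spliced transcript, re-translates, and derives the
protein-level change by comparing reference and mutant proteins (first
difference, maximal common prefix then suffix, which realizes the HGVS
3'-most placement rule at protein level).  Intronic variants get splice
labels from the position classifier; variants straddling an exon/intron
junction or hitting splice-consensus bases are labelled splice-disrupting
and receive no protein prediction, because the transcript outcome is
unknowable without a splicing model.

Conventions (documented in docs/methods.md):

* frameshift whose first shifted codon is already a stop -> nonsense;
* in-frame events whose translation terminates early are named by what the
  protein comparison shows (alt segment exactly Ter -> nonsense, otherwise
  delins ending in Ter);
* any change of the initiator codon region -> start_loss, p.(Met1?);
* changes at the stop codon (residue protein_length + 1) -> stop_loss,
  p.(Ter#XaaextTer?), extension length unevaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from Bio.Data import CodonTable

from .errors import CoordinateError, ValidationError
from .gene_models import GeneModel, PositionAnnotation, revcomp
from .hgvs import ProteinChange, format_hgvs_p
from .variant_io import Variant

# codon -> residue, standard nuclear code, '*' for stops
_table = CodonTable.unambiguous_dna_by_name["Standard"]
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"


def translate_cds(seq: str) -> tuple[str, bool]:
    """Translate a coding sequence up to (excluding) the first stop codon.

    Returns (protein, stop_found).  Trailing partial codons are ignored;
    codons with non-ACGT bases translate to 'X' with a warning.
    """
    if len(seq) < 3:
        raise ValidationError(f"coding sequence too short to translate ({len(seq)} nt)")
    seq = seq.upper()
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            warnings.warn(f"non-ACGT codon {codon!r}; translating as 'X'")
            aa = "X"
        if aa == "*":
            return "".join(out), True
        out.append(aa)
    return "".join(out), False


def apply_variant_to_cds(cds: str, cds_pos: int, ref: str, alt: str) -> str:
    """Replace cds[cds_pos .. cds_pos+len(ref)-1] with alt (1-based)."""
    if cds_pos < 1 or cds_pos + len(ref) - 1 > len(cds):
        raise CoordinateError(f"CDS position {cds_pos} (+{len(ref)}nt) out of range")
    if cds[cds_pos - 1 : cds_pos - 1 + len(ref)] != ref.upper():
        raise ValidationError(
            f"CDS ref mismatch at {cds_pos}: expected {ref!r}, "
            f"found {cds[cds_pos - 1:cds_pos - 1 + len(ref)]!r}"
        )
    return cds[: cds_pos - 1] + alt.upper() + cds[cds_pos - 1 + len(ref) :]


@dataclass
class ConsequenceRecord:
    """Predicted effect of one variant on one gene (primary transcript)."""

    variant_key: str
    gene_id: str
    annotation: PositionAnnotation
    protein_change: Optional[ProteinChange] = None
    hgvs_p: Optional[str] = None
    noncoding_label: Optional[str] = None
    # variant class bookkeeping used by downstream summaries
    is_snp: bool = True

    @property
    def label(self) -> str:
        if self.protein_change is not None:
            return self.protein_change.kind
        return self.noncoding_label or "intergenic"


# ---------------------------------------------------------------------------
# Transcript context


class TranscriptContext:
    """Cached spliced-transcript view of one gene on its reference sequence."""

    def __init__(self, model: GeneModel, chrom_seq: str):
        model._require_structure()
        self.model = model
        positions: list[int] = []
        for ex in model.exons:
            positions.extend(range(ex.start, ex.end + 1))
        seq = "".join(chrom_seq[p - 1] for p in positions).upper()
        if model.strand == "-":
            positions.reverse()
            seq = revcomp(seq)
        self.positions = positions                  # transcript order
        self.seq = seq                              # transcript orientation
        self.t_index = {p: i for i, p in enumerate(positions)}  # 0-based
        cds_genomic = model.cds_start if model.strand == "+" else model.cds_end
        self.cds_offset = self.t_index[cds_genomic]  # 0-based index of CDS base 1
        self.cds_len = model.cds_length
        self.coding_seq = self.seq[self.cds_offset : self.cds_offset + self.cds_len]
        # reference protein, translated once
        self.ref_protein, self.ref_stop = translate_cds(
            self.seq[self.cds_offset :]
        )


# ---------------------------------------------------------------------------
# Protein comparison -> ProteinChange


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def compare_proteins(
    ref_p: str,
    mut_p: str,
    ref_stop: bool,
    mut_stop: bool,
    frame_preserved: bool,
    syn_codon: Optional[int] = None,
) -> ProteinChange:
    """Derive a ProteinChange from reference and mutant protein strings.

    `syn_codon` names the codon used for a synonymous description.  The
    mutant protein must be translated from the same start as the reference,
    with translation continuing past the original stop (into the 3' UTR)
    for frameshift/stop-loss resolution.
    """
    s_r = ref_p + ("*" if ref_stop else "")
    s_m = mut_p + ("*" if mut_stop else "")
    if s_r == s_m:
        if syn_codon is not None and syn_codon <= len(ref_p):
            return ProteinChange("synonymous", syn_codon, ref_aa=ref_p[syn_codon - 1])
        # change at/after the stop codon with no protein effect: stop-retained
        return ProteinChange("synonymous", 1)

    if not frame_preserved:
        p = _common_prefix(s_r, s_m)
        if p == 0 and ref_p[:1] == "M":
            return ProteinChange("start_loss", 1, ref_aa="M")
        if p >= len(s_r) - (1 if ref_stop else 0):
            # difference only at/after the reference stop
            alt = s_m[p] if p < len(s_m) else ""
            return ProteinChange(
                "stop_loss", len(ref_p) + 1, ref_aa="*", alt_aa=alt if alt != "*" else ""
            )
        r_res = s_r[p]
        m_res = s_m[p] if p < len(s_m) else None
        if m_res is None:
            # mutant ran off the transcript end without diverging or stopping
            return ProteinChange("frameshift", p + 1, ref_aa=r_res, no_stop=True)
        if m_res == "*":
            return ProteinChange("nonsense", p + 1, ref_aa=r_res)
        if not mut_stop:
            return ProteinChange(
                "frameshift", p + 1, ref_aa=r_res, alt_aa=m_res, no_stop=True
            )
        ter = len(mut_p) + 1 - p  # stop counted with first changed residue as 1
        return ProteinChange(
            "frameshift", p + 1, ref_aa=r_res, alt_aa=m_res, ter_offset=ter
        )

    # --- in-frame ---
    a = _common_prefix(s_r, s_m)
    if a == 0 and ref_p[:1] == "M":
        return ProteinChange("start_loss", 1, ref_aa="M")
    if mut_stop and len(s_m) < len(s_r) and a == len(s_m) - 1:
        # clean truncation: mutant = ref prefix + stop
        return ProteinChange("nonsense", len(s_m), ref_aa=s_r[len(s_m) - 1])
    if ref_stop and a == len(ref_p):
        # every real residue matches, so the change starts at the stop codon;
        # the 3'-most reading of "insert before Ter" is also an extension
        alt = s_m[a] if a < len(s_m) else ""
        return ProteinChange(
            "stop_loss", len(ref_p) + 1, ref_aa="*", alt_aa=alt if alt != "*" else ""
        )
    b = _common_suffix(s_r[a:], s_m[a:])
    r_seg = s_r[a : len(s_r) - b]
    m_seg = s_m[a : len(s_m) - b]

    if "*" in r_seg:
        # the reference stop is inside the changed segment -> extension
        alt = m_seg[0] if m_seg and m_seg[0] != "*" else ""
        return ProteinChange("stop_loss", len(ref_p) + 1, ref_aa="*", alt_aa=alt)
    if "*" in m_seg:
        # early stop within a larger in-frame rearrangement
        end = len(ref_p)
        return ProteinChange(
            "inframe_delins",
            a + 1,
            end=end if end != a + 1 else None,
            ref_aa=(r_seg[0] + r_seg[-1]) if len(r_seg) > 1 else r_seg,
            alt_aa=m_seg,
        )
    if not m_seg:
        end = a + len(r_seg)
        return ProteinChange(
            "inframe_del",
            a + 1,
            end=end if end != a + 1 else None,
            ref_aa=(r_seg[0] + r_seg[-1]) if len(r_seg) > 1 else r_seg,
        )
    if not r_seg:
        k = len(m_seg)
        if a >= k and s_r[a - k : a] == m_seg:
            start = a - k + 1
            return ProteinChange(
                "inframe_dup",
                start,
                end=a if a != start else None,
                ref_aa=(m_seg[0] + m_seg[-1]) if k > 1 else m_seg,
            )
        return ProteinChange(
            "inframe_ins",
            a,
            end=a + 1,
            ref_aa=s_r[a - 1] + s_r[a],
            alt_aa=m_seg,
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


def detect_duplication(cds: str, cds_pos: int, inserted: str) -> str:
    """Classify an in-frame coding insertion as 'inframe_dup' or 'inframe_ins'.

    `cds_pos` is the CDS coordinate of the anchor base the insertion follows;
    `inserted` are the inserted bases (coding-strand).  Duplication means the
    inserted residues equal those immediately 5' of the (3'-most-placed)
    insertion point.
    """
    if len(inserted) % 3 != 0:
        raise ValidationError("detect_duplication requires an in-frame insertion")
    mutant = cds[:cds_pos] + inserted.upper() + cds[cds_pos:]
    ref_p, ref_stop = translate_cds(cds)
    mut_p, mut_stop = translate_cds(mutant)
    pc = compare_proteins(ref_p, mut_p, ref_stop, mut_stop, frame_preserved=True)
    return pc.kind if pc.kind in {"inframe_dup", "inframe_ins"} else pc.kind


# ---------------------------------------------------------------------------
# Predictor

_SPLICE_SEVERITY = ["splice_donor", "splice_acceptor", "splice_region", "intron"]


def _most_severe_intronic(annos: list[PositionAnnotation]) -> PositionAnnotation:
    return min(annos, key=lambda a: _SPLICE_SEVERITY.index(a.region))


def predict_consequence(
    model: GeneModel,
    chrom_seq: str,
    v: Variant,
    ctx: Optional[TranscriptContext] = None,
) -> ConsequenceRecord:
    """Predict the primary-transcript consequence of a normalized variant."""
    if v.chrom != model.chrom or not (
        model.span.start <= v.end and v.pos <= model.span.end
    ):
        raise CoordinateError(
            f"variant {v.key} does not overlap gene {model.gene_id}"
        )
    if chrom_seq[v.pos - 1 : v.end].upper() != v.ref:
        raise ValidationError(
            f"REF mismatch for {v.key}: reference has "
            f"{chrom_seq[v.pos - 1:v.end].upper()!r}"
        )
    if ctx is None:
        ctx = TranscriptContext(model, chrom_seq)

    # changed genomic positions (anchor base excluded for anchored indels)
    anchored = v.is_indel and v.ref[0] == v.alt[0]
    changed = list(range(v.pos + (1 if anchored else 0), v.end + 1))
    if not changed:  # pure insertion: the anchor stands in for the site
        changed = [v.pos]

    annos = [model.classify_position(p) for p in changed]
    regions = {a.region for a in annos}

    exonic_regions = {"cds", "utr5", "utr3"}
    intronic_regions = {"intron", "splice_donor", "splice_acceptor", "splice_region"}

    rec = ConsequenceRecord(
        variant_key=v.key,
        gene_id=model.gene_id,
        annotation=annos[0],
        is_snp=v.is_snp,
    )

    if regions <= intronic_regions:
        intron_ids = {a.intron_index for a in annos}
        if len(intron_ids) > 1:
            rec.noncoding_label = "splice_disrupting"
        else:
            worst = _most_severe_intronic(annos)
            rec.annotation = worst
            rec.noncoding_label = worst.region
        # pure insertion whose anchor is the intron's last base belongs to
        # the acceptor junction; classification above already reflects it.
        return rec
    if "intergenic" in regions:
        rec.noncoding_label = "splice_disrupting" if len(regions) > 1 else "intergenic"
        return rec
    if not regions <= exonic_regions:
        # exon/intron straddle
        rec.noncoding_label = "splice_disrupting"
        return rec

    # fully exonic: check transcript contiguity of the REF span
    span_positions = list(range(v.pos, v.end + 1))
    try:
        t_idx = [ctx.t_index[p] for p in span_positions]
    except KeyError:
        rec.noncoding_label = "splice_disrupting"
        return rec
    t_idx_sorted = sorted(t_idx)
    if t_idx_sorted != list(range(t_idx_sorted[0], t_idx_sorted[0] + len(t_idx))):
        rec.noncoding_label = "splice_disrupting"
        return rec

    if regions == {"utr5"}:
        rec.noncoding_label = "utr5"
        return rec
    if regions == {"utr3"}:
        rec.noncoding_label = "utr3"
        return rec

    # pure insertions live in the genomic gap after the anchor: resolve the
    # transcript insertion point and handle junction/boundary placements
    pure_ins = len(v.ref) == 1 and len(v.alt) > 1 and v.ref[0] == v.alt[0]
    if pure_ins:
        t_anchor = ctx.t_index[v.pos]
        t_next = ctx.t_index.get(v.pos + 1)
        if t_next is None or abs(t_next - t_anchor) != 1:
            # the gap sits at an exon/intron (or transcript-end) boundary
            rec.noncoding_label = "splice_disrupting"
            return rec
        ins_point = t_anchor + 1 if model.strand == "+" else t_anchor
        if ins_point <= ctx.cds_offset:
            rec.noncoding_label = "utr5"
            return rec
        if ins_point >= ctx.cds_offset + ctx.cds_len:
            rec.noncoding_label = "utr3"
            return rec

    # variant touches the CDS -> protein prediction
    t_lo = t_idx_sorted[0]
    t_ref = v.ref if model.strand == "+" else revcomp(v.ref)
    t_alt = v.alt if model.strand == "+" else revcomp(v.alt)
    if ctx.seq[t_lo : t_lo + len(t_ref)] != t_ref:
        raise ValidationError(f"transcript REF mismatch for {v.key}")
    if t_lo < ctx.cds_offset:
        # deletion/delins spanning the 5'UTR / start-codon boundary
        pc = ProteinChange("start_loss", 1, ref_aa="M")
        rec.protein_change = pc
        rec.hgvs_p = format_hgvs_p(pc)
        return rec

    mutant = ctx.seq[:t_lo] + t_alt + ctx.seq[t_lo + len(t_ref) :]
    mut_p, mut_stop = translate_cds(mutant[ctx.cds_offset :])
    frame_preserved = (len(t_alt) - len(t_ref)) % 3 == 0
    first_cds = t_lo - ctx.cds_offset + 1  # 1-based CDS coord of first REF-span base
    syn_codon = (first_cds + 2) // 3
    pc = compare_proteins(
        ctx.ref_protein, mut_p, ctx.ref_stop, mut_stop, frame_preserved, syn_codon
    )
    rec.protein_change = pc
    rec.hgvs_p = format_hgvs_p(pc)
    return rec


def consequence_table(records: list[ConsequenceRecord]) -> "pd.DataFrame":
    """Flatten ConsequenceRecords to the TSV-ready consequence table."""
    import pandas as pd

    rows = []
    for r in records:
        pc = r.protein_change
        rows.append(
            {
                "variant_id": r.variant_key,
                "gene_id": r.gene_id,
                "region": r.annotation.region,
                "kind": r.label,
                "hgvs_p": r.hgvs_p or "",
                "protein_position": pc.start if pc else "",
                "ter_offset": pc.ter_offset if pc and pc.ter_offset else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "gene_id",
            "region",
            "kind",
            "hgvs_p",
            "protein_position",
            "ter_offset",
        ],
    )
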