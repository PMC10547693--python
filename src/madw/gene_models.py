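"""Candidate-gene structures and coordinate arithmetic.

A :class:`GeneModel` holds the genomic span, strand, exon structure and CDS
geometry of one locus (primary transcript only).  All coordinates, external
and internal, are 1-based inclusive — the GFF3/VCF convention — so a
single-base feature has ``start == end``.

Splice-site geometry follows the windows used for the sorghum maturity/dwarf
screen: intron offsets +1/+2 are the donor consensus, -1/-2 the acceptor
consensus, and the flanking windows +3..+5 (donor side) and -3..-10
(acceptor side) are the splice region, where variants may perturb splicing
without hitting the GT/AG dinucleotides.  Offsets are counted on the coding
strand: +k is the k-th intronic base from the intron's 5' end, -k the k-th
base from its 3' end.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .errors import CoordinateError, ParseError, ValidationError

DONOR_CONSENSUS = (1, 2)
DONOR_REGION = (3, 5)          # inclusive window, donor side
ACCEPTOR_CONSENSUS = (1, 2)    # -1, -2
ACCEPTOR_REGION = (3, 10)      # -3 .. -10

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"interval start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValidationError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class PositionAnnotation:
    """Region call for a single genomic position relative to one gene model."""

    region: str  # cds | utr5 | utr3 | intron | splice_donor | splice_acceptor | splice_region | intergenic
    exon_index: Optional[int] = None     # 1-based, transcript order
    intron_index: Optional[int] = None   # 1-based, transcript order
    intron_offset: Optional[int] = None  # +k from intron 5' end, -k from 3' end
    cds_position: Optional[int] = None   # 1-based CDS coordinate


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    span: GenomicInterval
    synonyms: list[str] = field(default_factory=list)
    exons: Optional[list[GenomicInterval]] = None  # genomic order; None = unavailable
    cds_start: Optional[int] = None  # genomic, lower coordinate of the CDS
    cds_end: Optional[int] = None    # genomic, higher coordinate of the CDS
    transcript_length: Optional[int] = None
    protein_length: Optional[int] = None
    exon_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ParseError(
                f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.exons is not None:
            if self.exon_count is None:
                self.exon_count = len(self.exons)
            elif self.exon_count != len(self.exons):
                raise ValidationError(
                    f"{self.gene_id}: exon_count {self.exon_count} != "
                    f"{len(self.exons)} exon intervals"
                )
            prev_end = None
            for ex in self.exons:
                if ex.chrom != self.chrom:
                    raise ValidationError(f"{self.gene_id}: exon on wrong chromosome")
                if not (self.span.start <= ex.start and ex.end <= self.span.end):
                    raise ValidationError(f"{self.gene_id}: exon outside gene span")
                if prev_end is not None and ex.start <= prev_end:
                    raise ValidationError(
                        f"{self.gene_id}: exons overlap or are unsorted"
                    )
                prev_end = ex.end
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError(f"{self.gene_id}: partial CDS boundaries")
        if self.cds_start is not None and self.cds_start > self.cds_end:
            raise ValidationError(f"{self.gene_id}: cds_start > cds_end")

    # -- structural helpers -------------------------------------------------

    @property
    def has_structure(self) -> bool:
        """True when exon intervals and CDS boundaries are available."""
        return self.exons is not None and self.cds_start is not None

    def _require_structure(self) -> None:
        if not self.has_structure:
            raise CoordinateError(
                f"{self.gene_id}: exon structure unavailable (metadata-only model); "
                "sequence-level operations need a GFF3 gene model"
            )

    @property
    def introns(self) -> list[GenomicInterval]:
        self._require_structure()
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end + 1:
                out.append(GenomicInterval(self.chrom, a.end + 1, b.start - 1))
        return out

    @property
    def coding_intervals(self) -> list[GenomicInterval]:
        """Exon pieces clipped to [cds_start, cds_end], genomic order."""
        self._require_structure()
        out = []
        for ex in self.exons:
            s, e = max(ex.start, self.cds_start), min(ex.end, self.cds_end)
            if s <= e:
                out.append(GenomicInterval(self.chrom, s, e))
        return out

    @property
    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.coding_intervals)

    # -- coordinate mapping -------------------------------------------------

    def genomic_to_cds(self, pos: int) -> int:
        """1-based CDS coordinate of a coding genomic position.

        On the + strand coding bases are counted upward from ``cds_start``;
        on the - strand downward from ``cds_end`` (reverse-complement
        orientation).
        """
        self._require_structure()
        ivs = self.coding_intervals
        total = 0
        if self.strand == "+":
            for iv in ivs:
                if iv.contains(pos):
                    return total + pos - iv.start + 1
                if iv.end < pos:
                    total += len(iv)
        else:
            for iv in reversed(ivs):
                if iv.contains(pos):
                    return total + iv.end - pos + 1
                if iv.start > pos:
                    total += len(iv)
        raise CoordinateError(
            f"{self.gene_id}: genomic position {pos} is not a coding base"
        )

    def cds_to_genomic(self, cds_pos: int) -> int:
        if cds_pos < 1:
            raise CoordinateError(f"CDS position must be >= 1, got {cds_pos}")
        self._require_structure()
        remaining = cds_pos
        ivs = self.coding_intervals
        order = ivs if self.strand == "+" else list(reversed(ivs))
        for iv in order:
            if remaining <= len(iv):
                if self.strand == "+":
                    return iv.start + remaining - 1
                return iv.end - remaining + 1
            remaining -= len(iv)
        raise CoordinateError(
            f"{self.gene_id}: CDS position {cds_pos} exceeds CDS length {self.cds_length}"
        )

    def is_coding(self, pos: int) -> bool:
        return any(iv.contains(pos) for iv in self.coding_intervals)

    # -- region classification ----------------------------------------------

    def classify_position(self, pos: int) -> PositionAnnotation:
        """Assign a genomic position to exactly one gene region.

        Donor consensus (+1/+2) takes precedence over acceptor windows when
        an intron is too short for both sets of windows to be disjoint.
        """
        self._require_structure()
        if not self.span.contains(pos):
            return PositionAnnotation(region="intergenic")

        n_exons = len(self.exons)
        for gi, ex in enumerate(self.exons):
            if ex.contains(pos):
                tx_index = gi + 1 if self.strand == "+" else n_exons - gi
                if self.is_coding(pos):
                    return PositionAnnotation(
                        region="cds",
                        exon_index=tx_index,
                        cds_position=self.genomic_to_cds(pos),
                    )
                before_cds = pos < self.cds_start
                if self.strand == "+":
                    region = "utr5" if before_cds else "utr3"
                else:
                    region = "utr3" if before_cds else "utr5"
                return PositionAnnotation(region=region, exon_index=tx_index)

        introns = self.introns
        n_introns = len(introns)
        for gi, intron in enumerate(introns):
            if not intron.contains(pos):
                continue
            tx_index = gi + 1 if self.strand == "+" else n_introns - gi
            length = len(intron)
            if self.strand == "+":
                d5 = pos - intron.start + 1
            else:
                d5 = intron.end - pos + 1
            d3 = -(length - d5 + 1)  # negative offset from the intron 3' end
            if d5 <= DONOR_CONSENSUS[1]:
                region, offset = "splice_donor", d5
            elif d5 <= DONOR_REGION[1]:
                region, offset = "splice_region", d5
            elif -d3 <= ACCEPTOR_CONSENSUS[1]:
                region, offset = "splice_acceptor", d3
            elif -d3 <= ACCEPTOR_REGION[1]:
                region, offset = "splice_region", d3
            else:
                region = "intron"
                offset = d5 if d5 <= -d3 else d3
            return PositionAnnotation(
                region=region, intron_index=tx_index, intron_offset=offset
            )
        # within span but in no exon/intron: only possible with a malformed model
        raise CoordinateError(f"{self.gene_id}: position {pos} unclassifiable")

    # -- sequence extraction --------------------------------------------------

    def cds_sequence(self, chrom_seq: str) -> str:
        """Coding sequence (incl. stop codon), coding-strand orientation."""
        self._require_structure()
        parts = [chrom_seq[iv.start - 1 : iv.end] for iv in self.coding_intervals]
        seq = "".join(parts).upper()
        return revcomp(seq) if self.strand == "-" else seq

    def utr3_sequence(self, chrom_seq: str) -> str:
        """Spliced exonic sequence 3' of the stop codon (transcript orientation)."""
        self._require_structure()
        parts = []
        for ex in self.exons:
            if self.strand == "+":
                s, e = max(ex.start, self.cds_end + 1), ex.end
            else:
                s, e = ex.start, min(ex.end, self.cds_start - 1)
            if s <= e:
                parts.append(chrom_seq[s - 1 : e])
        seq = "".join(parts).upper()
        return revcomp(seq) if self.strand == "-" else seq

    def validate_against_sequence(self, chrom_seq: str) -> None:
        """Check CDS length consistency: 3 * (protein_length + 1), divisible by 3."""
        n = self.cds_length
        if n % 3 != 0:
            raise ValidationError(f"{self.gene_id}: CDS length {n} not divisible by 3")
        if self.protein_length is not None and n != 3 * (self.protein_length + 1):
            raise ValidationError(
                f"{self.gene_id}: CDS length {n} != 3*(protein_length+1) "
                f"= {3 * (self.protein_length + 1)}"
            )


def cds_to_protein(cds_pos: int) -> tuple[int, int]:
    """Map a CDS coordinate to (residue index, within-codon offset), both 1-based."""
    if cds_pos < 1:
        raise CoordinateError(f"CDS position must be >= 1, got {cds_pos}")
    return math.ceil(cds_pos / 3), (cds_pos - 1) % 3 + 1


# ---------------------------------------------------------------------------
# Loading


_TSV_COLUMNS = [
    "gene_id",
    "synonyms",
    "chrom",
    "strand",
    "span_start",
    "span_end",
    "transcript_length",
    "protein_length",
    "exon_count",
]


def _load_tsv(lines: Iterable[str], source: str) -> dict[str, GeneModel]:
    rows = [ln.rstrip("\n") for ln in lines if ln.strip() and not ln.startswith("#")]
    if not rows:
        return {}
    header = rows[0].split("\t")
    if header != _TSV_COLUMNS:
        raise ParseError(f"{source}: unexpected TSV header {header}")
    models: dict[str, GeneModel] = {}
    for ln in rows[1:]:
        f = ln.split("\t")
        if len(f) != len(_TSV_COLUMNS):
            raise ParseError(f"{source}: bad field count in record {f[0] if f else ln!r}")
        try:
            span = GenomicInterval(f[2], int(f[4]), int(f[5]))
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{source}: bad coordinates in record {f[0]}: {exc}") from exc
        model = GeneModel(
            gene_id=f[0],
            synonyms=[s for s in f[1].split(",") if s],
            chrom=f[2],
            strand=f[3],
            span=span,
            transcript_length=int(f[6]),
            protein_length=int(f[7]),
            exon_count=int(f[8]),
        )
        models[model.gene_id] = model
    return models


_GFF_ATTR = re.compile(r"([^;=]+)=([^;]*)")


def _gff_attrs(field9: str) -> dict[str, str]:
    return {m.group(1).strip(): m.group(2).strip() for m in _GFF_ATTR.finditer(field9)}


def _load_gff3(lines: Iterable[str], source: str) -> dict[str, GeneModel]:
    """Parse the gene/mRNA/exon/CDS subset of GFF3 (primary transcript = first
    mRNA of each gene, or the only one)."""
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    mrnas: dict[str, dict] = {}
    for i, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ParseError(f"{source}:{i}: expected 9 GFF3 columns, got {len(f)}")
        chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = f
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"{source}:{i}: non-integer coordinates") from exc
        if start < 1 or start > end:
            raise ParseError(f"{source}:{i}: bad interval {start}-{end}")
        attrs = _gff_attrs(attrs_s)
        if ftype == "gene":
            gid = attrs.get("ID")
            if not gid:
                raise ParseError(f"{source}:{i}: gene record without ID")
            if strand not in {"+", "-"}:
                raise ParseError(f"{source}:{i}: record {gid}: bad strand {strand!r}")
            genes[gid] = {
                "chrom": chrom,
                "strand": strand,
                "start": start,
                "end": end,
                "name": attrs.get("Name", gid),
                "mrnas": [],
            }
        elif ftype == "mRNA":
            mid, parent = attrs.get("ID"), attrs.get("Parent")
            if not mid or not parent:
                raise ParseError(f"{source}:{i}: mRNA needs ID and Parent")
            if strand not in {"+", "-"}:
                raise ParseError(f"{source}:{i}: record {mid}: bad strand {strand!r}")
            mrna_to_gene[mid] = parent
            mrnas[mid] = {"exons": [], "cds": []}
            if parent in genes:
                genes[parent]["mrnas"].append(mid)
        elif ftype in {"exon", "CDS"}:
            parent = attrs.get("Parent")
            if not parent or parent not in mrnas:
                raise ParseError(f"{source}:{i}: {ftype} with unknown Parent")
            key = "exons" if ftype == "exon" else "cds"
            mrnas[parent][key].append((chrom, start, end))

    models: dict[str, GeneModel] = {}
    for gid, g in genes.items():
        if not g["mrnas"]:
            continue
        mid = sorted(g["mrnas"])[0]  # primary transcript
        m = mrnas[mid]
        if not m["exons"]:
            raise ParseError(f"{source}: mRNA {mid} has no exons")
        exons = sorted(
            (GenomicInterval(c, s, e) for c, s, e in m["exons"]),
            key=lambda iv: iv.start,
        )
        cds_start = min(s for _c, s, _e in m["cds"]) if m["cds"] else None
        cds_end = max(e for _c, _s, e in m["cds"]) if m["cds"] else None
        name = g["name"]
        tx_len = sum(len(iv) for iv in exons)
        model = GeneModel(
            gene_id=name,
            synonyms=[gid] if gid != name else [],
            chrom=g["chrom"],
            strand=g["strand"],
            span=GenomicInterval(g["chrom"], g["start"], g["end"]),
            exons=exons,
            cds_start=cds_start,
            cds_end=cds_end,
            transcript_length=tx_len,
            protein_length=(
                sum(e - s + 1 for _c, s, e in m["cds"]) // 3 - 1 if m["cds"] else None
            ),
            exon_count=len(exons),
        )
        models[model.gene_id] = model
    return models


def load_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Load gene models from GFF3 or the fixture TSV dialect.

    Format is detected from content: a line starting with ``##gff`` or a
    9-column tab layout is GFF3, a ``gene_id`` header is the TSV dialect.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    stripped = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not stripped:
        return {}
    if stripped[0].split("\t")[0] == "gene_id":
        return _load_tsv(lines, str(path))
    return _load_gff3(lines, str(path))


def table1_fixture() -> dict[str, GeneModel]:
    """The eight characterized sorghum Maturity/Dwarf loci.

    Metadata only: genomic span, strand, transcript/protein length and exon
    count.  Exon boundaries are not part of the published table, so these
    models are not usable for sequence-level operations; supply a GFF3 +
    FASTA for that.
    """
    ref = resources.files("madw.data").joinpath("table1_loci.tsv")
    return _load_tsv(ref.read_text().splitlines(), "table1_loci.tsv")
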