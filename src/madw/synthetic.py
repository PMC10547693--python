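"""Synthetic references, panels and phenotypes with known ground truth.

The generator emulates the structure of a resequenced inbred sorghum
germplasm panel at the eight Maturity/Dwarf loci: synthetic chromosomes
carrying one gene each (real protein lengths, exon counts and strands;
invented exon boundaries and sequence), catalog alleles planted as concrete
variants at configurable frequencies, novel deleterious and neutral
variants, optional genotype missingness and heterozygosity, SIFT-like
scores concordant with the planted categories, and additive phenotypes with
Gaussian noise.  A :class:`TruthManifest` records everything so every
pipeline stage can be recovery-tested without downloads.

Inbred-line genotype model: an accession is homozygous for at most one
planted allele per locus (het carriers are a separate dial, not
Hardy-Weinberg), reflecting how heterozygotes are exceptional in such
panels.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import textwrap
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .catalog import AlleleDefinition, VariantMatcher, builtin_catalog, catalog_to_json
from .classify import SIFT_THRESHOLD, ScoreRecord
from .consequence import (
    CODON_TO_AA,
    ConsequenceRecord,
    TranscriptContext,
    predict_consequence,
)
from .errors import ValidationError
from .gene_models import GeneModel, GenomicInterval, revcomp, table1_fixture
from .hgvs import ProteinChange, parse_hgvs_p
from .variant_io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, Variant, normalize_variant

AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)
_NONSTOP_CODONS = sorted(c for c, a in CODON_TO_AA.items() if a != "*")
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic panel.

    Defaults emulate the screen's desk-scale recovery conditions: a
    500-accession inbred panel over the eight loci, catalog alleles planted
    at frequencies between 0.05 and 0.5 per locus, a small supply of novel
    deleterious and neutral variants, and no missingness or heterozygosity
    unless dialed in.
    """

    seed: int
    n_accessions: int = 500
    allele_frequencies: Optional[dict[str, float]] = None  # allele name -> freq
    novel_deleterious_rate: float = 0.02   # per locus, fraction of panel
    neutral_variants_per_locus: int = 3
    novel_deleterious_per_locus: int = 1
    genotype_missingness: float = 0.0
    het_rate: float = 0.0                  # fraction of carriers that are het
    utr5_length: int = 90
    utr3_length: int = 240
    intron_length_range: tuple[int, int] = (80, 200)
    flank: int = 2000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("simulation seed is mandatory")
        for name, rate in (
            ("novel_deleterious_rate", self.novel_deleterious_rate),
            ("genotype_missingness", self.genotype_missingness),
            ("het_rate", self.het_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {rate}")
        if self.n_accessions < 1:
            raise ValidationError("panel size must be >= 1")
        lo, hi = self.intron_length_range
        if lo < 15 or hi < lo:
            raise ValidationError("intron lengths must be >= 15 and ordered")


_DEFAULT_FREQ_LADDER = [0.30, 0.15, 0.10, 0.05, 0.05, 0.05, 0.05]


def default_allele_frequencies(catalog: Iterable[AlleleDefinition]) -> dict[str, float]:
    """Per-allele planting frequencies in [0.05, 0.5], ladder per locus."""
    by_locus: dict[str, list[AlleleDefinition]] = {}
    for d in catalog:
        if d.matchable:
            by_locus.setdefault(d.locus, []).append(d)
    freqs = {}
    for locus in sorted(by_locus):
        for i, d in enumerate(sorted(by_locus[locus], key=lambda x: x.name)):
            freqs[d.name] = _DEFAULT_FREQ_LADDER[min(i, len(_DEFAULT_FREQ_LADDER) - 1)]
    return freqs


# ---------------------------------------------------------------------------
# Truth manifest


@dataclass
class TruthManifest:
    """Ground truth for one simulated panel (JSON-serializable)."""

    variants: dict[str, dict] = field(default_factory=dict)
    # accession -> locus -> {"status": ..., "allele": ...}
    locus_status: dict[str, dict[str, dict]] = field(default_factory=dict)
    phenotype_expectation: dict[str, float] = field(default_factory=dict)
    masked: list[list] = field(default_factory=list)  # [accession, variant_key]

    def to_json(self) -> str:
        return json.dumps(
            {
                "variants": self.variants,
                "locus_status": self.locus_status,
                "phenotype_expectation": self.phenotype_expectation,
                "masked": self.masked,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        d = json.loads(text)
        return cls(
            variants=d["variants"],
            locus_status=d["locus_status"],
            phenotype_expectation=d.get("phenotype_expectation", {}),
            masked=d.get("masked", []),
        )


# ---------------------------------------------------------------------------
# Codon planning


def codon_for_transition(ref_aa: str, alt_aa: str, rng: np.random.Generator) -> str:
    """A codon for `ref_aa` from which some codon of `alt_aa` is reachable
    with the fewest base changes (preferring a single SNP)."""
    best, best_d = None, 4
    for c_ref in AA_TO_CODONS[ref_aa]:
        for c_alt in AA_TO_CODONS[alt_aa]:
            d = sum(1 for x, y in zip(c_ref, c_alt) if x != y)
            if d < best_d:
                best, best_d = c_ref, d
    return best


def minimal_codon_edit(codon: str, alt_aa: str) -> str:
    """The codon of `alt_aa` closest (Hamming) to `codon`."""
    return min(
        AA_TO_CODONS[alt_aa],
        key=lambda c: (sum(1 for x, y in zip(codon, c) if x != y), c),
    )


# ---------------------------------------------------------------------------
# Gene assembly


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _random_nonstop_codons(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n)
    return [_NONSTOP_CODONS[i] for i in idx]


def build_cds(
    rng: np.random.Generator,
    protein_length: int,
    required_codons: Optional[Mapping[int, str]] = None,
    forbidden_aa: Optional[Mapping[int, str]] = None,
) -> str:
    """A CDS: ATG, `protein_length` - 1 random non-stop codons with required
    overrides, and a TAA stop.  `forbidden_aa` prevents residue repeats that
    would shift dup placements."""
    required_codons = dict(required_codons or {})
    forbidden_aa = dict(forbidden_aa or {})
    codons = ["ATG"] + _random_nonstop_codons(rng, protein_length - 1) + ["TAA"]
    for pos, codon in required_codons.items():
        if pos == 1 and CODON_TO_AA[codon] != "M":
            raise ValidationError("codon 1 must encode Met")
        if not 1 <= pos <= protein_length:
            raise ValidationError(
                f"required codon position {pos} exceeds protein length {protein_length}"
            )
        codons[pos - 1] = codon
    for pos, aa in forbidden_aa.items():
        if 1 <= pos <= protein_length and pos not in required_codons:
            while CODON_TO_AA[codons[pos - 1]] == aa:
                codons[pos - 1] = _random_nonstop_codons(rng, 1)[0]
    return "".join(codons)


@dataclass
class _GeneLayout:
    model: GeneModel
    chrom_seq: str


def assemble_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    cds: str,
    rng: np.random.Generator,
    exon_count: int,
    utr5_length: int = 90,
    utr3_length: int = 240,
    intron_length_range: tuple[int, int] = (80, 200),
    flank: int = 2000,
    keepout_codons: Iterable[int] = (),
    synonyms: Optional[list[str]] = None,
) -> _GeneLayout:
    """Place a CDS with UTRs and GT..AG introns on a fresh chromosome.

    Intron insertion points avoid +-4 nt around `keepout_codons` (1-based
    residue indices) so planted edits stay within contiguous coding
    sequence.  Returns the gene model plus the chromosome sequence.
    """
    transcript = _random_seq(rng, utr5_length) + cds + _random_seq(rng, utr3_length)
    t_len = len(transcript)
    keepout: set[int] = set()
    for res in keepout_codons:
        lo = utr5_length + 3 * (res - 1) - 4
        hi = utr5_length + 3 * res + 4
        keepout.update(range(max(1, lo), hi + 1))
    # candidate cut points: after transcript position i (1-based), away from ends
    candidates = [
        i for i in range(20, t_len - 20) if i not in keepout
    ]
    n_introns = exon_count - 1
    if n_introns > 0:
        if len(candidates) < n_introns:
            raise ValidationError(f"{gene_id}: cannot place {n_introns} introns")
        cuts = sorted(rng.choice(candidates, size=n_introns, replace=False).tolist())
        # enforce a minimum exon width of 10 nt
        ok = all(b - a >= 10 for a, b in zip(cuts, cuts[1:]))
        attempts = 0
        while not ok and attempts < 100:
            cuts = sorted(rng.choice(candidates, size=n_introns, replace=False).tolist())
            ok = all(b - a >= 10 for a, b in zip(cuts, cuts[1:]))
            attempts += 1
        if not ok:
            raise ValidationError(f"{gene_id}: cannot satisfy exon width constraints")
    else:
        cuts = []

    lo, hi = intron_length_range
    intron_lens = [int(rng.integers(lo, hi + 1)) for _ in cuts]
    introns = [
        "GT" + _random_seq(rng, L - 4) + "AG" for L in intron_lens
    ]

    # assemble the coding-strand gene sequence and record exon spans (local,
    # 1-based on the coding strand)
    pieces = []
    exon_local: list[tuple[int, int]] = []
    prev = 0
    offset = 0
    for cut, intron in zip(cuts, introns):
        pieces.append(transcript[prev:cut])
        exon_local.append((offset + prev + 1, offset + cut))
        pieces.append(intron)
        offset += len(intron)
        prev = cut
    pieces.append(transcript[prev:])
    exon_local.append((offset + prev + 1, offset + t_len))
    gene_seq = "".join(pieces)
    glen = len(gene_seq)

    # transcript position of CDS bounds -> local gene coords
    def local_of_transcript(tpos: int) -> int:
        shift = 0
        for cut, L in zip(cuts, intron_lens):
            if tpos > cut:
                shift += L
        return tpos + shift

    cds_lo_local = local_of_transcript(utr5_length + 1)
    cds_hi_local = local_of_transcript(utr5_length + len(cds))

    start = flank + 1
    if strand == "+":
        chrom_seq = _random_seq(rng, flank) + gene_seq + _random_seq(rng, flank)
        exons = [
            GenomicInterval(chrom, start + a - 1, start + b - 1) for a, b in exon_local
        ]
        cds_start = start + cds_lo_local - 1
        cds_end = start + cds_hi_local - 1
    else:
        chrom_seq = _random_seq(rng, flank) + revcomp(gene_seq) + _random_seq(rng, flank)
        # local coding-strand coordinate i maps to genomic start + glen - i
        exons = [
            GenomicInterval(chrom, start + glen - b, start + glen - a)
            for a, b in exon_local
        ]
        exons.sort(key=lambda iv: iv.start)
        cds_start = start + glen - cds_hi_local
        cds_end = start + glen - cds_lo_local

    model = GeneModel(
        gene_id=gene_id,
        synonyms=synonyms or [],
        chrom=chrom,
        strand=strand,
        span=GenomicInterval(chrom, start, start + glen - 1),
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        transcript_length=t_len,
        protein_length=len(cds) // 3 - 1,
        exon_count=len(exons),
    )
    model.validate_against_sequence(chrom_seq)
    return _GeneLayout(model, chrom_seq)


def random_gene_model(
    rng: np.random.Generator,
    chrom: str = "chrT",
    protein_length: Optional[int] = None,
    exon_count: Optional[int] = None,
    strand: Optional[str] = None,
) -> tuple[GeneModel, str]:
    """A small random gene for property/oracle testing (both strands)."""
    if protein_length is None:
        protein_length = int(rng.integers(30, 90))
    if exon_count is None:
        exon_count = int(rng.integers(1, 4))
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    cds = build_cds(rng, protein_length)
    layout = assemble_gene(
        gene_id=f"g_{chrom}",
        chrom=chrom,
        strand=strand,
        cds=cds,
        rng=rng,
        exon_count=exon_count,
        utr5_length=int(rng.integers(20, 60)),
        utr3_length=int(rng.integers(120, 240)),
        intron_length_range=(30, 80),
        flank=100,
    )
    return layout.model, layout.chrom_seq


# ---------------------------------------------------------------------------
# Variant planting


@dataclass
class PlantTarget:
    """What to plant: a protein-level change or a region label."""

    protein_change: Optional[ProteinChange] = None
    region: Optional[str] = None           # intron | splice_region | splice_donor | splice_acceptor
    intron_index: Optional[int] = None     # 1-based, transcript order
    intron_offset: Optional[int] = None    # signed, as in PositionAnnotation
    insertion: Optional[str] = None        # explicit inserted bases
    insertion_length: Optional[int] = None # random insertion of this length


def _genomic_replace(
    model: GeneModel,
    chrom_seq: str,
    cds_lo: int,
    cds_hi: int,
    alt_coding: str,
) -> Variant:
    """Realize 'replace CDS[lo..hi] with alt_coding' as a genomic Variant."""
    gpos = [model.cds_to_genomic(c) for c in range(cds_lo, cds_hi + 1)]
    step = -1 if model.strand == "-" else 1
    for a, b in zip(gpos, gpos[1:]):
        if b - a != step:
            raise ValidationError(
                f"{model.gene_id}: CDS {cds_lo}..{cds_hi} not genomically contiguous"
            )
    glo, ghi = min(gpos), max(gpos)
    ref = chrom_seq[glo - 1 : ghi].upper()
    alt = alt_coding.upper() if model.strand == "+" else revcomp(alt_coding.upper())
    if alt and ref != alt:
        v = Variant(model.chrom, glo, ref, alt)
    elif not alt:
        # pure deletion: anchor on the preceding genomic base
        anchor = chrom_seq[glo - 2].upper()
        v = Variant(model.chrom, glo - 1, anchor + ref, anchor)
    else:
        raise ValidationError("replacement equals reference")
    return normalize_variant(v, chrom_seq)


def _genomic_insert_after(
    model: GeneModel, chrom_seq: str, cds_pos: int, inserted_coding: str
) -> Variant:
    """Insert coding-strand bases between CDS positions cds_pos and cds_pos+1."""
    if model.strand == "+":
        g = model.cds_to_genomic(cds_pos)
        alt = chrom_seq[g - 1].upper() + inserted_coding.upper()
    else:
        g = model.cds_to_genomic(cds_pos + 1)
        alt = chrom_seq[g - 1].upper() + revcomp(inserted_coding.upper())
    v = Variant(model.chrom, g, chrom_seq[g - 1].upper(), alt)
    return normalize_variant(v, chrom_seq)


def _intron_position(model: GeneModel, intron_index: int, offset: int) -> int:
    introns = model.introns
    n = len(introns)
    if not 1 <= intron_index <= n:
        raise ValidationError(f"{model.gene_id}: no intron {intron_index}")
    gi = intron_index - 1 if model.strand == "+" else n - intron_index
    intron = introns[gi]
    L = len(intron)
    if offset > 0:
        d5 = offset
    else:
        d5 = L + offset + 1
    if not 1 <= d5 <= L:
        raise ValidationError(f"intron offset {offset} outside intron of length {L}")
    if model.strand == "+":
        return intron.start + d5 - 1
    return intron.end - d5 + 1


class PlantError(ValidationError):
    """The requested target cannot be realized on this model."""


def plant_variant(
    model: GeneModel,
    chrom_seq: str,
    target: PlantTarget,
    rng: np.random.Generator,
    ctx: Optional[TranscriptContext] = None,
) -> tuple[Variant, ConsequenceRecord]:
    """Plant a variant achieving `target`; returns it with its predicted
    consequence (self-consistency is verified)."""
    if ctx is None:
        ctx = TranscriptContext(model, chrom_seq)
    pc = target.protein_change

    if pc is not None:
        protein = ctx.ref_protein
        if pc.start > len(protein) + (1 if pc.kind == "stop_loss" else 0):
            raise PlantError(
                f"{model.gene_id}: residue {pc.start} exceeds protein length "
                f"{len(protein)}"
            )
        if pc.kind in {"missense", "nonsense", "synonymous"}:
            codon = ctx.coding_seq[3 * pc.start - 3 : 3 * pc.start]
            if pc.ref_aa and protein[pc.start - 1] != pc.ref_aa[0]:
                raise PlantError(
                    f"{model.gene_id}: residue {pc.start} is "
                    f"{protein[pc.start - 1]}, target expects {pc.ref_aa}"
                )
            if pc.kind == "missense":
                new = minimal_codon_edit(codon, pc.alt_aa)
            elif pc.kind == "nonsense":
                new = minimal_codon_edit(codon, "*")
            else:
                choices = [c for c in AA_TO_CODONS[CODON_TO_AA[codon]] if c != codon]
                if not choices:
                    raise PlantError(f"no synonymous codon for {codon}")
                new = min(
                    choices,
                    key=lambda c: (sum(1 for x, y in zip(codon, c) if x != y), c),
                )
            # restrict the edit to the changed bases
            lo = next(i for i in range(3) if codon[i] != new[i])
            hi = next(i for i in reversed(range(3)) if codon[i] != new[i])
            v = _genomic_replace(
                model,
                chrom_seq,
                3 * (pc.start - 1) + lo + 1,
                3 * (pc.start - 1) + hi + 1,
                new[lo : hi + 1],
            )
            expect_kind = pc.kind
        elif pc.kind == "frameshift":
            ins = target.insertion
            v = None
            if ins:
                v = _genomic_insert_after(model, chrom_seq, 3 * pc.start - 1, ins)
            else:
                for off in (0, 1, 2):
                    cpos = 3 * (pc.start - 1) + 1 + off
                    cand = _genomic_replace(model, chrom_seq, cpos, cpos, "")
                    rec = predict_consequence(model, chrom_seq, cand, ctx)
                    if rec.protein_change is not None and rec.protein_change.kind == "frameshift":
                        v = cand
                        break
                if v is None:
                    raise PlantError(
                        f"{model.gene_id}: cannot realize frameshift at {pc.start}"
                    )
            expect_kind = "frameshift"
        elif pc.kind == "inframe_dup":
            codon = ctx.coding_seq[3 * pc.start - 3 : 3 * pc.start]
            if pc.ref_aa and protein[pc.start - 1] != pc.ref_aa[0]:
                raise PlantError(
                    f"{model.gene_id}: residue {pc.start} is {protein[pc.start - 1]}"
                )
            v = _genomic_insert_after(model, chrom_seq, 3 * pc.start, codon)
            expect_kind = "inframe_dup"
        elif pc.kind == "inframe_del":
            end = pc.end or pc.start
            v = _genomic_replace(model, chrom_seq, 3 * (pc.start - 1) + 1, 3 * end, "")
            expect_kind = "inframe_del"
        else:
            raise PlantError(f"cannot plant target kind {pc.kind!r}")
        rec = predict_consequence(model, chrom_seq, v, ctx)
        got = rec.protein_change
        if got is None or got.kind != expect_kind:
            raise PlantError(
                f"{model.gene_id}: planted variant produced "
                f"{rec.label!r}, wanted {expect_kind!r}"
            )
        if pc.kind in {"missense", "nonsense", "synonymous"} and got.start != pc.start:
            raise PlantError(
                f"{model.gene_id}: planted {pc.kind} landed at residue "
                f"{got.start}, wanted {pc.start}"
            )
        return v, rec

    # region targets
    if target.region is None:
        raise PlantError("target needs a protein change or a region")
    if target.intron_index is None or target.intron_offset is None:
        raise PlantError("region targets need intron_index and intron_offset")
    gpos = _intron_position(model, target.intron_index, target.intron_offset)
    if target.insertion or target.insertion_length:
        ins = target.insertion or _random_seq(rng, target.insertion_length)
        anchor = chrom_seq[gpos - 1].upper()
        v = Variant(model.chrom, gpos, anchor, anchor + ins)
    else:
        old = chrom_seq[gpos - 1].upper()
        new = _BASES[(_BASES.index(old) + 1 + int(rng.integers(0, 3))) % 4]
        v = Variant(model.chrom, gpos, old, new)
    v = normalize_variant(v, chrom_seq)
    rec = predict_consequence(model, chrom_seq, v, ctx)
    if rec.noncoding_label != target.region:
        raise PlantError(
            f"{model.gene_id}: region target {target.region} produced "
            f"{rec.noncoding_label}"
        )
    return v, rec


# ---------------------------------------------------------------------------
# Reference simulation for the eight loci


def _required_codons_for_locus(
    defs: list[AlleleDefinition], rng: np.random.Generator
) -> tuple[dict[int, str], dict[int, str]]:
    """Plan reference codons so every catalog component is plantable."""
    required: dict[int, str] = {}
    forbidden: dict[int, str] = {}
    for d in defs:
        for comp in d.components:
            if comp.mode != "consequence":
                continue
            pc = parse_hgvs_p(comp.hgvs_p)
            if pc.kind in {"missense", "nonsense"}:
                alt = "*" if pc.kind == "nonsense" else pc.alt_aa
                required[pc.start] = codon_for_transition(pc.ref_aa, alt, rng)
            elif pc.kind == "frameshift":
                required.setdefault(pc.start, AA_TO_CODONS[pc.ref_aa][0])
            elif pc.kind == "inframe_dup":
                required[pc.start] = AA_TO_CODONS[pc.ref_aa[0]][0]
                forbidden[pc.start + 1] = pc.ref_aa[0]
                forbidden[pc.start - 1] = pc.ref_aa[0]
            elif pc.kind == "inframe_del":
                required[pc.start] = AA_TO_CODONS[pc.ref_aa[0]][0]
                if pc.end:
                    required[pc.end] = AA_TO_CODONS[pc.ref_aa[-1]][0]
    return required, forbidden


def simulate_reference(
    config: SimulationConfig,
    catalog: Optional[list[AlleleDefinition]] = None,
) -> tuple[dict[str, str], dict[str, GeneModel]]:
    """Synthetic chromosomes and gene models for the eight loci.

    Protein lengths, exon counts and strands follow the characterized loci;
    exon boundaries and sequence are synthetic.  Reference codons are seeded
    so that every catalog signature is plantable at its stated residue.
    """
    if catalog is None:
        catalog = builtin_catalog()
    rng = np.random.default_rng(config.seed)
    fixture = table1_fixture()
    reference: dict[str, str] = {}
    models: dict[str, GeneModel] = {}
    for locus in sorted(fixture):
        meta = fixture[locus]
        defs = [d for d in catalog if d.locus == locus and d.matchable]
        required, forbidden = _required_codons_for_locus(defs, rng)
        cds = build_cds(rng, meta.protein_length, required, forbidden)
        chrom = f"chr_{locus}"
        layout = assemble_gene(
            gene_id=locus,
            chrom=chrom,
            strand=meta.strand,
            cds=cds,
            rng=rng,
            exon_count=meta.exon_count,
            utr5_length=config.utr5_length,
            utr3_length=config.utr3_length,
            intron_length_range=config.intron_length_range,
            flank=config.flank,
            keepout_codons=sorted(required),
            synonyms=meta.synonyms,
        )
        reference[chrom] = layout.chrom_seq
        models[locus] = layout.model
    return reference, models


# ---------------------------------------------------------------------------
# Panel simulation


@dataclass
class SimulatedPanel:
    variants: list[Variant]
    matrix: GenotypeMatrix
    consequences: dict[str, ConsequenceRecord]
    scores: dict[str, ScoreRecord]
    catalog: list[AlleleDefinition]  # remapped to synthetic coordinates
    manifest: TruthManifest


def _remap_catalog(
    catalog: list[AlleleDefinition],
    models: Mapping[str, GeneModel],
    reference: Mapping[str, str],
    rng: np.random.Generator,
    ctxs: Mapping[str, TranscriptContext],
) -> tuple[list[AlleleDefinition], dict[str, list[tuple[Variant, ConsequenceRecord]]]]:
    """Plant every matchable catalog allele on the synthetic models.

    Components are re-expressed against the synthetic panel: consequence
    signatures use the planted variant's computed HGVS description and
    window matchers are re-centered on the planted insertion.
    """
    remapped: list[AlleleDefinition] = []
    planted: dict[str, list[tuple[Variant, ConsequenceRecord]]] = {}
    for d in catalog:
        if not d.matchable:
            remapped.append(d)
            continue
        model = models[d.locus]
        ctx = ctxs[d.locus]
        chrom_seq = reference[model.chrom]
        new_components: list[VariantMatcher] = []
        plant_list: list[tuple[Variant, ConsequenceRecord]] = []
        for comp in d.components:
            if comp.mode == "consequence":
                pc = parse_hgvs_p(comp.hgvs_p)
                ins = "GTCGA" if d.name == "Sbghd7-1" else None
                v, rec = plant_variant(
                    model,
                    chrom_seq,
                    PlantTarget(protein_change=pc, insertion=ins),
                    rng,
                    ctx,
                )
                new_components.append(
                    VariantMatcher(
                        mode="consequence", gene_id=d.locus, hgvs_p=rec.hgvs_p
                    )
                )
            else:  # window matcher: plant an intronic insertion in intron 2
                length = int(rng.integers(comp.min_indel_length, 40))
                intron_index = min(2, model.exon_count - 1)
                v, rec = plant_variant(
                    model,
                    chrom_seq,
                    PlantTarget(
                        region="intron",
                        intron_index=intron_index,
                        intron_offset=30,
                        insertion_length=max(length, comp.min_indel_length),
                    ),
                    rng,
                    ctx,
                )
                new_components.append(
                    VariantMatcher(
                        mode="coordinate",
                        chrom=model.chrom,
                        window_start=v.pos - 15,
                        window_end=v.pos + 15,
                        min_indel_length=comp.min_indel_length,
                    )
                )
            plant_list.append((v, rec))
        remapped.append(
            AlleleDefinition(
                locus=d.locus,
                name=d.name,
                synonyms=d.synonyms,
                allele_class=d.allele_class,
                zygosity=d.zygosity,
                matchable=True,
                components=new_components,
                provenance=d.provenance,
            )
        )
        planted[d.name] = plant_list
    return remapped, planted


_NOVEL_KINDS = ["nonsense", "frameshift", "missense"]


def simulate_panel(
    config: SimulationConfig,
    reference: Mapping[str, str],
    models: Mapping[str, GeneModel],
    catalog: Optional[list[AlleleDefinition]] = None,
) -> SimulatedPanel:
    """Simulate genotypes, scores and ground truth for an inbred panel."""
    if catalog is None:
        catalog = builtin_catalog()
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))
    ctxs = {
        locus: TranscriptContext(models[locus], reference[models[locus].chrom])
        for locus in models
    }

    freqs = dict(
        config.allele_frequencies
        if config.allele_frequencies is not None
        else default_allele_frequencies(catalog)
    )
    known = {d.name for d in catalog}
    for name in freqs:
        if name not in known:
            raise ValidationError(f"frequency map references unknown allele {name!r}")

    remapped, planted = _remap_catalog(catalog, models, reference, rng, ctxs)
    manifest = TruthManifest()
    variants: list[Variant] = []
    consequences: dict[str, ConsequenceRecord] = {}
    scores: dict[str, ScoreRecord] = {}

    def register(v: Variant, rec: ConsequenceRecord, category: str, band: str) -> None:
        if v.key in consequences:
            return
        variants.append(v)
        consequences[v.key] = rec
        manifest.variants[v.key] = {
            "gene_id": rec.gene_id,
            "kind": rec.label,
            "category": category,
            "score_band": band,
        }
        if band == "deleterious":
            scores[v.key] = ScoreRecord(
                v.key, float(rng.uniform(0.0, SIFT_THRESHOLD - 1e-6)), "synthetic"
            )
        elif band == "tolerated":
            scores[v.key] = ScoreRecord(
                v.key, float(rng.uniform(SIFT_THRESHOLD, 1.0)), "synthetic"
            )

    # catalog allele variants
    allele_keys: dict[str, list[str]] = {}
    for d in remapped:
        if d.name not in planted:
            continue
        keys = []
        for v, rec in planted[d.name]:
            kind = rec.label
            if kind in {"missense", "inframe_dup", "inframe_del", "inframe_ins", "inframe_delins"}:
                category, band = "deleterious_missense", "deleterious"
            elif kind == "nonsense":
                category, band = "nonsense", "none"
            elif kind == "frameshift":
                category, band = "frameshift", "none"
            elif kind in {"splice_donor", "splice_acceptor", "splice_disrupting"}:
                category, band = "splice_disrupting", "none"
            elif kind == "splice_region":
                category, band = "splice_region", "none"
            else:
                category, band = "other_noncoding", "none"
            register(v, rec, category, band)
            keys.append(v.key)
        allele_keys[d.name] = keys

    # novel deleterious variants (uncataloged)
    novel_keys: dict[str, list[str]] = {locus: [] for locus in models}
    for locus in sorted(models):
        model = models[locus]
        ctx = ctxs[locus]
        chrom_seq = reference[model.chrom]
        taken = {
            (consequences[k].protein_change.start)
            for k in consequences
            if consequences[k].gene_id == locus
            and consequences[k].protein_change is not None
        }
        for i in range(config.novel_deleterious_per_locus):
            kind = _NOVEL_KINDS[i % len(_NOVEL_KINDS)]
            for _attempt in range(50):
                pos = int(rng.integers(10, model.protein_length - 10))
                if pos in taken or (pos - 1) in taken or (pos + 1) in taken:
                    continue
                aa = ctx.ref_protein[pos - 1]
                try:
                    if kind == "nonsense":
                        target = ProteinChange("nonsense", pos, ref_aa=aa)
                    elif kind == "frameshift":
                        target = ProteinChange(
                            "frameshift", pos, ref_aa=aa, no_stop=True
                        )
                    else:
                        alt = "W" if aa != "W" else "R"
                        target = ProteinChange("missense", pos, ref_aa=aa, alt_aa=alt)
                    v, rec = plant_variant(
                        model, chrom_seq, PlantTarget(protein_change=target), rng, ctx
                    )
                except (PlantError, ValidationError):
                    continue
                if v.key in consequences:
                    continue
                band = "deleterious" if rec.label == "missense" else "none"
                category = {
                    "missense": "deleterious_missense",
                    "nonsense": "nonsense",
                    "frameshift": "frameshift",
                }.get(rec.label, "other_noncoding")
                register(v, rec, category, band)
                novel_keys[locus].append(v.key)
                taken.add(pos)
                break

    # neutral variants: synonymous, deep intronic, tolerated missense
    for locus in sorted(models):
        model = models[locus]
        ctx = ctxs[locus]
        chrom_seq = reference[model.chrom]
        kinds = ["synonymous", "intron", "tolerated_missense"]
        for i in range(config.neutral_variants_per_locus):
            kind = kinds[i % len(kinds)]
            for _attempt in range(50):
                try:
                    if kind == "intron" and model.exon_count > 1:
                        target = PlantTarget(
                            region="intron",
                            intron_index=1,
                            intron_offset=int(rng.integers(15, 40)),
                        )
                    elif kind == "synonymous":
                        pos = int(rng.integers(5, model.protein_length - 5))
                        target = PlantTarget(
                            protein_change=ProteinChange(
                                "synonymous", pos, ref_aa=ctx.ref_protein[pos - 1]
                            )
                        )
                    else:
                        pos = int(rng.integers(5, model.protein_length - 5))
                        aa = ctx.ref_protein[pos - 1]
                        alt = "A" if aa != "A" else "V"
                        target = PlantTarget(
                            protein_change=ProteinChange(
                                "missense", pos, ref_aa=aa, alt_aa=alt
                            )
                        )
                    v, rec = plant_variant(model, chrom_seq, target, rng, ctx)
                except (PlantError, ValidationError):
                    continue
                if v.key in consequences:
                    continue
                if rec.label == "missense":
                    register(v, rec, "tolerated_missense", "tolerated")
                elif rec.label == "synonymous":
                    register(v, rec, "same_sense", "none")
                else:
                    register(v, rec, "other_noncoding", "none")
                break

    # genotype assignment (inbred model)
    accessions = [f"PI_{600000 + i}" for i in range(config.n_accessions)]
    keys = [v.key for v in variants]
    kidx = {k: i for i, k in enumerate(keys)}
    calls = np.full((len(keys), len(accessions)), HOM_REF, dtype=np.int8)

    by_locus: dict[str, list[AlleleDefinition]] = {}
    for d in remapped:
        if d.matchable and d.name in freqs and freqs[d.name] > 0:
            by_locus.setdefault(d.locus, []).append(d)

    for ai, acc in enumerate(accessions):
        manifest.locus_status[acc] = {}
        for locus in sorted(models):
            defs = by_locus.get(locus, [])
            u = rng.random()
            cum = 0.0
            chosen: Optional[AlleleDefinition] = None
            for d in defs:
                cum += freqs[d.name]
                if u < cum:
                    chosen = d
                    break
            status, allele = "wildtype", None
            if chosen is not None:
                het = rng.random() < config.het_rate
                code = HET if het else HOM_ALT
                for key in allele_keys[chosen.name]:
                    calls[kidx[key], ai] = code
                status = "heterozygous_carrier" if het else "named"
                allele = chosen.name
            elif novel_keys[locus] and rng.random() < config.novel_deleterious_rate:
                key = novel_keys[locus][
                    int(rng.integers(0, len(novel_keys[locus])))
                ]
                calls[kidx[key], ai] = HOM_ALT
                status, allele = "novel_deleterious", key
            manifest.locus_status[acc][locus] = {"status": status, "allele": allele}

    if config.genotype_missingness > 0:
        mask = rng.random(calls.shape) < config.genotype_missingness
        for vi, ai in zip(*np.nonzero(mask)):
            manifest.masked.append([accessions[ai], keys[vi]])
        calls[mask] = MISSING

    matrix = GenotypeMatrix(accessions, keys, calls)
    return SimulatedPanel(variants, matrix, consequences, scores, remapped, manifest)


# ---------------------------------------------------------------------------
# Phenotypes


def simulate_phenotypes(
    manifest: TruthManifest,
    effects: Mapping[str, float],
    sigma: float,
    seed: int,
    baseline: float = 250.0,
    trait: str = "plant_height",
    unit: str = "cm",
    novel_effect_key: str = "novel",
) -> pd.DataFrame:
    """Additive phenotypes: baseline + sum of allele effects + N(0, sigma).

    `effects` is keyed by allele name; homozygous novel deleterious calls
    use `novel_effect_key`.  Heterozygous carriers contribute no effect (the
    inbred screen treats them as ambiguous).  Every planted allele must have
    an effect entry.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for acc in sorted(manifest.locus_status):
        expectation = baseline
        for locus, d in sorted(manifest.locus_status[acc].items()):
            if d["status"] == "named":
                name = d["allele"]
                if name not in effects:
                    raise ValidationError(f"no effect for planted allele {name!r}")
                expectation += effects[name]
            elif d["status"] == "novel_deleterious":
                if novel_effect_key not in effects:
                    raise ValidationError(
                        f"no effect entry {novel_effect_key!r} for novel alleles"
                    )
                expectation += effects[novel_effect_key]
        value = expectation + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
        manifest.phenotype_expectation[acc] = float(expectation)
        rows.append(
            {"accession": acc, "trait": trait, "value": value, "unit": unit}
        )
    return pd.DataFrame(rows, columns=["accession", "trait", "value", "unit"])


# ---------------------------------------------------------------------------
# Dataset writer


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            fh.write(textwrap.fill(sequences[name], 80) + "\n")


def write_gff3(path: str | Path, models: Mapping[str, GeneModel]) -> None:
    lines = ["##gff-version 3"]
    for gid in sorted(models):
        m = models[gid]
        attrs = f"ID=gene:{gid};Name={gid}"
        lines.append(
            "\t".join(
                [
                    m.chrom,
                    "madw_sim",
                    "gene",
                    str(m.span.start),
                    str(m.span.end),
                    ".",
                    m.strand,
                    ".",
                    attrs,
                ]
            )
        )
        mid = f"mRNA:{gid}.1"
        lines.append(
            "\t".join(
                [
                    m.chrom,
                    "madw_sim",
                    "mRNA",
                    str(m.span.start),
                    str(m.span.end),
                    ".",
                    m.strand,
                    ".",
                    f"ID={mid};Parent=gene:{gid}",
                ]
            )
        )
        for ex in m.exons:
            lines.append(
                "\t".join(
                    [
                        m.chrom,
                        "madw_sim",
                        "exon",
                        str(ex.start),
                        str(ex.end),
                        ".",
                        m.strand,
                        ".",
                        f"Parent={mid}",
                    ]
                )
            )
        for iv in m.coding_intervals:
            lines.append(
                "\t".join(
                    [
                        m.chrom,
                        "madw_sim",
                        "CDS",
                        str(iv.start),
                        str(iv.end),
                        ".",
                        m.strand,
                        "0",
                        f"Parent={mid}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_dataset(
    outdir: str | Path,
    config: SimulationConfig,
    reference: Mapping[str, str],
    models: Mapping[str, GeneModel],
    panel: SimulatedPanel,
    phenotypes: Optional[pd.DataFrame] = None,
) -> dict[str, Path]:
    """Write the full synthetic dataset as plain-text files."""
    from .variant_io import write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "gff3": outdir / "genes.gff3",
        "vcf": outdir / "panel.vcf",
        "scores": outdir / "scores.tsv",
        "catalog": outdir / "catalog.json",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(paths["reference"], reference)
    write_gff3(paths["gff3"], models)
    write_vcf(
        paths["vcf"],
        panel.variants,
        panel.matrix,
        {c: len(s) for c, s in reference.items()},
    )
    pd.DataFrame(
        [
            {"variant_id": s.variant_key, "score": s.score, "source": s.source}
            for s in panel.scores.values()
        ],
        columns=["variant_id", "score", "source"],
    ).to_csv(paths["scores"], sep="\t", index=False)
    paths["catalog"].write_text(catalog_to_json(panel.catalog))
    paths["manifest"].write_text(panel.manifest.to_json())
    if phenotypes is not None:
        paths["phenotypes"] = outdir / "phenotypes.tsv"
        phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    return paths
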