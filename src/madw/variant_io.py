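"""Region-restricted VCF reading, variant normalization and panel merging.

The screen works at candidate loci only, so VCF records are filtered by
overlap of their REF span with the locus intervals (the interval-intersection
stage of the pipeline).  Multiallelic records are split into biallelic
variants, indels are left-aligned (VCF convention — the HGVS 3' rule applies
only at protein-level naming), and panels from different resequencing
studies are merged over their accession union.

Genotypes are unphased diploid calls collapsed to four states:
hom_ref / het / hom_alt / missing.  Any half-missing genotype is missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ParseError, ValidationError
from .gene_models import GenomicInterval

# call codes used in GenotypeMatrix arrays
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1
CALL_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class Variant:
    """A normalized biallelic variant (VCF anchor convention for indels)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValidationError(
                    f"bad allele {allele!r} at {self.chrom}:{self.pos}"
                )
        if self.ref == self.alt:
            raise ValidationError(f"REF == ALT at {self.chrom}:{self.pos}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def end(self) -> int:
        """Last genomic position of the REF span."""
        return self.pos + len(self.ref) - 1

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))


@dataclass
class GenotypeMatrix:
    """Complete calls over accessions x variants (int8 codes, see CALL_NAMES)."""

    accessions: list[str]
    variants: list[str]  # variant keys, same order as rows of `calls`
    calls: np.ndarray    # shape (n_variants, n_accessions)

    def __post_init__(self) -> None:
        if len(set(self.accessions)) != len(self.accessions):
            raise ValidationError("duplicate accession identifiers in panel")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.accessions)):
            raise ValidationError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.variants)}, {len(self.accessions)})"
            )
        self._vidx = {v: i for i, v in enumerate(self.variants)}
        self._aidx = {a: i for i, a in enumerate(self.accessions)}

    def call(self, accession: str, variant_key: str) -> str:
        return CALL_NAMES[int(self.calls[self._vidx[variant_key], self._aidx[accession]])]

    def code(self, accession: str, variant_key: str) -> int:
        return int(self.calls[self._vidx[variant_key], self._aidx[accession]])

    def accession_calls(self, accession: str) -> dict[str, int]:
        col = self.calls[:, self._aidx[accession]]
        return {v: int(c) for v, c in zip(self.variants, col)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.variants, columns=self.accessions)

    @classmethod
    def empty(cls, accessions: Sequence[str] = ()) -> "GenotypeMatrix":
        return cls(list(accessions), [], np.zeros((0, len(accessions)), dtype=np.int8))


def _map_gt(alleles: tuple, k: int) -> int:
    """Collapse a diploid GT tuple to a call code for split allele index k."""
    if len(alleles) != 2 or any(a is None for a in alleles):
        return MISSING
    dosage = sum(1 for a in alleles if a == k)
    if dosage == 2:
        return HOM_ALT
    if dosage == 1:
        return HET
    return HOM_REF  # carries only REF and/or other ALT alleles


def split_multiallelic(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    genotypes: Sequence[tuple],
) -> list[tuple[Variant, np.ndarray]]:
    """Split a k-ALT record into k biallelic (Variant, call column) pairs.

    Genotype allele indices refer to the original record (0 = REF).
    Biallelic input passes through unchanged (idempotent).
    """
    if not alts:
        raise ParseError(f"{chrom}:{pos}: record has no ALT alleles")
    n_alt = len(alts)
    for gt in genotypes:
        for a in gt:
            if a is not None and not (0 <= a <= n_alt):
                raise ParseError(
                    f"{chrom}:{pos}: genotype allele index {a} exceeds ALT count {n_alt}"
                )
    out = []
    for k, alt in enumerate(alts, start=1):
        v = Variant(chrom, pos, ref.upper(), alt.upper())
        col = np.array([_map_gt(gt, k) for gt in genotypes], dtype=np.int8)
        out.append((v, col))
    return out


def normalize_variant(v: Variant, chrom_seq: str) -> Variant:
    """Trim shared bases and left-align indels (the standard vt algorithm).

    Keeps one anchor base for pure indels.  Idempotent, and preserves the
    mutated sequence: applying the normalized variant to the reference gives
    the same sequence as applying the original.
    """
    if chrom_seq[v.pos - 1 : v.end].upper() != v.ref:
        raise ValidationError(
            f"REF mismatch at {v.chrom}:{v.pos}: expected {v.ref}, "
            f"reference has {chrom_seq[v.pos - 1 : v.end].upper()!r}"
        )
    pos, ref, alt = v.pos, v.ref, v.alt
    while True:
        changed = False
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if (not ref or not alt) and pos > 1:
            pos -= 1
            b = chrom_seq[pos - 1].upper()
            ref, alt = b + ref, b + alt
            changed = True
        if not changed:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return Variant(v.chrom, pos, ref, alt)


def read_panel_vcf(
    path: str | Path,
    regions: Iterable[GenomicInterval],
    reference: Optional[dict[str, str]] = None,
) -> tuple[list[Variant], GenotypeMatrix]:
    """Read a panel VCF keeping records whose REF span overlaps a region.

    Multiallelic records are split; when `reference` (chrom -> sequence) is
    given, variants are normalized against it.  A sites-only VCF yields an
    empty-accession matrix with a warning.
    """
    regions = list(regions)
    if not regions:
        raise ValidationError("read_panel_vcf requires at least one region")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)

    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot read VCF {path}: {exc}") from exc

    samples = list(vf.header.samples)
    if not samples:
        warnings.warn(f"{path}: sites-only VCF, genotype matrix will have 0 accessions")

    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()
    for rec in vf:
        chrom_regions = by_chrom.get(rec.chrom)
        if not chrom_regions:
            continue
        ref = (rec.ref or "").upper()
        start, end = rec.pos, rec.pos + max(len(ref), 1) - 1
        if not any(r.start <= end and start <= r.end for r in chrom_regions):
            continue
        alts = [a for a in (rec.alts or ()) if a is not None and a != "*"]
        if not alts or not ref:
            continue
        gts = [rec.samples[s].get("GT", (None, None)) or (None, None) for s in samples]
        gts = [tuple(gt) if gt is not None else (None, None) for gt in gts]
        for v, col in split_multiallelic(rec.chrom, rec.pos, ref, alts, gts):
            if reference is not None and v.chrom in reference:
                v = normalize_variant(v, reference[v.chrom])
            if v.key in seen:
                continue
            seen.add(v.key)
            variants.append(v)
            columns.append(col)
    vf.close()

    calls = (
        np.vstack(columns)
        if columns
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    return variants, GenotypeMatrix(samples, [v.key for v in variants], calls)


@dataclass
class MergeResult:
    matrix: GenotypeMatrix
    conflicts: pd.DataFrame  # columns: accession, variant, call_a, call_b, resolution
    sources: dict[str, list[str]] = field(default_factory=dict)


def merge_panels(
    a: GenotypeMatrix,
    b: GenotypeMatrix,
    policy: str = "missing",
    absent_fill: int = MISSING,
    source_tags: tuple[str, str] = ("a", "b"),
) -> MergeResult:
    """Merge two panels over the union of accessions and variants.

    Shared accessions with discordant calls are resolved per `policy`:
    "missing" (conservative default), "a-wins" or "b-wins"; every
    discordance is logged.  Cells for variants absent from an accession's
    source VCF are filled with `absent_fill` (default missing — merged VCFs
    do not assert reference calls at sites they lack; this inflates the
    uncharacterized count and is deliberate).
    """
    if policy not in {"missing", "a-wins", "b-wins"}:
        raise ValidationError(f"unknown merge policy {policy!r}")
    accessions = list(a.accessions) + [x for x in b.accessions if x not in a._aidx]
    variants = list(a.variants) + [v for v in b.variants if v not in a._vidx]
    calls = np.full((len(variants), len(accessions)), absent_fill, dtype=np.int8)
    vidx = {v: i for i, v in enumerate(variants)}
    aidx = {x: i for i, x in enumerate(accessions)}

    for vi, v in enumerate(a.variants):
        for ai, acc in enumerate(a.accessions):
            calls[vidx[v], aidx[acc]] = a.calls[vi, ai]

    conflicts = []
    shared = set(a.accessions) & set(b.accessions)
    for vi, v in enumerate(b.variants):
        row = vidx[v]
        in_a = v in a._vidx
        for ai, acc in enumerate(b.accessions):
            cb = int(b.calls[vi, ai])
            if acc in shared and in_a:
                ca = int(calls[row, aidx[acc]])
                if ca == cb:
                    continue
                if ca == MISSING:
                    calls[row, aidx[acc]] = cb
                    continue
                if cb == MISSING:
                    continue
                resolution = {"missing": MISSING, "a-wins": ca, "b-wins": cb}[policy]
                conflicts.append(
                    {
                        "accession": acc,
                        "variant": v,
                        "call_a": CALL_NAMES[ca],
                        "call_b": CALL_NAMES[cb],
                        "resolution": CALL_NAMES[resolution],
                    }
                )
                calls[row, aidx[acc]] = resolution
            else:
                calls[row, aidx[acc]] = cb

    sources: dict[str, list[str]] = {}
    for acc in accessions:
        tags = []
        if acc in a._aidx:
            tags.append(source_tags[0])
        if acc in b._aidx:
            tags.append(source_tags[1])
        sources[acc] = tags
    log = pd.DataFrame(
        conflicts, columns=["accession", "variant", "call_a", "call_b", "resolution"]
    )
    return MergeResult(GenotypeMatrix(accessions, variants, calls), log, sources)


# ---------------------------------------------------------------------------
# Output / region helpers


_CODE_TO_GT = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}


def write_vcf(
    path: str | Path,
    variants: Sequence[Variant],
    matrix: Optional[GenotypeMatrix] = None,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write variants (and genotypes, if a matrix is given) as plain VCF 4.2."""
    header = pysam.VariantHeader()
    contigs = contig_lengths or {}
    seen = dict(contigs)
    for v in variants:
        seen.setdefault(v.chrom, 0)
        seen[v.chrom] = max(seen[v.chrom], v.end + 1000)
    for chrom, length in seen.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    samples = matrix.accessions if matrix is not None else []
    for s in samples:
        header.add_sample(s)
    out = pysam.VariantFile(str(path), "w", header=header)
    for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
        rec = out.new_record(
            contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt), id=v.key
        )
        if matrix is not None:
            for s in samples:
                rec.samples[s]["GT"] = _CODE_TO_GT[matrix.code(s, v.key)]
                rec.samples[s].phased = False
        out.write(rec)
    out.close()


def bed_to_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise ParseError(f"{path}:{i}: BED needs >= 3 columns")
        try:
            start0, end0 = int(f[1]), int(f[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: non-integer BED coordinates") from exc
        out.append(GenomicInterval(f[0], start0 + 1, end0))
    return out
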