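"""Shared generators for the test suite."""

from __future__ import annotations

import numpy as np

from madw import Variant
from madw.gene_models import GeneModel
from madw.variant_io import normalize_variant


def random_coding_variant(
    rng: np.random.Generator, model: GeneModel, chrom_seq: str
) -> Variant | None:
    """A random SNP/MNP/indel whose edit lies in contiguous coding sequence."""
    L = model.cds_length
    for _ in range(100):
        kind = rng.choice(["snp", "snp", "snp", "del", "ins", "mnp"])
        c = int(rng.integers(1, L + 1))
        if kind in ("del", "mnp"):
            n = int(rng.integers(1, 7)) if kind == "del" else int(rng.integers(2, 4))
            if c + n - 1 > L:
                continue
            coords = list(range(c, c + n))
        else:
            coords = [c]
        g = [model.cds_to_genomic(x) for x in coords]
        step = -1 if model.strand == "-" else 1
        if any(b - a != step for a, b in zip(g, g[1:])):
            continue
        glo, ghi = min(g), max(g)
        ref = chrom_seq[glo - 1 : ghi]
        if kind == "snp":
            alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        elif kind == "mnp":
            alt = "".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=len(ref)))
            if alt == ref:
                continue
        elif kind == "del":
            if glo < 3:
                continue
            a = chrom_seq[glo - 2]
            return normalize_variant(Variant(model.chrom, glo - 1, a + ref, a), chrom_seq)
        else:
            ins = "".join(
                "ACGT"[int(i)] for i in rng.integers(0, 4, size=int(rng.integers(1, 7)))
            )
            return normalize_variant(Variant(model.chrom, glo, ref, ref + ins), chrom_seq)
        return normalize_variant(Variant(model.chrom, glo, ref, alt), chrom_seq)
    return None


def explicit_gene(codons: list[str], strand: str = "+", exon_count: int = 2,
                  seed: int = 11, **kwargs):
    """A gene with a fully specified CDS (list of codons incl. final stop)."""
    from madw.synthetic import assemble_gene

    rng = np.random.default_rng(seed)
    cds = "".join(codons)
    layout = assemble_gene(
        gene_id="toy",
        chrom="chrToy",
        strand=strand,
        cds=cds,
        rng=rng,
        exon_count=exon_count,
        utr5_length=40,
        utr3_length=160,
        intron_length_range=(30, 60),
        flank=150,
        **kwargs,
    )
    return layout.model, layout.chrom_seq
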