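"""The eight characterized Maturity/Dwarf loci and their splice-window geometry.

Loads the packaged locus metadata (genomic span, strand, protein length,
exon count) and shows how intronic positions are classified into
donor/acceptor consensus and splice-region windows on a toy two-exon gene.
"""

from madw import GeneModel, GenomicInterval, table1_fixture

loci = table1_fixture()
print(f"{'locus':<5} {'chrom':<6} {'strand':<6} {'span':<28} {'protein':>7} {'exons':>5}")
for name, m in sorted(loci.items()):
    span = f"{m.span.start:,}-{m.span.end:,}"
    print(f"{name:<5} {m.chrom:<6} {m.strand:<6} {span:<28} {m.protein_length:>6}aa {m.exon_count:>5}")

print()
print("Splice windows on a 30-base intron (donor +1/+2, region +3..+5 and -3..-10,")
print("acceptor -1/-2); variants in the region windows may perturb splicing without")
print("touching the GT/AG consensus:")

toy = GeneModel(
    gene_id="toy",
    chrom="c",
    strand="+",
    span=GenomicInterval("c", 1, 230),
    exons=[GenomicInterval("c", 1, 100), GenomicInterval("c", 131, 230)],
    cds_start=1,
    cds_end=230,
)
for pos in [101, 102, 103, 105, 106, 120, 121, 128, 129, 130]:
    a = toy.classify_position(pos)
    print(f"  intron position {pos}: offset {a.intron_offset:+d} -> {a.region}")
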