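"""Protein-consequence prediction with HGVS p. nomenclature.

Builds a synthetic gene, plants the kinds of variants reported at the
sorghum Ma/Dw loci (nonsense, frameshift via a 5-bp insertion, in-frame
deletion, duplication), and prints the predicted HGVS descriptions.
"""

import numpy as np

from madw import ProteinChange, Variant, plant_variant, predict_consequence
from madw.synthetic import PlantTarget, assemble_gene

rng = np.random.default_rng(1)

# a 200-residue gene whose codons we control at the planting sites
codons = ["ATG"] + ["GCT"] * 199 + ["TAA"]
codons[99] = "CAA"   # Gln100 -> nonsense target
codons[93] = "GAA"   # Glu94  -> frameshift target
codons[73] = "CAA"   # Gln74 \
codons[74] = "AGA"   # Arg75 /  in-frame deletion target
codons[30] = "CAT"   # His31  -> duplication target
layout = assemble_gene(
    "demo", "chrDemo", "+", "".join(codons), rng, exon_count=3,
)
model, seq = layout.model, layout.chrom_seq

targets = [
    ("nonsense SNP", PlantTarget(protein_change=ProteinChange("nonsense", 100, ref_aa="Q"))),
    ("5-bp insertion (GTCGA)", PlantTarget(
        protein_change=ProteinChange("frameshift", 94, ref_aa="E", no_stop=True),
        insertion="GTCGA",
    )),
    ("6-bp in-frame deletion", PlantTarget(
        protein_change=ProteinChange("inframe_del", 74, end=75, ref_aa="QR"))),
    ("3-bp duplication", PlantTarget(
        protein_change=ProteinChange("inframe_dup", 31, ref_aa="H"))),
]
print("planted DNA event            -> predicted protein consequence")
for label, target in targets:
    v, rec = plant_variant(model, seq, target, rng)
    print(f"  {label:<26} {v.key:<28} {rec.hgvs_p}")

# an intronic variant in the +3..+5 window gets a splice label, no protein call
intron = model.introns[0]
pos = intron.start + 3
v = Variant(model.chrom, pos, seq[pos - 1], "ACGT".replace(seq[pos - 1], "")[0])
rec = predict_consequence(model, seq, v)
print(f"  intronic SNP at offset +4  {v.key:<28} {rec.noncoding_label} (no protein prediction)")
print()
print("Frameshift descriptions count the new stop from the first changed")
print("residue (fsTer6 = stop at the 6th codon of the shifted frame).")
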