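# Methods

## Scope and model

`madw` screens diploid, mostly-inbred germplasm panels for deleterious
alleles at candidate loci. The unit of analysis is one locus's primary
transcript: a gene model (span, strand, exons, CDS boundaries) plus a
reference sequence. Variants are normalized biallelic records in VCF
conventions (1-based anchor position; indels left-aligned with one anchor
base). All coordinates everywhere in the package are 1-based inclusive —
the GFF3/VCF convention — with BED input converted on read; a single
convention eliminates an entire class of off-by-one defects.

The packaged metadata for the eight characterized sorghum loci (`Ma1`,
`Ma2`, `Ma3`, `Ma5`, `Ma6`, `Dw1`, `Dw2`, `Dw3`) carries genomic span,
strand, transcript/protein length and exon count only. Exon boundaries for
the real loci are deliberately **not** fabricated: sequence-level work on
real data requires a user-supplied GFF3 + FASTA, and all sequence-level
testing here uses synthetic models.

## Splice geometry

Intron offsets are counted on the coding strand: +k is the k-th base from
the intron 5' end (donor side), −k the k-th base from the 3' end (acceptor
side). Offsets +1/+2 and −1/−2 are the GT/AG consensus
(`splice_donor`/`splice_acceptor`); +3..+5 and −3..−10 are `splice_region`
— windows where variants can perturb splicing without touching the
consensus. For introns shorter than the 15 bases needed to keep both
window sets disjoint, donor-side classification takes precedence — a
deterministic tie-break. A variant whose changed bases straddle an
exon/intron junction, or a pure insertion sitting in the genomic gap at a
junction, is labelled `splice_disrupting` and gets no protein prediction,
because the transcript outcome is unknowable without a splicing model.

## Consequence prediction

Coding variants are applied to the spliced transcript; the mutant coding
region (extended through the 3' UTR, so frameshifts can find their new
stop) is re-translated with the standard nuclear code and compared with
the reference protein. The comparison takes the maximal common prefix,
then the maximal common suffix of the remainders — which realizes the
HGVS 3'-most placement rule at protein level — and names the change:

* identical proteins → synonymous, `p.(Leu54=)` (position-less `p.(=)`
  when only the stop codon is touched without effect);
* single residue substituted → missense, or nonsense when the new residue
  is a stop;
* frame-disrupting indels → frameshift `p.(Xaa#YaafsTer#)`, the stop
  counted with the first changed residue as codon 1; a frameshift whose
  first shifted codon is already a stop is reported as nonsense (fsTer1
  does not exist); a frameshift that never reaches a stop before the
  transcript end is flagged, never silently numbered;
* in-frame indels → del/ins/dup/delins; an insertion equal to the
  residues immediately 5' of the (3'-most) insertion point is a
  duplication;
* in-frame events whose translation terminates early are named by what
  the protein comparison shows: an alt segment of exactly Ter is nonsense
  `p.(Xaa#Ter)`, otherwise a delins ending in Ter — protein-level
  nomenclature cannot (and need not) distinguish the underlying DNA event;
* any disruption of the initiator codon region → `p.(Met1?)`; changes at
  the stop codon (residue protein_length + 1) → `p.(Ter#XaaextTer?)` with
  the extension length unevaluated. By the 3'-most rule this also covers
  pure insertions between the last residue and the stop.

Variant matching at DNA level uses VCF left-alignment; the HGVS 3' rule
applies only at protein naming. The two standards disagree and each is
applied in its own domain.

The test suite holds an independent oracle that rebuilds the mutant
chromosome, shifts every model coordinate, re-extracts and fully
re-translates the transcript with Biopython, and names the difference
separately; predictor and oracle agree exactly on ≥ 10,000 random
(gene, variant) pairs per run, both strands.

## Effect classification

Substitution-tolerance scores (SIFT-like, in [0, 1], lower = more
damaging) are an input channel only — recomputing them would require the
alignment pipeline that produces them, which is out of scope. Missense
(and in-frame) changes with score < 0.05 are `deleterious_missense`;
score ≥ 0.05 is tolerated. The boundary value 0.05 itself is tolerated:
the screen's definition labels "< 0.05" deleterious and "> 0.05"
tolerated, leaving 0.05 unassigned, and the strict reading is adopted. A
missense variant with no score is reported as `unscored_missense` rather
than silently tolerated, so missing annotations cannot masquerade as
benign. The deleterious set is {deleterious missense, nonsense,
frameshift, splice-disrupting}; `splice_region` alone is reported but not
counted deleterious by default (a configurable flag, since practice
varies).

## Allele catalog and panel genotyping

A characterized allele is a conjunction of variant matchers — ALL
components must be present, homozygous by default, because heterozygous
carriers are reported separately. Matchers are either *coordinate* (exact
normalized key, or a position window with a minimum indel length — used
only for the `Sbghd7-2` intron-2 insertion hallmarks, whose exact content
varies) or *consequence* (gene + HGVS p., compared as parsed values so
`p.Lys184Asn` ≡ `p.(Lys184Asn)`). `dw3-ref` (an 882-bp tandem
duplication) is catalog metadata only and always genotypes as unknown:
short-read resequencing against a reference assembly cannot see it.

Three catalog choices worth recording. The `Sbprr37-3` signature uses
Gln270Ter + Lys184Asn (the componentized description; the conflicting
Gln292Ter statement is kept in the provenance note, not matched). The
`Sbphyb-2` in-frame event is described ambiguously as His31dup or
His31del in its source; the dup form is matched. `Sbprr37-1` has no
published protein coordinate ("a 1-bp deletion upstream of the
pseudoreceiver motif", residues 99–207), so its signature is a frameshift
placed at residue 80 — a package convention, flagged in the provenance
note, that only matters for the synthetic pipeline (real-data users
supply their own coordinate for it).

Locus-call precedence is total and deterministic: (1) any homozygous
catalog allele → `named`, all matched names listed (a compound allele's
carrier also matches its sub-signatures); (2) any homozygous uncataloged
deleterious variant → `novel_deleterious`; (3) any heterozygous allele or
deleterious variant → `heterozygous_carrier`; (4) missing-data fraction at
the locus's interrogated sites above the threshold → `uncharacterized`;
(5) otherwise `wildtype`. The missingness threshold defaults to 0.5 — the
source procedure gives no number ("poor or missing data"), so the knob is
explicit. Panel merging is conservative: discordant calls between studies
become missing by default (selectable a-wins/b-wins), and absent
variant × accession cells are missing, not hom-ref, because merged VCFs
do not assert reference calls at sites they lack; both behaviors inflate
`uncharacterized` and are logged.

## Association statistics

Per locus: a one-way group-means linear model, treatment-coded against
the wildtype level, with two-sided coefficient t-tests at α = 0.05
(configurable). Shapiro–Wilk is run on the residuals (scipy's
implementation, cross-checked in the suite against R's `shapiro.test` to
1e-4 on a fixed n = 500 sample) and Kruskal–Wallis (mid-ranks, tie
correction, χ²_{k−1} tail) is attached as the non-parametric companion;
an all-identical sample is an error since the tie-corrected statistic is
undefined. The multi-locus model is additive in locus factors with no
interactions; aliased columns are detected by QR and dropped with a
singularity report. Accessions with `uncharacterized` or
`heterozygous_carrier` status are excluded from association by default —
their allele level is ambiguous. Levels need ≥ 2 observations; dropped
levels are reported, never silently absorbed.

## Synthetic data

The generator emulates the structure of a resequenced inbred sorghum
panel; it defines the study conditions for every recovery test.

* **Reference**: one synthetic chromosome per locus, gene protein lengths,
  exon counts and strands taken from the real loci, exon boundaries and
  sequence random (ATG start, single in-frame TAA stop, GT..AG introns,
  CDS ≡ 0 mod 3). Reference codons are seeded so every catalog signature
  is plantable at its stated residue (e.g. Lys at 184 with Asn one SNP
  away), and intron insertion points keep ±4 nt clearance around those
  codons so planted edits stay in contiguous coding sequence.
* **Planting**: catalog alleles are realized as concrete variants via
  consequence-mode targets (missense/nonsense as minimal codon edits,
  frameshifts as 1-bp deletions — `Sbghd7-1` as its 5-bp GTCGA insertion —
  dup/del as codon-level indels, `Sbghd7-2` as an intron-2 insertion with
  a window matcher re-centered on it). Each planted variant's *computed*
  consequence becomes the signature in the remapped catalog, so
  self-consistency is guaranteed and verified at plant time.
* **Panel**: each accession draws at most one allele per locus with the
  configured frequency (default ladder 0.30/0.15/0.10/0.05 per locus,
  all within 0.05–0.5), is otherwise a novel-deleterious homozygote with
  rate 0.02 or wildtype; carriers become heterozygous with a separate
  het-rate dial (not Hardy–Weinberg — heterozygotes are exceptional in
  inbred panels). Missingness is uniform over cells. Scores are drawn
  concordant with the planted category: U[0, 0.05) for deleterious
  missense/in-frame events, U[0.05, 1] for tolerated.
* **Phenotypes**: value = baseline + Σ allele effects + N(0, σ), default
  baseline 250 cm and σ = 10 cm with −50 cm for dwarfing alleles in the
  examples — magnitudes typical of the dw loci. Homozygous novel calls
  use a shared `novel` effect key; heterozygous carriers contribute no
  effect (they are excluded from association anyway).
* All randomness flows from the single config seed; identical seeds give
  byte-identical outputs.

What the generator does **not** emulate: linkage disequilibrium,
population structure, realistic site-frequency spectra, read-level error,
or genotyping error correlated with depth. Passing recovery tests
therefore demonstrate the correctness of the pipeline's logic — interval
filtering, consequence calling, signature matching, precedence,
bookkeeping — not robustness to real-data artifacts.

## Problem sizes and numerical choices

The default test conditions are desk-scale by design: recovery uses a
500-accession, 8-locus panel (~55 variants); the oracle-equivalence suite
uses ~10,000 pairs on genes of 30–90 residues; null calibration uses
1,000 permutation replicates at n = 60. The panel-level headline numbers
of the original screen (1,445 gene variants over 860 accessions, and the
per-locus mutant tallies) require the two external whole-genome
resequencing datasets (~33 M SNPs, ~4.4 M InDels) and are not reproducible
from synthetic data; the package's claims are therefore about pipeline
correctness under known ground truth, not about those counts.

Numerical details: group comparisons use exact string/integer arithmetic
(no tolerances); binomial acceptance bands are central 99% intervals;
OLS is ordinary pinv-based least squares via statsmodels; genotype codes
are int8 (hom_ref 0, het 1, hom_alt 2, missing −1).

## Known limitations

* Only primary transcripts are modeled; no alternative splicing, no
  UTR inference beyond CDS-boundary arithmetic.
* No splice-outcome prediction: consensus and junction variants stop at a
  `splice_disrupting` label.
* HGVS support is p.-level only (DNA identity uses normalized VCF keys,
  not c./g. descriptions).
* Large structural variants are out of reach by construction (mirrored by
  the unmatchable `dw3-ref` entry).
* The per-locus mutant tallies count homozygous calls; whether
  heterozygous carriers should be included in headline tallies is left to
  the caller (they are reported separately).
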