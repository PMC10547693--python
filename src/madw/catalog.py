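"""Characterized-allele signatures, panel genotyping and summaries.

An :class:`AlleleDefinition` encodes a named allele (e.g. ``Sbprr37-3``) as
a conjunction of variant matchers: ALL components must be present for the
allele to be called, homozygous by default (the screen reports heterozygous
carriers separately throughout).  Matchers come in two modes: *coordinate*
(a normalized variant key, or a position window with a minimum indel length
for imprecise signatures like the Sbghd7-2 intron-2 insertions) and
*consequence* (gene + HGVS p. description, compared as parsed
:class:`~madw.hgvs.ProteinChange` values so that ``p.Lys184Asn`` and
``p.(Lys184Asn)`` match).

Locus status precedence for one accession: named catalog allele (hom) >
novel homozygous deleterious variant > heterozygous carrier >
uncharacterized (missing data above threshold) > wildtype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .classify import is_deleterious
from .consequence import ConsequenceRecord
from .errors import ValidationError
from .gene_models import GeneModel
from .hgvs import ProteinChange, parse_hgvs_p
from .variant_io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, Variant

ALLELE_CLASSES = {"amorphic", "hypomorphic", "missense", "unknown"}
STATUSES = [
    "named",
    "novel_deleterious",
    "heterozygous_carrier",
    "wildtype",
    "uncharacterized",
]

DEFAULT_MISSINGNESS_THRESHOLD = 0.5


@dataclass(frozen=True)
class VariantMatcher:
    mode: str  # "coordinate" | "consequence"
    # coordinate mode (exact)
    chrom: Optional[str] = None
    pos: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    # coordinate mode (window)
    window_start: Optional[int] = None
    window_end: Optional[int] = None
    min_indel_length: Optional[int] = None
    # consequence mode
    gene_id: Optional[str] = None
    hgvs_p: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode == "coordinate":
            exact = self.pos is not None and self.ref and self.alt
            window = self.window_start is not None and self.window_end is not None
            if not self.chrom or not (exact or window):
                raise ValidationError(
                    "coordinate matcher needs chrom + (pos/ref/alt or an explicit window)"
                )
            if window and self.min_indel_length is None:
                raise ValidationError("window matcher needs min_indel_length")
        elif self.mode == "consequence":
            if not self.gene_id or not self.hgvs_p:
                raise ValidationError("consequence matcher needs gene_id and hgvs_p")
        else:
            raise ValidationError(f"unknown matcher mode {self.mode!r}")

    @property
    def is_window(self) -> bool:
        return self.mode == "coordinate" and self.window_start is not None

    @property
    def protein_change(self) -> Optional[ProteinChange]:
        return parse_hgvs_p(self.hgvs_p) if self.mode == "consequence" else None

    def matching_keys(
        self,
        variants: Mapping[str, Variant],
        consequences: Mapping[str, ConsequenceRecord],
    ) -> list[str]:
        """Variant keys in the panel satisfying this matcher."""
        if self.mode == "coordinate":
            if not self.is_window:
                key = f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"
                return [key] if key in variants else []
            out = []
            for key, v in variants.items():
                if (
                    v.chrom == self.chrom
                    and self.window_start <= v.pos <= self.window_end
                    and v.indel_length >= self.min_indel_length
                ):
                    out.append(key)
            return sorted(out)
        target = self.protein_change
        out = []
        for key, rec in consequences.items():
            if rec.gene_id == self.gene_id and rec.protein_change == target:
                out.append(key)
        return sorted(out)


@dataclass
class AlleleDefinition:
    locus: str
    name: str
    components: list[VariantMatcher]
    synonyms: list[str] = field(default_factory=list)
    allele_class: str = "unknown"
    zygosity: str = "hom_alt"
    matchable: bool = True
    duplication_length: Optional[int] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.allele_class not in ALLELE_CLASSES:
            raise ValidationError(
                f"{self.name}: unknown allele class {self.allele_class!r}"
            )
        if self.matchable and not self.components:
            raise ValidationError(f"{self.name}: matchable allele needs >= 1 component")


@dataclass
class LocusCall:
    accession: str
    locus: str
    status: str
    matched_alleles: list[str] = field(default_factory=list)
    supporting_variants: list[str] = field(default_factory=list)
    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValidationError(f"unknown locus status {self.status!r}")
        if (self.status == "named") != bool(self.matched_alleles):
            raise ValidationError("matched_alleles non-empty iff status == named")


# ---------------------------------------------------------------------------
# Catalog (de)serialization


def _matcher_to_dict(m: VariantMatcher) -> dict:
    d = {"mode": m.mode}
    for k in (
        "chrom",
        "pos",
        "ref",
        "alt",
        "window_start",
        "window_end",
        "min_indel_length",
        "gene_id",
        "hgvs_p",
    ):
        v = getattr(m, k)
        if v is not None:
            d[k] = v
    return d


def catalog_to_json(catalog: Iterable[AlleleDefinition]) -> str:
    alleles = []
    for d in catalog:
        alleles.append(
            {
                "locus": d.locus,
                "name": d.name,
                "synonyms": d.synonyms,
                "allele_class": d.allele_class,
                "zygosity": d.zygosity,
                "matchable": d.matchable,
                **(
                    {"duplication_length": d.duplication_length}
                    if d.duplication_length is not None
                    else {}
                ),
                "components": [_matcher_to_dict(m) for m in d.components],
                "provenance": d.provenance,
            }
        )
    return json.dumps(
        {"schema": "madw-allele-catalog-v1", "alleles": alleles}, indent=2
    )


def catalog_from_json(text: str) -> list[AlleleDefinition]:
    doc = json.loads(text)
    out: list[AlleleDefinition] = []
    names = set()
    for a in doc["alleles"]:
        d = AlleleDefinition(
            locus=a["locus"],
            name=a["name"],
            synonyms=list(a.get("synonyms", [])),
            allele_class=a.get("allele_class", "unknown"),
            zygosity=a.get("zygosity", "hom_alt"),
            matchable=a.get("matchable", True),
            duplication_length=a.get("duplication_length"),
            components=[VariantMatcher(**m) for m in a.get("components", [])],
            provenance=a.get("provenance", ""),
        )
        if d.name in names:
            raise ValidationError(f"duplicate allele name {d.name!r} in catalog")
        names.add(d.name)
        out.append(d)
    return out


def load_catalog(path: str | Path) -> list[AlleleDefinition]:
    return catalog_from_json(Path(path).read_text())


def builtin_catalog() -> list[AlleleDefinition]:
    """The characterized Ma/Dw alleles of the screen, as machine signatures."""
    ref = resources.files("madw.data").joinpath("builtin_catalog.json")
    return catalog_from_json(ref.read_text())


# ---------------------------------------------------------------------------
# Matching


def match_allele(
    genotypes: Mapping[str, int],
    definition: AlleleDefinition,
    variants: Mapping[str, Variant],
    consequences: Mapping[str, ConsequenceRecord],
) -> tuple[str, list[str]]:
    """Match one accession's genotypes against one allele definition.

    Returns (status, supporting variant keys) with status in
    {present_hom, present_het, absent, unknown}.  An unmatchable definition
    (dw3-ref) is always unknown.
    """
    if not definition.matchable:
        return "unknown", []

    component_codes: list[int] = []
    support: list[str] = []
    for comp in definition.components:
        keys = comp.matching_keys(variants, consequences)
        best = MISSING
        best_key = None
        for k in keys:
            code = genotypes.get(k, MISSING)
            if code == HOM_ALT:
                best, best_key = HOM_ALT, k
                break
            if code == HET and best != HET:
                best, best_key = HET, k
            elif code == HOM_REF and best == MISSING:
                best, best_key = HOM_REF, k
        if not keys:
            best = MISSING
        component_codes.append(best)
        if best_key is not None and best in (HET, HOM_ALT):
            support.append(best_key)

    if any(c == HOM_REF for c in component_codes):
        return "absent", []
    if any(c == MISSING for c in component_codes):
        return "unknown", []
    if all(c == HOM_ALT for c in component_codes):
        return "present_hom", support
    return "present_het", support


def call_locus(
    accession: str,
    locus: str,
    catalog: Iterable[AlleleDefinition],
    categories: Mapping[str, str],
    genotypes: Mapping[str, int],
    variants: Mapping[str, Variant],
    consequences: Mapping[str, ConsequenceRecord],
    missingness_threshold: float = DEFAULT_MISSINGNESS_THRESHOLD,
) -> LocusCall:
    """Resolve one accession x locus to a single status.

    `categories` maps variant key -> effect category (from classify);
    `consequences` maps variant key -> ConsequenceRecord.  Interrogated
    sites are the panel variants assigned to this locus.
    """
    defs = [d for d in catalog if d.locus == locus]
    if not defs:
        raise ValidationError(f"locus {locus!r} absent from catalog")

    locus_keys = [k for k, rec in consequences.items() if rec.gene_id == locus]
    n_missing = sum(1 for k in locus_keys if genotypes.get(k, MISSING) == MISSING)
    missing_fraction = n_missing / len(locus_keys) if locus_keys else 0.0

    named: list[str] = []
    het_alleles: list[str] = []
    support: list[str] = []
    for d in defs:
        status, keys = match_allele(genotypes, d, variants, consequences)
        if status == "present_hom":
            named.append(d.name)
            support.extend(keys)
        elif status == "present_het":
            het_alleles.append(d.name)

    if named:
        return LocusCall(
            accession,
            locus,
            "named",
            matched_alleles=sorted(set(named)),
            supporting_variants=sorted(set(support)),
            missing_fraction=missing_fraction,
        )

    hom_del = [
        k
        for k in locus_keys
        if genotypes.get(k, MISSING) == HOM_ALT and is_deleterious(categories[k])
    ]
    if hom_del:
        return LocusCall(
            accession,
            locus,
            "novel_deleterious",
            supporting_variants=sorted(hom_del),
            missing_fraction=missing_fraction,
        )

    het_del = [
        k
        for k in locus_keys
        if genotypes.get(k, MISSING) == HET and is_deleterious(categories[k])
    ]
    if het_alleles or het_del:
        return LocusCall(
            accession,
            locus,
            "heterozygous_carrier",
            supporting_variants=sorted(set(het_del)),
            missing_fraction=missing_fraction,
        )

    if missing_fraction > missingness_threshold:
        return LocusCall(
            accession, locus, "uncharacterized", missing_fraction=missing_fraction
        )
    return LocusCall(accession, locus, "wildtype", missing_fraction=missing_fraction)


def genotype_panel(
    panel: GenotypeMatrix,
    catalog: Iterable[AlleleDefinition],
    categories: Mapping[str, str],
    variants: Mapping[str, Variant],
    consequences: Mapping[str, ConsequenceRecord],
    loci: Optional[list[str]] = None,
    missingness_threshold: float = DEFAULT_MISSINGNESS_THRESHOLD,
) -> list[LocusCall]:
    """One LocusCall per accession x locus."""
    catalog = list(catalog)
    if loci is None:
        loci = sorted({d.locus for d in catalog})
    calls = []
    for acc in panel.accessions:
        genos = panel.accession_calls(acc)
        for locus in loci:
            calls.append(
                call_locus(
                    acc,
                    locus,
                    catalog,
                    categories,
                    genos,
                    variants,
                    consequences,
                    missingness_threshold,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Summaries


@dataclass
class PanelSummary:
    panel_size: int
    status_counts: pd.DataFrame          # locus x status counts
    allele_counts: pd.DataFrame          # locus, allele, count (named hom calls)
    mutant_locus_counts: pd.Series       # accession -> number of mutant loci
    multilocus_report: pd.DataFrame      # accessions with >= k mutant maturity loci

    def to_dict(self) -> dict:
        return {
            "panel_size": self.panel_size,
            "status_counts": {
                locus: {k: int(v) for k, v in row.items()}
                for locus, row in self.status_counts.iterrows()
            },
            "allele_counts": [
                dict(r) for r in self.allele_counts.to_dict(orient="records")
            ],
            "multilocus_report": [
                dict(r) for r in self.multilocus_report.to_dict(orient="records")
            ],
        }


def summarize_panel(
    calls: Iterable[LocusCall],
    min_mutant_loci: int = 4,
    maturity_loci: Optional[set[str]] = None,
) -> PanelSummary:
    """Tabulate per-locus status counts, per-allele counts and the
    multi-locus mutant report.

    "Mutant" at a locus means a named (homozygous) or novel homozygous
    deleterious call; heterozygous carriers are reported but not counted as
    mutant.  The multi-locus report lists accessions with mutant calls at
    >= `min_mutant_loci` maturity loci, with their remaining wildtype loci.
    """
    calls = list(calls)
    loci = sorted({c.locus for c in calls})
    accs = sorted({c.accession for c in calls})
    if maturity_loci is None:
        maturity_loci = {l for l in loci if l.startswith("Ma")}

    rows = pd.DataFrame(
        [
            {"locus": c.locus, "status": c.status, "accession": c.accession}
            for c in calls
        ]
    )
    if rows.empty:
        empty = pd.DataFrame(columns=STATUSES)
        return PanelSummary(
            0,
            empty,
            pd.DataFrame(columns=["locus", "allele", "count"]),
            pd.Series(dtype=int),
            pd.DataFrame(columns=["accession", "mutant_maturity_loci", "wildtype_loci"]),
        )
    status_counts = (
        rows.pivot_table(
            index="locus", columns="status", aggfunc="size", fill_value=0
        )
        .reindex(columns=STATUSES, fill_value=0)
        .reindex(loci, fill_value=0)
    )

    allele_rows = []
    for c in calls:
        for name in c.matched_alleles:
            allele_rows.append({"locus": c.locus, "allele": name})
    allele_counts = (
        pd.DataFrame(allele_rows)
        .groupby(["locus", "allele"])
        .size()
        .reset_index(name="count")
        if allele_rows
        else pd.DataFrame(columns=["locus", "allele", "count"])
    )

    mutant = {
        (c.accession, c.locus)
        for c in calls
        if c.status in {"named", "novel_deleterious"}
    }
    mutant_counts = pd.Series(
        {acc: sum(1 for l in loci if (acc, l) in mutant) for acc in accs}, dtype=int
    )

    report_rows = []
    for acc in accs:
        mut_ma = [l for l in sorted(maturity_loci) if (acc, l) in mutant]
        if len(mut_ma) >= min_mutant_loci:
            wt = [
                c.locus
                for c in calls
                if c.accession == acc and c.status == "wildtype"
            ]
            report_rows.append(
                {
                    "accession": acc,
                    "mutant_maturity_loci": ",".join(mut_ma),
                    "wildtype_loci": ",".join(sorted(wt)),
                }
            )
    report = pd.DataFrame(
        report_rows, columns=["accession", "mutant_maturity_loci", "wildtype_loci"]
    )
    return PanelSummary(len(accs), status_counts, allele_counts, mutant_counts, report)


def export_lollipop_table(
    consequences: Iterable[ConsequenceRecord], model: GeneModel
) -> pd.DataFrame:
    """Per-variant plotting table for lollipop schematics of one locus.

    Glyphs: circle = substitution, triangle_down = insertion, triangle_up =
    deletion, diamond = length-preserving multi-base change.  Color classes:
    missense (incl. in-frame events), nonsense (incl. frameshift and
    start/stop loss), splice (coding variants in a splice-region window).
    """
    rows = []
    for rec in consequences:
        if rec.gene_id != model.gene_id or rec.protein_change is None:
            continue
        pc = rec.protein_change
        chrom, pos, ref, alt = rec.variant_key.rsplit(":", 3)
        if len(alt) > len(ref):
            glyph = "triangle_down"
        elif len(alt) < len(ref):
            glyph = "triangle_up"
        elif len(ref) == 1:
            glyph = "circle"
        else:
            glyph = "diamond"
        if rec.annotation.region == "splice_region":
            color = "splice"
        elif pc.kind in {"nonsense", "frameshift", "start_loss", "stop_loss"}:
            color = "nonsense"
        else:
            color = "missense"
        position = pc.start
        if model.protein_length is not None:
            position = min(position, model.protein_length)
        rows.append(
            {
                "protein_position": position,
                "glyph": glyph,
                "color_class": color,
                "hgvs_p": rec.hgvs_p,
            }
        )
    return pd.DataFrame(
        rows, columns=["protein_position", "glyph", "color_class", "hgvs_p"]
    )
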