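"""End-to-end screen orchestration shared by the CLI and the examples.

`run_screen` wires the stages together: region-restricted VCF reading ->
normalization -> consequence prediction -> effect classification -> panel
genotyping -> summaries, with per-stage record counts that reconcile
exactly (records in = records out + records dropped, per stage).  Outputs
are plain TSV/JSON and byte-stable for identical inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
from pyfaidx import Fasta

from .catalog import (
    AlleleDefinition,
    builtin_catalog,
    export_lollipop_table,
    genotype_panel,
    load_catalog,
    summarize_panel,
)
from .classify import classify_effect, effect_counts, read_scores
from .consequence import TranscriptContext, consequence_table, predict_consequence
from .errors import ValidationError
from .gene_models import GeneModel, load_gene_models
from .phenostats import (
    allele_levels_from_calls,
    fit_allele_means,
    read_phenotypes,
)
from .variant_io import GenotypeMatrix, Variant, read_panel_vcf

log = logging.getLogger("madw")


@dataclass
class ScreenResult:
    variants: list[Variant]
    matrix: GenotypeMatrix
    consequences: dict
    categories: dict[str, str]
    calls: list
    summary: object
    counts: dict[str, int] = field(default_factory=dict)


def load_reference(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def run_screen(
    vcf: str | Path,
    gff3: str | Path,
    fasta: str | Path,
    scores: Optional[str | Path] = None,
    catalog_path: Optional[str | Path] = None,
    score_threshold: float = 0.05,
    missingness_threshold: float = 0.5,
    min_mutant_loci: int = 4,
    outdir: Optional[str | Path] = None,
) -> ScreenResult:
    """Run the full screen; write TSV/JSON outputs when `outdir` is given."""
    for p in (vcf, gff3, fasta):
        if not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")
    models = load_gene_models(gff3)
    if not models:
        raise ValidationError(f"{gff3}: no gene models found")
    reference = load_reference(fasta)
    catalog = load_catalog(catalog_path) if catalog_path else builtin_catalog()
    score_map = read_scores(scores) if scores else {}

    regions = [m.span for m in models.values()]
    variants, matrix = read_panel_vcf(vcf, regions, reference=reference)
    log.info("stage=read records_in_region=%d accessions=%d", len(variants), len(matrix.accessions))

    ctxs = {
        gid: TranscriptContext(m, reference[m.chrom]) for gid, m in models.items()
    }
    consequences = {}
    dropped = 0
    for v in variants:
        hit = None
        for gid, m in models.items():
            if m.chrom == v.chrom and m.span.start <= v.end and v.pos <= m.span.end:
                hit = gid
                break
        if hit is None:
            dropped += 1
            continue
        consequences[v.key] = predict_consequence(
            models[hit], reference[models[hit].chrom], v, ctxs[hit]
        )
    log.info("stage=consequence annotated=%d dropped=%d", len(consequences), dropped)

    categories = {
        k: classify_effect(rec, score_map.get(k), score_threshold)
        for k, rec in consequences.items()
    }
    vmap = {v.key: v for v in variants}
    calls = genotype_panel(
        matrix,
        catalog,
        categories,
        vmap,
        consequences,
        loci=sorted(models),
        missingness_threshold=missingness_threshold,
    )
    summary = summarize_panel(calls, min_mutant_loci=min_mutant_loci)
    counts = {
        "records_in_region": len(variants),
        "accessions": len(matrix.accessions),
        "annotated": len(consequences),
        "dropped_no_gene": dropped,
        "classified": len(categories),
        "locus_calls": len(calls),
    }
    assert counts["annotated"] + counts["dropped_no_gene"] == counts["records_in_region"]

    result = ScreenResult(
        variants, matrix, consequences, categories, calls, summary, counts
    )
    if outdir is not None:
        write_screen_outputs(result, models, score_map, Path(outdir))
    return result


def write_screen_outputs(
    result: ScreenResult,
    models: Mapping[str, GeneModel],
    score_map: Mapping,
    outdir: Path,
) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    tbl = consequence_table(list(result.consequences.values()))
    tbl["category"] = [result.categories[k] for k in tbl["variant_id"]]
    paths["consequences"] = outdir / "consequences.tsv"
    tbl.to_csv(paths["consequences"], sep="\t", index=False)

    call_rows = pd.DataFrame(
        [
            {
                "accession": c.accession,
                "locus": c.locus,
                "status": c.status,
                "matched_alleles": ",".join(c.matched_alleles),
                "supporting_variants": ",".join(c.supporting_variants),
                "missing_fraction": round(c.missing_fraction, 4),
            }
            for c in result.calls
        ]
    )
    paths["locus_calls"] = outdir / "locus_calls.tsv"
    call_rows.to_csv(paths["locus_calls"], sep="\t", index=False)

    paths["summary"] = outdir / "panel_summary.json"
    paths["summary"].write_text(json.dumps(result.summary.to_dict(), indent=1, sort_keys=True))

    counts_tbl = effect_counts(result.consequences.values(), score_map)
    paths["effect_counts"] = outdir / "effect_counts.tsv"
    counts_tbl.to_csv(paths["effect_counts"], sep="\t", index=False)

    lolli = []
    for gid, model in sorted(models.items()):
        t = export_lollipop_table(result.consequences.values(), model)
        t.insert(0, "gene_id", gid)
        lolli.append(t)
    paths["lollipop"] = outdir / "lollipop.tsv"
    pd.concat(lolli, ignore_index=True).to_csv(paths["lollipop"], sep="\t", index=False)

    paths["counts"] = outdir / "stage_counts.json"
    paths["counts"].write_text(json.dumps(result.counts, indent=1, sort_keys=True))
    return paths


def run_associate(
    calls,
    phenotype_path: str | Path,
    loci: list[str],
    alpha: float = 0.05,
    outdir: Optional[str | Path] = None,
) -> dict:
    """Per-locus association of allele levels with each trait."""
    pheno = read_phenotypes(phenotype_path)
    results = []
    for trait, sub in pheno.groupby("trait"):
        values = dict(zip(sub["accession"], sub["value"]))
        for locus in loci:
            levels = allele_levels_from_calls(calls, locus)
            shared = [a for a in levels if a in values]
            if not shared:
                raise ValidationError(
                    f"no overlapping accessions between locus calls and phenotypes "
                    f"for {locus}/{trait}"
                )
            try:
                res = fit_allele_means(
                    [values[a] for a in shared],
                    [levels[a] for a in shared],
                    locus=locus,
                    trait=str(trait),
                    alpha=alpha,
                )
            except ValidationError as exc:
                log.warning("associate %s/%s skipped: %s", locus, trait, exc)
                continue
            results.append(res)
    report = {"alpha": alpha, "results": [r.to_dict() for r in results]}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "association.json").write_text(
            json.dumps(report, indent=1, sort_keys=True)
        )
        rows = []
        for r in results:
            for rec in r.coefficients.to_dict(orient="records"):
                rows.append({"locus": r.locus, "trait": r.trait, **rec})
        pd.DataFrame(rows).to_csv(outdir / "association.tsv", sep="\t", index=False)
    return report
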