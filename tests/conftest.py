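import numpy as np
import pytest

from madw import (
    GeneModel,
    GenomicInterval,
    SimulationConfig,
    builtin_catalog,
    classify_effect,
    simulate_panel,
    simulate_reference,
)


@pytest.fixture(scope="session")
def toy_plus() -> GeneModel:
    """Two-exon + strand gene: exon1 101-200 (all CDS), exon2 301-400."""
    return GeneModel(
        gene_id="toyP",
        chrom="chr1",
        strand="+",
        span=GenomicInterval("chr1", 101, 400),
        exons=[GenomicInterval("chr1", 101, 200), GenomicInterval("chr1", 301, 400)],
        cds_start=101,
        cds_end=400,
    )


@pytest.fixture(scope="session")
def toy_minus() -> GeneModel:
    """Mirror of toy_plus on the - strand."""
    return GeneModel(
        gene_id="toyM",
        chrom="chr1",
        strand="-",
        span=GenomicInterval("chr1", 101, 400),
        exons=[GenomicInterval("chr1", 101, 200), GenomicInterval("chr1", 301, 400)],
        cds_start=101,
        cds_end=400,
    )


@pytest.fixture(scope="session")
def sim_small():
    """A small clean simulated panel (no missingness, no hets) with truth."""
    cfg = SimulationConfig(seed=2021, n_accessions=80)
    reference, models = simulate_reference(cfg)
    panel = simulate_panel(cfg, reference, models)
    categories = {
        k: classify_effect(rec, panel.scores.get(k))
        for k, rec in panel.consequences.items()
    }
    return {
        "config": cfg,
        "reference": reference,
        "models": models,
        "panel": panel,
        "categories": categories,
        "catalog": builtin_catalog(),
    }
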