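"""Allele catalog content, signature matching and locus-call precedence."""

import numpy as np
import pytest

from madw import (
    AlleleDefinition,
    ValidationError,
    VariantMatcher,
    builtin_catalog,
    call_locus,
    catalog_from_json,
    catalog_to_json,
    export_lollipop_table,
    genotype_panel,
    match_allele,
    summarize_panel,
)
from madw.catalog import LocusCall
from madw.variant_io import HET, HOM_ALT, HOM_REF, MISSING, Variant
from madw.consequence import ConsequenceRecord
from madw.gene_models import PositionAnnotation
from madw.hgvs import ProteinChange, parse_hgvs_p


class TestBuiltinCatalog:
    def test_ma1_has_seven_characterized_alleles(self):
        assert sum(1 for d in builtin_catalog() if d.locus == "Ma1") == 7

    def test_dw3_has_three_characterized_alleles(self):
        assert sum(1 for d in builtin_catalog() if d.locus == "Dw3") == 3

    def test_sbprr37_3_is_a_two_component_compound(self):
        d = next(x for x in builtin_catalog() if x.name == "Sbprr37-3")
        assert len(d.components) == 2
        hgvs = {c.hgvs_p for c in d.components}
        assert hgvs == {"p.(Gln270Ter)", "p.(Lys184Asn)"}

    def test_dw3_ref_is_metadata_only(self):
        d = next(x for x in builtin_catalog() if x.name == "dw3-ref")
        assert not d.matchable
        assert d.duplication_length == 882

    def test_sbghd7_2_uses_the_only_window_matcher(self):
        windows = [
            c
            for d in builtin_catalog()
            for c in d.components
            if c.mode == "coordinate" and c.is_window
        ]
        assert len(windows) == 1
        w = windows[0]
        assert (w.window_start, w.window_end) == (698150, 698185)
        assert w.min_indel_length == 10

    def test_every_locus_present(self):
        loci = {d.locus for d in builtin_catalog()}
        assert loci == {"Ma1", "Ma2", "Ma3", "Ma5", "Ma6", "Dw1", "Dw2", "Dw3"}

    def test_json_round_trip_is_lossless(self):
        cat = builtin_catalog()
        again = catalog_from_json(catalog_to_json(cat))
        assert again == cat


def _consequence(key, gene, hgvs):
    pc = parse_hgvs_p(hgvs)
    return ConsequenceRecord(
        variant_key=key,
        gene_id=gene,
        annotation=PositionAnnotation(region="cds"),
        protein_change=pc,
        hgvs_p=hgvs,
    )


@pytest.fixture
def tiny_locus():
    """A hand-built locus with a simple and a compound allele."""
    v1 = Variant("c1", 100, "A", "G")   # Lys10Asn-like
    v2 = Variant("c1", 200, "C", "T")   # Gln20Ter-like
    v3 = Variant("c1", 300, "G", "T")   # novel nonsense
    variants = {v.key: v for v in (v1, v2, v3)}
    consequences = {
        v1.key: _consequence(v1.key, "LocX", "p.(Lys10Asn)"),
        v2.key: _consequence(v2.key, "LocX", "p.(Gln20Ter)"),
        v3.key: _consequence(v3.key, "LocX", "p.(Trp30Ter)"),
    }
    categories = {
        v1.key: "deleterious_missense",
        v2.key: "nonsense",
        v3.key: "nonsense",
    }
    simple = AlleleDefinition(
        locus="LocX",
        name="locx-1",
        components=[VariantMatcher(mode="consequence", gene_id="LocX", hgvs_p="p.(Lys10Asn)")],
    )
    compound = AlleleDefinition(
        locus="LocX",
        name="locx-2",
        components=[
            VariantMatcher(mode="consequence", gene_id="LocX", hgvs_p="p.(Lys10Asn)"),
            VariantMatcher(mode="consequence", gene_id="LocX", hgvs_p="p.(Gln20Ter)"),
        ],
    )
    return {
        "variants": variants,
        "consequences": consequences,
        "categories": categories,
        "catalog": [simple, compound],
        "keys": (v1.key, v2.key, v3.key),
    }


class TestMatchAllele:
    def test_all_components_hom_is_present_hom(self, tiny_locus):
        k1, k2, _ = tiny_locus["keys"]
        d = tiny_locus["catalog"][1]
        status, support = match_allele(
            {k1: HOM_ALT, k2: HOM_ALT},
            d,
            tiny_locus["variants"],
            tiny_locus["consequences"],
        )
        assert status == "present_hom"
        assert set(support) == {k1, k2}

    def test_het_component_is_present_het_not_the_allele(self, tiny_locus):
        k1, k2, _ = tiny_locus["keys"]
        d = tiny_locus["catalog"][1]
        status, _ = match_allele(
            {k1: HOM_ALT, k2: HET},
            d,
            tiny_locus["variants"],
            tiny_locus["consequences"],
        )
        assert status == "present_het"

    def test_missing_component_genotype_is_unknown(self, tiny_locus):
        k1, k2, _ = tiny_locus["keys"]
        d = tiny_locus["catalog"][1]
        status, _ = match_allele(
            {k1: HOM_ALT, k2: MISSING},
            d,
            tiny_locus["variants"],
            tiny_locus["consequences"],
        )
        assert status == "unknown"

    def test_hom_ref_component_is_absent_even_with_missing_elsewhere(self, tiny_locus):
        k1, k2, _ = tiny_locus["keys"]
        d = tiny_locus["catalog"][1]
        status, _ = match_allele(
            {k1: HOM_REF, k2: MISSING},
            d,
            tiny_locus["variants"],
            tiny_locus["consequences"],
        )
        assert status == "absent"

    def test_unmatchable_allele_always_unknown(self):
        d = next(x for x in builtin_catalog() if x.name == "dw3-ref")
        assert match_allele({}, d, {}, {})[0] == "unknown"

    def test_hgvs_matching_ignores_parentheses(self, tiny_locus):
        k1, *_ = tiny_locus["keys"]
        bare = AlleleDefinition(
            locus="LocX",
            name="bare",
            components=[VariantMatcher(mode="consequence", gene_id="LocX", hgvs_p="p.Lys10Asn")],
        )
        status, _ = match_allele(
            {k1: HOM_ALT}, bare, tiny_locus["variants"], tiny_locus["consequences"]
        )
        assert status == "present_hom"

    def test_window_matcher_requires_min_indel_length(self):
        w = VariantMatcher(
            mode="coordinate",
            chrom="c1",
            window_start=90,
            window_end=110,
            min_indel_length=10,
        )
        small = Variant("c1", 100, "A", "AGG")        # 2 bp
        big = Variant("c1", 100, "A", "A" + "G" * 12)  # 12 bp
        variants = {small.key: small, big.key: big}
        assert w.matching_keys(variants, {}) == [big.key]


class TestCallLocus:
    def _call(self, tiny, genotypes, threshold=0.5):
        return call_locus(
            "acc",
            "LocX",
            tiny["catalog"],
            tiny["categories"],
            genotypes,
            tiny["variants"],
            tiny["consequences"],
            missingness_threshold=threshold,
        )

    def test_named_beats_novel(self, tiny_locus):
        k1, k2, k3 = tiny_locus["keys"]
        c = self._call(tiny_locus, {k1: HOM_ALT, k2: HOM_REF, k3: HOM_ALT})
        assert c.status == "named"
        assert c.matched_alleles == ["locx-1"]

    def test_compound_lists_all_matched_names(self, tiny_locus):
        k1, k2, k3 = tiny_locus["keys"]
        c = self._call(tiny_locus, {k1: HOM_ALT, k2: HOM_ALT, k3: HOM_REF})
        assert c.status == "named"
        assert c.matched_alleles == ["locx-1", "locx-2"]

    def test_uncataloged_hom_deleterious_is_novel(self, tiny_locus):
        k1, k2, k3 = tiny_locus["keys"]
        c = self._call(tiny_locus, {k1: HOM_REF, k2: HOM_REF, k3: HOM_ALT})
        assert c.status == "novel_deleterious"
        assert c.supporting_variants == [k3]

    def test_het_deleterious_is_carrier(self, tiny_locus):
        k1, k2, k3 = tiny_locus["keys"]
        c = self._call(tiny_locus, {k1: HOM_REF, k2: HOM_REF, k3: HET})
        assert c.status == "heterozygous_carrier"

    def test_all_sites_missing_is_uncharacterized(self, tiny_locus):
        k1, k2, k3 = tiny_locus["keys"]
        c = self._call(tiny_locus, {k1: MISSING, k2: MISSING, k3: MISSING})
        assert c.status == "uncharacterized"
        assert c.missing_fraction == 1.0

    def test_full_data_no_alt_is_wildtype(self, tiny_locus):
        k1, k2, k3 = tiny_locus["keys"]
        c = self._call(tiny_locus, {k1: HOM_REF, k2: HOM_REF, k3: HOM_REF})
        assert c.status == "wildtype"

    def test_unknown_locus_is_an_error(self, tiny_locus):
        with pytest.raises(ValidationError):
            call_locus(
                "acc",
                "NoSuchLocus",
                tiny_locus["catalog"],
                tiny_locus["categories"],
                {},
                tiny_locus["variants"],
                tiny_locus["consequences"],
            )

    def test_precedence_stable_under_variant_permutation(self, tiny_locus):
        k1, k2, k3 = tiny_locus["keys"]
        genos = {k1: HOM_ALT, k2: HET, k3: HET}
        base = self._call(tiny_locus, genos)
        for _ in range(5):
            items = list(genos.items())
            np.random.default_rng(1).shuffle(items)
            again = self._call(tiny_locus, dict(items))
            assert again.status == base.status


class TestPanelOperations:
    def test_every_accession_locus_pair_has_exactly_one_status(self, sim_small):
        panel = sim_small["panel"]
        calls = genotype_panel(
            panel.matrix,
            panel.catalog,
            sim_small["categories"],
            {v.key: v for v in panel.variants},
            panel.consequences,
            loci=sorted(sim_small["models"]),
        )
        assert len(calls) == len(panel.matrix.accessions) * 8
        seen = {(c.accession, c.locus) for c in calls}
        assert len(seen) == len(calls)

    def test_empty_panel_yields_empty_table(self, sim_small):
        from madw.variant_io import GenotypeMatrix

        panel = sim_small["panel"]
        empty = GenotypeMatrix.empty()
        calls = genotype_panel(
            empty,
            panel.catalog,
            sim_small["categories"],
            {v.key: v for v in panel.variants},
            panel.consequences,
        )
        assert calls == []

    def test_status_counts_sum_to_panel_size(self, sim_small):
        panel = sim_small["panel"]
        calls = genotype_panel(
            panel.matrix,
            panel.catalog,
            sim_small["categories"],
            {v.key: v for v in panel.variants},
            panel.consequences,
            loci=sorted(sim_small["models"]),
        )
        summary = summarize_panel(calls)
        n = len(panel.matrix.accessions)
        assert (summary.status_counts.sum(axis=1) == n).all()

    def test_multilocus_report_flags_four_of_five_maturity_mutant(self):
        """An accession mutant at 4 of the 5 maturity loci appears in the
        k=4 report with its remaining wildtype locus identified."""
        loci = ["Ma1", "Ma2", "Ma3", "Ma5", "Ma6", "Dw1"]
        calls = []
        for locus in loci:
            status = "wildtype" if locus in ("Ma2", "Dw1") else "named"
            calls.append(
                LocusCall(
                    accession="PI_533839x",
                    locus=locus,
                    status=status,
                    matched_alleles=["a-" + locus] if status == "named" else [],
                )
            )
            calls.append(LocusCall(accession="other", locus=locus, status="wildtype"))
        summary = summarize_panel(calls, min_mutant_loci=4)
        report = summary.multilocus_report
        assert list(report["accession"]) == ["PI_533839x"]
        assert "Ma2" in report.iloc[0]["wildtype_loci"]
        assert "Dw1" in report.iloc[0]["wildtype_loci"]


class TestLollipopExport:
    def test_rows_glyphs_and_bounds(self, sim_small):
        panel = sim_small["panel"]
        models = sim_small["models"]
        for gid, model in models.items():
            tbl = export_lollipop_table(panel.consequences.values(), model)
            if tbl.empty:
                continue
            assert (tbl["protein_position"] >= 1).all()
            assert (tbl["protein_position"] <= model.protein_length).all()
            assert set(tbl["glyph"]) <= {
                "circle",
                "triangle_down",
                "triangle_up",
                "diamond",
            }
            assert set(tbl["color_class"]) <= {"missense", "nonsense", "splice"}

    def test_nonsense_snp_is_a_circle_in_the_nonsense_class(self, sim_small):
        panel = sim_small["panel"]
        models = sim_small["models"]
        rows = []
        for gid, model in models.items():
            tbl = export_lollipop_table(panel.consequences.values(), model)
            rows.extend(tbl.to_dict(orient="records"))
        nonsense_circles = [
            r for r in rows if r["glyph"] == "circle" and r["color_class"] == "nonsense"
        ]
        assert nonsense_circles  # planted nonsense SNPs exist in every panel

    def test_insertions_point_down(self, sim_small):
        panel = sim_small["panel"]
        model = sim_small["models"]["Ma6"]
        tbl = export_lollipop_table(panel.consequences.values(), model)
        ins = tbl[tbl["glyph"] == "triangle_down"]
        # Sbghd7-1 is planted as a 5-bp insertion in Ma6
        assert len(ins) >= 1
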