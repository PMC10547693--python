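"""Synthetic reference/panel generator: determinism, structural invariants,
planting contracts and ground-truth consistency."""

import numpy as np
import pytest
import scipy.stats as sps

from madw import (
    ProteinChange,
    SimulationConfig,
    ValidationError,
    builtin_catalog,
    default_allele_frequencies,
    plant_variant,
    simulate_panel,
    simulate_phenotypes,
    simulate_reference,
    translate_cds,
)
from madw.synthetic import PlantError, PlantTarget
from madw.consequence import TranscriptContext
from madw.variant_io import HOM_ALT, MISSING


class TestSimulateReference:
    def test_same_seed_is_byte_identical(self):
        cfg = SimulationConfig(seed=5, n_accessions=10)
        r1, m1 = simulate_reference(cfg)
        r2, m2 = simulate_reference(cfg)
        assert r1 == r2
        assert all(
            [(e.start, e.end) for e in m1[g].exons]
            == [(e.start, e.end) for e in m2[g].exons]
            for g in m1
        )

    def test_gene_structure_matches_characterized_loci(self, sim_small):
        models = sim_small["models"]
        assert models["Ma1"].protein_length == 739
        assert models["Ma1"].exon_count == 8
        assert models["Dw3"].strand == "-"
        assert models["Dw2"].strand == "-"

    def test_cds_translates_to_expected_protein_length(self, sim_small):
        for gid, model in sim_small["models"].items():
            seq = sim_small["reference"][model.chrom]
            cds = model.cds_sequence(seq)
            assert len(cds) == 3 * (model.protein_length + 1)
            protein, stop = translate_cds(cds)
            assert stop
            assert len(protein) == model.protein_length

    def test_all_splice_dinucleotides_are_gt_ag(self, sim_small):
        from madw.gene_models import revcomp

        for gid, model in sim_small["models"].items():
            seq = sim_small["reference"][model.chrom]
            for intron in model.introns:
                s = seq[intron.start - 1 : intron.end]
                if model.strand == "-":
                    s = revcomp(s)
                assert s[:2] == "GT" and s[-2:] == "AG"

    def test_infeasible_intron_length_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(seed=1, intron_length_range=(5, 10))

    def test_seed_is_mandatory(self):
        with pytest.raises((ValidationError, TypeError)):
            SimulationConfig(seed=None)


class TestPlantVariant:
    def test_missense_target_reproduced_exactly(self, sim_small):
        model = sim_small["models"]["Ma2"]
        seq = sim_small["reference"][model.chrom]
        ctx = TranscriptContext(model, seq)
        pos = 50
        aa = ctx.ref_protein[pos - 1]
        alt = "W" if aa != "W" else "R"
        v, rec = plant_variant(
            model,
            seq,
            PlantTarget(
                protein_change=ProteinChange("missense", pos, ref_aa=aa, alt_aa=alt)
            ),
            np.random.default_rng(0),
            ctx,
        )
        assert rec.protein_change.kind == "missense"
        assert rec.protein_change.start == pos
        assert rec.protein_change.alt_aa == alt

    def test_nonsense_target_reproduced(self, sim_small):
        model = sim_small["models"]["Dw1"]
        seq = sim_small["reference"][model.chrom]
        ctx = TranscriptContext(model, seq)
        aa = ctx.ref_protein[198]
        v, rec = plant_variant(
            model,
            seq,
            PlantTarget(protein_change=ProteinChange("nonsense", 199, ref_aa=aa)),
            np.random.default_rng(0),
            ctx,
        )
        assert rec.protein_change == ProteinChange("nonsense", 199, ref_aa=aa)

    def test_target_beyond_protein_length_is_an_error(self, sim_small):
        model = sim_small["models"]["Ma6"]  # 246 aa
        seq = sim_small["reference"][model.chrom]
        with pytest.raises(PlantError):
            plant_variant(
                model,
                seq,
                PlantTarget(
                    protein_change=ProteinChange("nonsense", 500, ref_aa="Q")
                ),
                np.random.default_rng(0),
            )

    def test_wrong_reference_residue_is_an_error(self, sim_small):
        model = sim_small["models"]["Ma6"]
        seq = sim_small["reference"][model.chrom]
        ctx = TranscriptContext(model, seq)
        aa = ctx.ref_protein[49]
        wrong = "K" if aa != "K" else "L"
        with pytest.raises(PlantError):
            plant_variant(
                model,
                seq,
                PlantTarget(
                    protein_change=ProteinChange(
                        "missense", 50, ref_aa=wrong, alt_aa="A"
                    )
                ),
                np.random.default_rng(0),
                ctx,
            )

    def test_splice_region_target(self, sim_small):
        model = sim_small["models"]["Ma1"]
        seq = sim_small["reference"][model.chrom]
        v, rec = plant_variant(
            model,
            seq,
            PlantTarget(region="splice_region", intron_index=1, intron_offset=4),
            np.random.default_rng(0),
        )
        assert rec.noncoding_label == "splice_region"


class TestSimulatePanel:
    def test_same_seed_gives_identical_panels(self, sim_small):
        cfg = sim_small["config"]
        p2 = simulate_panel(cfg, sim_small["reference"], sim_small["models"])
        p1 = sim_small["panel"]
        assert [v.key for v in p1.variants] == [v.key for v in p2.variants]
        assert (p1.matrix.calls == p2.matrix.calls).all()
        assert p1.manifest.to_json() == p2.manifest.to_json()

    def test_zero_missingness_means_no_missing_cells(self, sim_small):
        assert (sim_small["panel"].matrix.calls != MISSING).all()

    def test_scores_concordant_with_truth_categories(self, sim_small):
        panel = sim_small["panel"]
        for key, truth in panel.manifest.variants.items():
            if truth["score_band"] == "deleterious":
                assert panel.scores[key].score < 0.05
            elif truth["score_band"] == "tolerated":
                assert panel.scores[key].score >= 0.05

    def test_frequency_zero_allele_absent_from_all_genotypes(self):
        cfg = SimulationConfig(seed=3, n_accessions=60)
        reference, models = simulate_reference(cfg)
        freqs = default_allele_frequencies(builtin_catalog())
        freqs["dw1"] = 0.0
        cfg2 = SimulationConfig(seed=3, n_accessions=60, allele_frequencies=freqs)
        panel = simulate_panel(cfg2, reference, models)
        named = [
            d["allele"]
            for acc in panel.manifest.locus_status.values()
            for d in acc.values()
            if d["status"] == "named"
        ]
        assert "dw1" not in named

    def test_unknown_allele_in_frequency_map_rejected(self):
        cfg = SimulationConfig(
            seed=3, n_accessions=10, allele_frequencies={"no-such-allele": 0.1}
        )
        reference, models = simulate_reference(SimulationConfig(seed=3))
        with pytest.raises(ValidationError):
            simulate_panel(cfg, reference, models)

    def test_carrier_count_within_99pct_binomial_interval(self):
        """Frequency 0.3 for dw1, n = 1000: hom carriers of the dw1 signature
        fall inside the central 99% binomial interval."""
        freq = 0.30
        n = 1000
        freqs = {"dw1": freq}
        cfg = SimulationConfig(seed=17, n_accessions=n, allele_frequencies=freqs)
        reference, models = simulate_reference(cfg)
        panel = simulate_panel(cfg, reference, models)
        carriers = sum(
            1
            for acc in panel.manifest.locus_status.values()
            if acc["Dw1"]["status"] == "named" and acc["Dw1"]["allele"] == "dw1"
        )
        lo = sps.binom.ppf(0.005, n, freq)
        hi = sps.binom.ppf(0.995, n, freq)
        assert lo <= carriers <= hi

    def test_het_rate_produces_heterozygous_carriers(self):
        cfg = SimulationConfig(seed=23, n_accessions=200, het_rate=0.5)
        reference, models = simulate_reference(cfg)
        panel = simulate_panel(cfg, reference, models)
        statuses = [
            d["status"]
            for acc in panel.manifest.locus_status.values()
            for d in acc.values()
        ]
        assert "heterozygous_carrier" in statuses
        # het carriers have het calls at their signature sites
        assert (panel.matrix.calls == 1).any()

    def test_manifest_covers_every_variant_and_accession(self, sim_small):
        panel = sim_small["panel"]
        assert set(panel.manifest.variants) == {v.key for v in panel.variants}
        assert set(panel.manifest.locus_status) == set(panel.matrix.accessions)
        for acc in panel.manifest.locus_status.values():
            assert set(acc) == {"Ma1", "Ma2", "Ma3", "Ma5", "Ma6", "Dw1", "Dw2", "Dw3"}


class TestSimulatePhenotypes:
    def _effects(self):
        eff = {d.name: (-50.0 if d.locus.startswith("Dw") else -12.0)
               for d in builtin_catalog() if d.matchable}
        eff["novel"] = -25.0
        return eff

    def test_sigma_zero_gives_exact_additive_values(self, sim_small):
        panel = sim_small["panel"]
        df = simulate_phenotypes(panel.manifest, self._effects(), sigma=0.0, seed=1)
        for row in df.itertuples(index=False):
            assert row.value == panel.manifest.phenotype_expectation[row.accession]

    def test_same_seed_identical_table(self, sim_small):
        panel = sim_small["panel"]
        a = simulate_phenotypes(panel.manifest, self._effects(), sigma=4.0, seed=9)
        b = simulate_phenotypes(panel.manifest, self._effects(), sigma=4.0, seed=9)
        assert a.equals(b)

    def test_missing_effect_for_planted_allele_is_an_error(self, sim_small):
        panel = sim_small["panel"]
        with pytest.raises(ValidationError):
            simulate_phenotypes(panel.manifest, {"novel": -25.0}, sigma=0.0, seed=1)

    def test_end_to_end_dwarf_effect_recovered_within_two_se(self, sim_small):
        """Screen the synthetic panel, group accessions by Dw1 status and
        recover the planted -50 cm height effect."""
        from madw import fit_allele_means, genotype_panel
        from madw.phenostats import allele_levels_from_calls

        panel = sim_small["panel"]
        pheno = simulate_phenotypes(panel.manifest, self._effects(), sigma=10.0, seed=4)
        calls = genotype_panel(
            panel.matrix,
            panel.catalog,
            sim_small["categories"],
            {v.key: v for v in panel.variants},
            panel.consequences,
            loci=["Dw1"],
        )
        levels = allele_levels_from_calls(calls, "Dw1")
        values = dict(zip(pheno["accession"], pheno["value"]))
        # isolate the Dw1 contrast: subtract each accession's expected
        # contribution from the other loci
        adjusted = {}
        eff = self._effects()
        for acc, lvl in levels.items():
            other = sum(
                eff[d["allele"]] if d["status"] == "named" else
                (eff["novel"] if d["status"] == "novel_deleterious" else 0.0)
                for locus, d in panel.manifest.locus_status[acc].items()
                if locus != "Dw1"
            )
            adjusted[acc] = values[acc] - other
        res = fit_allele_means(
            [adjusted[a] for a in levels], [levels[a] for a in levels], locus="Dw1"
        )
        coef = res.coefficients.set_index("level")
        assert "dw1" in coef.index
        est, se = coef.loc["dw1", "estimate"], coef.loc["dw1", "se"]
        assert abs(est - (-50.0)) < 2 * se
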