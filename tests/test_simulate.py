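"""Synthetic scenario generator: determinism, planted truth, recovery."""

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

from glutenquant import epitopes, quantitation, simulate
from glutenquant.digestion import DigestionRules, digest
from glutenquant.simulate import (
    ScenarioConfig,
    generate_proteome,
    generate_quant,
    generate_scenario,
    paper_scenario,
    truth_aggregates,
)


def recover(run):
    """Pipeline compute path (in memory): areas -> normalize -> ratios."""
    table = quantitation.validate_quant_table(run.quant)
    norm = quantitation.normalize(quantitation.peptide_area(table))
    alloc = dict(zip(run.manifest.peptide_truth["sequence"],
                     run.manifest.peptide_truth["group"]))
    groups = quantitation.group_abundance(norm, alloc)
    net = quantitation.net_gluten_ratio(groups)
    matches = epitopes.find_epitopes(list(norm.values.index), run.epitopes)
    cats = epitopes.category_abundance(matches, norm)
    return net, groups, cats


class TestGenerateProteome:
    def test_default_config_cardinality(self):
        """One background protein per family -> 7 proteins, 7 overrides."""
        proteome = generate_proteome(ScenarioConfig(seed=5))
        assert len(proteome.proteins) == 7
        assert len(proteome.overrides) == 7

    def test_same_seed_is_byte_identical(self, tmp_path):
        a = generate_scenario(paper_scenario(11))
        b = generate_scenario(paper_scenario(11))
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        for name in ("proteome.fasta", "quant.csv", "overrides.tsv",
                     "epitopes.tsv", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        a = generate_proteome(paper_scenario(1))
        b = generate_proteome(paper_scenario(2))
        assert [p.sequence for p in a.proteins] != [p.sequence for p in b.proteins]

    def test_wdeia_epitope_planted_in_omega_carrier(self, paper_run):
        carriers = [p for p in paper_run.proteome.proteins
                    if "QILQQQLIPC" in p.sequence]
        assert len(carriers) == 1
        assert carriers[0].group == "omega_gliadin"
        assert "QQQQQQQQILQQILQQQLIPCR" in carriers[0].sequence

    def test_monitored_tryptic_peptides_are_digest_products(self, paper_run):
        by_id = {p.id: p.sequence for p in paper_run.proteome.proteins}
        rules = DigestionRules.trypsin()
        for m in paper_run.proteome.monitored[:30]:
            if m.protease != "trypsin":
                continue
            products = {p for p, _, _ in digest(by_id[m.protein_id], rules)}
            assert m.sequence in products

    def test_monitored_peptides_map_uniquely(self, paper_run):
        seqs = [p.sequence for p in paper_run.proteome.proteins]
        for m in paper_run.proteome.monitored:
            assert sum(m.sequence in s for s in seqs) == 1

    def test_category_composition_matches_design(self, paper_run):
        pt = paper_run.manifest.peptide_truth
        counts = {c: int(pt["categories"].str.contains(c).sum())
                  for c in ("CD_HLA_DQ", "BA", "WA", "WDEIA")}
        assert counts == {"CD_HLA_DQ": 25, "BA": 12, "WA": 10, "WDEIA": 1}


class TestPlantedTruth:
    def test_paper_targets_planted_exactly(self, paper_run):
        m = paper_run.manifest
        assert m.net_gluten_ratio == pytest.approx(0.67, abs=1e-9)
        assert m.category_ratios["CD_HLA_DQ"] == pytest.approx(0.67, abs=1e-9)
        assert m.category_ratios["BA"] == pytest.approx(1.80, abs=1e-9)
        assert m.category_ratios["WA"] == pytest.approx(3.79, abs=1e-9)
        assert m.category_ratios["WDEIA"] == pytest.approx(0.177, abs=1e-9)
        assert m.category_ratios["ALLERGY_TOTAL"] == pytest.approx(1.535, abs=1e-9)

    def test_group_directionality(self, paper_run):
        g = paper_run.manifest.group_ratios
        assert g["hmw_gs"] > 1 and g["ati"] > 1
        assert g["lmw_gs"] < 1 and g["alpha_gliadin"] < 1
        assert g["gamma_gliadin"] < 1 and g["alp"] < 1
        assert g["omega_gliadin"] == pytest.approx(1.0, abs=1e-9)

    def test_manifest_self_consistency(self, paper_run):
        """Recomputing every aggregate from per-peptide truth reproduces
        the stored ratios to 1e-12."""
        m = paper_run.manifest
        groups, net, cats = truth_aggregates(m.peptide_truth)
        assert net == pytest.approx(m.net_gluten_ratio, abs=1e-12)
        for k, v in m.group_ratios.items():
            assert groups[k] == pytest.approx(v, abs=1e-12)
        for k, v in m.category_ratios.items():
            assert cats[k] == pytest.approx(v, abs=1e-12)

    def test_doubling_gw_truth_doubles_gw_sums(self, paper_run):
        pt = paper_run.manifest.peptide_truth
        doubled = pt.assign(true_gw=pt["true_gw"] * 2)
        a = pt.groupby("group")["true_gw"].sum()
        b = doubled.groupby("group")["true_gw"].sum()
        assert np.allclose(b, 2 * a)


class TestRecovery:
    def test_zero_noise_recovers_all_planted_ratios_exactly(self):
        cfg = dataclasses.replace(paper_scenario(3), peptide_cv=0.0)
        run = generate_scenario(cfg)
        net, groups, cats = recover(run)
        assert net == pytest.approx(67.0, rel=1e-9)
        for g, planted in run.manifest.group_ratios.items():
            assert groups.loc[g, "ratio_gw_mw"] == pytest.approx(planted, rel=1e-9)
        for c, planted in run.manifest.category_ratios.items():
            if c == "ALLERGY_TOTAL":
                continue
            assert cats.loc[c, "ratio_percent"] == pytest.approx(100 * planted, rel=1e-9)
        assert cats.loc["ALLERGY_TOTAL", "ratio_percent"] == pytest.approx(153.5, rel=1e-9)

    def test_zero_noise_areas_equal_true_means(self):
        cfg = dataclasses.replace(paper_scenario(3), peptide_cv=0.0)
        run = generate_scenario(cfg)
        truth = run.manifest.peptide_truth.set_index("sequence")
        areas = run.quant.groupby(["peptide", "replicate"])["area"].sum().reset_index()
        gw = areas[areas["replicate"] == "GW_1"].set_index("peptide")["area"]
        for pep in truth.index[:20]:
            assert gw[pep] == pytest.approx(truth.loc[pep, "true_gw"], rel=1e-9)

    def test_median_net_error_under_3_points_across_seeds(self):
        """Sampling property at the study conditions (cv 0.15, n = 4):
        the median absolute error of the net gluten percentage over 25
        seeds stays below 3 percentage points."""
        errors = []
        for seed in range(25):
            run = generate_scenario(paper_scenario(seed))
            net, _, _ = recover(run)
            errors.append(abs(net - 67.0))
        assert np.median(errors) < 3.0

    def test_transition_split_proportions(self, paper_run):
        one = paper_run.quant[
            (paper_run.quant["peptide"] == paper_run.quant["peptide"].iloc[0])
            & (paper_run.quant["replicate"] == "GW_1")
        ].sort_values("transition")
        fractions = one["area"] / one["area"].sum()
        assert np.allclose(fractions, [0.5, 0.3, 0.2])


class TestConfigValidation:
    def test_bad_replicates(self):
        with pytest.raises(ValueError):
            ScenarioConfig(seed=1, n_replicates=1)

    def test_bad_cv(self):
        with pytest.raises(ValueError):
            ScenarioConfig(seed=1, peptide_cv=-0.1)

    def test_unsolved_ratio_without_targets(self):
        cfg = ScenarioConfig(seed=1)
        cfg.baseline_ratios["lmw_gs"] = None
        with pytest.raises(ValueError, match="unsolved"):
            generate_quant(cfg, generate_proteome(cfg))
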