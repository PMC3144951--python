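import math
from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from ferricnv.qpcr import fit_standard_curve, genotype_population
from ferricnv.simulate import (
    JH_LIKE,
    PY_LIKE,
    CtNoiseModel,
    PhenotypeEffectSpec,
    PopulationSpec,
    Scenario,
    expected_target_ct,
    load_scenario,
    reference_effect_spec,
    simulate_ct_table,
    simulate_dilution_series,
    simulate_phenotypes,
    simulate_population,
    simulate_scenario,
)


class TestPopulationSpec:
    def test_presets_are_valid(self):
        for spec in (PY_LIKE, JH_LIKE):
            assert abs(sum(spec.genotype_distribution.values()) - 1.0) < 1e-9
        assert set(PY_LIKE.genotype_distribution) == set(range(2, 13))
        assert set(JH_LIKE.genotype_distribution) == set(range(2, 7))
        assert JH_LIKE.genotype_distribution[3] == pytest.approx(0.40)
        assert JH_LIKE.genotype_distribution[4] == pytest.approx(0.49)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            PopulationSpec("p", {2: 0.5, 3: 0.3}, n=10)
        with pytest.raises(ValueError, match="copy number 1"):
            PopulationSpec("p", {1: 0.5, 3: 0.5}, n=10)


class TestSimulatePopulation:
    def test_degenerate_spec(self):
        spec = PopulationSpec("p", {2: 1.0}, n=25)
        draws = simulate_population(spec, seed=3)
        assert len(draws) == 25
        assert all(copies == 2 for _sid, copies in draws)

    def test_determinism(self):
        assert simulate_population(JH_LIKE, seed=42) == simulate_population(
            JH_LIKE, seed=42
        )
        assert simulate_population(JH_LIKE, seed=42) != simulate_population(
            JH_LIKE, seed=43
        )

    def test_law_of_large_numbers(self):
        spec = replace(JH_LIKE, n=100_000)
        draws = simulate_population(spec, seed=0)
        counts = Counter(copies for _sid, copies in draws)
        for cn, p in spec.genotype_distribution.items():
            assert counts[cn] / spec.n == pytest.approx(p, abs=0.01)

    def test_unique_sample_ids(self):
        draws = simulate_population(JH_LIKE, seed=1)
        assert len({sid for sid, _ in draws}) == len(draws)


class TestSimulateCtTable:
    def test_noiseless_copies_4_delta_one(self):
        wells = simulate_ct_table(
            [("s1", 4)], CtNoiseModel.noiseless(), replicates=3, seed=0
        )
        by_assay = {}
        for w in wells:
            by_assay.setdefault(w.assay, []).append(w.ct)
        assert len(wells) == 6
        delta = np.mean(by_assay["control"]) - np.mean(by_assay["target"])
        assert delta == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_copies_2_delta_zero(self):
        wells = simulate_ct_table([("s1", 2)], CtNoiseModel.noiseless(), seed=0)
        cts = {w.assay: w.ct for w in wells}
        assert cts["target"] == pytest.approx(cts["control"], abs=1e-12)

    def test_efficiency_corrected_inverse(self):
        noise = CtNoiseModel.noiseless(eff_target=0.97, eff_control=0.98)
        wells = simulate_ct_table([("s1", 6)], noise, seed=0)
        cts = {w.assay: w.ct for w in wells}
        # invert by hand: 2 * 1.98^ctc * 1.97^-ctt should equal 6
        recovered = 2.0 * 1.98 ** cts["control"] * 1.97 ** (-cts["target"])
        assert recovered == pytest.approx(6.0, rel=1e-9)

    def test_expected_target_ct_plain_inverse(self):
        assert expected_target_ct(4, 26.0) == pytest.approx(25.0)
        assert expected_target_ct(2, 26.0) == pytest.approx(26.0)

    def test_determinism(self):
        genotypes = [("s1", 3), ("s2", 4)]
        a = simulate_ct_table(genotypes, seed=5)
        b = simulate_ct_table(genotypes, seed=5)
        assert a == b

    def test_end_to_end_recovery(self):
        spec = replace(JH_LIKE, n=500)
        genotypes = simulate_population(spec, seed=7)
        wells = simulate_ct_table(
            genotypes, CtNoiseModel(replicate_sd=0.1), seed=8
        )
        results = genotype_population(wells)
        truth = dict(genotypes)
        called = [r for r in results if r.call is not None]
        assert len(called) > 0.5 * len(results)
        accuracy = sum(r.call == truth[r.sample_id] for r in called) / len(called)
        assert accuracy >= 0.95

    def test_call_accuracy_declines_with_copy_number(self):
        # delta-Ct spacing log2((n+1)/n) shrinks with n, so at fixed noise
        # strict per-class accuracy must trend downward
        noise = CtNoiseModel(replicate_sd=0.1)
        accuracies = []
        for copies in range(2, 13):
            genotypes = [(f"c{copies}_{i}", copies) for i in range(800)]
            wells = simulate_ct_table(genotypes, noise, seed=100 + copies)
            results = genotype_population(wells)
            accuracies.append(
                sum(r.call == copies for r in results) / len(results)
            )
        for lower, higher in zip(accuracies, accuracies[1:]):
            assert higher <= lower + 0.03
        assert accuracies[0] > accuracies[-1] + 0.3


class TestSimulatePhenotypes:
    def test_zero_sd_gives_class_means(self):
        effects = PhenotypeEffectSpec(
            class_params={
                3: {
                    "shell_length": (130.0, 0.0),
                    "shell_width": (33.0, 0.0),
                    "body_weight": (250.0, 0.0),
                }
            }
        )
        records = simulate_phenotypes([("a", 3), ("b", 3)], effects, seed=0)
        assert all(r.shell_length == 130.0 for r in records)
        assert all(r.body_weight == 250.0 for r in records)

    def test_reference_cohort_moments(self):
        effects = reference_effect_spec()
        genotypes = [(f"g3_{i}", 3) for i in range(40)]
        genotypes += [(f"g4_{i}", 4) for i in range(49)]
        records = simulate_phenotypes(genotypes, effects, seed=21)
        lengths3 = [r.shell_length for r in records[:40]]
        lengths4 = [r.shell_length for r in records[40:]]
        # published SE * 3 tolerance (normal-theory check at fixed seed)
        assert np.mean(lengths3) == pytest.approx(133.37, abs=3 * 1.29)
        assert np.mean(lengths4) == pytest.approx(136.57, abs=3 * 1.30)

    def test_missing_class_errors(self):
        effects = reference_effect_spec()
        with pytest.raises(ValueError, match="copy class 7"):
            simulate_phenotypes([("a", 7)], effects, seed=0)

    def test_determinism(self):
        effects = reference_effect_spec()
        genotypes = [("a", 3), ("b", 4)]
        assert simulate_phenotypes(genotypes, effects, seed=9) == simulate_phenotypes(
            genotypes, effects, seed=9
        )

    def test_sd_reconstruction_from_se(self):
        assert PhenotypeEffectSpec.sd_from_se(1.29, 40) == pytest.approx(
            1.29 * math.sqrt(40)
        )


class TestSimulateDilutionSeries:
    def test_factor_2_noiseless(self):
        points = simulate_dilution_series(2.0, levels=5, replicates=1)
        est = fit_standard_curve(points)
        assert est.slope == pytest.approx(-3.321928, abs=1e-5)
        assert est.efficiency_percent == pytest.approx(100.0, abs=1e-6)

    def test_factor_1_97_noiseless(self):
        points = simulate_dilution_series(1.97, levels=5, replicates=3)
        est = fit_standard_curve(points)
        assert est.efficiency_percent == pytest.approx(97.0, abs=1e-6)

    def test_invalid_factor(self):
        with pytest.raises(ValueError, match="amplification factor"):
            simulate_dilution_series(1.0)
        with pytest.raises(ValueError, match="amplification factor"):
            simulate_dilution_series(2.5)

    def test_noisy_fit_within_two_points(self):
        hits = 0
        for rep in range(10):
            points = simulate_dilution_series(
                1.97, levels=5, replicates=3, noise_sd=0.05, seed=rep
            )
            est = fit_standard_curve(points)
            hits += abs(est.efficiency_percent - 97.0) <= 2.0
        assert hits >= 9

    def test_explicit_levels(self):
        points = simulate_dilution_series(2.0, levels=[0.0, -0.5, -1.0, -1.5])
        assert sorted({p.log10_quantity for p in points}) == [-1.5, -1.0, -0.5, 0.0]

    def test_efficiency_identity_property(self):
        for factor in np.linspace(1.05, 2.2, 12):
            points = simulate_dilution_series(float(factor), levels=4, replicates=1)
            est = fit_standard_curve(points)
            assert est.efficiency_percent == pytest.approx(
                (factor - 1) * 100, abs=1e-6
            )


class TestScenario:
    CONFIG = """
population:
  population_id: JH
  n: 60
  genotype_distribution: {"2": 0.02, "3": 0.40, "4": 0.49, "5": 0.05, "6": 0.04}
ct_noise:
  replicate_sd: 0.05
  between_sample_sd: 0.2
replicates: 3
phenotypes:
  "3":
    shell_length: {mean: 133.37, sd: 8.16}
    shell_width: {mean: 33.23, sd: 8.54}
    body_weight: {mean: 256.85, sd: 99.04}
  "4":
    shell_length: {mean: 136.57, sd: 9.10}
    shell_width: {mean: 32.98, sd: 5.18}
    body_weight: {mean: 267.39, sd: 69.79}
  "2": {shell_length: {mean: 133.0, sd: 8.0}, shell_width: {mean: 33.0, sd: 8.0}, body_weight: {mean: 250.0, sd: 90.0}}
  "5": {shell_length: {mean: 133.0, sd: 8.0}, shell_width: {mean: 33.0, sd: 8.0}, body_weight: {mean: 250.0, sd: 90.0}}
  "6": {shell_length: {mean: 133.0, sd: 8.0}, shell_width: {mean: 33.0, sd: 8.0}, body_weight: {mean: 250.0, sd: 90.0}}
"""

    def test_load_and_run(self, tmp_path):
        path = tmp_path / "scenario.yaml"
        path.write_text(self.CONFIG)
        scenario = load_scenario(path)
        assert isinstance(scenario, Scenario)
        assert scenario.population.n == 60
        out = simulate_scenario(scenario, seed=2)
        assert len(out["genotypes"]) == 60
        assert len(out["wells"]) == 60 * 2 * 3
        assert len(out["phenotypes"]) == 60

    def test_scenario_reproducible(self, tmp_path):
        path = tmp_path / "scenario.yaml"
        path.write_text(self.CONFIG)
        scenario = load_scenario(path)
        a = simulate_scenario(scenario, seed=4)
        b = simulate_scenario(scenario, seed=4)
        assert a["wells"] == b["wells"]
        assert a["phenotypes"] == b["phenotypes"]


class TestFullPipelineRecovery:
    def test_frequency_and_effect_recovery(self):
        from ferricnv.assoc import associate, genotype_frequencies

        spec = replace(JH_LIKE, n=100)
        genotypes = simulate_population(spec, seed=31)
        wells = simulate_ct_table(genotypes, CtNoiseModel(replicate_sd=0.1), seed=32)
        results = genotype_population(wells)
        calls = [(r.sample_id, r.call) for r in results]
        table = genotype_frequencies(calls, population_id="JH")
        tv = 0.5 * sum(
            abs(table.frequencies.get(cn, 0.0) - spec.genotype_distribution.get(cn, 0.0))
            for cn in set(table.frequencies) | set(spec.genotype_distribution)
        )
        assert tv <= 0.1

        effects = reference_effect_spec()
        padded = dict(effects.class_params)
        for cn in spec.genotype_distribution:
            padded.setdefault(cn, effects.class_params[3])
        phenotypes = simulate_phenotypes(
            genotypes, PhenotypeEffectSpec(class_params=padded), seed=33
        )
        report = associate(calls, phenotypes, class_a=3, class_b=4)
        length = [r for r in report.results if r.trait == "shell_length"][0]
        assert length.t_statistic > 0
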