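"""Synthetic cohort generator: reproducibility, calibration of the score
model, planted-signal construction and recovery."""

from __future__ import annotations

import numpy as np
import pytest

from fhburden.genescore import apoe_from_snps, gene_score
from fhburden.synthetic_data import (
    GeneSpec,
    SimConfig,
    _model_weights,
    default_catalogue,
    default_config,
    default_gene_panel,
    default_score_model,
    null_calibration,
    recover_parameters,
    simulate_cohort,
    simulate_gene_counts,
)


@pytest.fixture(scope="module")
def default_sim():
    return simulate_cohort(default_config(seed=20140))


class TestReproducibility:
    def test_same_seed_identical_output(self):
        a = simulate_cohort(default_config(seed=9, n_genes=50))
        b = simulate_cohort(default_config(seed=9, n_genes=50))
        assert [(c.sample_id, c.variant.key, c.zygosity) for c in a.dataset.calls] == [
            (c.sample_id, c.variant.key, c.zygosity) for c in b.dataset.calls
        ]
        assert a.genotypes == b.genotypes
        assert a.truth.planted_polygenic == b.truth.planted_polygenic

    def test_different_seed_differs(self):
        a = simulate_cohort(default_config(seed=9, n_genes=50))
        b = simulate_cohort(default_config(seed=10, n_genes=50))
        assert a.genotypes != b.genotypes


class TestScoreModel:
    def test_calibrated_moments(self):
        """Analytic mean hits the target exactly; the distributional 90th
        percentile (Monte Carlo, large n) hits the cutoff target."""
        from fhburden.synthetic_data import _fast_sample_totals

        model = default_score_model()
        mean, var = model.moments()
        assert mean == pytest.approx(0.90, abs=1e-6)
        w = np.array([s.weight for s in model.snps])
        p = np.array([s.freq for s in model.snps])
        totals = _fast_sample_totals(w, p, model.apoe_freqs, np.random.default_rng(99), 300_000)
        assert float(np.quantile(totals, 0.9)) == pytest.approx(1.16, abs=0.005)

    def test_empirical_percentile_approaches_target(self, default_sim):
        """The generated control distribution's 90th percentile sits near the
        configured cutoff (normal-approximation calibration, n=1926)."""
        model = default_sim.config.score_model
        weights = _model_weights(model)
        totals = []
        for sample in sorted(default_sim.dataset.controls):
            g = default_sim.genotypes[sample]
            apoe = apoe_from_snps(g["rs429358"], g["rs7412"])
            totals.append(gene_score(g, weights, apoe).total)
        p90 = float(np.quantile(totals, 0.9))
        assert p90 == pytest.approx(1.16, abs=0.03)
        assert float(np.mean(totals)) == pytest.approx(0.90, abs=0.02)


class TestCohortConstruction:
    def test_zero_rates_empty_call_set(self):
        config = SimConfig(
            seed=1,
            n_cases=10,
            n_controls=20,
            genes=[GeneSpec("G1", "1", 0.0)],
            score_model=default_score_model(),
            polygenic_case_fraction=0.0,
            unscored_case_fraction=0.0,
            noise_rate=0.0,
        )
        result = simulate_cohort(config)
        assert result.dataset.calls == []

    def test_spiked_keys_match_catalogue(self, default_sim):
        """Every spiked mutation call normalizes to a catalogue key."""
        catalogue_keys = {m.key for m in default_catalogue()}
        spiked = {
            c.variant.key
            for c in default_sim.dataset.calls
            if c.variant.gene in {"LDLR", "APOB", "PCSK9", "LDLRAP1"}
        }
        assert spiked <= catalogue_keys
        assert len(default_sim.truth.spiked_tier1) == 26  # 25 dominant + 1 recessive het
        assert len(default_sim.truth.tier1_explained) == 25

    def test_enriched_gene_expected_counts(self):
        """A gene planted at case rate 3/71 against control rate 2/1926
        averages the published count pair over replicates."""
        control_rate = 2 / 1926
        mult = (3 / 71) / control_rate
        config = SimConfig(
            seed=2,
            n_cases=71,
            n_controls=1926,
            genes=[GeneSpec("TARGET", "10", control_rate)],
            enrichment={"TARGET": mult},
        )
        rng = np.random.default_rng(2)
        reps = [simulate_gene_counts(config, rng) for _ in range(400)]
        k_case = np.mean([r["k_case"][0] for r in reps])
        k_control = np.mean([r["k_control"][0] for r in reps])
        assert k_case == pytest.approx(3.0, abs=0.3)
        assert k_control == pytest.approx(2.0, abs=0.3)

    def test_impossible_rate_fatal(self):
        with pytest.raises(ValueError):
            SimConfig(
                seed=1, n_cases=5, n_controls=5,
                genes=[GeneSpec("G1", "1", 0.5)],
                enrichment={"G1": 3.0},
            )


class TestCalibrationAndRecovery:
    def test_null_scan_conservative_small(self):
        report = null_calibration(n_replicates=50, seed=8)
        assert report["mean_fraction"] <= report["alpha"] + 3 * max(report["se"], 1e-6)

    def test_tier1_recall_and_polygenic_recovery(self, default_sim):
        rec = recover_parameters(default_sim)
        assert rec.tier1_recall == 1.0
        assert rec.tier1_recovered == rec.tier1_planted == 25
        f = rec.polygenic_planted_fraction
        se = np.sqrt(f * (1 - f) / rec.n_polygenic_base)
        assert abs(rec.polygenic_recovered_fraction - f) <= 3 * se
        assert rec.control_decile_fraction == pytest.approx(0.10, abs=0.02)

    def test_exclusion_arithmetic_emerges_from_generator(self, default_sim):
        """With the default design the cascade removes exactly 25 mutation
        carriers and 29 polygenic cases, leaving 71 — for any seed, because
        the planted fractions are the study's."""
        from fhburden.pipeline import run_pipeline_data

        report = run_pipeline_data(
            default_sim.dataset,
            default_sim.catalogue,
            default_sim.genotypes,
            default_sim.config.score_model.weights(),
        )
        assert (report.n_tier1_excluded, report.n_polygenic_excluded, report.n_remaining) == (25, 29, 71)

    def test_planted_enrichment_recovered_as_power(self):
        control_rate = 2 / 1926
        config = default_config(seed=31, n_genes=100)
        config.n_cases = 71
        config.tier1_spikes = []
        config.polygenic_case_fraction = 0.0
        config.unscored_case_fraction = 0.0
        # plant strong enrichment in three genes
        strong = {g.gene: (8 / 71) / g.rate for g in config.genes[:3]}
        config.genes = [GeneSpec(g.gene, g.chrom, control_rate if g.gene in strong else g.rate) for g in config.genes]
        config.enrichment = {g: (8 / 71) / control_rate for g in strong}
        result = simulate_cohort(config)
        rec = recover_parameters(result)
        assert rec.power is not None and rec.power >= 2 / 3  # strong spikes are found
        assert rec.type_i_rate is not None and rec.type_i_rate <= 0.02
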