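import logging
import math

import numpy as np
import pytest
import scipy.stats as sps

from mitopid.reference import RegionSpec, encode_bases, region_sequence
from mitopid.simulate import (
    DEFAULT_MIDS,
    CohortEffects,
    SimConfig,
    SimConfigError,
    simulate_cohort,
    simulate_control_run,
    simulate_reads,
    simulate_sample,
    simulate_templates,
    synthetic_reference,
)


@pytest.fixture(scope="module")
def ref_codes(genome, region):
    return encode_bases(region_sequence(genome, region))


class TestDefaultMids:
    def test_twelve_barcodes_pairwise_distance_at_least_four(self):
        seqs = list(DEFAULT_MIDS.values())
        assert len(seqs) == 12 and all(len(s) == 10 for s in seqs)
        for i, a in enumerate(seqs):
            for b in seqs[i + 1 :]:
                assert sum(x != y for x, y in zip(a, b)) >= 4


class TestSimulateTemplates:
    def test_clean_templates_equal_reference(self, genome, region, ref_codes):
        cfg = SimConfig(seed=0, n_templates=50, somatic_rate=0.0)
        rng = np.random.default_rng(cfg.seed)
        templates, truth = simulate_templates(genome, region, cfg, rng)
        assert np.all(templates == ref_codes)
        assert truth.planted_somatic == []

    def test_heteroplasmy_carrier_count_binomial(self, genome, region):
        # choose an alt differing from the reference base at position 73
        alt = "A" if genome.base(73) != "A" else "C"
        cfg = SimConfig(
            seed=4, n_templates=2000, somatic_rate=0.0,
            heteroplasmies=((73, alt, 0.05),),
        )
        rng = np.random.default_rng(cfg.seed)
        _, truth = simulate_templates(genome, region, cfg, rng)
        carriers = len(truth.het_carriers[(73, alt)])
        sigma = math.sqrt(2000 * 0.05 * 0.95)
        assert abs(carriers - 100) <= 3 * sigma

    def test_exact_planting_gives_exact_carrier_count(self, genome, region):
        alt = "A" if genome.base(73) != "A" else "C"
        cfg = SimConfig(
            seed=4, n_templates=400, somatic_rate=0.0,
            heteroplasmies=((73, alt, 0.02),), het_planting="exact",
        )
        rng = np.random.default_rng(cfg.seed)
        _, truth = simulate_templates(genome, region, cfg, rng)
        assert len(truth.het_carriers[(73, alt)]) == 8

    def test_poisson_mean_of_planted_substitutions(self, genome, region):
        cfg = SimConfig(seed=8, n_templates=10_000, somatic_rate=0.5)
        rng = np.random.default_rng(cfg.seed)
        _, truth = simulate_templates(genome, region, cfg, rng)
        mean = len(truth.planted_somatic) / 10_000
        sigma = math.sqrt(0.5 / 10_000)
        assert abs(mean - 0.5) <= 3 * sigma

    def test_truth_conservation_by_diffing(self, genome, region, ref_codes):
        cfg = SimConfig(seed=9, n_templates=500, somatic_rate=0.3)
        rng = np.random.default_rng(cfg.seed)
        templates, truth = simulate_templates(genome, region, cfg, rng)
        n_diffs = int(np.sum(templates != ref_codes))
        assert n_diffs == len(truth.planted_somatic)

    def test_position_outside_region_rejected(self, genome, region):
        cfg = SimConfig(seed=0, n_templates=10, heteroplasmies=((500, "A", 0.1),))
        rng = np.random.default_rng(0)
        with pytest.raises(SimConfigError):
            simulate_templates(genome, region, cfg, rng)

    def test_pid_collision_logged(self, genome, region, caplog):
        cfg = SimConfig(seed=0, n_templates=300, somatic_rate=0.0, pid_length=2)
        rng = np.random.default_rng(cfg.seed)
        with caplog.at_level(logging.WARNING):
            simulate_templates(genome, region, cfg, rng)
        assert "PID collision" in caplog.text


class TestSimulateReads:
    def test_error_free_reads_equal_template(self, genome, region):
        cfg = SimConfig(seed=3, n_templates=30, somatic_rate=0.2, error_rate=0.0)
        reads, truth = simulate_sample(genome, region, cfg)
        by_pid: dict[str, set] = {}
        for _, seq in reads:
            pid, payload = seq[10:29], seq[29:]
            by_pid.setdefault(pid, set()).add(payload)
        # all reads of one template are identical
        assert all(len(v) == 1 for v in by_pid.values())

    def test_error_count_binomial(self, genome, region):
        cfg = SimConfig(
            seed=5, n_templates=600, somatic_rate=0.0, error_rate=0.01,
            reads_per_template=("poisson", 6.0),
        )
        reads, truth = simulate_sample(genome, region, cfg)
        total_bases = sum(truth.reads_per_template) * 289
        expected = total_bases * 0.01
        sigma = math.sqrt(total_bases * 0.01 * 0.99)
        assert abs(truth.n_error_bases - expected) <= 3 * sigma

    def test_reads_carry_mid_and_pid_layout(self, genome, region):
        cfg = SimConfig(seed=1, n_templates=20, reads_per_template=("fixed", 2))
        reads, truth = simulate_sample(genome, region, cfg)
        assert len(reads) == 40
        for _, seq in reads:
            assert seq.startswith(DEFAULT_MIDS["MID01"])
            assert seq[10:29] in truth.pids

    def test_reproducibility_and_seed_sensitivity(self, genome, region):
        cfg = SimConfig(seed=17, n_templates=100, somatic_rate=0.1, error_rate=0.005)
        a, _ = simulate_sample(genome, region, cfg)
        b, _ = simulate_sample(genome, region, cfg)
        assert a == b
        c, _ = simulate_sample(genome, region, SimConfig(
            seed=18, n_templates=100, somatic_rate=0.1, error_rate=0.005))
        assert a != c

    def test_control_run_has_no_planted_variation(self, genome, region, ref_codes):
        cfg = SimConfig(seed=2, n_templates=50, somatic_rate=0.5, error_rate=0.0,
                        heteroplasmies=())
        reads, truth = simulate_control_run(genome, region, cfg)
        assert truth.planted_somatic == []
        region_seq = region_sequence(genome, region)
        assert all(seq[29:] == region_seq for _, seq in reads)


class TestSimConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"somatic_rate": -0.1},
            {"error_rate": 0.3},
            {"heteroplasmies": ((73, "A", 1.5),)},
            {"heteroplasmies": ((73, "Z", 0.1),)},
            {"reads_per_template": ("geometric", 5)},
            {"het_planting": "random"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(SimConfigError):
            SimConfig(**kwargs)


class TestSimulateCohort:
    def test_smoker_fraction_within_3_sigma_at_n_164(self):
        df, _ = simulate_cohort(n=164, seed=0)
        frac = (df["smoking"] == "current").mean()
        sigma = math.sqrt(0.35 * 0.65 / 164)
        assert abs(frac - 0.35) <= 3 * sigma

    def test_null_effects_leave_groups_exchangeable(self):
        effects = CohortEffects(
            beta_age=0.0, beta_smoking=0.0, beta_hiv_low=0.0, beta_hiv_high=0.0,
            burden_intercept=0.5,
        )
        df, _ = simulate_cohort(n=500, effects=effects, seed=11)
        a = df.loc[df["smoking"] == "current", "burden_t"]
        b = df.loc[df["smoking"] == "never", "burden_t"]
        _, p = sps.mannwhitneyu(a, b)
        assert p > 0.01

    def test_positive_age_effect_yields_positive_correlation(self):
        df, _ = simulate_cohort(n=500, seed=12)
        assert df["age"].corr(df["burden_t"]) > 0

    def test_truth_records_all_coefficients(self):
        _, truth = simulate_cohort(n=50, seed=1)
        for key in ("beta_age", "het_beta_interaction", "p_smoker", "noise_sd"):
            assert key in truth

    def test_invalid_probability_rejected(self):
        with pytest.raises(SimConfigError):
            simulate_cohort(n=10, effects=CohortEffects(p_smoker=1.5), seed=0)


def test_synthetic_reference_is_deterministic():
    a, b = synthetic_reference(), synthetic_reference()
    assert a.sequence == b.sequence and a.length == 16569
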