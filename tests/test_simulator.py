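import math

import numpy as np
import pytest
from scipy import stats

from micquant.calibration import InsufficientDepthError, calibrate
from micquant.metrics import median_fold, pooled_cv
from micquant.simulator import (
    DEFAULT_TAXA,
    EmptyLibraryError,
    SimulationConfig,
    amplify_bulk,
    amplify_micelle,
    draw_templates,
    sequence_reads,
    simulate_experiment,
    simulate_replicate,
)

TAXA4 = tuple((t, 250.0) for t in DEFAULT_TAXA)


def quiet_config(**kw):
    """Config without contamination/chimeras unless the test asks for them."""
    defaults = dict(
        taxa=TAXA4,
        ic_spike_copies=100.0,
        reagent_contaminants=(),
        env_rate=0.0,
        chimera_fraction=0.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestDrawTemplates:
    def test_poisson_moments_at_low_copy_number(self):
        """Template counts at 2.5 copies/reaction are Poisson: mean and the
        zero-probability e^-2.5 both match at 100,000 draws."""
        cfg = quiet_config(taxa=(("A", 2.5),))
        rng = np.random.default_rng(321)
        draws = np.array([draw_templates(cfg, rng)[0]["A"] for _ in range(100_000)])
        se_mean = math.sqrt(2.5 / draws.size)
        assert abs(draws.mean() - 2.5) < 3 * se_mean
        p0 = math.exp(-2.5)
        se_p0 = math.sqrt(p0 * (1 - p0) / draws.size)
        assert abs((draws == 0).mean() - p0) < 3 * se_p0

    def test_zero_copies_never_yields_templates(self):
        cfg = quiet_config(taxa=(("A", 0.0),))
        for seed in range(20):
            assert draw_templates(cfg, seed)[0]["A"] == 0

    def test_no_contamination_means_community_plus_calibrator_only(self):
        cfg = quiet_config()
        templates, provenance = draw_templates(cfg, 0)
        assert set(templates) == set(DEFAULT_TAXA) | {cfg.ic_otu_id}
        assert provenance[cfg.ic_otu_id] == "ic"

    def test_provenance_is_a_partition(self):
        cfg = SimulationConfig(taxa=TAXA4, env_rate=3.0)
        templates, provenance = draw_templates(cfg, 11)
        present = {o for o, n in templates.items() if n > 0}
        assert present <= set(provenance)


class TestAmplifyMicelle:
    def test_degenerate_lognormal_is_proportional(self):
        cfg = quiet_config(micelle_yield_sigma=0.0)
        masses = amplify_micelle({"A": 7, "B": 3, "C": 0}, cfg, 0)
        assert masses == {"A": 7.0, "B": 3.0, "C": 0.0}

    def test_single_molecule_mean_yield(self):
        """Mean mass of one molecule over 100,000 draws = exp(sigma^2/2)."""
        sigma = 0.3
        cfg = quiet_config(micelle_yield_sigma=sigma)
        rng = np.random.default_rng(17)
        masses = np.array(
            [amplify_micelle({"A": 1}, cfg, rng)["A"] for _ in range(100_000)]
        )
        mu = math.exp(sigma**2 / 2)
        se = math.sqrt((math.exp(sigma**2) - 1) * math.exp(sigma**2)) / math.sqrt(masses.size)
        assert abs(masses.mean() - mu) < 3 * se

    def test_no_cross_otu_interaction(self):
        """The mass an OTU receives is distributionally unchanged by a
        high-copy competitor (KS over 1,000 seeds)."""
        cfg = quiet_config()
        alone, crowded = [], []
        for seed in range(1000):
            alone.append(amplify_micelle({"A": 10}, cfg, seed)["A"])
            crowded.append(amplify_micelle({"A": 10, "BIG": 5000}, cfg, seed + 10_000)["A"])
        assert stats.ks_2samp(alone, crowded).pvalue > 0.01


class TestAmplifyBulk:
    def test_point_efficiency_closed_form(self):
        cfg = quiet_config(bulk_efficiency_range=(0.9, 0.9), method="traditional")
        masses = amplify_bulk({"A": 5, "B": 0}, cfg, 0)
        assert masses["A"] == pytest.approx(5 * 1.9**30)
        assert masses["B"] == 0.0

    def test_efficiency_dispersion_spans_expected_ratio_range(self):
        """Two equal-template OTUs: the extreme mass ratio approaches
        (1.95/1.85)^30 ~ 4.8 at the default efficiency range."""
        cfg = quiet_config(method="traditional")
        ratios = []
        for seed in range(2000):
            m = amplify_bulk({"A": 100, "B": 100}, cfg, seed)
            ratios.append(m["A"] / m["B"])
        limit = (1.95 / 1.85) ** 30
        assert max(ratios) <= limit * 1.0000001
        assert min(ratios) >= 1 / limit * 0.9999999
        assert max(ratios) > 0.5 * limit  # the extremes are actually approached


class TestSequenceReads:
    def test_no_chimeras_when_fraction_zero(self):
        cfg = quiet_config()
        masses = {"A": 10.0, cfg.ic_otu_id: 5.0}
        profile, truth = sequence_reads(masses, cfg, 3, sample_id="s")
        assert truth.pre_qc_chimera_reads == 0
        assert not any(o.startswith("chimera:") for o in profile.otu_reads)

    def test_bulk_default_chimera_rate(self):
        """Pre-QC chimera fraction over 100 replicates matches the configured
        4.5% within 3 SE of the binomial rate."""
        cfg = quiet_config(method="traditional", chimera_fraction=None)
        assert cfg.effective_chimera_fraction == 0.045
        fracs = []
        for seed in range(100):
            _, truth = sequence_reads({"A": 1.0, cfg.ic_otu_id: 0.5}, cfg, seed)
            fracs.append(truth.pre_qc_chimera_reads / cfg.depth_mean)
        se = math.sqrt(0.045 * 0.955 / (100 * cfg.depth_mean))
        assert abs(np.mean(fracs) - 0.045) < 3 * se

    def test_surviving_chimeras_become_novel_otus(self):
        cfg = quiet_config(chimera_fraction=0.2, chimera_detection_sensitivity=0.0)
        profile, truth = sequence_reads({"A": 1.0, "B": 1.0, cfg.ic_otu_id: 0.5}, cfg, 5)
        chimera_otus = [o for o in profile.otu_reads if o.startswith("chimera:")]
        assert truth.pre_qc_chimera_reads > 0 and chimera_otus

    def test_zero_mass_raises_empty_library(self):
        cfg = quiet_config()
        with pytest.raises(EmptyLibraryError):
            sequence_reads({"A": 0.0}, cfg, 0)

    def test_shallow_library_surfaces_insufficient_depth(self):
        cfg = quiet_config(depth_mean=500, rarefaction_depth=1000)
        with pytest.raises(InsufficientDepthError):
            sequence_reads({"A": 1.0, cfg.ic_otu_id: 0.5}, cfg, 0)


class TestHostDnaInhibition:
    def test_bulk_library_fails_under_host_excess(self):
        cfg = quiet_config(method="traditional", host_dna_excess=True, host_failure_prob=1.0)
        with pytest.raises(EmptyLibraryError, match="host"):
            simulate_replicate(cfg, 0)

    def test_compartmentalized_reaction_is_immune(self):
        cfg = quiet_config(method="micelle", host_dna_excess=True, host_failure_prob=1.0)
        profile, _ = simulate_replicate(cfg, 0)
        assert profile.total_reads > 0


class TestSimulateExperiment:
    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(method="micelle")
        a = simulate_experiment([250.0, 25.0], cfg, seed=42)
        b = simulate_experiment([250.0, 25.0], cfg, seed=42)
        for ga, gb in zip(a.groups, b.groups):
            for pa, pb in zip(ga.profiles, gb.profiles):
                assert pa.otu_reads == pb.otu_reads

    def test_nec_without_contamination_contains_only_calibrator(self):
        cfg = SimulationConfig(method="micelle", reagent_contaminants=(), env_rate=0.0,
                               chimera_fraction=0.0)
        exp = simulate_experiment([250.0], cfg, seed=3)
        nec = next(g for g in exp.groups if g.role == "nec")
        for profile in nec.profiles:
            observed = {o for o, n in profile.otu_reads.items() if n > 0}
            assert observed == {cfg.ic_otu_id}

    def test_levels_must_be_positive_descending(self):
        cfg = SimulationConfig()
        with pytest.raises(ValueError):
            simulate_experiment([25.0, 250.0], cfg, seed=0)
        with pytest.raises(ValueError):
            simulate_experiment([250.0, -1.0], cfg, seed=0)

    def test_spike_follows_recommendation_rule(self):
        cfg = SimulationConfig(method="micelle")
        exp = simulate_experiment([2500.0, 2.5], cfg, seed=0)
        by_level = {g.level: g for g in exp.groups}
        assert by_level[2500.0].profiles[0].ic_spike_copies == 1000.0
        assert by_level[2.5].profiles[0].ic_spike_copies == 50.0
        assert by_level[None].profiles[0].ic_spike_copies == 50.0

    def test_micelle_more_precise_than_bulk_at_250(self):
        """Pooled CV of calibrated copies at the 250-copy level: the
        compartmentalized arm beats the bulk arm (20 seeds here; the full
        100-seed check runs with the acceptance suite)."""
        wins = 0
        for seed in range(20):
            cvs = {}
            for method in ("micelle", "traditional"):
                cfg = SimulationConfig(method=method)
                exp = simulate_experiment([250.0], cfg, seed=seed)
                group = next(g for g in exp.groups if g.role == "specimen")
                values = []
                for profile in group.profiles:
                    cal = calibrate(profile)
                    values.extend(cal.otu_copies.get(t, 0.0) for t in DEFAULT_TAXA)
                cvs[method] = pooled_cv(values)
            wins += cvs["micelle"] < cvs["traditional"]
        assert wins >= 18

    def test_calibration_recovers_input_without_bias(self):
        """Median fold of corrected micelle output at levels >= 250 stays in
        [0.8, 1.25] (parameter recovery; 20 seeds)."""
        from micquant.model import AbsoluteAbundanceModel

        folds = []
        for seed in range(20):
            exp = simulate_experiment([2500.0, 250.0], SimulationConfig(method="micelle"), seed=seed)
            res = AbsoluteAbundanceModel.from_simulation(exp).fit(
                seed=seed, expected_otus=DEFAULT_TAXA
            )
            truenesses = [r.trueness for r in res.accuracy.rows]
            folds.append(median_fold(truenesses))
        assert 0.8 <= float(np.median(folds)) <= 1.25
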