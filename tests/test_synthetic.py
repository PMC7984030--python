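"""Generator correctness: quotas, closed-form kinetics, buoyancy algebra,
determinism and the variance structure the campaigns are built to carry."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cooktime.synthetic import (
    GROUP_CT_RANGES,
    GenotypeProfile,
    NoiseModel,
    SimulationError,
    TrialDesign,
    default_designs,
    density_design,
    dmc_to_relative_density,
    generate_campaign,
    generate_genotypes,
    hydrostatic_weight,
    simulate_density_trial,
    simulate_trait_table,
    simulate_wab_trial,
)


def _profile(**kw):
    base = dict(
        genotype_id="G1",
        group="short",
        ct_true=20.0,
        wab_max=20.0,
        wab_tau=10.0,
        dmc_true=38.0,
        swell_alpha=1.4,
        frag_onset=None,
    )
    base.update(kw)
    return GenotypeProfile(**base)


NOISELESS = NoiseModel(ve_ct=0.0, ve_wab=0.0, convection_range=0.0,
                       scale_resolution=1e-9, den_noise_sd=0.0, frag_rate=0.0)


class TestGenerateGenotypes:
    def test_empty(self):
        assert generate_genotypes(0) == []

    def test_observed_group_counts_reproduced_by_quota(self):
        # the study's short/medium/long split: 15, 8 and 11 genotypes
        profiles = generate_genotypes(34)
        counts = pd.Series([p.group for p in profiles]).value_counts()
        assert counts["short"] == 15
        assert counts["medium"] == 8
        assert counts["long"] == 11

    def test_default_campaign_preserves_proportions(self):
        counts = pd.Series(
            [p.group for p in generate_genotypes(36)]
        ).value_counts()
        assert counts["short"] == 16 and counts["medium"] == 8 and counts["long"] == 12

    def test_large_sample_frequencies_within_3se(self, rng):
        props = (0.5, 0.3, 0.2)
        n = 1000
        profiles = generate_genotypes(n, props, rng=rng)
        counts = pd.Series([p.group for p in profiles]).value_counts()
        for group, p in zip(("short", "medium", "long"), props):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[group] / n - p) <= 3 * se

    @pytest.mark.parametrize(
        "n,props",
        [(-1, (0.5, 0.3, 0.2)), (5, (0.5, 0.5, 0.5)), (5, (-0.1, 0.6, 0.5)),
         (5, (1.0, 0.0))],
    )
    def test_invalid_arguments(self, n, props):
        with pytest.raises(ValueError):
            generate_genotypes(n, props)

    def test_groups_consistent_with_ct_rule(self):
        for p in generate_genotypes(60, rng=np.random.default_rng(3)):
            if p.group == "short":
                assert p.ct_true <= 25
            elif p.group == "medium":
                assert 25 < p.ct_true <= 40
            else:
                assert p.ct_true > 40

    def test_deterministic_under_fixed_seed(self):
        a = generate_genotypes(20, rng=np.random.default_rng(9))
        b = generate_genotypes(20, rng=np.random.default_rng(9))
        assert a == b

    def test_tau_positively_associated_with_ct(self):
        profiles = generate_genotypes(36, rng=np.random.default_rng(1))
        cts = np.array([p.ct_true for p in profiles])
        taus = np.array([p.wab_tau for p in profiles])
        assert np.corrcoef(cts, taus)[0, 1] > 0


class TestProfileValidation:
    def test_group_ct_mismatch_rejected(self):
        with pytest.raises(ValueError):
            _profile(group="short", ct_true=30.0)

    def test_swell_alpha_below_one_rejected(self):
        with pytest.raises(ValueError):
            _profile(swell_alpha=0.9)

    def test_wab_closed_form(self):
        # wab(t) = wab_max (1 - exp(-t/tau)); at t = tau this is
        # 20 (1 - 1/e) = 12.642%
        p = _profile(wab_max=20.0, wab_tau=10.0)
        assert p.wab(10.0) == pytest.approx(12.642, abs=5e-4)


class TestWabTrial:
    def test_null_kinetics_all_weights_equal_initial(self):
        p = _profile(wab_max=0.0)
        design = TrialDesign("H", 10, 2, 8, stop_at_ct=False)
        for res in simulate_wab_trial(p, design, NOISELESS,
                                      rng=np.random.default_rng(0)):
            t, w = res.series.air_events()
            assert np.allclose(w, w[0], atol=1e-6)

    def test_noise_free_curve_matches_closed_form(self):
        p = _profile(wab_max=20.0, wab_tau=10.0, ct_true=20.0)
        design = TrialDesign("H", 10, 1, 8, stop_at_ct=False)
        res = simulate_wab_trial(p, design, NOISELESS,
                                 rng=np.random.default_rng(0))[0]
        t, w = res.series.air_events()
        net = w - res.series.tare_g
        wab = 100.0 * (net - net[0]) / net[0]
        assert wab[np.isclose(t, 10.0)][0] == pytest.approx(12.642, abs=5e-4)
        expected = 20.0 * (1.0 - np.exp(-t / 10.0))
        assert np.allclose(wab, expected, atol=1e-6)

    def test_max_convection_distortion_on_800g(self):
        # +/-10 g on an 800 g strainer is at most 2.5% of initial weight
        assert 100.0 * 20.0 / 800.0 == pytest.approx(2.5)

    def test_stop_at_ct_truncates_series(self):
        p = _profile(ct_true=22.0, wab_tau=11.0)
        design = TrialDesign("H", 8, 1, 1, stop_at_ct=True)
        res = simulate_wab_trial(p, design, NOISELESS,
                                 rng=np.random.default_rng(0))[0]
        t, _ = res.series.air_events()
        # final weighing at the rep's CT (= true CT, noise-free, no shift)
        assert t[-1] == pytest.approx(22.0)
        assert t[-2] <= 20.0 + 1e-9

    def test_fragmentation_makes_recorded_wab_non_monotone(self):
        p = _profile(ct_true=16.0, wab_max=18.0, wab_tau=8.0, frag_onset=26.0)
        noise = NoiseModel(ve_ct=0.0, ve_wab=0.0, convection_range=0.0,
                           scale_resolution=1e-9, frag_rate=0.8)
        design = TrialDesign("H", 10, 1, 8, stop_at_ct=False)
        res = simulate_wab_trial(p, design, noise,
                                 rng=np.random.default_rng(0))[0]
        t, w = res.series.air_events()
        net = w - res.series.tare_g
        assert net[-1] < net[np.isclose(t, 30.0)][0]

    def test_bit_identical_under_fixed_seed(self):
        p = _profile()
        design = TrialDesign("H", 10, 3, 8)
        noise = NoiseModel(seed=4)
        a = simulate_wab_trial(p, design, noise, rng=np.random.default_rng(4))
        b = simulate_wab_trial(p, design, noise, rng=np.random.default_rng(4))
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.series.weight_g, rb.series.weight_g)
            assert np.array_equal(ra.series.t_min, rb.series.t_min)
            assert np.array_equal(ra.piece_soft_times, rb.piece_soft_times,
                                  equal_nan=True)


class TestDensityTrial:
    def test_buoyancy_hand_value(self):
        # 1000 g at d0 = 1.10 absorbs 50 g with swell ratio 1.2:
        # 1050 - (909.09 + 60) = 80.91 g
        assert hydrostatic_weight(1000.0, 1.10, 50.0, 1.2) == pytest.approx(
            80.909, abs=1e-3
        )

    def test_inert_root_constant_weight(self):
        p = _profile(wab_max=0.0)
        s = simulate_density_trial(p, density_design(), NOISELESS,
                                   rng=np.random.default_rng(0))
        assert np.allclose(s.weight_g, s.weight_g[0], atol=1e-6)

    def test_weight_strictly_decreasing_before_fragmentation(self):
        p = _profile(group="medium", ct_true=30.0, wab_max=12.0, wab_tau=15.0)
        s = simulate_density_trial(p, density_design(), NOISELESS,
                                   rng=np.random.default_rng(0))
        assert np.all(np.diff(s.weight_g) < 0)

    def test_fragmentation_reverses_trend(self):
        p = _profile(ct_true=16.0, wab_max=18.0, wab_tau=8.0, frag_onset=26.0)
        noise = NoiseModel(ve_ct=0, ve_wab=0, convection_range=0,
                           scale_resolution=1e-9, den_noise_sd=0.0,
                           frag_rate=0.8)
        s = simulate_density_trial(p, density_design(), noise,
                                   rng=np.random.default_rng(0))
        assert s.weight_g[-1] > s.weight_g[np.isclose(s.t_min, 30.0)][0]

    def test_floating_sample_rejected(self):
        # dmc below the float point of the specific-gravity map
        p = _profile(dmc_true=21.0)
        design = TrialDesign("H", 10, 1, 16, weigh_interval=5.0,
                             harvest_dmc_shift=-6.0)
        assert dmc_to_relative_density(15.0) < 1
        with pytest.raises(SimulationError, match="float"):
            simulate_density_trial(p, design, NOISELESS,
                                   rng=np.random.default_rng(0))


class TestCampaign:
    def test_fixed_seed_bit_identical(self):
        a = generate_campaign(n_genotypes=6, seed=11)
        b = generate_campaign(n_genotypes=6, seed=11)
        for x, y in [(a.weights, b.weights), (a.softening, b.softening),
                     (a.density, b.density), (a.truth, b.truth)]:
            pd.testing.assert_frame_equal(x, y)

    def test_ct_wab30_true_correlation_negative(self, small_campaign):
        truth = small_campaign.truth
        wab30_true = truth["wab_max"] * (1 - np.exp(-30.0 / truth["wab_tau"]))
        r = np.corrcoef(truth["ct_true"], wab30_true)[0, 1]
        assert r < 0

    def test_trait_table_recovers_genotype_variance(self):
        # noise-free residual: one-way ANOVA on genotype means gives vg
        biases = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df = simulate_trait_table(80, 3, vg=150.0, ve=0.0, rng=rng)
            means = df.groupby("genotype")["value"].mean()
            biases.append(means.var(ddof=1) / 150.0 - 1.0)
        assert abs(np.mean(biases)) < 0.10


@given(st.floats(min_value=20.5, max_value=49.5))
def test_density_map_monotone_and_above_one(dmc):
    d0 = dmc_to_relative_density(dmc)
    assert d0 > 1.0
    assert dmc_to_relative_density(dmc + 0.5) > d0
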