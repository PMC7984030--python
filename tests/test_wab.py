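"""WAB curves, the cooking-time rule, grouping, correlation tables and the
replicate-reduction analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cooktime.synthetic import WeighingSeries
from cooktime.wab import (
    CookingRecord,
    WabCurve,
    compute_wab_curve,
    convection_accuracy_bound,
    determine_cooking_time,
    group_by_ct,
    replicate_subsample_analysis,
    summarize_groups,
    wab_ct_correlation_table,
)


def _series(weights, tare=100.0, interval=10.0, out_dur=1.0):
    """Build a series with weighings at in-water times 0, 10, 20, ..."""
    t, w, ph = [0.0, 0.0], [weights[0], weights[0]], ["air", "water"]
    accrued = 0.0
    for k, wt in enumerate(weights[1:], start=1):
        t_out = k * interval + accrued
        t += [t_out, t_out + out_dur]
        w += [wt, wt]
        ph += ["air", "water"]
        accrued += out_dur
    return WeighingSeries("G1", "H1", "R1", "strainer", tare,
                          np.array(t), np.array(w), np.array(ph, dtype=object))


class TestComputeWabCurve:
    def test_no_uptake_gives_zero_curve(self):
        c = compute_wab_curve(_series([600.0, 600.0, 600.0]))
        assert np.allclose(c.wab, 0.0)

    def test_single_20g_perturbation_on_800g_gross(self):
        # 20 g on a 700 g net (800 g gross incl. tare) weighing
        c = compute_wab_curve(_series([900.0, 920.0], tare=100.0))
        assert c.wab[1] == pytest.approx(100.0 * 20.0 / 800.0)
        # the accuracy bound itself is quoted on the gross weight
        assert convection_accuracy_bound(20.0, 800.0) == pytest.approx(2.5)
        assert convection_accuracy_bound(20.0, 1100.0) == pytest.approx(1.818, abs=1e-3)

    def test_arithmetic(self):
        c = compute_wab_curve(_series([600.0, 650.0, 660.0], tare=100.0))
        # net 500 -> 560 at the third weighing: 12.0%
        assert c.wab[2] == pytest.approx(12.0)

    def test_in_water_clock_excludes_out_of_water_time(self):
        c = compute_wab_curve(_series([600.0, 650.0, 660.0], out_dur=1.0))
        assert np.allclose(c.times, [0.0, 10.0, 20.0])

    def test_non_positive_initial_net_rejected(self):
        with pytest.raises(ValueError, match="non-positive initial net"):
            compute_wab_curve(_series([90.0, 95.0], tare=100.0))

    def test_missing_tare_names_record(self):
        s = _series([600.0, 650.0])
        s.tare_g = None
        with pytest.raises(ValueError, match="G1/H1/R1"):
            compute_wab_curve(s)


class TestDetermineCookingTime:
    def test_six_of_eight_rule_with_correction(self):
        # 6th piece soft at total-clock 26 with 2 min out of water before
        record = CookingRecord(
            rep_id="R1",
            piece_soft_times=np.array([15, 18, 20, 22, 23, 26, 40, 52], float),
            out_of_water=[(10.0, 1.0), (21.0, 1.0)],
            observation_end=60.0,
        )
        res = determine_cooking_time(record)
        assert not res.censored
        assert res.ct == pytest.approx(24.0)

    def test_degenerate_simultaneous_softening(self):
        record = CookingRecord("R1", np.full(8, 30.0), [], 60.0)
        res = determine_cooking_time(record)
        assert res.ct == pytest.approx(30.0)

    def test_censored_when_too_few_soften(self):
        soft = np.array([20, 25, 30, 35, 40, np.nan, np.nan, np.nan])
        record = CookingRecord("R1", soft, [], 60.0)
        res = determine_cooking_time(record)
        assert res.censored
        assert res.ct == 60.0
        assert res.label == "> 60"

    def test_single_piece_record_uses_own_softening_time(self):
        record = CookingRecord("R1", np.array([28.0]), [(10.0, 1.0)], 60.0)
        res = determine_cooking_time(record)
        assert res.ct == pytest.approx(27.0)

    def test_required_exceeding_pieces_rejected(self):
        record = CookingRecord("R1", np.array([10.0, 12.0]), [], 60.0)
        with pytest.raises(ValueError):
            determine_cooking_time(record, required=3)

    def test_empty_piece_list_rejected(self):
        with pytest.raises(ValueError):
            CookingRecord("R1", np.array([]), [], 60.0)

    @given(
        soft=st.lists(st.floats(5.0, 55.0), min_size=4, max_size=12),
        durs=st.lists(st.floats(0.5, 2.0), min_size=0, max_size=5),
    )
    def test_clock_decomposition_conserved(self, soft, durs):
        """corrected CT + out-of-water time before softening = total-clock
        softening instant."""
        intervals = [(5.0 + 10.0 * k, d) for k, d in enumerate(durs)]
        record = CookingRecord("R1", np.array(soft), intervals, 100.0)
        res = determine_cooking_time(record)
        k = int(np.ceil(0.75 * len(soft)))
        t_soft = np.sort(soft)[k - 1]
        spent = sum(d for s, d in intervals if s < t_soft - 1e-12)
        assert res.ct + spent == pytest.approx(t_soft)


class TestGroupByCt:
    @pytest.mark.parametrize(
        "ct,expected",
        [(20.0, "short"), (25.0, "short"), (25.0001, "medium"),
         (40.0, "medium"), (43.0, "long")],
    )
    def test_rule(self, ct, expected):
        assert group_by_ct(ct) == expected

    @pytest.mark.parametrize("bad", [0.0, -3.0, float("nan"), float("inf")])
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            group_by_ct(bad)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_partition(self, ct):
        assert group_by_ct(ct) in ("short", "medium", "long")


def _curve(g, h, wab30):
    return WabCurve(g, h, "R1", np.array([0.0, 30.0]), np.array([0.0, wab30]))


class TestCorrelationTable:
    def test_hand_dataset(self):
        curves = [_curve(g, "H1", w) for g, w in
                  [("A", 15.0), ("B", 10.0), ("C", 5.0)]]
        cts = {"A": 20.0, "B": 30.0, "C": 50.0}
        tab = wab_ct_correlation_table(curves, cts, [30.0])
        # independent closed-form Pearson: -150 / sqrt(466.67 * 50)
        assert tab["r"].iloc[0] == pytest.approx(-0.98198, abs=1e-4)

    def test_zero_ct_variance_undefined(self):
        curves = [_curve(g, "H1", w) for g, w in
                  [("A", 15.0), ("B", 10.0), ("C", 5.0)]]
        cts = {"A": 30.0, "B": 30.0, "C": 30.0}
        tab = wab_ct_correlation_table(curves, cts, [30.0])
        assert np.isnan(tab["r"].iloc[0])
        assert not tab["significant"].iloc[0]

    def test_fewer_than_three_pairs_undefined_not_raised(self):
        curves = [_curve("A", "H1", 15.0), _curve("B", "H1", 10.0)]
        tab = wab_ct_correlation_table(curves, {"A": 20.0, "B": 30.0}, [30.0])
        assert np.isnan(tab["r"].iloc[0])


class TestReplicateSubsample:
    def _toy(self, n_reps=3):
        rng = np.random.default_rng(5)
        genos = [f"G{i}" for i in range(5)]
        cts = {g: 20.0 + 8.0 * i for i, g in enumerate(genos)}
        rows = []
        for g in genos:
            for r in range(1, n_reps + 1):
                rows.append((g, f"R{r}", 18.0 - 0.3 * cts[g] + rng.normal(0, 1)))
        return pd.DataFrame(rows, columns=["genotype", "rep", "wab30"]), cts

    def test_matches_bruteforce_enumeration(self):
        wab30, cts = self._toy()
        table = replicate_subsample_analysis(wab30, cts).set_index("subset")
        reps = sorted(wab30["rep"].unique())
        pivot = wab30.pivot(index="genotype", columns="rep", values="wab30")
        x = np.array([cts[g] for g in pivot.index])
        for k in range(1, 4):
            for combo in itertools.combinations(range(3), k):
                label = "Rep" + "_".join(str(i + 1) for i in combo)
                y = pivot[[reps[i] for i in combo]].mean(axis=1).to_numpy()
                r = np.corrcoef(x, y)[0, 1]
                assert table.loc[label, "r"] == pytest.approx(r, abs=1e-12)

    def test_identical_reps_give_identical_r(self):
        genos = [f"G{i}" for i in range(5)]
        cts = {g: 20.0 + 5 * i for i, g in enumerate(genos)}
        rows = [(g, f"R{r}", 18.0 - 0.3 * cts[g]) for g in genos
                for r in (1, 2, 3)]
        wab30 = pd.DataFrame(rows, columns=["genotype", "rep", "wab30"])
        table = replicate_subsample_analysis(wab30, cts)
        assert np.allclose(table["r"], table["r"].iloc[0])

    def test_averaging_reps_rarely_hurts(self):
        """|r| of the 3-rep mean is within 0.05 of the best single rep in
        >= 90% of simulations (averaging reduces replicate noise)."""
        wins = 0
        n_sim = 100
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            genos = [f"G{i}" for i in range(36)]
            cts = {g: float(rng.uniform(15, 60)) for g in genos}
            rows = [
                (g, f"R{r}", 18.0 - 0.25 * cts[g] + rng.normal(0, 2.0))
                for g in genos for r in (1, 2, 3)
            ]
            wab30 = pd.DataFrame(rows, columns=["genotype", "rep", "wab30"])
            tab = replicate_subsample_analysis(wab30, cts).set_index("subset")
            singles = max(abs(tab.loc[f"Rep{r}", "r"]) for r in (1, 2, 3))
            if abs(tab.loc["Rep1_2_3", "r"]) >= singles - 0.05:
                wins += 1
        assert wins >= 0.9 * n_sim

    def test_single_rep_input_rejected(self):
        df = pd.DataFrame({"genotype": ["A", "B"], "rep": ["R1", "R1"],
                           "wab30": [1.0, 2.0]})
        with pytest.raises(ValueError):
            replicate_subsample_analysis(df, {"A": 20.0, "B": 30.0})


class TestSummarizeGroups:
    def test_toy_mean_sd(self):
        df = pd.DataFrame(
            {"genotype": ["A", "B", "C"], "group": ["short"] * 3,
             "wab30": [15.0, 16.0, 14.0]}
        )
        out = summarize_groups(df).set_index("group")
        assert out.loc["short", "wab30_mean"] == pytest.approx(15.0)
        assert out.loc["short", "wab30_sd"] == pytest.approx(1.0)
        assert np.isnan(out.loc["medium", "wab30_mean"])

    def test_singleton_group_sd_undefined(self):
        df = pd.DataFrame({"genotype": ["A"], "group": ["long"],
                           "wab30": [5.0]})
        out = summarize_groups(df).set_index("group")
        assert out.loc["long", "wab30_mean"] == pytest.approx(5.0)
        assert np.isnan(out.loc["long", "wab30_sd"])

    def test_campaign_group_means_ordered(self, small_campaign_wab):
        out = small_campaign_wab["group_summary"].set_index("group")
        assert (out.loc["short", "wab30_mean"]
                > out.loc["medium", "wab30_mean"]
                > out.loc["long", "wab30_mean"])


class TestCampaignPipeline:
    def test_noise_free_curves_match_closed_form(self):
        from cooktime.synthetic import (
            GenotypeProfile,
            NoiseModel,
            TrialDesign,
            simulate_wab_trial,
        )
        from cooktime.wab import compute_wab_curve

        p = GenotypeProfile(
            genotype_id="G1", group="short", ct_true=20.0, wab_max=18.0,
            wab_tau=9.0, dmc_true=38.0, swell_alpha=1.4,
        )
        noise = NoiseModel(ve_ct=0, ve_wab=0, convection_range=0,
                           scale_resolution=1e-12, frag_rate=0.0)
        res = simulate_wab_trial(p, TrialDesign("H", 10, 1, 8), noise,
                                 rng=np.random.default_rng(0))[0]
        c = compute_wab_curve(res.series)
        expected = 18.0 * (1.0 - np.exp(-c.times / 9.0))
        assert np.allclose(c.wab, expected, atol=1e-7)

    def test_correlation_signs_on_default_campaign(self, small_campaign_wab):
        s = small_campaign_wab["summary"]
        r = np.corrcoef(s["ct_mean"], s["wab30"])[0, 1]
        assert r < -0.5
        assert abs(small_campaign_wab["ct_dmc"].r) < 0.45  # single campaign
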