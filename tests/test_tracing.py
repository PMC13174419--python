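import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ccmetab import (
    enrichment_discontinuity,
    fraction_test,
    fractional_labeling,
    generate_tracing,
    pool_partition,
)
from ccmetab.datamodel import IsotopologueTable
from ccmetab.diffstats import welch_arrays


def table_from_areas(areas_by_sample, conditions, metabolite="met", n_max=None):
    """areas_by_sample: {sample: [area_M0, area_M1, ...]}"""
    rows = []
    for sample, areas in areas_by_sample.items():
        for i, a in enumerate(areas):
            rows.append((metabolite, "C1", i, sample, float(a)))
    data = pd.DataFrame(rows, columns=["metabolite", "kegg_id", "mass_shift",
                                       "sample", "area"])
    cap = n_max if n_max is not None else max(len(v) for v in areas_by_sample.values()) - 1
    return IsotopologueTable(
        data=data, condition=pd.Series(conditions, name="condition"),
        n_max={metabolite: cap},
    )


class TestFractionalLabeling:
    def test_unlabeled_pool(self):
        t = table_from_areas({"s1": [100, 0, 0]}, {"s1": "c"})
        fl = fractional_labeling(t)
        row = fl.summary.iloc[0]
        assert row["labeled_fraction"] == 0.0
        assert row["mean_enrichment"] == 0.0
        assert fl.wide("met").iloc[0].tolist() == [1.0, 0.0, 0.0]

    def test_closed_form_fractions(self):
        t = table_from_areas({"s1": [25, 25, 50]}, {"s1": "c"})
        fl = fractional_labeling(t)
        row = fl.summary.iloc[0]
        assert fl.wide("met").iloc[0].tolist() == [0.25, 0.25, 0.5]
        assert row["labeled_fraction"] == pytest.approx(0.75)
        assert row["mean_enrichment"] == pytest.approx(0.625)
        assert row["pool"] == 100.0

    @settings(derandomize=True, max_examples=30)
    @given(c=st.floats(min_value=1e-6, max_value=1e6,
                       allow_nan=False, allow_infinity=False))
    def test_homogeneity_under_rescaling(self, c):
        base = table_from_areas({"s1": [40, 35, 25]}, {"s1": "c"})
        scaled = table_from_areas({"s1": [40 * c, 35 * c, 25 * c]}, {"s1": "c"})
        f1 = fractional_labeling(base).summary.iloc[0]
        f2 = fractional_labeling(scaled).summary.iloc[0]
        assert f2["labeled_fraction"] == pytest.approx(f1["labeled_fraction"], rel=1e-9)
        assert f2["mean_enrichment"] == pytest.approx(f1["mean_enrichment"], rel=1e-9)
        assert f2["pool"] == pytest.approx(c * f1["pool"], rel=1e-9)

    def test_zero_pool_flagged_undefined(self):
        t = table_from_areas({"s1": [0, 0, 0], "s2": [10, 5, 5]},
                             {"s1": "c", "s2": "c"})
        fl = fractional_labeling(t)
        by_sample = fl.summary.set_index("sample")
        assert not by_sample.loc["s1", "defined"]
        assert by_sample.loc["s2", "defined"]

    def test_missing_channels_filled_with_zero(self):
        # only M+0 and M+2 monitored for a 3-carbon metabolite
        rows = pd.DataFrame({
            "metabolite": ["met", "met"], "kegg_id": ["C1", "C1"],
            "mass_shift": [0, 2], "sample": ["s1", "s1"], "area": [60.0, 40.0],
        })
        t = IsotopologueTable(rows, pd.Series({"s1": "c"}), n_max={"met": 3})
        fl = fractional_labeling(t)
        assert fl.wide("met").iloc[0].tolist() == [0.6, 0.0, 0.4, 0.0]

    def test_fractions_sum_to_one(self):
        table, _ = generate_tracing(
            {("x", "c"): [0.2, 0.3, 0.5], ("x", "t"): [0.6, 0.3, 0.1]},
            n_per_group=5, noise_cv=0.2, seed=3)
        fl = fractional_labeling(table)
        sums = fl.fractions.groupby(["metabolite", "sample"])["f"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestPoolPartition:
    def test_identical_groups_null(self):
        areas = {"c_1": [50, 30, 20], "c_2": [50, 30, 20],
                 "t_1": [50, 30, 20], "t_2": [50, 30, 20]}
        t = table_from_areas(areas, {"c_1": "c", "c_2": "c", "t_1": "t", "t_2": "t"})
        res = pool_partition(t, "c", "t")
        assert (res["delta"] == 0.0).all()
        assert (res["p"] == 1.0).all()

    def test_planted_shift_detected(self):
        # unlabeled fraction collapses 0.9 -> 0.4 with strong labeling
        hits_m0_down = hits_m1_up = 0
        for seed in range(20):
            table, _ = generate_tracing(
                {("x", "c"): [0.9, 0.1], ("x", "t"): [0.4, 0.6]},
                n_per_group=6, noise_cv=0.1, seed=seed)
            res = pool_partition(table, "c", "t").set_index("quantity")
            hits_m0_down += res.loc["M+0", "direction"] == "down"
            hits_m1_up += res.loc["M+1", "direction"] == "up"
        assert hits_m0_down >= 19
        assert hits_m1_up >= 19

    def test_matches_direct_welch_on_columns(self):
        table, _ = generate_tracing(
            {("x", "c"): [0.5, 0.5], ("x", "t"): [0.3, 0.7]},
            n_per_group=4, noise_cv=0.2, seed=1)
        res = pool_partition(table, "c", "t").set_index("quantity")
        wide = table.data.pivot(index="sample", columns="mass_shift", values="area")
        x = wide.loc[[f"c_{i}" for i in range(1, 5)], 1].to_numpy()
        y = wide.loc[[f"t_{i}" for i in range(1, 5)], 1].to_numpy()
        t_direct, _, p_direct = welch_arrays(x, y)
        assert res.loc["M+1", "t"] == pytest.approx(t_direct, abs=1e-12)
        assert res.loc["M+1", "p"] == pytest.approx(p_direct, abs=1e-12)

    def test_unknown_condition_rejected(self):
        t = table_from_areas({"s1": [1, 1], "s2": [1, 1]}, {"s1": "c", "s2": "c"})
        with pytest.raises(ValueError):
            pool_partition(t, "c", "nope")


class TestFractionTest:
    def test_null_fractions_give_p_one(self):
        areas = {"c_1": [60, 40], "c_2": [60, 40], "t_1": [30, 20], "t_2": [30, 20]}
        t = table_from_areas(areas, {"c_1": "c", "c_2": "c", "t_1": "t", "t_2": "t"})
        res = fraction_test(fractional_labeling(t), "c", "t")
        assert (res["p"] == 1.0).all()       # same fractions despite pool change
        assert not res["reciprocal"].any()

    def test_planted_labeling_gain_flagged_up(self):
        hits = 0
        for seed in range(20):
            table, _ = generate_tracing(
                {("x", "c"): [0.8, 0.1, 0.1], ("x", "t"): [0.3, 0.2, 0.5]},
                n_per_group=6, noise_cv=0.1, seed=seed)
            res = fraction_test(fractional_labeling(table), "c", "t")
            row = res[(res["quantity"] == "L")].iloc[0]
            hits += row["direction"] == "up"
        assert hits >= 19

    def test_fraction_deltas_balance(self):
        table, _ = generate_tracing(
            {("x", "c"): [0.7, 0.2, 0.1], ("x", "t"): [0.2, 0.3, 0.5]},
            n_per_group=5, noise_cv=0.15, seed=2)
        res = fraction_test(fractional_labeling(table), "c", "t")
        deltas = res[res["quantity"].str.startswith("f_")]["delta"]
        assert deltas.sum() == pytest.approx(0.0, abs=1e-9)

    def test_reciprocal_flag_set_on_strong_shift(self):
        table, _ = generate_tracing(
            {("x", "c"): [0.9, 0.05, 0.05], ("x", "t"): [0.2, 0.3, 0.5]},
            n_per_group=6, noise_cv=0.05, seed=4)
        res = fraction_test(fractional_labeling(table), "c", "t")
        assert res["reciprocal"].all()


class TestRecovery:
    @pytest.mark.parametrize("cv", [0.0, 0.05, 0.2])
    def test_mean_fractions_converge_to_truth(self, cv):
        pi = np.array([0.25, 0.25, 0.5])
        table, _ = generate_tracing({("x", "t"): pi}, n_per_group=40,
                                    noise_cv=cv, seed=8)
        fl = fractional_labeling(table)
        est = fl.wide("x").mean(axis=0).to_numpy()
        tol = 1e-12 if cv == 0.0 else 4 * cv / np.sqrt(40)
        assert np.allclose(est, pi, atol=max(tol, 1e-12))


class TestDiscontinuity:
    def _chain_table(self, e_plan, seed, n=6, cv=0.1):
        # n_max=2 per metabolite; pi chosen to hit the target enrichment E
        lab = {(met, "t"): [1.0 - e, 0.0, e] for met, e in e_plan.items()}
        return generate_tracing(lab, n_per_group=n, noise_cv=cv, seed=seed)[0]

    def test_uniform_chain_all_zero_scores(self):
        areas = {"t_1": [20, 20, 60], "t_2": [20, 20, 60]}
        rows = []
        for met in ["a", "b", "c"]:
            for s, ar in areas.items():
                for i, v in enumerate(ar):
                    rows.append((met, "C1", i, s, float(v)))
        data = pd.DataFrame(rows, columns=["metabolite", "kegg_id", "mass_shift",
                                           "sample", "area"])
        t = IsotopologueTable(data, pd.Series({"t_1": "t", "t_2": "t"}),
                              n_max={m: 2 for m in "abc"})
        disc = enrichment_discontinuity(fractional_labeling(t), ["a", "b", "c"], "t",
                                        n_boot=0)
        assert (disc.edge_scores == 0.0).all()
        assert disc.argmax_edge is None

    def test_forced_step_profile(self):
        # E = (0.8, 0.8, 0.3, 0.3) exactly, no noise
        table = self._chain_table({"a": 0.8, "b": 0.8, "c": 0.3, "d": 0.3},
                                  seed=0, cv=0.0)
        disc = enrichment_discontinuity(fractional_labeling(table),
                                        ["a", "b", "c", "d"], "t", n_boot=100, seed=1)
        assert np.allclose(disc.edge_scores, [0.0, 0.5, 0.0], atol=1e-12)
        assert disc.argmax_edge == 2
        assert disc.ci[0] - 1e-9 <= 0.5 <= disc.ci[1] + 1e-9

    def test_planted_drain_detected_across_seeds(self):
        hits = 0
        for seed in range(30):
            table = self._chain_table({"a": 0.8, "b": 0.8, "c": 0.3, "d": 0.3},
                                      seed=seed, cv=0.1)
            disc = enrichment_discontinuity(fractional_labeling(table),
                                            ["a", "b", "c", "d"], "t", n_boot=0)
            hits += disc.argmax_edge == 2
        assert hits >= 29

    def test_absent_chain_member_named(self):
        t = table_from_areas({"t_1": [1, 1], "t_2": [1, 1]},
                             {"t_1": "t", "t_2": "t"})
        with pytest.raises(ValueError, match="ghost"):
            enrichment_discontinuity(fractional_labeling(t), ["met", "ghost"], "t")
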