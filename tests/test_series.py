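import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from palynostats import (CountTable, PalynError, cereal_ratio_series,
                         compare_modern, compose, coprophilous_continuity,
                         step_change, window_aggregate)


def make_series(cereal, denom, ages=None, flagged=None):
    n = len(cereal)
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "cereal_count": cereal,
        "denominator_count": denom,
        "flagged": flagged if flagged is not None else [d == 0 for d in denom],
    })
    df["ratio_percent"] = np.where(
        df["denominator_count"] > 0,
        100.0 * df["cereal_count"] / df["denominator_count"].replace(0, 1),
        np.nan)
    if ages is not None:
        df["age_ma"] = ages
    return df


def count_table(counts_dict, depths):
    counts = pd.DataFrame(counts_dict)
    counts.index = [f"s{i}" for i in range(len(counts))]
    meta = pd.DataFrame({"depth_m": depths}, index=counts.index)
    return CountTable(counts=counts, meta=meta)


class TestCerealRatioSeries:
    def test_no_cereals_gives_zero(self, toy_catalogue):
        t = count_table({"Poaceae": [37], "Cerealia-type": [0]}, [1.0])
        row = cereal_ratio_series(t, toy_catalogue).iloc[0]
        assert row["ratio_percent"] == 0.0

    def test_quarter_of_poaceae(self, toy_catalogue):
        # 5 cereal-type among 20 Poaceae in total
        t = count_table({"Poaceae": [15], "Cerealia-type": [5]}, [1.0])
        row = cereal_ratio_series(t, toy_catalogue).iloc[0]
        assert row["ratio_percent"] == pytest.approx(25.0)
        assert row["poaceae_total"] == 20

    def test_wild_only_denominator(self, toy_catalogue):
        t = count_table({"Poaceae": [15], "Cerealia-type": [5]}, [1.0])
        row = cereal_ratio_series(t, toy_catalogue,
                                  denominator="wild_only").iloc[0]
        assert row["ratio_percent"] == pytest.approx(100 * 5 / 15)

    def test_no_poaceae_flagged(self, toy_catalogue):
        t = count_table({"Poaceae": [0, 10], "Cerealia-type": [0, 0],
                         "Artemisia": [50, 50]}, [1.0, 2.0])
        out = cereal_ratio_series(t, toy_catalogue)
        assert bool(out.iloc[0]["flagged"])
        assert np.isnan(out.iloc[0]["ratio_percent"])

    def test_cereal_percent_of_ps_from_composition(self, toy_catalogue):
        t = count_table({"Poaceae": [150], "Cerealia-type": [50]}, [1.0])
        comp = compose(t, toy_catalogue)
        out = cereal_ratio_series(t, toy_catalogue, composition=comp)
        assert out.iloc[0]["cereal_percent_of_ps"] == pytest.approx(25.0)


class TestWindowAggregate:
    def test_pooled_and_mean_agree_for_equal_ratios(self):
        s = make_series([2, 3], [10, 10], ages=[1.0, 2.0])
        out = window_aggregate(s, 0.5, 2.5)
        assert out["pooled"] == pytest.approx(25.0)
        assert out["mean_of_samples"] == pytest.approx(25.0)
        assert out["n_samples"] == 2

    def test_single_sample_window(self):
        s = make_series([2, 9], [10, 10], ages=[1.0, 2.0])
        out = window_aggregate(s, 1.5, 2.5)
        assert out["pooled"] == out["mean_of_samples"] == pytest.approx(90.0)

    def test_empty_window_names_bounds(self):
        s = make_series([2], [10], ages=[1.0])
        with pytest.raises(PalynError, match=r"\[3.0, 4.0\]"):
            window_aggregate(s, 3.0, 4.0)

    def test_window_bounds_are_closed(self):
        s = make_series([1, 1], [10, 10], ages=[1.0, 2.0])
        assert window_aggregate(s, 1.0, 2.0)["n_samples"] == 2

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 100)),
                    min_size=1, max_size=20))
    def test_pooled_is_count_weighted_mean(self, pairs):
        cereal = [min(c, d) for c, d in pairs]
        denom = [d for _, d in pairs]
        s = make_series(cereal, denom,
                        ages=np.linspace(0, 2, len(pairs)))
        out = window_aggregate(s, -1, 3)
        weights = np.array(denom) / sum(denom)
        weighted = (weights * s["ratio_percent"].to_numpy()).sum()
        assert out["pooled"] == pytest.approx(weighted, rel=1e-9)


class TestStepChange:
    def test_exact_two_level_series(self):
        ages = np.linspace(0.1, 2.3, 12)
        ratios = np.where(ages >= 1.5, 25.0, 3.0)
        s = make_series((ratios / 10).astype(int) * 0 + 1,
                        [1] * 12, ages=ages)
        s["ratio_percent"] = ratios
        out = step_change(s)
        lo = ages[ages < 1.5].max()
        hi = ages[ages >= 1.5].min()
        assert lo < out["breakpoint_age_ma"] <= hi
        assert out["contrast"] == pytest.approx(22.0)
        assert out["before_mean"] == pytest.approx(25.0)
        assert out["after_mean"] == pytest.approx(3.0)

    def test_noisy_step_recovered_within_tolerance(self):
        rng = np.random.default_rng(0)
        ages = np.linspace(0.05, 2.3, 72)
        ratios = np.where(ages > 1.5, 25.0, 3.0) + rng.normal(0, 1.0, 72)
        s = make_series([1] * 72, [1] * 72, ages=ages)
        s["ratio_percent"] = ratios
        out = step_change(s)
        assert out["breakpoint_age_ma"] == pytest.approx(1.5, abs=0.1)

    def test_constant_series_warns_with_zero_contrast(self):
        s = make_series([2] * 6, [10] * 6, ages=np.linspace(0, 2, 6))
        with pytest.warns(UserWarning, match="constant"):
            out = step_change(s)
        assert out["contrast"] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_samples(self):
        s = make_series([1, 2], [10, 10], ages=[0.5, 1.5])
        with pytest.raises(PalynError, match="4"):
            step_change(s)


class TestCompareModern:
    def test_identical_series_difference_zero(self):
        s = make_series([5, 10, 3], [50, 60, 40], ages=[0.1, 0.2, 0.3])
        out = compare_modern(s, s.copy(), n_boot=500, seed=0)
        assert out["difference"] == 0.0
        lo, hi = out["bootstrap_ci95"]
        assert lo <= 0.0 <= hi

    def test_seed_determinism(self):
        f = make_series([5, 10, 3], [50, 60, 40])
        m = make_series([1, 0], [40, 30])
        a = compare_modern(f, m, n_boot=300, seed=7)
        b = compare_modern(f, m, n_boot=300, seed=7)
        assert a["bootstrap_ci95"] == b["bootstrap_ci95"]

    def test_clear_separation_excludes_zero(self):
        rng = np.random.default_rng(1)
        denom_f = rng.poisson(110, 72)
        f = make_series(rng.binomial(denom_f, 0.17), denom_f)
        denom_m = rng.poisson(80, 8)
        m = make_series(rng.binomial(denom_m, 0.045), denom_m)
        out = compare_modern(f, m, n_boot=1000, seed=1)
        lo, hi = out["bootstrap_ci95"]
        assert lo > 0.0

    def test_small_n_boot_warns(self):
        s = make_series([5], [50])
        with pytest.warns(UserWarning, match="n_boot"):
            compare_modern(s, s.copy(), n_boot=50, seed=0)

    def test_empty_series_rejected(self):
        s = make_series([5], [50])
        with pytest.raises(PalynError, match="non-empty"):
            compare_modern(s, s.iloc[:0], n_boot=200, seed=0)


class TestCoprophilousContinuity:
    def comp_frame(self, copro, ages):
        return pd.DataFrame({"coprophilous_percent": copro, "age_ma": ages})

    def test_all_present(self):
        ages = [0.0, 0.5, 1.5, 2.0]
        out = coprophilous_continuity(self.comp_frame([1, 2, 0.5, 3], ages))
        assert out["fraction_of_samples_present"] == 100.0
        assert out["longest_gap_ma"] == pytest.approx(1.0)

    def test_alternating_presence(self):
        out = coprophilous_continuity(
            self.comp_frame([1, 0, 2, 0], [0, 1, 2, 3]))
        assert out["fraction_of_samples_present"] == 50.0
        assert out["longest_gap_ma"] == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(PalynError):
            coprophilous_continuity(pd.DataFrame(
                columns=["coprophilous_percent"]))
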