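import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from midgepop.assay_stats import (
    angular_transform,
    inverse_angular_transform,
    estimate_fecundity,
    estimate_survival,
    two_sample_t,
    oneway_anova_tukey,
    summarize_thermal_profile,
    estimates_table,
)
from midgepop.synthetic_data import (
    gen_study_bundle,
    gen_thermal_profile,
    FECUNDITY_TREATMENTS,
    SURVIVAL_TREATMENTS,
)


def fec_table(counts, treatment="t"):
    return pd.DataFrame(
        {
            "pair_id": [f"p{i}" for i in range(len(counts))],
            "treatment": treatment,
            "eggs_laid": counts,
            "viable_eggs": [0] * len(counts),
        }
    )


def surv_table(pairs, treatment="t"):
    return pd.DataFrame(
        {
            "replicate_id": [f"r{i}" for i in range(len(pairs))],
            "treatment": treatment,
            "n_start": [n for _, n in pairs],
            "n_alive": [a for a, _ in pairs],
        }
    )


class TestAngularTransform:
    @pytest.mark.parametrize("p,expected", [(0, 0.0), (1, math.pi / 2), (0.5, math.pi / 4)])
    def test_boundary_and_symmetry_points(self, p, expected):
        assert angular_transform(p) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            angular_transform(1.01)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_and_exactly_inverted(self, p, q):
        lo, hi = sorted((p, q))
        assert angular_transform(lo) <= angular_transform(hi)
        assert inverse_angular_transform(angular_transform(p)) == pytest.approx(p, abs=1e-12)


class TestEstimateFecundity:
    def test_hand_computed_summary(self):
        est = estimate_fecundity(fec_table([40, 45, 44]), "t")
        assert est.mean == pytest.approx(43.0)
        assert est.sd == pytest.approx(math.sqrt(7), abs=1e-4)  # 2.6458
        assert est.se == pytest.approx(math.sqrt(7 / 3), abs=1e-4)  # 1.5275

    def test_constant_sample_has_zero_spread(self):
        est = estimate_fecundity(fec_table([42.9, 42.9, 42.9]), "t")
        assert est.mean == pytest.approx(42.9) and est.sd == 0.0

    def test_single_row_insufficient(self):
        with pytest.raises(ValueError):
            estimate_fecundity(fec_table([40]), "t")

    def test_row_order_invariance(self):
        a = estimate_fecundity(fec_table([40, 45, 44]), "t")
        b = estimate_fecundity(fec_table([44, 40, 45]), "t")
        assert (a.mean, a.sd) == (b.mean, b.sd)


class TestEstimateSurvival:
    def test_hand_computed_angular_means(self):
        est = estimate_survival(surv_table([(20, 25), (18, 25), (21, 25)]), "t")
        assert est.pooled_p == pytest.approx(59 / 75, abs=1e-4)
        assert est.mean_transformed == pytest.approx(1.0932, abs=1e-4)
        assert est.back_transformed_p == pytest.approx(0.789, abs=1e-3)
        assert est.back_transformed_p == pytest.approx(
            math.sin(est.mean_transformed) ** 2, abs=1e-12
        )

    def test_all_alive(self):
        est = estimate_survival(surv_table([(25, 25), (25, 25)]), "t")
        assert est.pooled_p == 1.0
        assert est.mean_transformed == pytest.approx(math.pi / 2, abs=1e-12)

    def test_total_mortality(self):
        est = estimate_survival(surv_table([(0, 40), (0, 40), (0, 40)]), "t")
        assert est.pooled_p == 0.0 and est.mean_transformed == 0.0

    def test_empty_treatment_rejected(self):
        with pytest.raises(ValueError):
            estimate_survival(surv_table([(20, 25)]), "missing")


class TestTwoSampleT:
    def test_pooled_variance_hand_computation(self):
        res = two_sample_t([1, 2, 3], [2, 3, 4], welch=False)
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4

    def test_identical_samples(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], welch=False)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_welch_equals_student_for_equal_n_and_variance(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]  # same spread, same n
        w = two_sample_t(x, y, welch=True)
        s = two_sample_t(x, y, welch=False)
        assert w.statistic == pytest.approx(s.statistic, abs=1e-12)
        assert w.df == pytest.approx(s.df, abs=1e-9)

    def test_short_sample_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1], [2, 3])


class TestAnovaTukey:
    def test_identical_groups_no_signal(self):
        res = oneway_anova_tukey({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.F == 0.0 and res.p_value == pytest.approx(1.0)
        assert all(p == pytest.approx(1.0, abs=1e-9) for *_, p in res.tukey_pairs)

    def test_one_shifted_group_drives_all_significance(self):
        res = oneway_anova_tukey({"a": [1, 2, 3], "b": [1, 2, 3], "c": [11, 12, 13]})
        padj = {frozenset((i, j)): p for i, j, _, p in res.tukey_pairs}
        assert padj[frozenset(("a", "b"))] == pytest.approx(1.0, abs=1e-6)
        assert padj[frozenset(("a", "c"))] < 0.01
        assert padj[frozenset(("b", "c"))] < 0.01

    def test_f_equals_t_squared_on_two_groups(self):
        x, y = [3.1, 4.5, 2.2, 5.0], [6.3, 7.1, 5.9]
        res = oneway_anova_tukey({"x": x, "y": y})
        t = two_sample_t(x, y, welch=False)
        assert res.F == pytest.approx(t.statistic**2, abs=1e-10)
        assert res.p_value == pytest.approx(t.p_value, abs=1e-10)

    def test_tukey_matches_reference_implementation(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = {
            "a": [5.1, 4.8, 5.5, 5.0],
            "b": [6.0, 6.4, 5.9, 6.2],
            "c": [5.3, 5.6, 5.2, 5.8],
        }
        res = oneway_anova_tukey(groups)
        vals = np.concatenate([groups[k] for k in groups])
        labs = np.repeat(list(groups), [len(groups[k]) for k in groups])
        ref = pairwise_tukeyhsd(vals, labs)
        ref_pairs = [(row[0], row[1]) for row in ref._results_table.data[1:]]
        ref_p = {frozenset(pair): p for pair, p in zip(ref_pairs, ref.pvalues)}
        ours = {frozenset((i, j)): p for i, j, _, p in res.tukey_pairs}
        for pair, p in ref_p.items():
            assert ours[pair] == pytest.approx(float(p), abs=1e-4)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova_tukey({"a": [1, 2, 3]})


class TestThermalSummary:
    def test_noise_free_sinusoid_closed_form(self):
        prof = gen_thermal_profile(days=1, interval=1, mean_temp=10, amplitude=5,
                                   damping=1.0, noise_sd=0.0)
        s = summarize_thermal_profile(prof, "outside")
        assert s.max_daily_change == pytest.approx(10.0, abs=1e-6)
        assert s.min_to_max_rate == pytest.approx(10.0 / 12.0, abs=1e-3)

    def test_constant_series_degenerate(self):
        prof = gen_thermal_profile(days=1, interval=1, mean_temp=4, amplitude=0,
                                   damping=1.0, noise_sd=0.0)
        s = summarize_thermal_profile(prof, "outside")
        assert s.max_daily_change == 0.0

    def test_damped_inside_has_half_the_change(self):
        prof = gen_thermal_profile(days=2, interval=1, mean_temp=4, amplitude=5,
                                   damping=0.5, noise_sd=0.0)
        out = summarize_thermal_profile(prof, "outside")
        ins = summarize_thermal_profile(prof, "inside")
        assert ins.max_daily_change == pytest.approx(out.max_daily_change / 2, abs=1e-9)

    def test_noisy_profile_gel_buffers_change(self):
        prof = gen_thermal_profile(days=3, interval=1, mean_temp=4, amplitude=5,
                                   damping=0.5, noise_sd=0.2, seed=9)
        out = summarize_thermal_profile(prof, "outside")
        ins = summarize_thermal_profile(prof, "inside")
        assert ins.max_daily_change < out.max_daily_change

    def test_short_profile_rejected(self):
        prof = gen_thermal_profile(days=1, interval=1, mean_temp=4, amplitude=5,
                                   damping=1.0)
        short = prof.data.iloc[:200]
        from midgepop.synthetic_data import ThermalProfile

        stub = ThermalProfile(data=short, sampling_interval=1, duration_days=0.14)
        with pytest.raises(ValueError):
            summarize_thermal_profile(stub, "outside")


class TestParameterRecovery:
    def test_all_estimates_within_three_se_at_scale(self):
        """Estimates from a x100 synthetic bundle recover generating values."""
        bundle = gen_study_bundle(seed=11, multiplier=100)
        for tr, params in FECUNDITY_TREATMENTS.items():
            est = estimate_fecundity(bundle.fecundity, tr)
            assert abs(est.mean - params["mean"]) < 3 * est.se, tr
        for tr, params in SURVIVAL_TREATMENTS.items():
            est = estimate_survival(bundle.survival, tr)
            n = params["n_replicates"] * 100 * params["unit_size"]
            se = math.sqrt(max(params["p"] * (1 - params["p"]), 1e-12) / n)
            if params["p"] in (0.0, 1.0):
                assert est.pooled_p == params["p"], tr
            else:
                assert abs(est.pooled_p - params["p"]) < 3 * se, tr

    def test_estimates_table_schema(self):
        tab = estimates_table(gen_study_bundle(seed=1))
        assert list(tab.columns) == ["treatment", "quantity", "estimate", "se", "n"]
        assert len(tab) == len(FECUNDITY_TREATMENTS) + len(SURVIVAL_TREATMENTS)
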