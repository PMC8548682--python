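"""Mixed ANOVA, simultaneous contrasts, subsampling, quantile comparisons."""

import numpy as np
import pandas as pd
import pytest

from digitbone.cohort_stats import (
    DEFAULT_CONTRASTS,
    compare_quantiles,
    fit_mixed_anova,
    subsample_for_modulus,
    test_contrasts as run_contrasts,
)
from digitbone.densitometry import DensitySample
from digitbone.synthetic import IndentationEffects, simulate_indentation_study

SINGLE_CONTRAST = [("UA distal vs D42 distal", ("distal", "UA"), ("distal", "D42"))]


class TestMixedAnova:
    def test_noiseless_design_recovers_status_effect_exactly(self):
        eff = IndentationEffects(
            sd_mouse=0.0, sd_site=0.0, sd_indent=0.0,
            sd_mouse_H=0.0, sd_site_H=0.0, sd_indent_H=0.0,
        )
        df = simulate_indentation_study(eff, seed=0)
        fit = fit_mixed_anova(df, response="E")
        c = run_contrasts(fit, SINGLE_CONTRAST)[0]
        assert c.estimate == pytest.approx(1.96, abs=1e-6)

    def test_constant_response_gives_zero_effects(self):
        eff = IndentationEffects(
            status_effect=0.0, status_effect_H=0.0,
            sd_mouse=0.0, sd_site=0.0, sd_indent=0.0,
            sd_mouse_H=0.0, sd_site_H=0.0, sd_indent_H=0.0,
        )
        df = simulate_indentation_study(eff, seed=0)
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_mixed_anova(df, response="E")
        np.testing.assert_allclose(fit.fe_params[1:], 0.0, atol=1e-6)
        assert fit.vcomp["mouse"] == pytest.approx(0.0, abs=1e-6)
        assert fit.vcomp["site"] == pytest.approx(0.0, abs=1e-6)

    def test_stochastic_recovery_within_three_se(self):
        df = simulate_indentation_study(IndentationEffects(), seed=42)
        fit = fit_mixed_anova(df, response="E")
        c = run_contrasts(fit, SINGLE_CONTRAST)[0]
        assert abs(c.estimate - 1.96) <= 3 * c.se

    def test_containment_df(self):
        df = simulate_indentation_study(IndentationEffects(), seed=0)
        fit = fit_mixed_anova(df, response="E")
        # 3 mice x 2 digits x 8 sites = 48 site units, minus 4 fixed effects
        assert fit.df_contrast == 44.0
        assert fit.metadata["df_method"] == "containment"
        no_site = fit_mixed_anova(df, response="E", include_site=False)
        assert no_site.df_contrast == len(df) - 4 - (3 - 1)

    def test_missing_cell_rejected(self):
        df = simulate_indentation_study(IndentationEffects(), seed=0)
        with pytest.raises(ValueError, match="cells"):
            fit_mixed_anova(df[df["region"] == "distal"], response="E")

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            fit_mixed_anova(pd.DataFrame({"E": [1.0]}), response="E")


class TestContrasts:
    @pytest.fixture(scope="class")
    def fitted(self):
        df = simulate_indentation_study(IndentationEffects(), seed=5)
        return fit_mixed_anova(df, response="E")

    def test_family_of_one_equals_unadjusted(self, fitted):
        from scipy import stats

        c = run_contrasts(fitted, SINGLE_CONTRAST)[0]
        t = c.estimate / c.se
        p_exact = 2 * stats.t.sf(abs(t), fitted.df_contrast)
        assert c.p_adjusted == pytest.approx(p_exact, abs=1e-12)

    def test_default_family_of_three(self, fitted):
        res = run_contrasts(fitted)
        assert [c.name for c in res] == [name for name, _, _ in DEFAULT_CONTRASTS]
        for c in res:
            assert c.ci_low <= c.estimate <= c.ci_high
            assert 0.0 <= c.p_adjusted <= 1.0

    def test_maxt_adjustment_between_unadjusted_and_bonferroni(self, fitted):
        from scipy import stats

        maxt = run_contrasts(fitted)
        bonf = run_contrasts(fitted, method="bonferroni")
        for cm, cb in zip(maxt, bonf):
            p_unadj = 2 * stats.t.sf(abs(cm.estimate / cm.se), fitted.df_contrast)
            assert cm.p_adjusted >= p_unadj - 0.01
            assert cm.p_adjusted <= cb.p_adjusted + 0.01

    def test_rank_deficient_family_rejected(self, fitted):
        dup = [SINGLE_CONTRAST[0], SINGLE_CONTRAST[0]]
        with pytest.raises(ValueError, match="rank-deficient"):
            run_contrasts(fitted, dup)


class TestSubsample:
    def _table(self, sizes):
        rows = []
        for (digit, region), size in sizes.items():
            for i in range(size):
                rows.append((digit, region, float(i)))
        return pd.DataFrame(rows, columns=["digit", "region", "modulus"])

    def test_exact_stratum_used_in_full(self):
        t = self._table({("d1", "proximal"): 1000, ("d1", "distal"): 1200})
        out = subsample_for_modulus(t, n=1000)
        counts = out.groupby(["digit", "region"]).size()
        assert counts[("d1", "proximal")] == 1000
        assert counts[("d1", "distal")] == 1000
        prox = out[out.region == "proximal"]["modulus"]
        np.testing.assert_array_equal(np.sort(prox), np.arange(1000.0))

    def test_small_stratum_warns_and_keeps_all(self):
        t = self._table({("d1", "proximal"): 50, ("d1", "distal"): 1000})
        with pytest.warns(UserWarning, match="using all"):
            out = subsample_for_modulus(t, n=1000)
        assert (out.groupby(["digit", "region"]).size()[("d1", "proximal")]) == 50

    def test_determinism_and_seed_record(self):
        t = self._table({("d1", "proximal"): 2000, ("d1", "distal"): 2000})
        a = subsample_for_modulus(t, n=1000, seed=3)
        b = subsample_for_modulus(t, n=1000, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert a.attrs["seed"] == 3


def _group(rng, shift=0.0, n_mice=3, n_digits=2, n_vals=500):
    out = []
    for m in range(n_mice):
        bm = rng.normal(0, 0.05)
        for d in range(n_digits):
            bd = rng.normal(0, 0.04)
            out.append(DensitySample(
                values=0.6 + bm + bd + rng.normal(0, 0.15, n_vals) + shift,
                mouse=f"m{m}", digit=f"m{m}-d{d}",
            ))
    return out


class TestCompareQuantiles:
    def test_identical_groups_give_zero_differences(self):
        rng = np.random.default_rng(0)
        a = _group(rng)
        b = [DensitySample(values=s.values.copy(), mouse=s.mouse, digit=s.digit)
             for s in a]
        res = compare_quantiles(a, b, n_boot=300, seed=1)
        np.testing.assert_allclose(res["estimate"], 0.0, atol=1e-12)
        assert ((res["ci_low"] <= 0) & (res["ci_high"] >= 0)).all()

    def test_constant_shift_recovered_at_every_percentile(self):
        rng = np.random.default_rng(1)
        a = _group(rng)
        b = [DensitySample(values=s.values + 0.1, mouse=s.mouse, digit=s.digit)
             for s in a]
        res = compare_quantiles(a, b, n_boot=300, seed=2)
        np.testing.assert_allclose(res["estimate"], 0.1, atol=1e-12)
        assert ((res["ci_low"] <= 0.1) & (res["ci_high"] >= 0.1)).all()

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(2)
        a, b = _group(rng), _group(rng, shift=0.05)
        ab = compare_quantiles(a, b, n_boot=200, seed=3)
        ba = compare_quantiles(b, a, n_boot=200, seed=3)
        np.testing.assert_allclose(ab["estimate"], -ba["estimate"], atol=1e-12)

    def test_equivariant_under_common_shift(self):
        rng = np.random.default_rng(3)
        a, b = _group(rng), _group(rng, shift=0.05)
        res = compare_quantiles(a, b, n_boot=200, seed=4)
        a2 = [DensitySample(values=s.values + 1.0, mouse=s.mouse, digit=s.digit)
              for s in a]
        b2 = [DensitySample(values=s.values + 1.0, mouse=s.mouse, digit=s.digit)
              for s in b]
        res2 = compare_quantiles(a2, b2, n_boot=200, seed=4)
        np.testing.assert_allclose(res["estimate"], res2["estimate"], atol=1e-9)

    def test_low_n_boot_warns(self):
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning, match="unstable"):
            compare_quantiles(_group(rng), _group(rng), n_boot=100, seed=0)

    def test_single_digit_group_rejected(self):
        rng = np.random.default_rng(5)
        a = _group(rng)
        with pytest.raises(ValueError, match="two digits"):
            compare_quantiles(a[:1], a, n_boot=300, seed=0)

    def test_bad_percentile_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="percentile"):
            compare_quantiles(_group(rng), _group(rng), percentiles=(0, 50),
                              n_boot=300)
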