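"""Colony-structured morphometric statistics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import beecastes as bc
from beecastes.synth import SpeciesGeneratorSpec, generate_colony_dataset


def make_records(colonies, species="sp"):
    """colonies: list of (guard_values, forager_values)."""
    rows = []
    for ci, (g, f) in enumerate(colonies):
        for role, vals in (("guard", g), ("forager", f)):
            for j, v in enumerate(vals):
                rows.append({"species": species, "colony": f"c{ci}",
                             "bee_id": f"c{ci}_{role}{j}", "role": role,
                             "head_width_mm": v, "wet_weight_mg": np.nan,
                             "gray_level": np.nan, "reference_gray": np.nan,
                             "cuticle_um": np.nan})
    return pd.DataFrame(rows)


class TestCVCorrected:
    def test_zero_variance(self):
        assert bc.cv_corrected([2, 2, 2]) == 0

    def test_hand_computation(self):
        x = [1.0, 1.1, 0.9, 1.0]
        expected = (1 + 1 / 16) * np.std(x, ddof=1) / np.mean(x)
        assert bc.cv_corrected(x) == pytest.approx(expected, rel=1e-12)

    @given(st.lists(st.floats(0.5, 10), min_size=2, max_size=30),
           st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, xs, c):
        a = bc.cv_corrected(xs)
        b = bc.cv_corrected([c * x for x in xs])
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)

    def test_correction_factor_shrinks_with_n(self, rng):
        x = rng.normal(10, 1, size=5000)
        assert bc.cv_corrected(x) == pytest.approx(np.std(x, ddof=1) / x.mean(),
                                                   rel=1e-3)

    def test_errors(self):
        with pytest.raises(ValueError):
            bc.cv_corrected([1.0])
        with pytest.raises(ValueError):
            bc.cv_corrected([-1.0, -2.0])


class TestDifferentiationIndex:
    def test_matches_definition_per_colony(self, rng):
        recs = make_records([(rng.normal(1.9, 0.05, 10), rng.normal(1.7, 0.05, 10)),
                             (rng.normal(1.95, 0.05, 8), rng.normal(1.72, 0.05, 12))])
        per_colony = []
        for _, grp in recs.groupby("colony"):
            g = grp[grp.role == "guard"].head_width_mm
            f = grp[grp.role == "forager"].head_width_mm
            per_colony.append(abs(g.mean() - f.mean())
                              / grp.head_width_mm.std(ddof=1))
        assert bc.differentiation_index(recs) == pytest.approx(np.mean(per_colony))

    def test_equal_means_give_zero(self):
        recs = make_records([( [1.6, 1.8], [1.8, 1.6] )])
        assert bc.differentiation_index(recs) == pytest.approx(0.0)

    def test_shift_and_scale_invariance(self, rng):
        recs = make_records([(rng.normal(2.0, 0.1, 12), rng.normal(1.8, 0.1, 12))])
        base = bc.differentiation_index(recs)
        shifted = recs.assign(head_width_mm=recs.head_width_mm + 5.0)
        scaled = recs.assign(head_width_mm=recs.head_width_mm * 3.0)
        assert bc.differentiation_index(shifted) == pytest.approx(base, rel=1e-9)
        assert bc.differentiation_index(scaled) == pytest.approx(base, rel=1e-9)

    def test_colony_lacking_one_role_skipped_then_error(self):
        recs = make_records([([1.9, 1.95], [1.7, 1.75]), ([1.9, 1.95], [])])
        with pytest.warns(UserWarning, match="skipped"):
            di = bc.differentiation_index(recs)
        assert di > 0
        only_bad = make_records([([1.9, 1.95], [])])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no colony"):
                bc.differentiation_index(only_bad)

    def test_generator_recovery_at_bimodal_settings(self):
        # two separated modes at the strongest differentiation seen in the wild
        est = []
        for i in range(60):
            spec = SpeciesGeneratorSpec(n_colonies=6, n_guards_target=50,
                                        n_foragers_target=50, di=1.6,
                                        bimodal=True)
            est.append(bc.differentiation_index(
                generate_colony_dataset(spec, seed=3000 + i)))
        assert np.mean(est) == pytest.approx(1.6, abs=0.15)


class TestCentreByColony:
    def test_single_colony(self):
        recs = make_records([([1.0, 2.0], [3.0])])
        out = bc.centre_by_colony(recs)
        assert sorted(out) == [-1.0, 0.0, 1.0]

    def test_colony_shift_removed(self, rng):
        recs = make_records([(rng.normal(2, 0.1, 6), rng.normal(2, 0.1, 6)),
                             (rng.normal(3, 0.1, 6), rng.normal(3, 0.1, 6))])
        out = bc.centre_by_colony(recs)
        shifted = recs.copy()
        mask = shifted.colony == "c1"
        shifted.loc[mask, "head_width_mm"] += 5.0
        out2 = bc.centre_by_colony(shifted)
        assert np.allclose(out, out2, atol=1e-12)
        for _, grp in recs.groupby("colony"):
            assert abs(out.loc[grp.index].mean()) < 1e-12
        assert abs(out.mean()) < 1e-12


class TestMelanization:
    @pytest.mark.parametrize("g,r,m", [(200, 200, 0.0), (0, 150, 1.0),
                                       (0.25, 0.50, 0.5)])
    def test_values(self, g, r, m):
        assert bc.melanization_level(g, r) == pytest.approx(m)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            bc.melanization_level(1.0, 0.0)


class TestLME:
    def test_no_colony_variance_matches_pooled_ols(self, rng):
        recs = make_records([(rng.normal(2.05, 0.03, 20), rng.normal(2.0, 0.03, 20)),
                             (rng.normal(2.05, 0.03, 20), rng.normal(2.0, 0.03, 20)),
                             (rng.normal(2.05, 0.03, 20), rng.normal(2.0, 0.03, 20))])
        fit = bc.lme_random_intercept(recs)
        g = recs[recs.role == "guard"].head_width_mm.mean()
        f = recs[recs.role == "forager"].head_width_mm.mean()
        assert fit.fixed_effect_estimate == pytest.approx(g - f, abs=1e-6)

    def test_balanced_design_matches_anova_variance_components(self, rng):
        c, m = 6, 10
        sd_col, sd_res, delta = 0.04, 0.02, 0.05
        rows = []
        for ci in range(c):
            u = rng.normal(0, sd_col)
            rows.append((rng.normal(2 + delta + u, sd_res, m),
                         rng.normal(2 + u, sd_res, m)))
        recs = make_records(rows)
        fit = bc.lme_random_intercept(recs)
        # ANOVA estimators: residual MS from the colony+role fixed model,
        # colony MS from colony means (role balanced within colony)
        y = recs.head_width_mm.to_numpy()
        cell = recs.groupby(["colony", "role"]).head_width_mm.transform("mean")
        # residual within colony x role cells, plus df bookkeeping for the
        # additive model (no interaction): fit fixed colony+role by centering
        role = (recs.role == "guard").astype(float)
        import numpy.linalg as la
        X = np.column_stack([np.ones_like(y), role.to_numpy()]
                            + [(recs.colony == f"c{i}").astype(float).to_numpy()
                               for i in range(1, c)])
        beta, *_ = la.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ms_e = resid @ resid / (len(y) - c - 1)
        cmeans = recs.groupby("colony").head_width_mm.mean()
        ms_c = 2 * m * cmeans.var(ddof=1)
        sigma_c2 = max((ms_c - ms_e) / (2 * m), 0.0)
        assert fit.variance_components["residual"] == pytest.approx(ms_e, rel=1e-3)
        assert fit.variance_components["colony"] == pytest.approx(sigma_c2, rel=0.05)

    def test_simulation_calibration_of_estimate(self):
        ests = []
        for i in range(80):
            spec = SpeciesGeneratorSpec(n_colonies=6, n_guards_target=20,
                                        n_foragers_target=20,
                                        forager_mean_mm=2.0, cv=0.015,
                                        colony_sd_mm=0.02)
            recs = generate_colony_dataset(spec, seed=4000 + i)
            recs.loc[recs.role == "guard", "head_width_mm"] += 0.05
            ests.append(bc.lme_random_intercept(recs).fixed_effect_estimate)
        assert np.mean(ests) == pytest.approx(0.05, abs=0.01)

    def test_shuffled_roles_give_uniform_pvalues(self, rng):
        spec = SpeciesGeneratorSpec(n_colonies=6, n_guards_target=15,
                                    n_foragers_target=15, colony_sd_mm=0.03)
        recs = generate_colony_dataset(spec, seed=77)
        pvals = []
        for i in range(300):
            shuffled = recs.copy()
            shuffled["role"] = rng.permutation(shuffled["role"].to_numpy())
            try:
                pvals.append(bc.lme_random_intercept(shuffled).p_value)
            except ValueError:
                continue
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_colony_falls_back_to_ttest(self, rng):
        recs = make_records([(rng.normal(2.1, 0.05, 10), rng.normal(2, 0.05, 10))])
        with pytest.warns(UserWarning, match="t-test"):
            fit = bc.lme_random_intercept(recs)
        assert fit.fallback_ttest
        g = recs[recs.role == "guard"].head_width_mm
        f = recs[recs.role == "forager"].head_width_mm
        t, p = stats.ttest_ind(g, f)
        assert fit.t_value == pytest.approx(t)
        assert fit.p_value == pytest.approx(p)

    def test_nested_random_effects_fit(self, rng):
        rows = []
        for ci in range(6):
            u = rng.normal(0, 0.3)
            for role, off in (("guard", 0.5), ("forager", 0.0)):
                for b in range(3):
                    bee_mean = rng.normal(5 + off + u, 0.2)
                    for rep in range(3):
                        rows.append({"species": "Fv", "colony": f"c{ci}",
                                     "bee_id": f"c{ci}_{role}{b}", "role": role,
                                     "head_width_mm": 2.0,
                                     "wet_weight_mg": np.nan,
                                     "gray_level": np.nan,
                                     "reference_gray": np.nan,
                                     "cuticle_um": rng.normal(bee_mean, 0.05)})
        recs = pd.DataFrame(rows)
        fit = bc.lme_random_intercept(recs, response="cuticle", nested=True)
        assert fit.fixed_effect_estimate == pytest.approx(0.5, abs=0.25)
        assert fit.variance_components["bee"] >= 0


class TestRMA:
    def test_perfect_isometry(self, rng):
        hw = rng.uniform(1.5, 2.5, 30)
        w = hw ** 3  # head width equals cube-root weight exactly
        fit = bc.rma_allometry(hw, w)
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert fit.p_value > 0.9

    def test_slope_is_sd_ratio(self, rng):
        x = rng.normal(0, 0.2, 60)
        y = 0.5 * x + rng.normal(0, 0.01, 60)
        hw = 10 ** y
        w = (10 ** x) ** 3
        fit = bc.rma_allometry(hw, w)
        sy, sx = np.std(np.log10(hw), ddof=1), np.std(np.log10(w) / 3, ddof=1)
        assert fit.slope == pytest.approx(sy / sx, rel=1e-10)

    def test_rma_identity_geometric_mean_of_ols_slopes(self, rng):
        x = rng.normal(0, 0.15, 40)
        y = 0.7 * x + rng.normal(0, 0.05, 40)
        fit = bc.rma_allometry(10 ** y, (10 ** x) ** 3)
        b_yx = np.polyfit(x, y, 1)[0]
        b_xy = np.polyfit(y, x, 1)[0]
        assert abs(fit.slope) == pytest.approx(np.sqrt(abs(b_yx / b_xy)),
                                               rel=1e-10)

    def test_power_against_isometry(self, rng):
        rejections = 0
        for i in range(200):
            r = np.random.default_rng(5000 + i)
            x = r.normal(0, 0.2, 60)
            y = 0.5 * x + r.normal(0, 0.075, 60)   # r ~ 0.8
            fit = bc.rma_allometry(10 ** y, (10 ** x) ** 3)
            rejections += (fit.p_value <= 0.05 and fit.slope < 1)
        assert rejections / 200 > 0.9

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            bc.rma_allometry([1, 2], [1, 2])
        with pytest.raises(ValueError):
            bc.rma_allometry([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            bc.rma_allometry([1, 2, -3], [1, 2, 3])


class TestBH:
    def test_single_p_unchanged(self):
        assert bc.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_ties_all_equal(self):
        assert np.allclose(bc.bh_adjust([0.2] * 5), 0.2)

    def test_matches_stepup_definition(self):
        p = np.array([0.01, 0.02, 0.03, 0.2])
        m = len(p)
        order = np.argsort(p)
        scaled = p[order] * m / (np.arange(m) + 1)
        expected = np.minimum.accumulate(scaled[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(expected, 1)
        assert np.allclose(bc.bh_adjust(p), out)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_never_decreases_and_preserves_bonferroni(self, ps):
        adj = bc.bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        m = len(ps)
        for p, a in zip(ps, adj):
            if p <= 0.05 / m:      # Bonferroni-significant stays significant
                assert a <= 0.05 + 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bc.bh_adjust([0.5, 1.2])
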