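"""Follicle shape statistics: axes, elongation coefficient, ANCOVA, eAR."""

import numpy as np
import pandas as pd
import pytest

from follipulse import follshape as fs
from follipulse.errors import GeometryError, InputError, InsufficientDataError
from follipulse.synthgen import CohortSpec, gen_ellipse_mask, gen_follicle_cohort


class TestAxes:
    def test_ellipse_axes_match_analytic_values(self):
        mask, _ = gen_ellipse_mask(40, 20, 0, 1.0)
        long_ax, short_ax, orient = fs.fit_follicle_axes(mask)
        assert long_ax == pytest.approx(80, rel=0.02)
        assert short_ax == pytest.approx(40, rel=0.02)
        assert abs(orient) < 2.0

    def test_circle_axes_equal(self):
        mask, _ = gen_ellipse_mask(25, 25, 0, 1.0)
        long_ax, short_ax, _ = fs.fit_follicle_axes(mask)
        assert long_ax == pytest.approx(short_ax, rel=0.01)

    def test_rotation_preserves_axes_and_reports_angle(self):
        m0, _ = gen_ellipse_mask(40, 20, 0, 1.0)
        m30, _ = gen_ellipse_mask(40, 20, 30, 1.0)
        l0, s0, _ = fs.fit_follicle_axes(m0)
        l30, s30, o30 = fs.fit_follicle_axes(m30)
        assert l30 == pytest.approx(l0, rel=0.02)
        assert s30 == pytest.approx(s0, rel=0.02)
        assert abs(abs(o30) - 30) < 2.0

    def test_disconnected_mask_rejected(self):
        mask = np.zeros((50, 50), bool)
        mask[5:15, 5:15] = True
        mask[30:45, 30:45] = True
        with pytest.raises(GeometryError):
            fs.fit_follicle_axes(mask)


class TestAspectRatio:
    def test_sphere_is_one(self):
        assert fs.aspect_ratio({"long_axis_um": 30, "short_axis_um": 30}) == 1.0

    def test_paper_style_value(self):
        assert fs.aspect_ratio({"long_axis_um": 50, "short_axis_um": 20}) == 2.5

    def test_noiseless_cohort_all_equal_slope(self):
        coh = gen_follicle_cohort(
            CohortSpec(n_follicles=20, slope=1.6, intercept=0.0, noise_sd=0.0)
        )
        ars = [fs.aspect_ratio(r) for _, r in coh.iterrows()]
        assert np.allclose(ars, 1.6)

    def test_invalid_record_rejected(self):
        with pytest.raises(InputError):
            fs.aspect_ratio({"long_axis_um": 10, "short_axis_um": 20})


class TestElongationCoefficient:
    def test_spheres_give_slope_exactly_one(self):
        coh = gen_follicle_cohort(
            CohortSpec(n_follicles=30, slope=1.0, intercept=0.0, noise_sd=0.0)
        )
        fit = fs.elongation_coefficient(coh, max_stage=None)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_slope_recovered_exactly(self):
        coh = gen_follicle_cohort(
            CohortSpec(n_follicles=25, slope=1.6, intercept=5.0, noise_sd=0.0)
        )
        fit = fs.elongation_coefficient(coh, max_stage=None)
        assert fit.slope == pytest.approx(1.6, abs=1e-9)

    def test_noisy_slope_ci_covers_truth(self):
        coh = gen_follicle_cohort(
            CohortSpec(n_follicles=200, slope=1.6, noise_sd=2.0, seed=31)
        )
        fit = fs.elongation_coefficient(coh, max_stage=None)
        assert fit.slope_ci[0] <= 1.6 <= fit.slope_ci[1]

    def test_stage_filter_excludes_late_stages(self):
        coh = gen_follicle_cohort(CohortSpec(n_follicles=30, noise_sd=0.0))
        coh.loc[coh.index[-10:], "stage"] = 8
        fit = fs.elongation_coefficient(coh, max_stage=8)
        assert fit.n == 20

    def test_too_few_records_rejected(self):
        coh = gen_follicle_cohort(CohortSpec(n_follicles=2, noise_sd=0.0))
        with pytest.raises(InsufficientDataError):
            fs.elongation_coefficient(coh, max_stage=None)


class TestAncova:
    def _cohorts(self, s1, s2, n=100, sd=2.0):
        a = gen_follicle_cohort(
            CohortSpec(n_follicles=n, slope=s1, noise_sd=sd,
                       genotype_label="wt", seed=1, spacing="random")
        )
        b = gen_follicle_cohort(
            CohortSpec(n_follicles=n, slope=s2, noise_sd=sd,
                       genotype_label="mut", seed=2, spacing="random")
        )
        return pd.concat([a, b], ignore_index=True)

    def test_identical_cohorts_not_significant(self):
        df = self._cohorts(1.3, 1.3)
        res = fs.compare_elongation(df, max_stage=None)
        assert (res.pairwise.p_adj > 0.05).all()

    def test_distinct_slopes_detected(self):
        df = self._cohorts(1.6, 1.0)
        res = fs.compare_elongation(df, max_stage=None)
        assert res.pairwise.p_adj.iloc[0] < 1e-3
        assert res.slopes["wt"] == pytest.approx(1.6, abs=0.1)
        assert res.slopes["mut"] == pytest.approx(1.0, abs=0.1)

    def test_three_groups_give_three_contrasts(self):
        df = self._cohorts(1.6, 1.0)
        c = gen_follicle_cohort(
            CohortSpec(n_follicles=50, slope=1.3, noise_sd=2.0,
                       genotype_label="het", seed=3, spacing="random")
        )
        res = fs.compare_elongation(
            pd.concat([df, c], ignore_index=True), max_stage=None
        )
        assert len(res.pairwise) == 3

    def test_single_group_rejected(self):
        coh = gen_follicle_cohort(CohortSpec(n_follicles=10, noise_sd=1.0))
        with pytest.raises(InputError):
            fs.compare_elongation(coh, max_stage=None)


class TestEAR:
    @pytest.mark.parametrize("a,b", [(40, 20), (60, 20), (28, 11)])
    def test_ellipse_identity_both_poles(self, a, b):
        mask, true_ar = gen_ellipse_mask(a, b, 0, 1.0)
        for pole in ("anterior", "posterior"):
            r = fs.extrapolated_AR(mask, pole)
            assert r.eAR == pytest.approx(true_ar, rel=0.02)

    def test_circle_ear_one(self):
        mask, _ = gen_ellipse_mask(30, 30, 0, 1.0)
        assert fs.extrapolated_AR(mask, "anterior").eAR == pytest.approx(
            1.0, rel=0.02
        )

    def test_extrapolated_width_at_least_chord(self):
        mask, _ = gen_ellipse_mask(40, 20, 0, 1.0)
        r = fs.extrapolated_AR(mask, "posterior")
        assert r.extrapolated_width >= r.width_at_25 * 0.99

    def test_rotation_invariance(self):
        vals = []
        for orient in (0, 30, 60):
            mask, _ = gen_ellipse_mask(40, 20, orient, 1.0)
            vals.append(fs.extrapolated_AR(mask, "anterior").eAR)
        assert np.ptp(vals) < 0.08

    def test_scale_invariance_via_pixel_size(self):
        m1, _ = gen_ellipse_mask(40, 20, 0, 1.0)
        m2, _ = gen_ellipse_mask(40, 20, 0, 0.5)  # double resolution
        e1 = fs.extrapolated_AR(m1, "anterior", 1.0).eAR
        e2 = fs.extrapolated_AR(m2, "anterior", 0.5).eAR
        assert e1 == pytest.approx(e2, rel=0.02)

    def test_stretched_anterior_half_raises_anterior_ear(self):
        # composite: anterior half of a longer ellipse glued to a shorter one
        long_m, _ = gen_ellipse_mask(50, 20, 0, 1.0)
        short_m, _ = gen_ellipse_mask(40, 20, 0, 1.0)
        hl, wl = long_m.shape
        hs, ws = short_m.shape
        comp = np.zeros((hl, wl // 2 + ws // 2), bool)
        comp[:, : wl // 2] = long_m[:, : wl // 2]
        comp[(hl - hs) // 2 : (hl - hs) // 2 + hs, wl // 2 :] = short_m[
            :, ws // 2 : ws // 2 + comp.shape[1] - wl // 2
        ]
        ant = fs.extrapolated_AR(comp, "anterior", orientation_deg=0.0).eAR
        post = fs.extrapolated_AR(comp, "posterior", orientation_deg=0.0).eAR
        assert ant > post

    def test_bad_pole_name_rejected(self):
        mask, _ = gen_ellipse_mask(30, 20, 0, 1.0)
        with pytest.raises(InputError):
            fs.extrapolated_AR(mask, "north")


class TestComparePoles:
    def _table(self, shift_wt=0.3, shift_mut=0.0, n=15, sd=0.1, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, shift in (("wt", shift_wt), ("mut", shift_mut)):
            for i in range(n):
                post = rng.normal(2.0, sd)
                ant = post + shift + rng.normal(0, sd)
                rows.append(dict(follicle_id=f"{g}{i}", genotype=g,
                                 pole="anterior", eAR=ant))
                rows.append(dict(follicle_id=f"{g}{i}", genotype=g,
                                 pole="posterior", eAR=post))
        return pd.DataFrame(rows)

    def test_no_pole_difference_not_significant(self):
        res = fs.compare_poles(self._table(shift_wt=0.0, shift_mut=0.0, seed=4))
        pole_p = res.anova.loc[res.anova.Source == "pole", "p_unc"].iloc[0]
        assert pole_p > 0.05

    def test_anterior_shift_detected(self):
        res = fs.compare_poles(self._table(seed=0))
        wt = res.pairwise[res.pairwise.genotype == "wt"]
        assert wt.p_adj.iloc[0] < 1e-3
        mut = res.pairwise[res.pairwise.genotype == "mut"]
        assert mut.p_adj.iloc[0] > 0.05

    def test_crossover_gives_interaction(self):
        res = fs.compare_poles(self._table(shift_wt=0.3, shift_mut=-0.3, seed=1))
        inter = res.anova.loc[res.anova.Source == "Interaction", "p_unc"].iloc[0]
        assert inter < 1e-3

    def test_incomplete_follicles_excluded_with_warning(self):
        df = self._table()
        df = df.drop(df[(df.follicle_id == "wt0")
                        & (df.pole == "posterior")].index)
        with pytest.warns(UserWarning):
            res = fs.compare_poles(df)
        assert "wt0" in res.excluded
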