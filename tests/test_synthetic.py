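"""Synthetic cohort, regional table, and phantom generators: moment and
correlation recovery, seeded determinism, and validity invariants."""

import numpy as np
import pandas as pd
import pytest

from neoclaustrum import defaults as D
from neoclaustrum.synthetic import (
    CohortSpec,
    EffectParams,
    OutcomeEffect,
    PhantomSpec,
    RegionalCovSpec,
    RegionDef,
    default_effects,
    default_longitudinal_effects,
    default_regional_spec,
    generate_cohort,
    generate_longitudinal_cohort,
    generate_phantom,
    generate_regional_table,
)


def _long_spec(n=53, seed=5, **kw):
    return CohortSpec(
        n_preterm=n,
        n_term=0,
        scan_age={"term": D.TERM_SCAN_AGE, "preterm": D.LONGITUDINAL_FIRST_SCAN_AGE},
        second_scan_age=D.LONGITUDINAL_SECOND_SCAN_AGE,
        scan_age_window=None,
        seed=seed,
        **kw,
    )


class TestCohort:
    def test_counts_and_demographic_invariants(self, default_cohort):
        t = default_cohort
        assert len(t) == 166
        assert t.groupby("group").size().to_dict() == {"preterm": 83, "term": 83}
        assert (t["scan_age"] >= t["birth_age"]).all()
        assert (t.loc[t.group == "preterm", "birth_age"] < 37).all()
        assert t.loc[t.group == "term", "birth_age"].between(37, 42).all()
        lo, hi = D.MATCHED_SCAN_AGE_WINDOW
        assert t["scan_age"].between(lo - 1e-9, hi + 1e-9).all()

    def test_seeded_determinism(self):
        a = generate_cohort(CohortSpec(seed=42))
        b = generate_cohort(CohortSpec(seed=42))
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(CohortSpec(seed=43))
        assert not a["volume_right"].equals(c["volume_right"])

    def test_moment_recovery_all_outcomes(self):
        """At n=2000 per group every outcome's empirical mean/SD sits within
        3 standard errors of its specified marginal value."""
        spec = CohortSpec(n_preterm=2000, n_term=2000, seed=7)
        eff = default_effects()
        t = generate_cohort(spec, eff)
        for name, o in eff.outcomes.items():
            for group in ("preterm", "term"):
                vals = t.loc[t.group == group, name]
                mean, sd = o.group(group)
                n = len(vals)
                se_mean = sd / np.sqrt(n)
                se_sd = sd / np.sqrt(2 * (n - 1))
                # the truncated scan-age window shifts the mean by
                # slope * (E[age|window] - mean age): well below 1 SE here
                assert abs(vals.mean() - mean) < 3 * se_mean + abs(o.slope) * 0.02, name
                assert abs(vals.std(ddof=1) - sd) < 3 * se_sd, name

    def test_term_fa_mean_recovers_printed_value(self):
        """Combined term-group claustrum FA ~ 0.218 (per-side means 0.216
        and 0.219)."""
        t = generate_cohort(CohortSpec(n_preterm=0, n_term=2000, seed=3))
        fa = t["fa_mean"]
        assert abs(fa.mean() - 0.218) < 3 * 0.025 / np.sqrt(len(fa)) + 5e-4

    def test_negative_residual_variance_is_a_parameter_error(self):
        eff = EffectParams(
            outcomes={"volume_right": OutcomeEffect(341, 5, 363, 5, slope=17.1)}
        )
        with pytest.raises(ValueError, match="residual variance"):
            generate_cohort(CohortSpec(seed=1), eff)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CohortSpec(n_preterm=-1)
        with pytest.raises(ValueError):
            CohortSpec(sex_ratio=1.5)
        with pytest.raises(ValueError, match="below GA 37"):
            CohortSpec(birth_age_bounds={"term": (37, 42), "preterm": (24, 38)})
        with pytest.raises(ValueError, match="FA mean"):
            EffectParams(outcomes={"fa_right": OutcomeEffect(1.2, 0.1, 0.5, 0.1)})


class TestLongitudinal:
    def test_two_sessions_per_subject_with_increasing_age(self):
        t = generate_longitudinal_cohort(_long_spec())
        assert len(t) == 106
        assert t["subject_id"].nunique() == 53
        wide = t.pivot(index="subject_id", columns="session_id", values="scan_age")
        assert (wide["ses-2"] > wide["ses-1"]).all()

    def test_difference_variance_decomposition_without_intercept(self):
        """With zero within-subject intercept SD, the first-to-second-scan
        difference variance equals slope^2 * var(delta age) + 2 * residual
        variance (independent-session decomposition)."""
        eff = default_longitudinal_effects()
        o = eff.outcomes["volume_right"]
        eff0 = EffectParams(
            outcomes={"volume_right": OutcomeEffect(
                o.term_mean, o.term_sd, o.preterm_mean, o.preterm_sd,
                slope=o.slope, intercept_sd=0.0)},
            side_correlation=eff.side_correlation,
        )
        t = generate_longitudinal_cohort(_long_spec(n=4000, seed=9), eff0)
        wide = t.pivot(index="subject_id", columns="session_id")
        dy = wide[("volume_right", "ses-2")] - wide[("volume_right", "ses-1")]
        da = wide[("scan_age", "ses-2")] - wide[("scan_age", "ses-1")]
        resid_var = o.preterm_sd**2 - o.slope**2 * D.LONGITUDINAL_SECOND_SCAN_AGE[1] ** 2
        expected = o.slope**2 * da.var(ddof=1) + 2 * resid_var
        assert dy.var(ddof=1) == pytest.approx(expected, rel=0.1)

    def test_mean_weekly_volume_change_recovers_slope(self):
        """With a volume growth of 14.6 mm^3/week injected, the regression
        of volume change on age change recovers the slope within 3 SE."""
        eff = default_longitudinal_effects()
        o = eff.outcomes["volume_right"]
        eff2 = EffectParams(outcomes={"volume_right": OutcomeEffect(
            o.term_mean, o.term_sd, o.preterm_mean, o.preterm_sd,
            slope=14.6, intercept_sd=o.intercept_sd)})
        t = generate_longitudinal_cohort(_long_spec(n=4000, seed=10), eff2)
        wide = t.pivot(index="subject_id", columns="session_id")
        dy = (wide[("volume_right", "ses-2")] - wide[("volume_right", "ses-1")]).to_numpy()
        da = (wide[("scan_age", "ses-2")] - wide[("scan_age", "ses-1")]).to_numpy()
        da_c = da - da.mean()
        slope = (da_c * dy).sum() / (da_c**2).sum()
        resid = dy - dy.mean() - slope * da_c
        se = np.sqrt(resid.var(ddof=2) / (da_c**2).sum())
        assert abs(slope - 14.6) < 3 * se

    def test_requires_second_scan_distribution(self):
        with pytest.raises(ValueError, match="second_scan_age"):
            generate_longitudinal_cohort(CohortSpec(n_preterm=5, n_term=0))


class TestRegionalTable:
    def test_default_scheme_has_published_region_counts(self, default_cohort):
        spec = default_regional_spec()
        table = generate_regional_table(spec, default_cohort, seed=1)
        for metric in ("md", "fa"):
            cols = [c for c in table.columns if c.endswith(f"__{metric}")
                    and not c.startswith("claustrum")]
            by_class = {
                cls: sum(c.startswith(cls) for c in cols)
                for cls in ("cortical_gm", "subcortical_gm", "wm")
            }
            assert by_class == {"cortical_gm": 34, "subcortical_gm": 12, "wm": 33}

    def test_null_correlations_scale_like_one_over_sqrt_n(self):
        regions = tuple(RegionDef(f"r{i}", "wm") for i in range(30))
        spec = RegionalCovSpec(
            regions=regions,
            rho={(g, "md"): {r.region_id: 0.0 for r in regions} for g in ("preterm", "term")},
            region_scale={(r.region_id, "md"): (1.0, 0.1) for r in regions},
            metrics=("md",),
        )
        n = 1000
        cohort = generate_cohort(CohortSpec(n_preterm=0, n_term=n, seed=4))
        table = generate_regional_table(spec, cohort, seed=4)
        rs = np.array([
            np.corrcoef(table["claustrum__md"], table[f"r{i}__md"])[0, 1]
            for i in range(30)
        ])
        # E|r| under the null is ~ sqrt(2/pi)/sqrt(n)
        assert np.abs(rs).mean() < 3 / np.sqrt(n)

    def test_strong_correlation_recovered(self):
        regions = (RegionDef("r0", "cortical_gm"),)
        spec = RegionalCovSpec(
            regions=regions,
            rho={(g, "md"): {"r0": 0.9} for g in ("preterm", "term")},
            region_scale={("r0", "md"): (1.2, 0.05)},
            metrics=("md",),
        )
        n = 5000
        cohort = generate_cohort(CohortSpec(n_preterm=0, n_term=n, seed=8))
        table = generate_regional_table(spec, cohort, seed=8)
        r = np.corrcoef(table["claustrum__md"], table["r0__md"])[0, 1]
        se = (1 - 0.9**2) / np.sqrt(n)
        assert abs(r - 0.9) < 3 * se

    def test_rho_out_of_range_rejected(self):
        regions = (RegionDef("r0", "wm"),)
        with pytest.raises(ValueError, match="rho"):
            RegionalCovSpec(
                regions=regions,
                rho={("term", "md"): {"r0": 1.0}},
                region_scale={("r0", "md"): (1.0, 0.1)},
                metrics=("md",),
            )


class TestPhantom:
    def test_claustrum_present_and_surrounded_by_insular_wm(self, small_phantom):
        from neoclaustrum.rois import dilate_chebyshev

        vol = small_phantom.labels
        for side in ("left", "right"):
            cla = vol.data == vol.scheme.claustrum_id(side)
            assert cla.sum() > 0
            shell = dilate_chebyshev(cla, 2) & ~cla
            insular = np.isin(vol.data, vol.scheme.role_ids("insular_wm"))
            assert (insular[shell]).all()

    def test_zero_noise_gives_exact_tissue_means(self, small_phantom):
        vol, fa = small_phantom.labels, small_phantom.fa
        cla = vol.data == vol.scheme.claustrum_id("left")
        vals = np.unique(fa.data[cla])
        assert len(vals) == 1
        assert vals[0] == small_phantom.expected["fa_left"]

    def test_seeds_change_noise_but_not_geometry(self):
        spec = PhantomSpec(shape=(48, 48, 40))
        a = generate_phantom(spec, seed=1)
        b = generate_phantom(spec, seed=2)
        assert np.array_equal(a.labels.data, b.labels.data)
        assert not np.array_equal(a.md.data, b.md.data)

    def test_grids_share_shape_and_all_labels_appear(self, small_phantom):
        assert small_phantom.labels.data.shape == small_phantom.md.data.shape
        present = set(np.unique(small_phantom.labels.data).tolist())
        assert present == set(small_phantom.labels.scheme.labels)

    def test_too_small_grid_is_a_generation_error(self):
        with pytest.raises(ValueError):
            generate_phantom(PhantomSpec(shape=(12, 12, 10)), seed=0)
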