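import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from penguinperf import preprocess as pp


class TestTransforms:
    @pytest.mark.parametrize(
        "date,expected",
        [
            (dt.date(2004, 12, 31), 0.0),
            (dt.date(2004, 12, 15), 16.0),
            (dt.date(2004, 11, 30), 31.0),
            (dt.date(2005, 1, 5), -5.0),  # January counts against prior 31 Dec
        ],
    )
    def test_clutch_date_days_prior_to_dec31(self, date, expected):
        assert pp.transform_clutch_date(date) == expected

    def test_clutch_date_outside_breeding_window(self):
        with pytest.raises(ValueError, match="window"):
            pp.transform_clutch_date(dt.date(2004, 3, 15))

    @pytest.mark.parametrize("hours,expected", [(60.0, 0.0), (48.0, 12.0), (75.0, -15.0)])
    def test_trip_duration_hours_short_of_60(self, hours, expected):
        assert pp.transform_trip_duration(hours) == expected

    def test_trip_duration_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            pp.transform_trip_duration(0.0)

    def test_logit_midpoint_and_closed_form(self):
        assert pp.logit_transform(0.5) == 0.0
        assert pp.logit_transform(0.75) == pytest.approx(math.log(3.0))

    def test_logit_empirical_adjustment_at_zero(self):
        # with 50 trials, the boundary proportion becomes (0 + 0.5) / 51
        q = 0.5 / 51
        assert pp.logit_transform(0.0, n=50) == pytest.approx(math.log(q / (1 - q)))

    def test_logit_clamps_without_counts(self):
        eps = 1e-3
        assert pp.logit_transform(0.0) == pytest.approx(math.log(eps / (1 - eps)))

    def test_logit_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            pp.logit_transform(1.2)

    def test_egg_volume_empirical_relationship(self):
        # V = c L W^2 with mm inputs and c = 0.000507 gives cm^3
        assert 0.000507 * 70 * 50**2 == pytest.approx(88.725)
        eggs = [(55.0, 70.0, 50.0), (45.0, 70.0, 50.0)]
        v = 0.000507 * 70 * 50**2
        assert pp.egg_density(eggs) == pytest.approx(100.0 / (2 * v))

    def test_egg_density_unit_example(self):
        # dimensions chosen so each egg has V = 50 cm^3: density = 100 g / 100 cm^3
        eggs = [(55.0, 10.0, 100.0), (45.0, 10.0, 100.0)]
        assert pp.egg_density(eggs, volume_coef=0.0005) == pytest.approx(1.0)

    def test_egg_density_homogeneous_in_mass(self):
        eggs = [(55.0, 68.0, 47.0), (45.0, 71.0, 49.0)]
        doubled = [(2 * m, length, w) for m, length, w in eggs]
        assert pp.egg_density(doubled) == pytest.approx(2 * pp.egg_density(eggs))

    def test_egg_density_requires_two_eggs(self):
        with pytest.raises(ValueError, match="2-egg"):
            pp.egg_density([(50.0, 70.0, 50.0)])


class TestStandardize:
    def test_three_point_example(self):
        np.testing.assert_allclose(pp.standardize([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        z = pp.standardize(np.random.default_rng(0).normal(3.0, 2.0, 40))
        np.testing.assert_allclose(pp.standardize(z), z, atol=1e-12)

    @given(
        loc=st.floats(-1e3, 1e3),
        scale=st.floats(0.01, 1e3),
        seed=st.integers(0, 2**16),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_group_moments_property(self, loc, scale, seed):
        vals = loc + scale * np.random.default_rng(seed).normal(size=30)
        z = pp.standardize(vals)
        assert abs(z.mean()) < 1e-10
        assert abs(z.var(ddof=1) - 1.0) < 1e-10

    def test_constant_group_errors_with_group_name(self):
        df = pd.DataFrame(
            dict(parameter="p", species="s", site="x", year=[1, 2, 3], value=1.0)
        )
        with pytest.raises(ValueError, match=r"\('p', 's', 'x'\)"):
            pp.standardize_performance(df)

    def test_all_groups_standardized(self, study):
        out = pp.standardize_performance(pp.apply_parameter_transform(study.performance))
        for _, grp in out.groupby(["parameter", "species", "site"]):
            assert abs(grp["value"].mean()) < 1e-10
            assert abs(grp["value"].var(ddof=1) - 1.0) < 1e-10


class TestSeasonalClimate:
    def _climate(self, entries):
        return pd.DataFrame(
            [{"index": "ONI", "year": y, "month": m, "value": v} for y, m, v in entries]
        )

    def test_constant_series(self):
        clim = self._climate([(2014, m, 0.7) for m in range(4, 10)])
        assert pp.seasonal_climate(clim, "ONI", "winter", 2014) == pytest.approx(0.7)

    def test_summer_split_year_assignment(self):
        # summer 2005 must average exactly Oct 2004 - Mar 2005
        months = [(2004, 10), (2004, 11), (2004, 12), (2005, 1), (2005, 2), (2005, 3)]
        vals = [0.1, 0.4, -0.2, 0.9, 0.5, -0.6]
        clim = self._climate([(y, m, v) for (y, m), v in zip(months, vals)])
        # decoys that must not enter the mean
        clim = pd.concat([clim, self._climate([(2005, 10, 9.9), (2004, 9, 9.9)])])
        assert pp.seasonal_climate(clim, "ONI", "summer", 2005) == pytest.approx(np.mean(vals))

    def test_winter_uses_apr_to_sep(self):
        vals = {4: 1.0, 5: 2.0, 6: 3.0, 7: 4.0, 8: 5.0, 9: 6.0}
        clim = self._climate([(2014, m, v) for m, v in vals.items()])
        assert pp.seasonal_climate(clim, "ONI", "winter", 2014) == pytest.approx(3.5)

    def test_missing_months_listed(self):
        clim = self._climate([(2014, m, 0.0) for m in (4, 5, 6)])
        with pytest.raises(ValueError, match=r"\(2014, 7\)"):
            pp.seasonal_climate(clim, "ONI", "winter", 2014)


class TestCategories:
    @pytest.mark.parametrize(
        "oni,cat", [(-0.5, "low"), (-0.51, "low"), (0.0, "mid"), (0.49, "mid"), (0.5, "high")]
    )
    def test_oni_event_thresholds(self, oni, cat):
        assert pp.categorize_oni(oni) == cat

    @pytest.mark.parametrize("sam,sign", [(-0.3, "neg"), (0.3, "pos"), (0.0, "pos")])
    def test_sam_sign_with_zero_tiebreak(self, sam, sign):
        assert pp.sam_sign(sam) == sign

    @pytest.mark.parametrize("lkb,cat", [(1e6, "low"), (1e6 + 1, "high"), (1e4, "low")])
    def test_lkb_one_megatonne_threshold(self, lkb, cat):
        assert pp.categorize_lkb(lkb) == cat

    @pytest.mark.parametrize(
        "lhr,cat", [(0.0, "low"), (0.01, "low"), (0.05, "mid"), (0.1, "high"), (0.32, "high")]
    )
    def test_lhr_thresholds(self, lhr, cat):
        assert pp.categorize_lhr(lhr) == cat

    @given(st.floats(-5, 5, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_oni_total_and_exclusive(self, oni):
        cats = [pp.categorize_oni(oni)]
        assert len(cats) == 1 and cats[0] in pp.ONI_LEVELS

    @given(st.floats(0.0, 1.0, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_lhr_total_and_exclusive(self, lhr):
        assert pp.categorize_lhr(lhr) in pp.LHR_LEVELS

    def test_bin_bijection_onto_1_to_18(self):
        seen = set()
        for o in pp.ONI_LEVELS:
            for b in pp.LKB_LEVELS:
                for h in pp.LHR_LEVELS:
                    k = pp.bin_label(o, b, h)
                    assert pp.bin_to_categories(k) == (o, b, h)
                    seen.add(k)
        assert seen == set(range(1, 19))

    def test_bin_rejects_bad_labels(self):
        with pytest.raises(ValueError):
            pp.bin_label("low", "medium", "low")


class TestLHR:
    def test_ratio(self):
        assert pp.compute_lhr(100_000, 1_000_000) == pytest.approx(0.1)
        assert pp.compute_lhr(0.0, 5e5) == 0.0

    @given(
        catch=st.floats(0, 1e5),
        lkb=st.floats(1e3, 1e8),
        k=st.floats(0.1, 10),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_scale_invariance(self, catch, lkb, k):
        assert pp.compute_lhr(k * catch, k * lkb) == pytest.approx(pp.compute_lhr(catch, lkb))

    def test_rejects_nonpositive_biomass(self):
        with pytest.raises(ValueError):
            pp.compute_lhr(10.0, 0.0)


class TestMatchAndPool:
    def _mini_predictors(self):
        rows = []
        for stratum in ("Bransfield", "Drake"):
            rows.append(
                dict(stratum=stratum, season="winter", year=2014, oni=0.0, oni_cat="mid",
                     sam=1.0, sam_sign="pos", lkb_t=2e6, catch_t=1e5, lhr=0.05,
                     lkb_cat="high", lhr_cat="mid", bin=pp.bin_label("mid", "high", "mid"))
            )
            rows.append(
                dict(stratum=stratum, season="winter", year=2013, oni=0.0, oni_cat="mid",
                     sam=1.0, sam_sign="pos", lkb_t=np.nan, catch_t=0.0, lhr=np.nan,
                     lkb_cat=None, lhr_cat=None, bin=np.nan)
            )
            rows.append(
                dict(stratum=stratum, season="summer", year=2013, oni=-1.0, oni_cat="low",
                     sam=-1.0, sam_sign="neg", lkb_t=np.nan, catch_t=100.0, lhr=np.nan,
                     lkb_cat=None, lhr_cat=None, bin=np.nan)
            )
        return pd.DataFrame(rows)

    def _obs(self, site, species, season, year):
        return pd.DataFrame(
            [dict(site=site, species=species, parameter="p", season=season, year=year, value=0.1)]
        )

    def test_copacabana_maps_to_bransfield(self):
        analysis, _ = pp.match_and_pool(
            self._obs("Copacabana", "Adelie", "winter", 2014), self._mini_predictors()
        )
        assert analysis.iloc[0]["stratum"] == "Bransfield"
        assert analysis.iloc[0]["bin"] == pp.bin_label("mid", "high", "mid")

    def test_cape_shirreff_chinstrap_maps_to_drake(self):
        analysis, _ = pp.match_and_pool(
            self._obs("Cape Shirreff", "chinstrap", "winter", 2014), self._mini_predictors()
        )
        assert analysis.iloc[0]["stratum"] == "Drake"

    def test_unmapped_site_errors(self):
        with pytest.raises(KeyError, match="Esperanza"):
            pp.match_and_pool(
                self._obs("Esperanza", "Adelie", "winter", 2014), self._mini_predictors()
            )

    def test_winter_without_lkb_excluded_with_reason(self):
        analysis, excl = pp.match_and_pool(
            self._obs("Copacabana", "gentoo", "winter", 2013), self._mini_predictors()
        )
        assert analysis.empty
        assert "not imputable" in excl.iloc[0]["reason"]

    def test_summer_without_lkb_flagged_imputable(self):
        analysis, excl = pp.match_and_pool(
            self._obs("Copacabana", "gentoo", "summer", 2013), self._mini_predictors()
        )
        assert excl.empty
        assert bool(analysis.iloc[0]["imputable"]) is True

    def test_missing_predictor_year_flagged_not_dropped_silently(self):
        _, excl = pp.match_and_pool(
            self._obs("Copacabana", "gentoo", "winter", 1999), self._mini_predictors()
        )
        assert excl.iloc[0]["reason"] == "no predictor record"

    def test_same_categories_same_bin(self, prepared):
        analysis, _, _ = prepared
        with_bin = analysis[analysis["bin"].notna()]
        for _, grp in with_bin.groupby(["oni_cat", "lkb_cat", "lhr_cat"]):
            assert grp["bin"].nunique() == 1
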