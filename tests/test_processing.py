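"""Spot aggregation, dilution-series fitting and normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossrppa.exceptions import ConfigError
from crossrppa.processing import (
    aggregate_technical_replicates,
    fit_dilution_matrix,
    fit_dilution_series,
    log2_matrix,
    normalise_total_protein,
    process_platform,
    qc_dynamic_range,
)
from crossrppa.synthetic import (
    AntigenConfig,
    AntibodyProbe,
    PlatformConfig,
    StudyDesign,
    generate_design,
    generate_latent_antigens,
    render_platform,
)

from .oracles import ols_line


def spot_rows(sample, antibody, step, intensities):
    return [
        {
            "sample_id": sample,
            "antibody_id": antibody,
            "dilution_step": step,
            "technical_replicate": k + 1,
            "intensity": v,
        }
        for k, v in enumerate(intensities)
    ]


class TestAggregation:
    @pytest.mark.parametrize(
        "intensities, expected",
        [((100, 110, 90), 100.0), ((42,), 42.0), ((100, 200), 150.0)],
    )
    def test_median_of_technical_replicates(self, intensities, expected):
        spots = pd.DataFrame(spot_rows("s1", "ab1", 0, intensities))
        agg = aggregate_technical_replicates(spots)
        assert agg.loc[0, "intensity"] == expected


class TestDilutionFit:
    def test_exact_twofold_series(self):
        fit = fit_dilution_series([0, 1, 2, 3], [800, 400, 200, 100])
        assert fit.intercept == pytest.approx(np.log2(800))
        assert fit.slope == pytest.approx(-1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_saturated_series_has_zero_slope(self):
        fit = fit_dilution_series([0, 1, 2, 3], [500, 500, 500, 500])
        assert fit.slope == pytest.approx(0.0)

    def test_matches_independent_least_squares(self):
        x = [0, 1, 2, 3]
        y = [1000, 480, 260, 130]
        fit = fit_dilution_series(x, y)
        intercept, slope = ols_line(x, np.log2(y))
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        assert fit.slope == pytest.approx(slope, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        ys=st.lists(st.floats(1.0, 1e6, allow_nan=False), min_size=3, max_size=8)
    )
    def test_random_series_match_oracle(self, ys):
        x = list(range(len(ys)))
        fit = fit_dilution_series(x, ys)
        intercept, slope = ols_line(x, np.log2(ys))
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)
        assert fit.slope == pytest.approx(slope, abs=1e-9)

    def test_all_floored_series_flagged(self):
        fit = fit_dilution_series([0, 1, 2], [1.0, 1.0, 1.0], detection_floor=1.0)
        assert fit.flag == "floored"
        assert np.isnan(fit.intercept)

    def test_single_usable_step_flagged_insufficient(self):
        fit = fit_dilution_series([0, 1, 2], [500.0, 0.0, 0.0])
        assert fit.flag == "insufficient"

    def test_vectorised_fits_match_per_series_calls(self, rng):
        rows = []
        for s in range(4):
            for ab in range(3):
                for step in range(4):
                    rows.extend(
                        spot_rows(f"s{s}", f"ab{ab}", step, rng.uniform(2, 1000, 2))
                    )
        spots = pd.DataFrame(rows)
        agg = aggregate_technical_replicates(spots)
        fits = fit_dilution_matrix(agg, detection_floor=1.0)
        for (sid, ab), grp in agg.groupby(["sample_id", "antibody_id"]):
            single = fit_dilution_series(
                grp["dilution_step"], grp["intensity"], detection_floor=1.0
            )
            row = fits.loc[(sid, ab)]
            assert row["intercept"] == pytest.approx(single.intercept, abs=1e-9)
            assert row["slope"] == pytest.approx(single.slope, abs=1e-9)
            assert row["r2"] == pytest.approx(single.r2, abs=1e-9)


class TestTotalProtein:
    def _values(self):
        return pd.DataFrame(
            [[10.0, 20.0], [30.0, 40.0]], index=["s1", "s2"], columns=["a", "b"]
        )

    def test_unit_total_protein_is_identity(self):
        tp = pd.Series([1.0, 1.0], index=["s1", "s2"])
        out = normalise_total_protein(self._values(), tp)
        pd.testing.assert_frame_equal(out, self._values())

    def test_homogeneity_in_total_protein(self):
        tp1 = pd.Series([1.0, 1.0], index=["s1", "s2"])
        tp2 = pd.Series([2.0, 1.0], index=["s1", "s2"])
        a = normalise_total_protein(self._values(), tp1)
        b = normalise_total_protein(self._values(), tp2)
        assert (b.loc["s1"] == a.loc["s1"] / 2).all()
        assert (b.loc["s2"] == a.loc["s2"]).all()

    def test_zero_total_protein_names_sample(self):
        tp = pd.Series([1.0, 0.0], index=["s1", "s2"])
        with pytest.raises(ConfigError, match="s2"):
            normalise_total_protein(self._values(), tp)

    def test_preserves_within_sample_rank_order(self, rng):
        values = pd.DataFrame(
            rng.uniform(1, 100, (5, 8)), index=[f"s{i}" for i in range(5)]
        )
        tp = pd.Series(rng.uniform(0.5, 2.0, 5), index=values.index)
        out = normalise_total_protein(values, tp)
        for s in values.index:
            assert (values.loc[s].rank() == out.loc[s].rank()).all()


class TestLog2:
    def test_values_and_guard(self):
        values = pd.DataFrame([[8.0, 1.0, 0.0]], index=["s1"], columns=list("abc"))
        with pytest.warns(UserWarning, match="non-positive"):
            out, flags = log2_matrix(values)
        assert out.loc["s1", "a"] == 3.0
        assert out.loc["s1", "b"] == 0.0
        assert np.isnan(out.loc["s1", "c"])
        assert flags.loc["s1", "c"] == "nonpositive"


class TestQcAndRecovery:
    def _noise_free_platform(self, **kw):
        probes = [AntibodyProbe("ab1", "A", "r1", noise_sd=0.0),
                  AntibodyProbe("ab2", "B", "r2", noise_sd=0.0)]
        return PlatformConfig("p", probes, detection_floor=kw.pop("floor", 0.0), **kw)

    def _latent(self):
        samples = generate_design(StudyDesign([("c1", "s"), ("c2", "r")], ["DMSO"], [20], 2))
        cfg = AntigenConfig(antigens=["A", "B"], coregulation_mean=0.0,
                            coregulation_sd=0.0, replicate_sd=0.0)
        return generate_latent_antigens(samples, cfg, seed=2)

    def test_noise_free_dilution_fit_recovers_latent_exactly(self):
        lat = self._latent()
        render = render_platform(lat, self._noise_free_platform(), seed=1)
        mat = process_platform(render.spots, "p", method="dilution_fit")
        for ab, antigen in [("ab1", "A"), ("ab2", "B")]:
            for sid in lat.values.columns:
                assert mat.values.loc[sid, ab] == pytest.approx(
                    lat.values.loc[antigen, sid], abs=1e-9
                )

    def test_ideal_slopes_all_in_range(self):
        lat = self._latent()
        render = render_platform(lat, self._noise_free_platform(), seed=1)
        agg = aggregate_technical_replicates(render.spots)
        qc = qc_dynamic_range(fit_dilution_matrix(agg))
        assert qc["frac_in_range"] == 1.0
        assert qc["frac_below_detection"] == 0.0

    def test_fully_floored_platform_reports_all_below_detection(self):
        lat = self._latent()
        pcfg = self._noise_free_platform(floor=1.0)
        pcfg.panel = [AntibodyProbe("ab1", "A", "r1", offset=-60.0, noise_sd=0.0)]
        render = render_platform(lat, pcfg, seed=1)
        agg = aggregate_technical_replicates(render.spots)
        qc = qc_dynamic_range(fit_dilution_matrix(agg, detection_floor=1.0))
        assert qc["frac_below_detection"] == 1.0

    def test_default_synthetic_config_mostly_in_dynamic_range(self, study_moderate):
        render = study_moderate.renders["paris"]
        agg = aggregate_technical_replicates(render.spots)
        qc = qc_dynamic_range(fit_dilution_matrix(agg, detection_floor=1.0))
        assert qc["frac_in_range"] > 0.99
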