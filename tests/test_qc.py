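import numpy as np
import pandas as pd
import pytest

from omixvar.containers import FeatureMatrix, OmixvarError
from omixvar.qc import (
    drop_zero_variance,
    filter_missingness,
    impute_half_min,
    log_transform,
    run_qc,
    winsorize,
)


class TestZeroVariance:
    def test_constant_and_single_observation_features_dropped(self, raw_matrix):
        out, report = drop_zero_variance(raw_matrix)
        assert set(report.features_dropped_zero_variance) == {"const", "one_obs"}
        assert set(out.feature_ids) == {"ok", "gappy"}

    def test_no_constant_features_is_identity(self):
        vals = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 1.0]})
        m = FeatureMatrix(vals)
        out, report = drop_zero_variance(m)
        assert out.values.equals(vals)
        assert report.features_dropped_zero_variance == []

    def test_all_dropped_warns_and_flags_empty(self):
        m = FeatureMatrix(pd.DataFrame({"a": [1.0, 1.0]}))
        with pytest.warns(UserWarning, match="all features dropped"):
            out, report = drop_zero_variance(m)
        assert out.n_features == 0 and report.empty_result


class TestMissingness:
    def test_boundary_strictly_greater(self):
        vals = pd.DataFrame(
            {
                "at25": [np.nan, 1.0, 2.0, 3.0],  # exactly 25%: retained
                "over25": [np.nan, np.nan, 2.0, 3.0],  # 50%: removed
            }
        )
        out, report = filter_missingness(FeatureMatrix(vals), threshold=0.25)
        assert report.features_dropped_missingness == ["over25"]
        assert out.feature_ids == ["at25"]

    def test_feature_30pct_missing_removed_at_default(self):
        col = [np.nan] * 3 + [1.0] * 7
        vals = pd.DataFrame({"f": col, "full": np.arange(10.0)})
        out, _ = filter_missingness(FeatureMatrix(vals))
        assert out.feature_ids == ["full"]

    def test_fully_observed_unchanged_and_samples_filtered_after_features(self):
        # row s0 is 50% missing only because of the doomed feature; once that
        # feature is dropped the row is complete and must survive
        vals = pd.DataFrame(
            {"bad": [np.nan, np.nan, np.nan, 1.0], "good": [1.0, 2.0, 3.0, 4.0]},
            index=list("abcd"),
        )
        out, report = filter_missingness(FeatureMatrix(vals))
        assert report.samples_dropped_missingness == []
        assert out.n_samples == 4

    @pytest.mark.parametrize("bad", [0.0, 1.5, -1.0])
    def test_threshold_domain(self, bad):
        with pytest.raises(OmixvarError):
            filter_missingness(FeatureMatrix(pd.DataFrame({"a": [1.0, 2.0]})), bad)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        vals = pd.DataFrame(rng.normal(size=(40, 15)))
        vals = vals.mask(rng.random((40, 15)) < 0.3)
        vals.columns = [f"f{j}" for j in range(15)]
        m = FeatureMatrix(vals)
        kept = [
            set(filter_missingness(m, t)[0].feature_ids) for t in (0.1, 0.25, 0.5, 1.0)
        ]
        for a, b in zip(kept, kept[1:]):
            assert a <= b


class TestImputation:
    def test_half_minimum_per_feature(self):
        vals = pd.DataFrame({"a": [4.0, np.nan, 8.0], "b": [10.0, 20.0, np.nan]})
        out, report = impute_half_min(FeatureMatrix(vals))
        assert out.values.loc[1, "a"] == 2.0
        assert out.values.loc[2, "b"] == 5.0
        assert report.imputation_values == {"a": 2.0, "b": 5.0}
        assert not out.values.isna().any().any()

    def test_no_missing_is_identity(self):
        vals = pd.DataFrame({"a": [1.0, 2.0]})
        out, report = impute_half_min(FeatureMatrix(vals))
        assert out.values.equals(vals) and report.imputation_values == {}

    def test_all_missing_feature_errors(self):
        with pytest.raises(OmixvarError, match="filtered"):
            impute_half_min(FeatureMatrix(pd.DataFrame({"a": [np.nan, np.nan]})))


class TestLogTransform:
    def test_natural_log_for_metabolites(self):
        m = FeatureMatrix(pd.DataFrame({"a": [np.e, 1.0]}))
        out, report = log_transform(m)
        assert out.values["a"].iloc[0] == pytest.approx(1.0)
        assert out.scale_state == "log" and report.log_base == "e"

    def test_protein_npx_passthrough(self):
        vals = pd.DataFrame({"p": [-1.0, 2.5]})
        m = FeatureMatrix(vals, omic_type="protein", scale_state="log")
        out, report = log_transform(m)
        assert out.values.equals(vals) and report.log_base == "log2"

    def test_nonpositive_value_errors_naming_feature(self):
        m = FeatureMatrix(pd.DataFrame({"zeroed": [0.0, 1.0]}))
        with pytest.raises(OmixvarError, match="zeroed"):
            log_transform(m)


class TestWinsorize:
    def test_clipping_at_five_sd(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(500)
        base = (base - base.mean()) / base.std(ddof=1)  # mean 0, sd 1
        vals = pd.DataFrame({"a": np.append(base, 7.0)})
        m = FeatureMatrix(vals, scale_state="log")
        out, report = winsorize(m, k_sd=5)
        mu, sd = vals["a"].mean(), vals["a"].std(ddof=1)
        assert out.values["a"].iloc[-1] == pytest.approx(mu + 5 * sd)
        assert report.winsorized_cell_count == 1

    def test_within_bounds_is_identity(self):
        vals = pd.DataFrame({"a": [0.0, 1.0, -1.0]})
        out, report = winsorize(FeatureMatrix(vals, scale_state="log"))
        assert out.values.equals(vals) and report.winsorized_cell_count == 0

    def test_fixed_bounds_idempotent(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame({"a": np.append(rng.standard_normal(200), [9.0, -9.0])})
        m = FeatureMatrix(vals, scale_state="log")
        once, _ = winsorize(m)
        # re-clipping at the ORIGINAL bounds changes nothing
        mu, sd = vals["a"].mean(), vals["a"].std(ddof=1)
        again = once.values.clip(mu - 5 * sd, mu + 5 * sd)
        pd.testing.assert_frame_equal(once.values, again)
        # recomputed-bounds idempotence is only approximate: the outliers
        # inflate the first-pass SD, so a second pass tightens slightly
        twice, _ = winsorize(once)
        interior = once.values["a"].abs() < 5
        pd.testing.assert_series_equal(
            once.values.loc[interior, "a"], twice.values.loc[interior, "a"]
        )
        assert np.allclose(once.values, twice.values, atol=1.0)

    def test_raw_scale_rejected(self):
        with pytest.raises(OmixvarError):
            winsorize(FeatureMatrix(pd.DataFrame({"a": [1.0, 2.0]})))


class TestFullPipeline:
    def test_output_complete_and_bounded(self, small_bundle):
        fm = small_bundle.features["metabolite"]
        out, report = run_qc(fm)
        assert out.scale_state == "winsorized"
        assert not out.values.isna().any().any()
        mu, sd = out.values.mean(), out.values.std(ddof=1)
        assert ((out.values <= mu + 5 * sd + 1e-9) & (out.values >= mu - 5 * sd - 1e-9)).all().all()

    def test_scale_state_cannot_regress(self):
        m = FeatureMatrix(pd.DataFrame({"a": [1.0, 2.0]}), scale_state="log")
        with pytest.raises(OmixvarError):
            m.copy_with(m.values, scale_state="raw")


class TestWinsorizeProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    @given(
        hnp.arrays(
            float,
            (20, 3),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_output_always_within_preclip_bounds(self, arr):
        vals = pd.DataFrame(arr, columns=list("abc"))
        m = FeatureMatrix(vals, scale_state="log")
        out, _ = winsorize(m, k_sd=5)
        mu, sd = vals.mean(), vals.std(ddof=1)
        ok = (out.values <= mu + 5 * sd + 1e-6) & (out.values >= mu - 5 * sd - 1e-6)
        assert ok.all().all()
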