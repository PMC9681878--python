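"""IS normalisation, LOQ gating, trend statistics and source calls."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cannatrace.degradation_trends import (
    CalibrationCurve,
    InternalStandardError,
    StudySample,
    build_trend_table,
    fit_calibration,
    internal_standard_mz,
    loq_gate,
    mann_kendall,
    normalize_to_is,
    quantify,
    source_markers,
    trend_stat,
)
from cannatrace.feature_io import Feature4D


def _feature(fid, mz, rt, intensity, snr=50.0):
    return Feature4D(feature_id=fid, sample_id="s", mz=mz, rt=rt, intensity=intensity, snr=snr)


IS_MZ = internal_standard_mz()


class TestStudySample:
    def test_valid_design_cell(self):
        s = StudySample("x", "stressed_40C_75RH", 29, 5, "plant")
        assert s.day == 29

    @pytest.mark.parametrize(
        "kw",
        [
            dict(condition="frozen"),
            dict(day=3),
            dict(replicate=6),
            dict(source="mixed"),
        ],
    )
    def test_out_of_design_rejected(self, kw):
        base = dict(sample_id="x", condition="refrigerated_4C", day=1, replicate=1, source="plant")
        base.update(kw)
        with pytest.raises(ValueError):
            StudySample(**base)


class TestNormalizeToIs:
    def test_is_mz_computed_from_deuterated_composition(self):
        assert round(IS_MZ, 4) == 318.2507

    def test_simple_ratio(self):
        feats = [
            _feature("a", 315.2319, 4.99, 1000.0),
            _feature("is", IS_MZ, 11.20, 500.0),
        ]
        assert normalize_to_is(feats) == {"a": 2.0}

    def test_missing_is_raises(self):
        with pytest.raises(InternalStandardError):
            normalize_to_is([_feature("a", 315.2319, 4.99, 1000.0)])

    def test_multiple_is_candidates_raise(self):
        feats = [
            _feature("is1", IS_MZ, 11.20, 500.0),
            _feature("is2", IS_MZ, 11.21, 400.0),
        ]
        with pytest.raises(InternalStandardError):
            normalize_to_is(feats)

    def test_invariant_under_global_rescaling(self):
        feats = [
            _feature("a", 315.2319, 4.99, 1234.0),
            _feature("b", 331.2268, 3.22, 77.0),
            _feature("is", IS_MZ, 11.20, 500.0),
        ]
        scaled = [
            Feature4D(
                feature_id=f.feature_id, sample_id=f.sample_id, mz=f.mz, rt=f.rt,
                intensity=f.intensity * 10.0, snr=f.snr,
            )
            for f in feats
        ]
        assert normalize_to_is(feats) == pytest.approx(normalize_to_is(scaled))


class TestLoqGate:
    def test_boundary_is_inclusive(self):
        assert loq_gate(_feature("a", 300.0, 1.0, 1000.0, snr=10.0)) == "quantifiable"

    def test_just_below_threshold(self):
        assert loq_gate(_feature("a", 300.0, 1.0, 990.0, snr=9.9)) == "below_loq"

    def test_missing_snr_is_below_loq_with_warning(self):
        f = Feature4D(feature_id="a", sample_id="s", mz=300.0, rt=1.0, intensity=10.0, snr=None)
        with pytest.warns(UserWarning):
            assert loq_gate(f) == "below_loq"


def _obs(compound, condition, day, rep, value, snr=50.0):
    return dict(
        compound=compound, condition=condition, day=day, replicate=rep,
        norm_abundance=value, snr=snr,
    )


class TestBuildTrendTable:
    def test_constant_replicates(self):
        obs = pd.DataFrame([_obs("CBE", "stressed_40C_75RH", 1, r, 2.0) for r in range(1, 6)])
        table = build_trend_table(obs)
        row = table.iloc[0]
        assert row["mean_norm_abundance"] == 2.0
        assert row["sd"] == 0.0
        assert row["n"] == 5 and row["below_loq_count"] == 0

    def test_below_loq_counted_not_imputed(self):
        rows = [_obs("CBE", "stressed_40C_75RH", 1, r, 2.0) for r in (1, 2, 3)]
        rows += [_obs("CBE", "stressed_40C_75RH", 1, r, 0.1, snr=5.0) for r in (4, 5)]
        table = build_trend_table(pd.DataFrame(rows))
        row = table.iloc[0]
        assert row["n"] == 5 and row["below_loq_count"] == 2
        assert row["mean_norm_abundance"] == 2.0  # mean over the 3 quantifiable

    def test_means_permutation_invariant(self):
        rows = [_obs("X", "refrigerated_4C", 8, r, v) for r, v in zip(range(1, 6), (1, 2, 3, 4, 5))]
        t1 = build_trend_table(pd.DataFrame(rows))
        t2 = build_trend_table(pd.DataFrame(rows[::-1]))
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="snr"):
            build_trend_table(pd.DataFrame([{"compound": "x"}]))


def _mk_brute_force_p(values):
    """Exact two-sided Mann-Kendall p by enumerating all permutations of
    the observed values (independent of the analytic null)."""
    def s_of(seq):
        return sum(
            (b > a) - (b < a) for a, b in itertools.combinations(seq, 2)
        )

    s_obs = abs(s_of(values))
    perms = list(itertools.permutations(values))
    tail = sum(1 for p in perms if abs(s_of(p)) >= s_obs)
    return tail / len(perms)


class TestMannKendall:
    def test_monotone_series_significant_at_n5(self):
        s, p, verdict = mann_kendall([1, 2, 3, 4, 5])
        assert s == 10
        assert verdict == "increasing"
        assert p == pytest.approx(2 / 120, rel=1e-9)  # 2 * Pr(S >= 10) = 2/5!

    def test_exact_null_matches_permutation_enumeration(self):
        for values in ([1, 3, 2, 5, 4], [5, 1, 4, 2, 3], [2, 1, 4, 3, 6, 5]):
            _, p, _ = mann_kendall(values, alpha=1.0)
            assert p == pytest.approx(min(1.0, _mk_brute_force_p(values)), rel=1e-9)

    def test_constant_series_has_no_trend(self):
        s, p, verdict = mann_kendall([2.0, 2.0, 2.0, 2.0])
        assert s == 0 and verdict == "none"

    def test_decreasing_series(self):
        _, _, verdict = mann_kendall([9, 7, 5, 3, 1])
        assert verdict == "decreasing"

    def test_large_n_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = list(np.arange(30) + rng.normal(0, 0.1, 30))
        _, p, verdict = mann_kendall(x)
        assert verdict == "increasing" and p < 1e-6

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            mann_kendall([1, 2])


class TestTrendStat:
    def test_unit_slope_series(self):
        stat = trend_stat([(1, 1), (8, 8), (15, 15), (22, 22), (29, 29)])
        assert stat.slope == pytest.approx(1.0)
        assert stat.verdict == "increasing"

    def test_constant_series(self):
        stat = trend_stat([(1, 3.0), (8, 3.0), (15, 3.0)])
        assert stat.slope == pytest.approx(0.0, abs=1e-12)
        assert stat.verdict == "none"

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            trend_stat([(1, 1.0), (8, 2.0)])


class TestCalibration:
    def test_exact_linear_inversion(self):
        curve = fit_calibration([(0.0, 0.0), (1.0, 10.0)])
        conc, below = quantify(curve, 59.0)
        assert conc == pytest.approx(5.9)
        assert not below

    def test_response_below_intercept_reported_below_range(self):
        curve = fit_calibration([(1.0, 20.0), (2.0, 30.0)])  # intercept 10
        conc, below = quantify(curve, 5.0)
        assert below and conc == 0.0

    def test_zero_slope_rejected(self):
        curve = CalibrationCurve(((0, 1.0), (1, 1.0)), 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            quantify(curve, 2.0)

    def test_recovery_from_noisy_five_point_curve(self):
        rng = np.random.default_rng(5)
        slope_true, intercept_true = 10.0, 2.0
        concs = [1.0, 2.0, 5.0, 10.0, 20.0]
        points = [
            (c, (slope_true * c + intercept_true) * (1 + rng.normal(0, 0.02)))
            for c in concs
        ]
        curve = fit_calibration(points)
        assert curve.r_squared > 0.99
        for c_true in (3.0, 8.0, 15.0):
            response = slope_true * c_true + intercept_true
            conc, _ = quantify(curve, response)
            assert conc == pytest.approx(c_true, rel=0.05)


class TestSourceMarkers:
    def test_plant_profile(self):
        report = source_markers(
            ["CBDV", "CBDP", "CBDH", "6a-OH-CBD", "7-OH-CBD", "CBDB", "HU-331", "OH-CBE"]
        )
        assert report.verdict == "plant"
        assert len(report.plant_markers_detected) == 5

    def test_synthetic_profile_via_cbdh_isomer(self):
        report = source_markers(["CBDH-isomer", "CBDB", "HU-331", "HU-331-like"])
        assert report.verdict == "synthetic"

    def test_shared_compounds_alone_are_indeterminate(self):
        # CBDB and HU-331 occur in both sources: never discriminative
        report = source_markers(["CBDB", "HU-331", "OH-CBE"])
        assert report.verdict == "indeterminate"
        assert report.shared_detected == ("CBDB", "HU-331", "OH-CBE")
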