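"""Entropy estimator unit tests: exact reference equivalence, invariances,
and the multiscale curve/area machinery."""

from __future__ import annotations

import numpy as np
import pytest

from attneeg.complexity import (
    MultiscaleCurve,
    apen,
    coarse_grain,
    complexity_features,
    curve_area_index,
    fuzzyen,
    multiscale_curve,
    sampen,
)
from attneeg.config import DEFAULT_ENTROPY_PARAMS, EntropyParams
from attneeg.core import Epoch

from conftest import SCALES_10
from reference import apen_naive, fuzzyen_naive, sampen_naive, trapezoid_naive

P_APEN = EntropyParams(m=2, r_factor=0.2, scales=(1,))
P_SAMPEN = EntropyParams(m=2, r_factor=0.15, scales=(1,))
P_FUZZY = EntropyParams(m=2, r_factor=0.15, n=2.0, scales=(1,))


@pytest.mark.parametrize("est,params", [
    (apen, P_APEN), (sampen, P_SAMPEN), (fuzzyen, P_FUZZY),
])
def test_constant_series_has_zero_entropy(est, params):
    assert est(np.full(100, 3.7), params) == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_estimators_match_naive_references(seed):
    x = np.random.default_rng(seed).standard_normal(120)
    assert abs(apen(x, P_APEN) - apen_naive(x, 2, 0.2)) < 1e-12
    se, se_ref = sampen(x, P_SAMPEN), sampen_naive(x, 2, 0.15)
    # both sides must agree on definedness; undefined == undefined
    assert (np.isnan(se) and np.isnan(se_ref)) or abs(se - se_ref) < 1e-12
    assert abs(fuzzyen(x, P_FUZZY) - fuzzyen_naive(x, 2, 0.15, 2.0)) < 1e-12


def test_alternating_series_is_fully_predictable():
    x = np.tile([1.0, -1.0], 50)
    assert sampen(x, P_SAMPEN) == pytest.approx(0.0, abs=1e-12)


def test_too_short_series_rejected():
    with pytest.raises(ValueError):
        sampen(np.arange(3.0), P_SAMPEN)


def test_fuzzyen_offset_invariance_within_vectors(rng):
    ramp = np.linspace(0, 1, 150) + 0.05 * rng.standard_normal(150)
    assert fuzzyen(ramp, P_FUZZY) == pytest.approx(fuzzyen(ramp + 42.0, P_FUZZY), abs=1e-9)


def test_fuzzyen_continuity_under_small_perturbation(rng):
    x = rng.standard_normal(200)
    base = fuzzyen(x, P_FUZZY)
    prev = np.inf
    for eps in (1e-2, 1e-4, 1e-6):
        diff = abs(fuzzyen(x + eps * rng.standard_normal(200), P_FUZZY) - base)
        assert diff < prev or diff < 1e-6
        prev = diff
    assert prev < 1e-4


@pytest.mark.parametrize("est,params", [
    (apen, P_APEN), (sampen, P_SAMPEN), (fuzzyen, P_FUZZY),
])
def test_amplitude_scale_invariance(est, params, rng):
    x = rng.standard_normal(250)
    assert est(7.3 * x, params) == pytest.approx(est(x, params), abs=1e-9)


class TestCoarseGrain:
    def test_scale_one_is_identity(self, rng):
        x = rng.standard_normal(50)
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_block_means(self):
        np.testing.assert_allclose(coarse_grain([1, 2, 3, 4, 5, 6], 2), [1.5, 3.5, 5.5])

    def test_trailing_partial_block_dropped(self):
        np.testing.assert_allclose(coarse_grain([1, 2, 3, 4, 5], 2), [1.5, 3.5])

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            coarse_grain([1, 2, 3], 0)
        with pytest.raises(ValueError):
            coarse_grain([1, 2, 3], 4)


class TestMultiscale:
    def test_scale_one_equals_single_scale_bit_exactly(self, rng):
        x = rng.standard_normal(400)
        curve = multiscale_curve(x, SCALES_10["mse"], "sampen")
        assert curve.values[0] == sampen(x, SCALES_10["mse"])
        mfe = multiscale_curve(x, SCALES_10["mfe"], "fuzzyen")
        assert mfe.values[0] == fuzzyen(x, SCALES_10["mfe"])

    def test_default_curve_spans_50_scales(self, rng):
        x = rng.standard_normal(1000)
        curve = multiscale_curve(x, DEFAULT_ENTROPY_PARAMS["mse"], "sampen")
        assert curve.scales == tuple(range(1, 51))
        assert len(curve.values) == 50

    def test_tolerance_fixed_from_original_series(self, rng):
        x = rng.standard_normal(600)
        curve = multiscale_curve(x, SCALES_10["mse"], "sampen")
        assert curve.r_value == pytest.approx(0.15 * x.std())
        # coarse-grained series have smaller SD, so a per-scale r would differ
        assert coarse_grain(x, 5).std() < x.std()

    def test_short_scales_flagged_undefined(self, rng):
        x = rng.standard_normal(30)
        params = EntropyParams(m=2, r_factor=0.15, scales=(1, 10, 15))
        curve = multiscale_curve(x, params, "sampen")
        assert 15 in curve.undefined_scales  # 2 coarse samples < m + 2
        assert np.isnan(curve.values[list(curve.scales).index(15)])


class TestCurveArea:
    def test_flat_curve_rectangle(self):
        c = MultiscaleCurve(tuple(range(1, 11)), np.full(10, 2.0), "MSE")
        assert curve_area_index(c) == pytest.approx(18.0)

    def test_single_trapezoid(self):
        c = MultiscaleCurve((1, 2), np.array([1.0, 2.0]), "MSE")
        assert curve_area_index(c, 1, 2) == pytest.approx(1.5)

    def test_matches_independent_trapezoid_sum(self, rng):
        vals = rng.uniform(1, 3, size=10)
        c = MultiscaleCurve(tuple(range(1, 11)), vals, "MFE")
        assert curve_area_index(c) == pytest.approx(trapezoid_naive(vals, range(1, 11)), abs=1e-12)

    def test_undefined_scale_inside_range_raises(self):
        vals = np.full(10, 2.0)
        vals[4] = np.nan
        c = MultiscaleCurve(tuple(range(1, 11)), vals, "MSE", undefined_scales=(5,))
        with pytest.raises(ValueError, match="undefined"):
            curve_area_index(c)

    def test_missing_scale_raises(self):
        c = MultiscaleCurve((1, 2, 3), np.ones(3), "MSE")
        with pytest.raises(ValueError, match="absent"):
            curve_area_index(c, 1, 10)


class TestFeatureAssembly:
    def test_frontal_region_yields_65_features(self, epoch_34ch):
        feats = complexity_features(epoch_34ch, params=SCALES_10)
        assert len(feats) == 65
        assert {n.split(".")[1] for n in feats} == {"apen", "sampen", "fuzzyen", "msei", "mfei"}

    def test_single_channel_yields_5(self, epoch_34ch):
        assert len(complexity_features(epoch_34ch, channels=("Fz",), params=SCALES_10)) == 5

    def test_identical_channels_identical_features(self, rng):
        x = rng.standard_normal(480)
        ep = Epoch(np.vstack([x, x]), 160.0, ["Fz", "F4"], "S00")
        feats = complexity_features(ep, channels=("Fz", "F4"), params=SCALES_10)
        for name in ("apen", "sampen", "fuzzyen", "msei", "mfei"):
            assert feats[f"Fz.{name}"] == feats[f"F4.{name}"]

    def test_missing_channel_rejected(self, epoch_34ch):
        with pytest.raises(ValueError):
            complexity_features(epoch_34ch, channels=("NoSuch",))
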