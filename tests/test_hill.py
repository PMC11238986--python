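"""Hill primitives: evaluation, normalization, fitting, median aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmloop import (
    DoseResponseTable,
    HillSpec,
    aggregate_medians,
    fit_hill,
    hill_decreasing,
    hill_increasing,
    shifted_self_limit,
    synth_dose_response,
)
from fmloop.errors import DomainError, FitError, ParameterError


class TestEvaluation:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (0.0, 0.0),  # 0^h := 0: curve passes through the origin
            (20.0, 50.0),  # half-saturation
            (40.0, 100.0 / (1.0 + 0.5**2.5)),  # direct arithmetic
        ],
    )
    def test_increasing_anchors(self, x, expected):
        spec = HillSpec("increasing", m=100, e=20, h=2.5)
        assert hill_increasing(x, spec) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "x, expected",
        [
            (0.0, 100.0),  # zero-input maximum
            (28.0, 50.0),  # half-saturation
            (56.0, 100.0 / (1.0 + 2.0**4.2)),  # direct arithmetic, ~5.17
        ],
    )
    def test_decreasing_anchors(self, x, expected):
        spec = HillSpec("decreasing", m=100, e=28, h=4.2)
        assert hill_decreasing(x, spec) == pytest.approx(expected, abs=1e-12)

    def test_offset_shifts_both_forms(self):
        inc = HillSpec("increasing", m=80, e=20, h=2.5, offset=20)
        dec = HillSpec("decreasing", m=80, e=20, h=2.5, offset=20)
        assert hill_increasing(20.0, inc) == pytest.approx(60.0)
        assert hill_decreasing(20.0, dec) == pytest.approx(60.0)

    def test_negative_input_rejected(self):
        spec = HillSpec("increasing", m=1, e=1, h=1)
        with pytest.raises(DomainError):
            hill_increasing(-0.1, spec)
        with pytest.raises(DomainError):
            hill_decreasing(np.array([1.0, -2.0]), spec)

    @pytest.mark.parametrize("bad", [{"m": -1}, {"e": 0}, {"h": -2}, {"offset": -1}])
    def test_invalid_spec_rejected(self, bad):
        kwargs = {"m": 1.0, "e": 1.0, "h": 1.0, "offset": 0.0, **bad}
        with pytest.raises(ParameterError):
            HillSpec("increasing", **kwargs)


class TestSelfLimit:
    def test_band_endpoints(self):
        # approaches 5 at zero activity, 3 at the effective midpoint
        assert shifted_self_limit(0.0, 25.57, 6.6, 0.48) == pytest.approx(5.0)
        x_mid = 25.57 / 0.48
        assert shifted_self_limit(x_mid, 25.57, 6.6, 0.48) == pytest.approx(3.0)

    def test_tends_to_one_at_high_activity(self):
        x = 10.0 * 25.57 / 0.48
        assert shifted_self_limit(x, 25.57, 6.6, 0.48) == pytest.approx(1.0, abs=1e-5)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.3, 2.0])
    def test_alpha_outside_unit_interval_rejected(self, alpha):
        with pytest.raises(ParameterError):
            shifted_self_limit(1.0, 25.57, 6.6, alpha)


@settings(max_examples=60, deadline=None)
@given(
    e=st.floats(0.5, 100.0),
    h=st.floats(0.5, 8.0),
    x=st.floats(0.0, 500.0),
    dx=st.floats(1e-6, 50.0),
)
def test_monotonicity(e, h, x, dx):
    inc = HillSpec("increasing", m=100, e=e, h=h)
    dec = HillSpec("decreasing", m=100, e=e, h=h)
    assert hill_increasing(x + dx, inc) >= hill_increasing(x, inc)
    assert hill_decreasing(x + dx, dec) <= hill_decreasing(x, dec)


@settings(max_examples=60, deadline=None)
@given(e=st.floats(0.5, 100.0), h=st.floats(0.5, 8.0), x=st.floats(0.0, 1e3))
def test_increasing_decreasing_complement(e, h, x):
    # x^h/(e^h+x^h) + 1/(1+(x/e)^h) = 1 for all x >= 0
    inc = HillSpec("increasing", m=1.0, e=e, h=h)
    dec = HillSpec("decreasing", m=1.0, e=e, h=h)
    total = hill_increasing(x, inc) + hill_decreasing(x, dec)
    assert total == pytest.approx(1.0, abs=1e-9)


class TestFit:
    @pytest.mark.parametrize("h_true", [1.0, 2.0, 4.2, 8.0])
    def test_noiseless_round_trip(self, h_true):
        truth = HillSpec("decreasing", m=100, e=28, h=h_true)
        table = synth_dose_response(truth, n=15, noise_sd=0.0)
        fit = fit_hill(table, "decreasing", normalize=False, fix_m=100.0)
        assert fit.spec.e == pytest.approx(28.0, rel=1e-6)
        assert fit.spec.h == pytest.approx(h_true, rel=1e-6)
        assert fit.rss < 1e-10

    def test_noisy_recovery_within_15_percent(self):
        truth = HillSpec("decreasing", m=100, e=28, h=4.2)
        table = synth_dose_response(truth, n=12, noise_sd=5.0, seed=7)
        fit = fit_hill(table, "decreasing", normalize=False, fix_m=100.0)
        assert fit.spec.e == pytest.approx(28.0, rel=0.15)

    def test_all_free_parameters_mode(self):
        truth = HillSpec("increasing", m=80, e=10, h=3, offset=5)
        table = synth_dose_response(truth, n=20, noise_sd=0.0)
        fit = fit_hill(table, "increasing", normalize=False, fix_m=None, fix_offset=None)
        assert fit.n_free == 4
        assert fit.spec.e == pytest.approx(10.0, rel=1e-4)

    def test_constant_outputs_fail(self):
        table = DoseResponseTable([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])
        with pytest.raises(FitError):
            fit_hill(table, "decreasing")

    def test_contradictory_trend_fails(self):
        truth = HillSpec("increasing", m=100, e=10, h=2)
        table = synth_dose_response(truth, n=10, noise_sd=0.0)
        with pytest.raises(FitError):
            fit_hill(table, "decreasing", normalize=False)

    def test_too_few_rows_fail(self):
        table = DoseResponseTable([1.0, 2.0], [9.0, 5.0])
        with pytest.raises(FitError):
            fit_hill(table, "decreasing")

    def test_normalization_spans_0_100(self):
        truth = HillSpec("decreasing", m=60, e=30, h=3, offset=10)
        table = synth_dose_response(truth, n=10, noise_sd=0.0)
        fit = fit_hill(table, "decreasing", normalize=True)
        assert fit.normalized
        # diagnostics carry the monotone-association p-value
        assert 0.0 <= fit.p_monotone <= 1.0


class TestMedians:
    def test_even_count_uses_midpoint(self):
        thresholds = [600, 1500, 150, 300, 90, 900]
        med = aggregate_medians([{"thr": v} for v in thresholds])
        assert med["thr"] == 450.0

    def test_odd_count(self):
        hs = [2, 2, 2, 2, 1.2, 1.15, 2.8]
        assert aggregate_medians([{"h": v} for v in hs])["h"] == 2.0

    def test_single_record_identity(self):
        rec = {"e": 28.0, "h": 4.2}
        assert aggregate_medians([rec]) == rec

    def test_permutation_invariance(self, rng):
        recs = [{"v": float(v)} for v in rng.normal(size=9)]
        shuffled = [recs[i] for i in rng.permutation(9)]
        assert aggregate_medians(recs) == aggregate_medians(shuffled)

    def test_missing_fields_skipped_per_field(self):
        out = aggregate_medians([{"e": 1.0, "h": 2.0}, {"e": 3.0}])
        assert out == {"e": 2.0, "h": 2.0}

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            aggregate_medians([])
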