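"""Pairing, phase summaries and the standardized/difference indexes."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from baepstd.config import StandardizationConfig
from baepstd.features import INDICATORS, WaveFeatures
from baepstd.standardize import (DivisionGuardError, PairedEpoch, PhaseSummary,
                                 compute_differences, compute_sti,
                                 pair_streams, standardized_difference_value,
                                 standardized_value, summarize_phase)


def _wf(t, phase="pre_resection", side="affected", **kw):
    return WaveFeatures(side=side, timestamp=t, phase=phase, **kw)


class TestPairing:
    def test_interval_at_179_seconds_pairs(self):
        pairs = pair_streams([_wf(600.0)], [_wf(779.0, side="healthy")])
        assert len(pairs) == 1
        assert pairs[0].interval == pytest.approx(179.0)

    def test_interval_boundary_inclusive_at_180(self):
        pairs = pair_streams([_wf(600.0)], [_wf(780.0, side="healthy")])
        assert len(pairs) == 1

    def test_interval_beyond_180_excluded(self):
        assert pair_streams([_wf(600.0)], [_wf(781.0, side="healthy")]) == []

    def test_empty_healthy_stream(self):
        assert pair_streams([_wf(600.0)], []) == []

    def test_each_epoch_used_once_nearest_first(self):
        affected = [_wf(0.0), _wf(100.0)]
        healthy = [_wf(90.0, side="healthy")]
        pairs = pair_streams(affected, healthy)
        assert len(pairs) == 1
        assert pairs[0].affected.timestamp == 100.0     # nearest wins

    def test_phase_mismatch_not_paired(self):
        a = [_wf(600.0, phase="pre_resection")]
        h = [_wf(650.0, phase="resection", side="healthy")]
        assert pair_streams(a, h) == []

    def test_unsorted_stream_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            pair_streams([_wf(100.0), _wf(50.0)], [_wf(60.0, side="healthy")])


def _pair(t, aff_vals, hea_vals, phase="pre_resection"):
    return PairedEpoch(_wf(t, phase, "affected", **aff_vals),
                       _wf(t + 30.0, phase, "healthy", **hea_vals), 30.0)


class TestPhaseSummary:
    def test_single_pair_is_its_own_summary(self):
        p = _pair(0.0, dict(la_v=5.8, am_v=0.25), dict(la_v=5.7, am_v=0.30))
        s = summarize_phase([p], "pre_resection")
        assert s.n_pairs == 1
        assert s.affected.la_v == 5.8
        assert s.healthy.am_v == 0.30

    def test_median_of_three(self):
        pairs = [_pair(100.0 * k, dict(am_v=v), dict(am_v=0.3))
                 for k, v in enumerate((0.2, 0.3, 0.4))]
        s = summarize_phase(pairs, "pre_resection")
        assert s.affected.am_v == pytest.approx(0.3)

    def test_majority_absence_rule(self):
        pairs = [_pair(0.0, dict(am_v=0.2), dict(am_v=0.3)),
                 _pair(200.0, dict(am_v=None), dict(am_v=0.3)),
                 _pair(400.0, dict(am_v=None), dict(am_v=0.3))]
        s = summarize_phase(pairs, "pre_resection")
        assert s.affected.am_v is None          # absent in 2 of 3
        assert s.healthy.am_v is not None

    def test_empty_phase_is_absence_not_error(self):
        assert summarize_phase([], "post_resection") is None

    def test_representative_within_envelope(self):
        vals = (5.6, 5.9, 6.2, 5.7)
        pairs = [_pair(100.0 * k, dict(la_v=v), dict(la_v=5.7))
                 for k, v in enumerate(vals)]
        for method in ("median", "mean"):
            s = summarize_phase(pairs, "pre_resection", method)
            assert min(vals) <= s.affected.la_v <= max(vals)


def _summary(aff, hea, phase="pre_resection"):
    return PhaseSummary(phase=phase,
                        affected=_wf(0.0, phase, "affected", **aff),
                        healthy=_wf(0.0, phase, "healthy", **hea),
                        n_pairs=1)


class TestSTI:
    def test_identity_gives_zero(self):
        vals = dict(la_v=5.7, la_i=1.7, am_v=0.3)
        sti = compute_sti(_summary(vals, dict(vals)))
        for ind, v in sti.sti.items():
            if v is not None:
                assert v == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic(self):
        sti = compute_sti(_summary(dict(la_v=6.27), dict(la_v=5.70)))
        assert sti.sti["la_v"] == pytest.approx(6.27 / 5.70 - 1.0)
        assert sti.sti["la_v"] == pytest.approx(0.100, abs=5e-4)

    def test_absence_propagates(self):
        sti = compute_sti(_summary(dict(la_v=6.0), dict(la_v=None)))
        assert sti.sti["la_v"] is None

    def test_division_guard_names_indicator(self):
        with pytest.raises(DivisionGuardError, match="am_v"):
            compute_sti(_summary(dict(am_v=0.2), dict(am_v=0.0)))

    @given(st.floats(0.01, 100.0),
           st.floats(0.05, 10.0),
           st.floats(0.05, 10.0))
    def test_common_mode_multiplicative_invariance(self, c, a, h):
        """STI(c*a, c*h) = STI(a, h) exactly, for any shared factor c > 0."""
        plain = compute_sti(_summary(dict(am_v=a), dict(am_v=h)))
        scaled = compute_sti(_summary(dict(am_v=c * a), dict(am_v=c * h)))
        assert scaled.sti["am_v"] == pytest.approx(plain.sti["am_v"],
                                                   rel=1e-12, abs=1e-12)


class TestDifferences:
    def test_null_change(self):
        pre = _summary(dict(am_v=0.3, la_v=5.7), dict(am_v=0.3, la_v=5.7))
        post = _summary(dict(am_v=0.3, la_v=5.7), dict(am_v=0.3, la_v=5.7),
                        "post_resection")
        diff = compute_differences(pre, post)
        assert diff.d["am_v"] == 0.0 and diff.std["am_v"] == 0.0

    def test_direct_arithmetic(self):
        pre = _summary(dict(am_v=0.30), dict(am_v=0.28))
        post = _summary(dict(am_v=0.20), dict(am_v=0.24), "post_resection")
        diff = compute_differences(pre, post)
        assert diff.d["am_v"] == pytest.approx(-0.10)
        assert diff.std["am_v"] == pytest.approx(-0.06)

    def test_shared_shift_cancels_in_std(self):
        delta = 0.7
        pre = _summary(dict(la_v=5.7), dict(la_v=5.6))
        post_a = _summary(dict(la_v=5.9), dict(la_v=5.8), "post_resection")
        post_b = _summary(dict(la_v=5.9 + delta), dict(la_v=5.8 + delta),
                          "post_resection")
        da = compute_differences(pre, post_a)
        db = compute_differences(pre, post_b)
        assert db.d["la_v"] - da.d["la_v"] == pytest.approx(delta)
        assert db.std["la_v"] == pytest.approx(da.std["la_v"])

    @given(st.floats(-0.5, 0.5), st.floats(5.0, 6.5), st.floats(5.0, 6.5),
           st.floats(5.0, 6.5), st.floats(5.0, 6.5))
    def test_additive_common_drift_invariance(self, drift, a0, a1, h0, h1):
        """Adding the same drift to both ears' post summaries leaves STD
        unchanged."""
        pre = _summary(dict(la_v=a0), dict(la_v=h0))
        post = _summary(dict(la_v=a1), dict(la_v=h1), "post_resection")
        shifted = _summary(dict(la_v=a1 + drift), dict(la_v=h1 + drift),
                           "post_resection")
        ref = compute_differences(pre, post)
        got = compute_differences(pre, shifted)
        assert got.std["la_v"] == pytest.approx(ref.std["la_v"],
                                                rel=1e-9, abs=1e-9)

    def test_absence_propagates(self):
        pre = _summary(dict(am_v=0.3), dict(am_v=None))
        post = _summary(dict(am_v=0.2), dict(am_v=0.25), "post_resection")
        diff = compute_differences(pre, post)
        assert diff.d["am_v"] == pytest.approx(-0.1)
        assert diff.std["am_v"] is None


def test_reference_scaled_values_are_constant_multiples():
    """With a configured normal reference, reference*(a/h - 1) equals
    reference * STI and reference*(a/h) equals reference * (STI + 1)."""
    cfg = StandardizationConfig(normal_reference={"la_v": 5.7, "am_v": 0.3})
    summary = _summary(dict(la_v=6.27, am_v=0.24), dict(la_v=5.70, am_v=0.30))
    sti = compute_sti(summary)
    sdv = standardized_difference_value(sti, cfg)
    sv = standardized_value(sti, cfg)
    for ind, ref in cfg.normal_reference.items():
        assert sdv[ind] == pytest.approx(ref * sti.sti[ind])
        assert sv[ind] == pytest.approx(ref * (sti.sti[ind] + 1.0))
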