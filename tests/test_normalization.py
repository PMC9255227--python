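"""Double normalization, relative variable fluorescence, difference kinetics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ojipkit import (
    CardinalPoints,
    NormalizationError,
    extract_cardinals,
    normalize,
    relative_variable_fluorescence,
)
from ojipkit.normalization import WINDOWS, difference_kinetics
from ojipkit.synth import flooding_preset, generate_transient


@pytest.fixture(scope="module")
def transient_and_cardinals():
    preset = flooding_preset()
    spec = preset.group_transient("CK")
    tr = generate_transient(spec.__class__(**{**spec.__dict__, "noise_cv": 0.0}), 0)
    return tr, extract_cardinals(tr)


class TestNormalize:
    @pytest.mark.parametrize("window", sorted(WINDOWS))
    def test_endpoint_pinning(self, window, transient_and_cardinals):
        tr, cards = transient_and_cardinals
        curve = normalize(tr, cards, window)
        assert abs(curve.v[0]) <= 1e-9
        assert abs(curve.v[-1] - 1.0) <= 1e-9

    def test_midpoint_value(self):
        # F_o=1000, F_P=5000, F_t=3000 -> V_O-P = 0.5 exactly
        cards = CardinalPoints(1000, 1500, 2000, 2500, 4000, 5000)
        assert (3000 - cards.f_o) / (cards.f_p - cards.f_o) == 0.5

    @given(st.floats(min_value=0.05, max_value=20.0))
    def test_scale_invariance(self, transient_and_cardinals, b):
        tr, cards = transient_and_cardinals
        base = normalize(tr, cards, "O-P")
        scaled = normalize(tr.scaled(b), cards.scaled(b), "O-P")
        np.testing.assert_allclose(scaled.v, base.v, atol=1e-12)

    def test_additive_shift_invariance(self, transient_and_cardinals):
        import dataclasses

        tr, cards = transient_and_cardinals
        shifted = dataclasses.replace(tr, signal=tr.signal + 1234.5)
        cards_shifted = extract_cardinals(shifted)
        base = normalize(tr, cards, "O-J")
        other = normalize(shifted, cards_shifted, "O-J")
        np.testing.assert_allclose(other.v, base.v, atol=1e-9)

    def test_non_inducing_curve_rejected(self, transient_and_cardinals):
        tr, _ = transient_and_cardinals
        bad = CardinalPoints(5000, 5000, 5000, 5000, 5000, 4000)
        with pytest.raises(NormalizationError, match="non-inducing"):
            normalize(tr, bad, "O-P")


class TestRelativeVariableFluorescence:
    def test_worked_example(self):
        cards = CardinalPoints(5000, 6000, 8000, 12000, 18000, 25000)
        rvf = relative_variable_fluorescence(cards)
        assert rvf.v_k == pytest.approx(3000 / 7000, abs=1e-12)
        assert rvf.v_j == pytest.approx(0.35, abs=1e-12)
        assert rvf.v_i == pytest.approx(0.65, abs=1e-12)
        assert rvf.v_l == pytest.approx(1000 / 3000, abs=1e-12)

    def test_zero_and_unit_edges(self):
        cards = CardinalPoints(5000, 5000, 8000, 25000, 25000, 25000)
        rvf = relative_variable_fluorescence(cards)
        assert rvf.v_l == 0.0      # F_L = F_o
        assert rvf.v_j == 1.0      # F_J = F_P

    def test_error_names_band(self):
        cards = CardinalPoints(5000, 5200, 5000, 12000, 18000, 25000)
        with pytest.raises(NormalizationError, match="O-K"):
            relative_variable_fluorescence(cards)

    def test_agrees_with_normalized_curve(self, transient_and_cardinals):
        # oracle: V from cardinals == reading the curve at the cardinal time
        tr, cards = transient_and_cardinals
        rvf = relative_variable_fluorescence(cards)
        assert normalize(tr, cards, "O-P").value_at(2.0) == pytest.approx(
            rvf.v_j, abs=1e-6)
        assert normalize(tr, cards, "O-J").value_at(0.3) == pytest.approx(
            rvf.v_k, abs=1e-6)
        assert normalize(tr, cards, "O-K").value_at(0.15) == pytest.approx(
            rvf.v_l, abs=1e-6)


class TestDifferenceKinetics:
    @staticmethod
    def _curves(group, n, noise, window, seed0=0):
        preset = flooding_preset(noise_cv=noise)
        spec = preset.group_transient(group)
        out = []
        for i in range(n):
            tr = generate_transient(spec, seed0 + i, group=group)
            out.append(normalize(tr, extract_cardinals(tr), window))
        return out

    def test_self_difference_is_zero(self):
        curves = self._curves("CK", 3, 0.0, "O-J")
        dk = difference_kinetics(curves, curves)
        np.testing.assert_allclose(dk.delta_v, 0.0, atol=1e-12)

    def test_single_replicate_equals_pointwise_difference(self):
        a = self._curves("D10", 1, 0.0, "O-P")
        b = self._curves("CK", 1, 0.0, "O-P")
        dk = difference_kinetics(a, b)
        expected = np.asarray(a[0].value_at(dk.time_ms)) - np.asarray(
            b[0].value_at(dk.time_ms))
        np.testing.assert_allclose(dk.delta_v, expected, atol=1e-12)

    def test_k_band_peak_for_flooded_group(self):
        # OEC damage (V_K multiplier > 1) shows as a positive delta-V_O-J
        # band peaking near 0.3 ms
        dk = difference_kinetics(self._curves("D15", 5, 0.02, "O-J"),
                                 self._curves("CK", 5, 0.02, "O-J", seed0=50))
        peak_t = dk.time_ms[np.argmax(dk.delta_v)]
        assert dk.delta_v.max() > 0.1
        assert 0.1 < peak_t < 1.0

    def test_window_mismatch_rejected(self):
        with pytest.raises(ValueError, match="window"):
            difference_kinetics(self._curves("CK", 2, 0.0, "O-J"),
                                self._curves("CK", 2, 0.0, "O-K"))
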