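"""Generator contracts: exact target recovery, determinism, scenarios."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ojipkit import extract_cardinals, relative_variable_fluorescence
from ojipkit.errors import OjipError, UnreachableTargetError
from ojipkit.synth import (
    FLOODING_RESPONSES,
    GroupEffects,
    MR820Spec,
    TransientSpec,
    flooding_preset,
    generate_study,
    generate_transient,
    null_preset,
    solve_amplitudes,
)


def extracted_op_targets(spec, seed=0):
    tr = generate_transient(spec, seed)
    c = extract_cardinals(tr)
    span = c.f_p - c.f_o
    return ((c.f_k - c.f_o) / span, (c.f_j - c.f_o) / span,
            (c.f_i - c.f_o) / span)


class TestGenerateTransient:
    def test_noise_free_recovery(self):
        spec = TransientSpec(v_k_target=0.15, v_j_target=0.35,
                             v_i_target=0.65, noise_cv=0.0)
        got = extracted_op_targets(spec)
        for value, target in zip(got, (0.15, 0.35, 0.65)):
            assert value == pytest.approx(target, abs=1e-3)

    def test_endpoints_exact(self):
        spec = TransientSpec(noise_cv=0.0)
        tr = generate_transient(spec, 0)
        assert tr.signal[0] == pytest.approx(spec.fo, rel=1e-9)
        assert tr.signal[-1] == pytest.approx(spec.fm, rel=1e-9)

    def test_seeded_determinism(self):
        spec = TransientSpec(noise_cv=0.02)
        a = generate_transient(spec, 1)
        b = generate_transient(spec, 1)
        c = generate_transient(spec, 2)
        np.testing.assert_array_equal(a.signal, b.signal)
        assert not np.array_equal(a.signal, c.signal)

    def test_amplitudes_nonnegative_and_curve_monotone(self):
        spec = TransientSpec(noise_cv=0.0)
        assert np.all(solve_amplitudes(spec) >= 0)
        tr = generate_transient(spec, 0)
        assert np.all(np.diff(tr.signal) >= -1e-9)

    def test_unreachable_targets_rejected(self):
        with pytest.raises(OjipError):
            TransientSpec(v_k_target=0.5, v_j_target=0.3, v_i_target=0.65)
        # monotone but impossibly steep for any nonnegative mix
        spec = TransientSpec(v_k_target=0.001, v_j_target=0.002,
                             v_i_target=0.998,
                             component_half_times_ms=(0.2, 5.0, 100.0, 400.0))
        with pytest.raises(UnreachableTargetError):
            solve_amplitudes(spec)

    @given(st.floats(min_value=0.08, max_value=0.32))
    def test_monotone_injection_of_v_k(self, v_k):
        got = extracted_op_targets(
            TransientSpec(v_k_target=v_k, v_j_target=0.45, v_i_target=0.75,
                          noise_cv=0.0))
        assert got[0] == pytest.approx(v_k, abs=1e-3)

    def test_recovery_grid(self):
        # interpolation-only error across a target grid
        for v_k in (0.1, 0.2, 0.3):
            for v_j in (0.25, 0.4, 0.55):
                for v_i in (0.6, 0.7, 0.8):
                    if not v_k < v_j < v_i:
                        continue
                    spec = TransientSpec(v_k_target=v_k, v_j_target=v_j,
                                         v_i_target=v_i, noise_cv=0.0)
                    got = extracted_op_targets(spec)
                    for value, target in zip(got, (v_k, v_j, v_i)):
                        assert value == pytest.approx(target, abs=1e-3)


class TestPresets:
    def test_flooding_truth_reproduces_reported_changes(self):
        preset = flooding_preset()
        truth = {g: preset.group_truth(g) for g in preset.groups}

        def pct(parameter, group):
            return 100.0 * (truth[group][parameter] / truth["CK"][parameter] - 1.0)

        assert pct("Fv/Fm", "D15") == pytest.approx(-22.13, abs=0.01)
        assert pct("PI_ABS", "D15") == pytest.approx(-96.99, abs=0.01)
        assert pct("PI_total", "D15") == pytest.approx(-91.72, abs=0.01)
        assert pct("dI/Io", "D15") == pytest.approx(-92.36, abs=0.05)
        for group, resp in FLOODING_RESPONSES.items():
            assert pct("V_J", group) == pytest.approx(resp["v_j"], abs=0.01)
            assert pct("V_K", group) == pytest.approx(resp["v_k"], abs=0.01)
            assert pct("V_L", group) == pytest.approx(resp["v_l"], abs=0.01)
        assert pct("Chl_a/b", "D10") == pytest.approx(-25.06, abs=0.2)
        assert pct("Ci", "D10") == pytest.approx(-85.30, abs=0.01)

    def test_flooding_targets_stay_ordered(self):
        preset = flooding_preset()
        for group in preset.groups:
            spec = preset.group_transient(group)
            assert (spec.v_l_target < spec.v_k_target < spec.v_j_target
                    < spec.v_i_target)

    def test_effect_validation_names_key(self):
        with pytest.raises(OjipError, match="v_k"):
            GroupEffects(v_k=-1.0)
        with pytest.raises(OjipError, match="unknown"):
            GroupEffects.from_mapping({"bogus": 2.0})

    def test_null_preset_groups_identical(self):
        preset = null_preset()
        truths = [preset.group_truth(g) for g in preset.groups]
        for other in truths[1:]:
            assert other == truths[0]


class TestGenerateStudy:
    def test_layout_and_counts(self, flooding_study):
        root = flooding_study.root
        assert len(list((root / "transients").glob("*.csv"))) == 20
        assert len(list((root / "mr820").glob("*.csv"))) == 20
        assert flooding_study.sample_sheet.exists()
        assert flooding_study.ground_truth.exists()

    def test_seeded_determinism_bit_identical(self, tmp_path):
        preset = flooding_preset(replicates=2)
        a = generate_study(preset, tmp_path / "a", seed=5)
        b = generate_study(preset, tmp_path / "b", seed=5)
        for pa in sorted(a.root.rglob("*.csv")):
            pb = b.root / pa.relative_to(a.root)
            assert pa.read_bytes() == pb.read_bytes(), pa.name

    def test_v_k_injection_propagates_downstream(self, flooding_study):
        # D15's K-band multiplier must surface as the largest positive V_K
        # change after a full re-extraction from the files on disk
        from ojipkit.io import read_sample_sheet, read_transient

        sheet = read_sample_sheet(flooding_study.sample_sheet)
        by_group = {}
        for row in sheet.rows():
            tr = read_transient(sheet.curve_path(row))
            rvf = relative_variable_fluorescence(extract_cardinals(tr))
            by_group.setdefault(row.group, []).append(rvf.v_k)
        means = {g: np.mean(v) for g, v in by_group.items()}
        changes = {g: means[g] / means["CK"] - 1 for g in ("D5", "D10", "D15")}
        assert all(c > 0 for c in changes.values())
        assert changes["D15"] == max(changes.values())
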