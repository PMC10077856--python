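import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saxskit import llc
from saxskit.llc import (
    Calibration,
    MillerIndex,
    Phase,
    ScatteringStandard,
    assign_phase,
    calibrate,
    compute_ratios,
    d_from_q,
    hexagonal_indices,
    lattice_parameter,
    load_standard,
    mass_fraction,
    prepare_standard,
    q_from_d,
)


class TestQDConversion:
    def test_closed_form(self):
        assert float(q_from_d(2.28)) == pytest.approx(2 * np.pi / 2.28, rel=1e-12)
        assert float(d_from_q(2 * np.pi)) == pytest.approx(1.0)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            q_from_d(0.0)
        with pytest.raises(ValueError):
            d_from_q(-1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_involution(self, x):
        assert float(d_from_q(q_from_d(x))) == pytest.approx(x, rel=1e-12)


class TestCalibration:
    STD = ScatteringStandard(name="synthetic", literature_q=[1.0, 2.0, 3.0, 4.0])

    def test_identity_when_measured_equals_literature(self):
        cal = prepare_standard(self.STD.literature_q, self.STD)
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-14)

    def test_exact_line_recovered(self):
        measured = 1.02 * self.STD.literature_q + 0.005
        cal = prepare_standard(measured, self.STD)
        assert cal.slope == pytest.approx(1.02, abs=1e-10)
        assert cal.intercept == pytest.approx(0.005, abs=1e-10)
        # inverse map returns the literature values
        np.testing.assert_allclose(
            calibrate(measured, cal), self.STD.literature_q, atol=1e-10
        )

    def test_two_points_interpolating_line(self):
        std = ScatteringStandard(name="s2", literature_q=[1.0, 3.0])
        cal = prepare_standard([1.1, 3.2], std)
        assert cal.slope == pytest.approx((3.2 - 1.1) / 2.0)
        assert cal.intercept == pytest.approx(1.1 - cal.slope)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            prepare_standard([1.0, 2.0], self.STD)

    def test_degenerate_standard_rejected(self):
        with pytest.raises(ValueError):
            prepare_standard([1.0, 1.0], ScatteringStandard(
                name="bad", literature_q=[2.0, 2.0]))

    def test_identity_calibration_is_noop(self):
        q = np.array([1.5, 2.5])
        np.testing.assert_array_equal(
            calibrate(q, Calibration(slope=1.0, intercept=0.0)), q
        )

    def test_monotonicity_preserved(self):
        q = np.array([1.0, 2.0, 3.0])
        out = calibrate(q, Calibration(slope=1.05, intercept=-0.01))
        assert np.all(np.diff(out) > 0)

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            Calibration(slope=-1.0, intercept=0.0)

    def test_standard_from_d_spacings(self):
        std = ScatteringStandard(name="from_d", literature_d=[5.25, 2.625, 1.75])
        np.testing.assert_allclose(
            std.literature_q, np.sort(2 * np.pi / np.array([5.25, 2.625, 1.75]))
        )

    def test_bundled_standard_loads(self):
        std = load_standard("cholesteryl palmitate")
        assert len(std.literature_q) >= 2
        assert np.all(np.diff(std.literature_q) > 0)

    def test_unknown_standard_rejected(self):
        with pytest.raises(KeyError, match="available"):
            load_standard("unobtainium")


class TestRatios:
    def test_single_value(self):
        np.testing.assert_allclose(compute_ratios([2.0]), [1.0])

    def test_hexagonal_closed_form(self):
        d = 2.5 * np.array([1, 1 / np.sqrt(3), 0.5])
        np.testing.assert_allclose(
            compute_ratios(d), [1.0, np.sqrt(3), 2.0], rtol=1e-12
        )

    def test_lamellar_closed_form(self):
        d = 2.28 * np.array([1, 0.5, 1 / 3])
        np.testing.assert_allclose(compute_ratios(d), [1.0, 2.0, 3.0], rtol=1e-12)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            compute_ratios([1.0, 2.0])


class TestPhaseAssignment:
    def test_hexagonal_pattern(self):
        d = 2.4855 * np.array([1, 1 / np.sqrt(3), 0.5])
        res = assign_phase(d)
        assert res.phase == Phase.HEXAGONAL
        assert [str(m) for m in res.indices] == ["10", "11", "20"]

    def test_cubic_body_centred_pattern(self):
        # q proportional to sqrt(6), sqrt(8), sqrt(10), sqrt(14), sqrt(38)
        n = np.array([6, 8, 10, 14, 38], dtype=float)
        d = 2.17 / np.sqrt(n)
        res = assign_phase(d)
        assert res.phase == Phase.CUBIC
        assert [str(m) for m in res.indices] == ["211", "220", "310", "321", "611"]
        assert res.centering == "body-centred"
        assert res.space_group == "Im3m"

    def test_lamellar_two_orders(self):
        res = assign_phase(np.array([2.28, 1.14]))
        assert res.phase == Phase.LAMELLAR

    def test_single_peak_indeterminate(self):
        res = assign_phase(np.array([2.28]))
        assert res.phase == Phase.INDETERMINATE

    def test_unmatchable_ratios_indeterminate(self):
        # two peaks with an irrational ratio match no lamellar/hexagonal
        # pattern, and two peaks are too few for a cubic assignment
        res = assign_phase(np.array([2.0, 2.0 / 1.31]))
        assert res.phase == Phase.INDETERMINATE

    def test_two_cubic_peaks_insufficient(self):
        # sqrt(8/6) ratio alone must not trigger a cubic assignment
        d = 2.17 / np.sqrt(np.array([6.0, 8.0]))
        res = assign_phase(d)
        assert res.phase == Phase.INDETERMINATE

    def test_tolerance_monotonicity(self):
        d = 2.5 * np.array([1, 1 / (np.sqrt(3) * 1.015), 0.5])
        matched_at = [
            tol
            for tol in (0.005, 0.01, 0.02, 0.05, 0.1)
            if assign_phase(d, tolerance=tol).phase == Phase.HEXAGONAL
        ]
        # once it matches at t it matches at every larger tolerance
        assert matched_at == [t for t in (0.005, 0.01, 0.02, 0.05, 0.1)
                              if t >= matched_at[0]]

    def test_invalid_tolerance_rejected(self):
        with pytest.raises(ValueError, match="tolerance"):
            assign_phase(np.array([2.0, 1.0]), tolerance=0.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_equivariance(self, c):
        d = 2.4855 * np.array([1, 1 / np.sqrt(3), 0.5])
        base = assign_phase(d)
        scaled = assign_phase(c * d)
        assert scaled.phase == base.phase
        assert scaled.indices == base.indices
        assert lattice_parameter(scaled) == pytest.approx(
            c * lattice_parameter(base), rel=1e-9
        )


class TestLatticeParameter:
    def test_hexagonal_closed_form(self):
        res = assign_phase(2.4855 * np.array([1, 1 / np.sqrt(3), 0.5]))
        assert lattice_parameter(res) == pytest.approx(2.87, abs=5e-3)
        assert res.a_spread == pytest.approx(0.0, abs=1e-12)

    def test_cubic_closed_form(self):
        d211 = 0.8859
        res = assign_phase(d211 * np.sqrt(6.0) / np.sqrt([6.0, 8.0, 10.0]))
        assert res.phase == Phase.CUBIC
        assert lattice_parameter(res) == pytest.approx(d211 * np.sqrt(6), rel=1e-9)

    def test_lamellar_layer_spacing(self):
        res = assign_phase(np.array([2.28, 1.14]))
        assert lattice_parameter(res) == pytest.approx(2.28)

    def test_indeterminate_rejected(self):
        res = assign_phase(np.array([2.28]))
        with pytest.raises(ValueError, match="indeterminate"):
            lattice_parameter(res)

    def test_self_consistency_round_trip(self):
        # generating the first k reflections of any phase and re-assigning
        # recovers the phase and lattice parameter exactly
        from saxskit.synth import peak_positions

        cases = [
            (Phase.HEXAGONAL, 2.87, 4, None),
            (Phase.CUBIC, 2.17, 5, "Im3m"),
            (Phase.CUBIC, 3.1, 5, "Ia3d"),
            (Phase.LAMELLAR, 2.28, 3, None),
        ]
        for phase, a, k, group in cases:
            q, _ = peak_positions(phase, a, k, group or "Im3m")
            res = assign_phase(np.sort(d_from_q(q))[::-1])
            assert res.phase == phase, (phase, a)
            assert lattice_parameter(res) == pytest.approx(a, rel=1e-9)


class TestMassFraction:
    @pytest.mark.parametrize(
        "ms, mw, w", [(1.0, 0.0, 1.0), (0.74, 0.26, 0.74), (3.0, 1.0, 0.75)]
    )
    def test_values(self, ms, mw, w):
        assert mass_fraction(ms, mw) == pytest.approx(w)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            mass_fraction(0.0, 0.0)


class TestMillerIndex:
    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            MillerIndex(0, 0, 0)

    def test_hexagonal_sequence(self):
        assert [m.N for m in hexagonal_indices(5)] == [1, 3, 4, 7, 9]


def test_export_tsv(tmp_path):
    res = assign_phase(2.4855 * np.array([1, 1 / np.sqrt(3), 0.5]))
    lattice_parameter(res)
    path = llc.export_tsv(res, tmp_path / "report.tsv")
    text = path.read_text()
    assert "# phase\tH1" in text
    assert "q_corrected\td_measured\td_ratio\thkl\ta_nm" in text
    assert text.count("\n") >= 7
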