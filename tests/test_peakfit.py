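import json

import numpy as np
import pytest

from saxskit import peakfit, synth
from saxskit.peakfit import (
    PeakModelSpec,
    auto_specs,
    detect_peaks,
    filter_significant,
    fit,
    fwhm_from_sigma,
    gaussian,
    load_specs,
    lorentzian,
    save_peak_centers,
    save_specs,
    voigt,
)
from saxskit.readers import Diffractogram


class TestLorentzianIdentities:
    I0, A, QC, FWHM = 1.0, 5.0, 2.0, 0.05

    def test_peak_maximum(self):
        assert lorentzian(self.QC, self.I0, self.A, self.QC, self.FWHM) == (
            pytest.approx(self.I0 + 2 * self.A / (np.pi * self.FWHM))
        )

    def test_half_maximum_at_half_width(self):
        for q in (self.QC - self.FWHM / 2, self.QC + self.FWHM / 2):
            assert lorentzian(q, self.I0, self.A, self.QC, self.FWHM) == (
                pytest.approx(self.I0 + self.A / (np.pi * self.FWHM))
            )

    def test_symmetry(self):
        deltas = np.linspace(0.001, 1.0, 17)
        left = lorentzian(self.QC - deltas, self.I0, self.A, self.QC, self.FWHM)
        right = lorentzian(self.QC + deltas, self.I0, self.A, self.QC, self.FWHM)
        np.testing.assert_allclose(left, right)

    def test_non_positive_width_rejected(self):
        with pytest.raises(ValueError):
            lorentzian(1.0, 0.0, 1.0, 1.0, 0.0)

    @pytest.mark.parametrize("profile", ["lorentzian", "gaussian", "voigt"])
    def test_area_conservation(self, profile):
        # integral of the peak term over +-50 FWHM equals A within 0.1%
        q = np.linspace(self.QC - 50 * self.FWHM, self.QC + 50 * self.FWHM, 200001)
        if profile == "lorentzian":
            y = lorentzian(q, 0.0, self.A, self.QC, self.FWHM)
            # closed form: windowed integral is A * (2/pi) * arctan(2L/FWHM)
            expected = self.A * (2 / np.pi) * np.arctan(100.0)
            tol = 1e-3
        elif profile == "gaussian":
            sigma = self.FWHM / (2 * np.sqrt(2 * np.log(2)))
            y = gaussian(q, 0.0, self.A, self.QC, sigma)
            expected = self.A
            tol = 1e-3
        else:
            y = voigt(q, 0.0, self.A, self.QC, self.FWHM / 4, self.FWHM / 4)
            expected = self.A  # Lorentzian tail beyond the window ~0.3%
            tol = 5e-3
        area = np.trapezoid(y, q)
        assert area == pytest.approx(expected, rel=tol)


class TestProfileLimits:
    def test_voigt_tends_to_gaussian(self):
        q = np.linspace(1.0, 3.0, 501)
        sigma = 0.05
        v = voigt(q, 0.0, 2.0, 2.0, sigma, 1e-12)
        g = gaussian(q, 0.0, 2.0, 2.0, sigma)
        assert np.max(np.abs(v - g)) <= 1e-6

    def test_voigt_tends_to_lorentzian(self):
        q = np.linspace(1.0, 3.0, 501)
        gamma = 0.05
        v = voigt(q, 0.0, 2.0, 2.0, 1e-13, gamma)
        lo = lorentzian(q, 0.0, 2.0, 2.0, 2 * gamma)
        assert np.max(np.abs(v - lo)) <= 1e-6

    def test_fwhm_derivations(self):
        assert fwhm_from_sigma("lorentzian", 0.04) == pytest.approx(0.08)
        assert fwhm_from_sigma("gaussian", 0.04) == pytest.approx(
            0.08 * np.sqrt(2 * np.log(2))
        )
        # Voigt approximation reduces to the pure limits
        assert fwhm_from_sigma("voigt", 1e-12, 0.04) == pytest.approx(0.08, rel=1e-3)


class TestDetection:
    def test_single_noiseless_peak_located(self):
        q = np.linspace(1.0, 3.0, 400)
        d = Diffractogram(q=q, intensity=lorentzian(q, 1.0, 5.0, 2.0, 0.05))
        centers = detect_peaks(d, width_range=(2, 20))
        assert len(centers) >= 1
        assert np.min(np.abs(centers - 2.0)) <= 0.02

    def test_constant_signal_yields_nothing(self):
        d = Diffractogram(q=np.linspace(1, 3, 100), intensity=np.ones(100))
        assert len(detect_peaks(d)) == 0

    def test_three_separated_peaks_ordered(self, hexagonal_truth):
        gt = hexagonal_truth
        d = synth.generate(gt)
        centers = detect_peaks(d)
        true_q = gt.positions()[0]
        for tq in true_q:
            assert np.min(np.abs(centers - tq)) < 0.05
        assert np.all(np.diff(centers) > 0)

    def test_too_few_points_rejected(self):
        d = Diffractogram(q=np.linspace(1, 2, 5), intensity=np.ones(5))
        with pytest.raises(ValueError, match="8 data points"):
            detect_peaks(d)


class TestSpecs:
    def test_one_spec_per_center(self, hexagonal_curve):
        centers = [2.5, 4.4, 5.1]
        specs = auto_specs(centers, hexagonal_curve)
        assert len(specs) == 3
        assert [s.center for s in specs] == centers
        assert all(s.kind == "lorentzian" for s in specs)

    def test_empty_centers_empty_specs(self, hexagonal_curve):
        assert auto_specs([], hexagonal_curve) == []

    def test_invalid_spec_parameters_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            PeakModelSpec(sigma=-1.0)
        with pytest.raises(ValueError, match="unknown model type"):
            PeakModelSpec(kind="parabola")
        with pytest.raises(ValueError, match="bounds"):
            PeakModelSpec(center=5.0, center_bounds=(1.0, 2.0))

    def test_json_round_trip(self, tmp_path):
        specs = [
            PeakModelSpec("lorentzian", 2.0, 5.0, 0.03),
            PeakModelSpec("gaussian", 4.0, 2.0, 0.02, center_bounds=(3.9, 4.1)),
            PeakModelSpec("voigt", 5.0, 1.0, 0.04),
        ]
        path = save_specs(specs, tmp_path / "models_dict.json")
        assert load_specs(path) == specs

    def test_empty_list_round_trip(self, tmp_path):
        path = save_specs([], tmp_path / "models_dict.json")
        assert path.read_text().strip() == "[]"
        assert load_specs(path) == []

    def test_unknown_type_on_load_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps([{"type": "parabola", "center": 1.0,
                                  "amplitude": 1.0, "sigma": 0.1}]))
        with pytest.raises(ValueError, match="parabola"):
            load_specs(p)


class TestFit:
    def _noiseless(self, I0=1.0, A=5.0, qc=2.0, fwhm=0.05):
        q = np.linspace(1.0, 3.0, 600)
        return Diffractogram(q=q, intensity=lorentzian(q, I0, A, qc, fwhm))

    def test_exact_guess_is_fixed_point(self):
        d = self._noiseless()
        specs = [PeakModelSpec("lorentzian", 2.0, 5.0, 0.025)]
        result = fit(d, specs)
        assert result.success
        peak = result.peaks[0]
        assert peak.center == pytest.approx(2.0, rel=1e-6)
        assert peak.amplitude == pytest.approx(5.0, rel=1e-6)
        assert peak.fwhm == pytest.approx(0.05, rel=1e-6)
        assert result.offset == pytest.approx(1.0, rel=1e-6)

    def test_noisy_center_recovery(self):
        q = np.linspace(1.0, 3.0, 600)
        clean = lorentzian(q, 1.0, 5.0, 2.0, 0.05)
        rng = np.random.default_rng(42)
        height = 2 * 5.0 / (np.pi * 0.05)
        noisy = clean + rng.standard_normal(q.size) * 0.01 * height
        d = Diffractogram(q=q, intensity=noisy)
        result = fit(d, [PeakModelSpec("lorentzian", 2.05, 4.0, 0.03)])
        assert result.peaks[0].center == pytest.approx(2.0, rel=0.005)

    def test_overlapping_peaks_resolved(self):
        q = np.linspace(1.0, 3.0, 800)
        fwhm = 0.05
        y = lorentzian(q, 0.5, 3.0, 2.0, fwhm) + lorentzian(
            q, 0.0, 2.0, 2.0 + 1.5 * fwhm, fwhm
        )
        d = Diffractogram(q=q, intensity=y)
        specs = [
            PeakModelSpec("lorentzian", 1.99, 2.0, 0.03),
            PeakModelSpec("lorentzian", 2.09, 2.0, 0.03),
        ]
        result = fit(d, specs)
        assert result.peaks[0].center == pytest.approx(2.0, rel=0.02)
        assert result.peaks[1].center == pytest.approx(2.075, rel=0.02)

    def test_too_few_points_rejected(self):
        d = Diffractogram(q=np.linspace(1, 2, 5), intensity=np.ones(5))
        with pytest.raises(ValueError, match="cannot constrain"):
            fit(d, [PeakModelSpec(), PeakModelSpec(center=1.5)])

    def test_deterministic_repeat(self, hexagonal_curve, tmp_path):
        specs = [
            PeakModelSpec("lorentzian", 2.53, 5.0, 0.04),
            PeakModelSpec("lorentzian", 4.38, 2.5, 0.04),
            PeakModelSpec("lorentzian", 5.06, 1.3, 0.04),
        ]
        r1 = fit(hexagonal_curve, specs)
        r2 = fit(hexagonal_curve, specs)
        p1 = save_peak_centers(r1, tmp_path / "c1.txt")
        p2 = save_peak_centers(r2, tmp_path / "c2.txt")
        assert p1.read_bytes() == p2.read_bytes()
        f1 = peakfit.save_fit_result(r1, tmp_path / "r1.json")
        f2 = peakfit.save_fit_result(r2, tmp_path / "r2.json")
        assert f1.read_bytes() == f2.read_bytes()

    def test_parameter_recovery_over_seeds(self):
        # seeded noisy single peak at SNR 20 (signal-proportional noise):
        # qc within 0.5%, FWHM within 5%, over 20 seeds
        for seed in range(20):
            gt = synth.GroundTruth(
                phase="La", a=2.28, n_reflections=1, snr=20.0, seed=seed
            )
            d = synth.generate(gt)
            qc = gt.positions()[0][0]
            result = fit(
                d, [PeakModelSpec("lorentzian", qc * 1.01, 4.0, 0.03)]
            )
            assert result.peaks[0].center == pytest.approx(qc, rel=0.005)
            assert result.peaks[0].fwhm == pytest.approx(gt.fwhm, rel=0.05)


class TestCenterPersistence:
    def test_centers_file_ascending_and_re_readable(self, tmp_path):
        d_q = np.linspace(1.0, 6.0, 1200)
        y = (
            lorentzian(d_q, 1.0, 5.0, 2.5278, 0.05)
            + lorentzian(d_q, 0.0, 2.0, 4.3783, 0.05)
            + lorentzian(d_q, 0.0, 1.0, 5.0556, 0.05)
        )
        d = Diffractogram(q=d_q, intensity=y)
        specs = [
            PeakModelSpec("lorentzian", c, 2.0, 0.03)
            for c in (2.53, 4.38, 5.05)
        ]
        result = fit(d, specs)
        path = save_peak_centers(result, tmp_path / "centers.txt")
        from saxskit.readers import read_center_list

        values = read_center_list(path)
        assert len(values) == 3
        assert np.all(np.diff(values) > 0)
        np.testing.assert_allclose(values, np.sort(result.centers), atol=5e-7)


def test_filter_significant_drops_noise_spikes(hexagonal_curve):
    centers = detect_peaks(hexagonal_curve)
    specs = auto_specs(centers, hexagonal_curve)
    result = fit(hexagonal_curve, specs)
    dq = float(np.median(np.diff(hexagonal_curve.q)))
    filtered = filter_significant(result, min_fwhm=2 * dq)
    assert len(filtered.peaks) == 3
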