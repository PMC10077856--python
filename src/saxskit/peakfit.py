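"""Peak detection and composite profile fitting of 1D diffractograms.

Diffraction reflections are modelled as area-parameterized Lorentzian,
Gaussian or Voigt profiles on a shared constant baseline I0.  The Lorentzian,
the default for line-collimated SAXS of lyotropic mesophases, is

    I(q) = I0 + (2 A / pi) * FWHM / (4 (q - qc)^2 + FWHM^2)

with integrated area A, center qc and full width at half maximum FWHM.
Candidate peaks are located with a continuous-wavelet-transform ridge search
(Mexican-hat kernel over a user width range); initial parameter guesses can
be derived automatically from the candidates; the composite model is
minimised by Levenberg-Marquardt least squares (via lmfit).  All fit inputs
are persisted to a JSON spec file so a fit can be re-run bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from lmfit import models as lmfit_models
from scipy import signal

from .readers import Diffractogram

__all__ = [
    "PeakModelSpec",
    "PeakFitResult",
    "FitResult",
    "lorentzian",
    "gaussian",
    "voigt",
    "fwhm_from_sigma",
    "detect_peaks",
    "auto_specs",
    "save_specs",
    "load_specs",
    "fit",
    "peak_height",
    "filter_significant",
    "save_peak_centers",
    "export_fit_table",
    "save_fit_result",
]

_KINDS = ("lorentzian", "gaussian", "voigt")


# ---------------------------------------------------------------------------
# analytic profiles


def lorentzian(q, I0, A, qc, fwhm):
    """Lorentzian peak on a constant offset, parameterized by area and FWHM.

    Peak maximum is ``I0 + 2A/(pi*FWHM)`` at ``q = qc``; the peak term
    integrates to ``A`` over the whole axis.
    """
    if fwhm <= 0:
        raise ValueError("FWHM must be positive")
    q = np.asarray(q, dtype=float)
    return I0 + (2.0 * A / np.pi) * fwhm / (4.0 * (q - qc) ** 2 + fwhm**2)


def gaussian(q, I0, A, qc, sigma):
    """Area-normalized Gaussian peak on a constant offset."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    q = np.asarray(q, dtype=float)
    return I0 + A / (sigma * np.sqrt(2.0 * np.pi)) * np.exp(
        -((q - qc) ** 2) / (2.0 * sigma**2)
    )


def voigt(q, I0, A, qc, sigma, gamma):
    """Voigt profile (Gaussian convolved with Lorentzian) via the Faddeeva
    function; area-parameterized.  ``sigma`` is the Gaussian width, ``gamma``
    the Lorentzian half width."""
    from scipy.special import wofz

    if sigma <= 0 and gamma <= 0:
        raise ValueError("sigma and gamma cannot both be non-positive")
    sigma = max(sigma, 1e-13)
    q = np.asarray(q, dtype=float)
    z = ((q - qc) + 1j * gamma) / (sigma * np.sqrt(2.0))
    return I0 + A * wofz(z).real / (sigma * np.sqrt(2.0 * np.pi))


def fwhm_from_sigma(kind: str, sigma: float, gamma: float | None = None) -> float:
    """Full width at half maximum for the stored width parameter.

    Lorentzian: FWHM = 2*sigma; Gaussian: FWHM = 2*sigma*sqrt(2 ln 2);
    Voigt: Olivero-Longbothum approximation from both widths.
    """
    if kind == "lorentzian":
        return 2.0 * sigma
    if kind == "gaussian":
        return 2.0 * sigma * np.sqrt(2.0 * np.log(2.0))
    if kind == "voigt":
        g = sigma if gamma is None else gamma
        fl = 2.0 * g
        fg = 2.0 * sigma * np.sqrt(2.0 * np.log(2.0))
        return 0.5346 * fl + np.sqrt(0.2166 * fl**2 + fg**2)
    raise ValueError(f"unknown profile kind {kind!r}")


# ---------------------------------------------------------------------------
# specs


@dataclass
class PeakModelSpec:
    """Initial description of one peak model for the composite fit.

    ``sigma`` is the stored width parameter (half width for Lorentzian);
    FWHM is derived per kind.  ``center_bounds`` restricts the center during
    optimisation.
    """

    kind: str = "lorentzian"
    center: float = 1.0
    amplitude: float = 1.0
    sigma: float = 0.05
    center_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(
                f"unknown model type {self.kind!r}; expected one of {_KINDS}"
            )
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.center_bounds is not None:
            lo, hi = self.center_bounds
            if not (lo < self.center < hi):
                raise ValueError(
                    f"center {self.center} outside bounds ({lo}, {hi})"
                )

    def to_dict(self) -> dict:
        d = {
            "type": self.kind,
            "center": self.center,
            "amplitude": self.amplitude,
            "sigma": self.sigma,
        }
        if self.center_bounds is not None:
            d["center_lower_bound"] = self.center_bounds[0]
            d["center_upper_bound"] = self.center_bounds[1]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PeakModelSpec":
        bounds = None
        if "center_lower_bound" in d or "center_upper_bound" in d:
            bounds = (d["center_lower_bound"], d["center_upper_bound"])
        return cls(
            kind=d["type"],
            center=d["center"],
            amplitude=d["amplitude"],
            sigma=d["sigma"],
            center_bounds=bounds,
        )


def save_specs(specs: Sequence[PeakModelSpec], path: str | Path) -> Path:
    """Persist the list of peak models as JSON (``models_dict`` schema)."""
    path = Path(path)
    path.write_text(
        json.dumps([s.to_dict() for s in specs], indent=2) + "\n"
    )
    return path


def load_specs(path: str | Path) -> list[PeakModelSpec]:
    data = json.loads(Path(path).read_text())
    if not isinstance(data, list):
        raise ValueError(f"{path}: expected a JSON list of peak models")
    return [PeakModelSpec.from_dict(d) for d in data]


# ---------------------------------------------------------------------------
# detection


def detect_peaks(
    d: Diffractogram,
    width_range: tuple[int, int] = (2, 30),
    n_widths: int = 15,
    min_snr: float = 2.0,
    exclude_edges: bool = True,
) -> np.ndarray:
    """Locate candidate peak centers with a CWT ridge search.

    Widths are in samples.  Returns candidate centers in q units, sorted
    ascending; a flat or featureless signal yields an empty array.  The CWT
    response is unreliable within one maximum width of the data boundaries
    (edge ringing of the kernel), so candidates there are dropped unless
    ``exclude_edges`` is disabled.  The deliberately permissive ``min_snr``
    favours recall; spurious candidates are cheap to discard after fitting
    (see :func:`filter_significant`).
    """
    if len(d) < 8:
        raise ValueError("need at least 8 data points for peak detection")
    wmin, wmax = width_range
    if not 0 < wmin < wmax:
        raise ValueError("width_range must satisfy 0 < min < max")
    widths = np.linspace(wmin, wmax, n_widths)
    if np.ptp(d.intensity) == 0:
        return np.array([])
    idx = signal.find_peaks_cwt(
        d.intensity,
        widths,
        min_length=len(widths) // 2,
        min_snr=min_snr,
    )
    idx = np.asarray(idx, dtype=int)
    if exclude_edges and idx.size:
        idx = idx[(idx >= wmax) & (idx < len(d) - wmax)]
    if idx.size == 0:
        return np.array([])
    return np.sort(d.q[idx])


def auto_specs(
    centers: Sequence[float],
    d: Diffractogram,
    width_range: tuple[int, int] = (2, 30),
    kind: str = "lorentzian",
) -> list[PeakModelSpec]:
    """Build one initial peak model per detected center.

    Initial sigma comes from the width-range midpoint (converted from samples
    to q units); initial amplitude from the local intensity above a baseline
    estimate (the data minimum), converted to peak area.
    """
    specs: list[PeakModelSpec] = []
    if len(centers) == 0:
        return specs
    dq = float(np.median(np.diff(d.q))) if len(d) > 1 else 1.0
    sigma0 = 0.5 * (width_range[0] + width_range[1]) / 2.0 * dq
    baseline = float(np.min(d.intensity))
    for c in centers:
        if not d.q[0] <= c <= d.q[-1]:
            raise ValueError(f"center {c} outside data range")
        height = float(np.interp(c, d.q, d.intensity)) - baseline
        height = max(height, np.ptp(d.intensity) * 1e-3)
        # invert peak-maximum relation of the profile to get an area guess
        if kind == "gaussian":
            area = height * sigma0 * np.sqrt(2.0 * np.pi)
        else:
            area = height * np.pi * sigma0
        # a genuine candidate center is off by at most a few search widths;
        # bounding it keeps spurious models from drifting out of range
        lo = max(float(d.q[0]), float(c) - 10.0 * sigma0)
        hi = min(float(d.q[-1]), float(c) + 10.0 * sigma0)
        specs.append(
            PeakModelSpec(
                kind=kind,
                center=float(c),
                amplitude=area,
                sigma=sigma0,
                center_bounds=(lo, hi),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# fitting


@dataclass
class PeakFitResult:
    """Best-fit parameters of one peak in the composite model."""

    kind: str
    center: float
    amplitude: float
    sigma: float
    fwhm: float
    stderr_center: float | None = None


@dataclass
class FitResult:
    """Outcome of a composite least-squares fit.

    ``offset`` is the shared additive baseline I0; ``peaks`` are sorted by
    center ascending.  ``success`` is lmfit's convergence flag — callers must
    check it, non-convergence is reported, never silent.
    """

    specs_used: list[PeakModelSpec]
    offset: float
    peaks: list[PeakFitResult]
    residuals: np.ndarray
    redchi: float
    success: bool
    message: str = ""
    settings: dict = field(default_factory=dict)

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.peaks])

    def validate(self) -> None:
        if len(self.peaks) != len(self.specs_used):
            raise ValueError("one best-fit entry required per spec")


_MAX_ITER = 1000
_TOL = 1e-8


def _build_model(specs: Sequence[PeakModelSpec]):
    model = lmfit_models.ConstantModel(prefix="bkg_")
    params = model.make_params(c=0.0)
    for i, spec in enumerate(specs):
        prefix = f"p{i}_"
        cls = {
            "lorentzian": lmfit_models.LorentzianModel,
            "gaussian": lmfit_models.GaussianModel,
            "voigt": lmfit_models.VoigtModel,
        }[spec.kind]
        peak = cls(prefix=prefix)
        model = model + peak
        params.update(
            peak.make_params(
                center=spec.center, amplitude=spec.amplitude, sigma=spec.sigma
            )
        )
        params[f"{prefix}amplitude"].set(min=0.0)
        params[f"{prefix}sigma"].set(min=1e-12)
        if spec.center_bounds is not None:
            lo, hi = spec.center_bounds
            params[f"{prefix}center"].set(min=lo, max=hi)
    return model, params


def fit(d: Diffractogram, specs: Sequence[PeakModelSpec]) -> FitResult:
    """Fit the composite model (shared offset + peak profiles) to the curve.

    Levenberg-Marquardt least squares with a fixed iteration cap and
    tolerance; given identical inputs the result is deterministic.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("at least one peak spec is required")
    for s in specs:
        if isinstance(s, dict):
            raise TypeError("specs must be PeakModelSpec instances")
    if len(d) < 3 * len(specs) + 1:
        raise ValueError(
            f"{len(d)} points cannot constrain {len(specs)} peaks "
            f"(need >= {3 * len(specs) + 1})"
        )
    model, params = _build_model(specs)
    # cap is per LM iteration; leastsq counts single evaluations, so scale
    # by the parameter count
    max_nfev = _MAX_ITER * len(params)
    settings = {
        "method": "leastsq",
        "max_nfev": max_nfev,
        "xtol": _TOL,
        "ftol": _TOL,
    }
    out = model.fit(
        d.intensity,
        params,
        x=d.q,
        method="leastsq",
        max_nfev=max_nfev,
        fit_kws={"xtol": _TOL, "ftol": _TOL},
    )
    order = np.argsort([out.params[f"p{i}_center"].value for i in range(len(specs))])
    peaks = []
    for i in order:
        kind = specs[i].kind
        sigma = out.params[f"p{i}_sigma"].value
        gamma = (
            out.params[f"p{i}_gamma"].value if kind == "voigt" else None
        )
        peaks.append(
            PeakFitResult(
                kind=kind,
                center=out.params[f"p{i}_center"].value,
                amplitude=out.params[f"p{i}_amplitude"].value,
                sigma=sigma,
                fwhm=fwhm_from_sigma(kind, sigma, gamma),
                stderr_center=out.params[f"p{i}_center"].stderr,
            )
        )
    result = FitResult(
        specs_used=[specs[i] for i in order],
        offset=out.params["bkg_c"].value,
        peaks=peaks,
        residuals=np.asarray(out.residual, dtype=float),
        redchi=float(out.redchi),
        success=bool(out.success),
        message=str(out.message),
        settings=settings,
    )
    result.validate()
    return result


def peak_height(p: PeakFitResult) -> float:
    """Peak maximum above the baseline from the fitted parameters."""
    if p.kind == "lorentzian":
        return 2.0 * p.amplitude / (np.pi * p.fwhm)
    if p.kind == "gaussian":
        return p.amplitude / (p.sigma * np.sqrt(2.0 * np.pi))
    # voigt: evaluate the profile at its center
    gamma = p.fwhm / 2.0  # upper bound; exact height needs the gamma value
    return float(
        voigt(np.array([p.center]), 0.0, p.amplitude, p.center, p.sigma, gamma)[0]
    )


def filter_significant(
    result: FitResult,
    min_height_snr: float = 5.0,
    min_fwhm: float | None = None,
) -> FitResult:
    """Drop fitted peaks that are not significant against the residual noise.

    A peak is kept when its fitted height above baseline exceeds
    ``min_height_snr`` times the residual standard deviation and its FWHM is
    at least ``min_fwhm`` (single noise spikes fit as peaks one sample wide;
    callers should pass the minimum search width in q units).  This removes
    candidates the permissive CWT search picked up from noise ripples or
    boundary artefacts while leaving genuine reflections untouched.
    """
    noise = float(np.std(result.residuals))
    if noise == 0:
        return result
    floor = 0.0 if min_fwhm is None else min_fwhm
    keep = [i for i, p in enumerate(result.peaks)
            if peak_height(p) >= min_height_snr * noise and p.fwhm >= floor]
    if len(keep) == len(result.peaks):
        return result
    return FitResult(
        specs_used=[result.specs_used[i] for i in keep],
        offset=result.offset,
        peaks=[result.peaks[i] for i in keep],
        residuals=result.residuals,
        redchi=result.redchi,
        success=result.success,
        message=result.message,
        settings=result.settings,
    )


def save_peak_centers(result: FitResult, path: str | Path) -> Path:
    """Write fitted peak centers, one per line ascending, fixed 6 decimals."""
    path = Path(path)
    centers = np.sort(result.centers)
    path.write_text("".join(f"{c:.6f}\n" for c in centers))
    return path


def export_fit_table(result: FitResult, path: str | Path) -> Path:
    """Write the per-peak fit parameters as a tab-separated table.

    Columns: peak index, shared offset I0, center qc, FWHM and area A — the
    same layout external fitting software exports, so the file is re-readable
    by :func:`saxskit.readers.read_external_fit_table`.
    """
    lines = ["peak\tI0\tqc\tFWHM\tA"]
    for i, p in enumerate(result.peaks, start=1):
        lines.append(
            f"{i}\t{result.offset:.9g}\t{p.center:.9g}\t{p.fwhm:.9g}"
            f"\t{p.amplitude:.9g}"
        )
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def save_fit_result(result: FitResult, path: str | Path) -> Path:
    """Persist the full fit outcome (parameters, settings, goodness) as JSON."""
    payload = {
        "offset_I0": result.offset,
        "success": result.success,
        "message": result.message,
        "reduced_chi_square": result.redchi,
        "settings": result.settings,
        "specs_used": [s.to_dict() for s in result.specs_used],
        "peaks": [
            {
                "type": p.kind,
                "center": p.center,
                "amplitude": p.amplitude,
                "sigma": p.sigma,
                "fwhm": p.fwhm,
            }
            for p in result.peaks
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
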