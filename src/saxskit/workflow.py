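"""End-to-end workflow functions: convert -> fit -> analyze -> package.

These are the library entry points behind the command-line interface.  Each
function is pure file-plumbing around the other modules: PDH files become
AnIML samples/experiment steps, detected and fitted peaks are persisted next
to the document, phase-assignment results are appended as an analysis
category and exported as TSV, and everything is bundled into a COMBINE
archive.  A fixed ``timestamp`` makes every produced byte reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import llc, peakfit
from .animl import (
    AnIMLDocument,
    Category,
    ExperimentStep,
    Method,
    Parameter,
    Sample,
    Series,
    SeriesSet,
    Unit,
)
from .readers import Diffractogram, PDHHeader, read_pdh

__all__ = [
    "RunConfig",
    "ConversionError",
    "FitNotConverged",
    "pdh_to_step",
    "convert",
    "fit_document",
    "analyze",
    "package",
]

Q_UNIT = Unit(label="1/nm", quantity="scattering vector")
INTENSITY_UNIT = Unit(label="a.u.", quantity="intensity")
NM_UNIT = Unit(label="nm", quantity="length")


class ConversionError(RuntimeError):
    """One or more input files could not be converted."""


class FitNotConverged(RuntimeError):
    """The least-squares fit did not converge."""


@dataclass
class RunConfig:
    """Options shared by the workflow steps.

    ``tolerance`` is the relative d-ratio tolerance of the phase matcher,
    ``width_range`` the CWT peak-search width window in samples, ``timestamp``
    an optional fixed audit/archive time for byte-reproducible output.
    """

    width_range: tuple[int, int] = (2, 30)
    profile_kind: str = "lorentzian"
    tolerance: float = 0.02
    standard: str | None = None
    literature_q: list[float] | None = None
    strict: bool = True
    timestamp: str | None = None
    creators: list[str] = field(default_factory=lambda: ["saxskit"])

    def __post_init__(self) -> None:
        if not 0 < self.tolerance <= 0.1:
            raise ValueError("tolerance must be in (0, 0.1]")


def _sample_id_for(path: Path) -> str:
    return path.stem


def pdh_to_step(
    d: Diffractogram, header: PDHHeader, sample_id: str
) -> tuple[Sample, ExperimentStep]:
    """Map one PDH measurement onto an AnIML Sample + ExperimentStep.

    Mapping: PDH description -> Sample.name; data columns -> a SeriesSet with
    q independent (nm^-1) and intensity dependent (a.u.); the raw header
    integers/reals and any embedded XML -> a Method category with parameter
    names prefixed ``pdh.`` (preserved, not interpreted).  Series IDs are
    ``<sampleID>/<column>``, which keeps them unique document-wide.
    """
    sample = Sample(sample_id=sample_id, name=header.description or sample_id)
    pdh_params = Category(name="instrument parameters")
    pdh_params.add_parameter(
        Parameter(name="pdh.keyword_line", value=header.keyword_line)
    )
    for i, v in enumerate(header.int_block):
        pdh_params.add_parameter(Parameter(name=f"pdh.int{i}", value=int(v)))
    for i, v in enumerate(header.real_blocks):
        pdh_params.add_parameter(Parameter(name=f"pdh.real{i}", value=float(v)))
    if header.extra_xml:
        pdh_params.add_parameter(
            Parameter(name="pdh.extra_xml", value=header.extra_xml)
        )
    series = [
        Series(
            series_id=f"{sample_id}/q",
            values=[float(v) for v in d.q],
            dependency="independent",
            unit=Q_UNIT,
        ),
        Series(
            series_id=f"{sample_id}/intensity",
            values=[float(v) for v in d.intensity],
            dependency="dependent",
            unit=INTENSITY_UNIT,
        ),
    ]
    if d.sigma_I is not None:
        series.append(
            Series(
                series_id=f"{sample_id}/sigma_I",
                values=[float(v) for v in d.sigma_I],
                dependency="dependent",
                unit=INTENSITY_UNIT,
            )
        )
    step = ExperimentStep(
        step_id=f"step_{sample_id}",
        name=f"SAXS measurement of {sample_id}",
        sample_refs=[sample_id],
        method=Method(
            instrument="SAXS (line collimation)",
            software="saxskit",
            parameters=[pdh_params],
        ),
        result=[SeriesSet(name="measurement", series=series)],
    )
    return sample, step


def convert(
    pdh_paths: Sequence[str | Path],
    out_path: str | Path,
    config: RunConfig | None = None,
) -> AnIMLDocument:
    """Convert PDH files into one AnIML document (one sample + step each)."""
    config = config or RunConfig()
    if not pdh_paths:
        raise ConversionError("no PDH input files given")
    doc = AnIMLDocument()
    failures: list[str] = []
    for p in pdh_paths:
        p = Path(p)
        try:
            d, header = read_pdh(p)
            sample, step = pdh_to_step(d, header, _sample_id_for(p))
            doc.add_sample(sample, timestamp=config.timestamp)
            doc.add_experiment_step(step, timestamp=config.timestamp)
        except Exception as exc:  # collect per-file failures
            failures.append(f"{p}: {exc}")
    if failures:
        raise ConversionError(
            "conversion failed for:\n" + "\n".join(failures)
        )
    Path(out_path).write_text(doc.to_xml())
    return doc


def _diffractogram_from_doc(doc: AnIMLDocument, sample_id: str) -> Diffractogram:
    q = doc.get_series(f"{sample_id}/q").values
    intensity = doc.get_series(f"{sample_id}/intensity").values
    return Diffractogram(
        q=np.asarray(q), intensity=np.asarray(intensity), label=sample_id
    )


def fit_document(
    doc: AnIMLDocument,
    sample_id: str,
    out_dir: str | Path,
    config: RunConfig | None = None,
    specs: Sequence[peakfit.PeakModelSpec] | None = None,
) -> peakfit.FitResult:
    """Detect and fit peaks for one sample of an AnIML document.

    Persists the model specs (JSON) and the fitted peak centers (TXT) into
    ``out_dir``; raises :class:`FitNotConverged` on optimiser failure.  When
    ``specs`` is given, detection is skipped and the fit is re-run exactly.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d = _diffractogram_from_doc(doc, sample_id)
    detected = specs is None
    if detected:
        centers = peakfit.detect_peaks(d, width_range=config.width_range)
        if len(centers) == 0:
            raise FitNotConverged(f"no peaks detected in {sample_id}")
        specs = peakfit.auto_specs(
            centers, d, width_range=config.width_range, kind=config.profile_kind
        )
    result = peakfit.fit(d, specs)
    if not result.success:
        raise FitNotConverged(
            f"fit did not converge for {sample_id}: {result.message}"
        )
    if detected:
        # prune noise pickups of the permissive CWT search
        dq = float(np.median(np.diff(d.q)))
        result = peakfit.filter_significant(
            result, min_fwhm=config.width_range[0] * dq
        )
        if not result.peaks:
            raise FitNotConverged(f"no significant peaks in {sample_id}")
    peakfit.save_specs(result.specs_used, out_dir / f"{sample_id}.models_dict.json")
    peakfit.save_peak_centers(result, out_dir / f"{sample_id}.peak_centers.txt")
    peakfit.save_fit_result(result, out_dir / f"{sample_id}.fit_result.json")
    return result


def _calibration_from_config(
    config: RunConfig, measured_q: Sequence[float] | None = None
) -> llc.Calibration:
    if config.standard is None and config.literature_q is None:
        return llc.Calibration(slope=1.0, intercept=0.0)
    if config.literature_q is not None:
        std = llc.ScatteringStandard(
            name="user", literature_q=np.asarray(config.literature_q)
        )
    else:
        std = llc.load_standard(config.standard)
    if measured_q is None:
        raise ValueError("calibration requires measured standard peaks")
    return llc.prepare_standard(measured_q, std)


def analyze(
    doc: AnIMLDocument,
    sample_id: str,
    peak_centers: Sequence[float],
    out_dir: str | Path,
    config: RunConfig | None = None,
    calibration: llc.Calibration | None = None,
) -> llc.LLCPhaseResult:
    """Calibrate peak centers, assign the LLC phase and compute the lattice
    parameter; append results to the document and export a TSV report.

    The analysis category carries q_corrected, d_measured and d_ratio per
    reflection plus the phase and lattice parameter.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cal = calibration or llc.Calibration(slope=1.0, intercept=0.0)
    q_corrected = np.sort(llc.calibrate(np.asarray(peak_centers, float), cal))
    d_spacings = np.sort(llc.d_from_q(q_corrected))[::-1]
    result = llc.assign_phase(d_spacings, tolerance=config.tolerance)
    if result.is_determinate:
        llc.lattice_parameter(result)

    category = Category(name=f"analysis {sample_id}")
    for i, (qc, dm, dr) in enumerate(
        zip(q_corrected, d_spacings, result.d_ratios), start=1
    ):
        sub = Category(name=f"reflection {i}")
        sub.add_parameter(Parameter(name="q_corrected", value=float(qc), unit=Q_UNIT))
        sub.add_parameter(Parameter(name="d_measured", value=float(dm), unit=NM_UNIT))
        sub.add_parameter(Parameter(name="d_ratio", value=float(dr)))
        if result.indices:
            sub.add_parameter(
                Parameter(name="miller_index", value=str(result.indices[i - 1]))
            )
        category.subcategories.append(sub)
    category.add_parameter(Parameter(name="phase", value=result.phase))
    if result.space_group:
        category.add_parameter(
            Parameter(name="space_group", value=result.space_group)
        )
    if result.a is not None:
        category.add_parameter(
            Parameter(name="lattice_parameter", value=float(result.a), unit=NM_UNIT)
        )
        category.add_parameter(
            Parameter(
                name="lattice_parameter_spread",
                value=float(result.a_spread),
                unit=NM_UNIT,
            )
        )
    category.add_parameter(Parameter(name="calibration_slope", value=float(cal.slope)))
    category.add_parameter(
        Parameter(name="calibration_intercept", value=float(cal.intercept))
    )
    doc.append_analysis_results(
        f"step_{sample_id}", category, strict=config.strict,
        timestamp=config.timestamp,
    )
    llc.export_tsv(result, out_dir / f"{sample_id}.analysis.tsv", q_corrected)
    return result


def package(
    animl_path: str | Path,
    extra_files: Sequence[str | Path],
    out_path: str | Path,
    config: RunConfig | None = None,
) -> Path:
    """Bundle the AnIML master document plus companion files into a COMBINE
    archive (ZIP with manifest.xml and per-file metadata.rdf)."""
    from . import omex

    config = config or RunConfig()
    return omex.create_archive(
        animl_path,
        extra_files,
        out_path,
        creators=config.creators,
        created=config.timestamp or "1970-01-01T00:00:00Z",
    )
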