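"""Seeded generator of mesophase diffractograms with known ground truth.

Emulates background-corrected, line-collimated 1D SAXS curves of lyotropic
liquid-crystal samples: Bragg peak positions follow from the lattice geometry
of the chosen phase, peaks are area-parameterized Lorentzians (optionally
Gaussian/Voigt), the background is a smooth decaying power law
``c0 + c1 * q**(-p)``, and Gaussian noise with variance proportional to the
signal (Poisson-like counting statistics) is added from a mandatory seed so
every curve is exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import peakfit
from .llc import (
    CUBIC_SPACE_GROUPS,
    Phase,
    MillerIndex,
    hexagonal_indices,
    q_from_d,
)
from .readers import Diffractogram, PDHHeader, write_pdh

__all__ = ["GroundTruth", "peak_positions", "generate", "write_fixture_set"]

TWO_PI = 2.0 * np.pi


def peak_positions(
    phase: str, a: float, k: int, space_group: str = "Im3m"
) -> tuple[np.ndarray, list[MillerIndex]]:
    """First ``k`` allowed Bragg positions (ascending q) for a phase.

    hexagonal:  q_hk  = (4*pi/sqrt(3)) * sqrt(h^2+hk+k^2) / a
    lamellar:   q_n   = 2*pi*n / a
    cubic:      q_hkl = (2*pi/a) * sqrt(h^2+k^2+l^2) over the space group's
                allowed reflection list

    Returns the positions and the Miller indices they belong to.
    """
    if a <= 0:
        raise ValueError("lattice parameter must be positive")
    if k < 1:
        raise ValueError("need k >= 1 reflections")
    if phase == Phase.HEXAGONAL:
        indices = hexagonal_indices(k)
        q = (2.0 * TWO_PI / np.sqrt(3.0)) * np.sqrt(
            [m.N for m in indices]
        ) / a
    elif phase == Phase.LAMELLAR:
        indices = [MillerIndex(n, 0, 0) for n in range(1, k + 1)]
        q = TWO_PI * np.arange(1, k + 1, dtype=float) / a
    elif phase == Phase.CUBIC:
        allowed = CUBIC_SPACE_GROUPS[space_group]
        if k > len(allowed):
            raise ValueError(
                f"only {len(allowed)} allowed reflections tabulated "
                f"for {space_group}"
            )
        indices = allowed[:k]
        q = (TWO_PI / a) * np.sqrt([m.N for m in indices])
    else:
        raise ValueError(f"unknown phase token {phase!r}")
    return np.asarray(q, dtype=float), indices


@dataclass
class GroundTruth:
    """Everything needed to regenerate one synthetic diffractogram.

    ``snr`` is the ratio of the first peak's height to the noise standard
    deviation at that height.  ``areas`` defaults to a geometric decay over
    reflections, as higher orders of real mesophase patterns are weaker.
    """

    phase: str
    a: float
    n_reflections: int = 3
    space_group: str = "Im3m"
    kind: str = "lorentzian"
    fwhm: float = 0.08
    areas: list[float] = field(default_factory=list)
    baseline_c0: float = 1.0
    baseline_c1: float = 0.5
    baseline_p: float = 2.0
    snr: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.areas:
            self.areas = [5.0 * 0.5**i for i in range(self.n_reflections)]
        if len(self.areas) != self.n_reflections:
            raise ValueError("one peak area required per reflection")

    def positions(self) -> tuple[np.ndarray, list[MillerIndex]]:
        return peak_positions(
            self.phase, self.a, self.n_reflections, self.space_group
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


def default_grid(gt: GroundTruth, n_points: int = 2000) -> np.ndarray:
    """A q grid comfortably covering all of the ground truth's peaks."""
    q_peaks, _ = gt.positions()
    lo = max(0.05, 0.4 * q_peaks[0])
    hi = 1.15 * q_peaks[-1] + 5 * gt.fwhm
    return np.linspace(lo, hi, n_points)


def generate(gt: GroundTruth, q_grid: np.ndarray | None = None) -> Diffractogram:
    """Render the ground truth onto a q grid.

    Deterministic for a fixed seed.  Raises if the grid does not cover every
    peak position.
    """
    if q_grid is None:
        q_grid = default_grid(gt)
    q_grid = np.asarray(q_grid, dtype=float)
    q_peaks, _ = gt.positions()
    uncovered = [
        float(qp) for qp in q_peaks if not q_grid[0] <= qp <= q_grid[-1]
    ]
    if uncovered:
        raise ValueError(
            f"q grid [{q_grid[0]:.3f}, {q_grid[-1]:.3f}] does not cover "
            f"peak positions {uncovered}"
        )
    intensity = gt.baseline_c0 + gt.baseline_c1 * q_grid ** (-gt.baseline_p)
    height0 = None
    for qc, area in zip(q_peaks, gt.areas):
        if gt.kind == "lorentzian":
            intensity += (
                peakfit.lorentzian(q_grid, 0.0, area, qc, gt.fwhm)
            )
            height = 2.0 * area / (np.pi * gt.fwhm)
        elif gt.kind == "gaussian":
            sigma = gt.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            intensity += peakfit.gaussian(q_grid, 0.0, area, qc, sigma)
            height = area / (sigma * np.sqrt(2.0 * np.pi))
        elif gt.kind == "voigt":
            sigma = gt.fwhm / 3.6013  # approximate equal-width split
            gamma = gt.fwhm / 3.6013
            intensity += peakfit.voigt(q_grid, 0.0, area, qc, sigma, gamma)
            height = float(peakfit.voigt(np.array([qc]), 0.0, area, qc, sigma, gamma)[0])
        else:
            raise ValueError(f"unknown peak kind {gt.kind!r}")
        if height0 is None:
            height0 = height
    if gt.snr > 0:
        rng = np.random.default_rng(gt.seed)
        # sigma proportional to sqrt(signal), scaled so the first peak's
        # height-to-noise ratio equals snr
        scale = height0 / (gt.snr * np.sqrt(height0))
        noise = rng.standard_normal(len(q_grid)) * scale * np.sqrt(
            np.clip(intensity, 0.0, None)
        )
        intensity = intensity + noise
    label = f"synthetic {gt.phase} a={gt.a} seed={gt.seed}"
    return Diffractogram(q=q_grid, intensity=intensity, label=label)


def write_fixture_set(
    directory: str | Path,
    seeds: Sequence[int],
    phases: Sequence[str] = (Phase.HEXAGONAL, Phase.CUBIC, Phase.LAMELLAR),
) -> Path:
    """Write one PDH file per (phase, seed) plus a JSON ground-truth manifest.

    Returns the manifest path.  Re-running with the same seeds reproduces
    identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    defaults = {
        Phase.HEXAGONAL: {"a": 2.87, "n_reflections": 3},
        Phase.CUBIC: {"a": 2.17, "n_reflections": 5},
        Phase.LAMELLAR: {"a": 2.28, "n_reflections": 2},
    }
    manifest = []
    for phase in phases:
        for seed in seeds:
            gt = GroundTruth(phase=phase, seed=int(seed), **defaults[phase])
            d = generate(gt)
            name = f"{phase.lower()}_seed{seed}.pdh"
            write_pdh(d, PDHHeader(description=d.label), directory / name)
            manifest.append({"file": name, "ground_truth": gt.to_dict()})
    manifest_path = directory / "ground_truth_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest_path
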