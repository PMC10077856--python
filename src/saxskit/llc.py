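"""Lyotropic liquid-crystal analysis of Bragg peak positions.

Given calibrated peak centers q_c of a 1D SAXS diffractogram, lattice-plane
distances follow from d = 2*pi/q_c, and the ratios d_1/d_i identify the
mesophase:

* lamellar (L_alpha): ratios 1 : 2 : 3 : ...
* 2D hexagonal (H1): ratios 1 : sqrt(3) : sqrt(4) : sqrt(7) : ... , i.e.
  sqrt(h^2 + h k + k^2) of the allowed (h k) reflections
* bicontinuous cubic (V1): sqrt(N_i / N_1) with N = h^2 + k^2 + l^2 running
  over the allowed reflections of a cubic space group

On success the lattice parameter is computed per reflection —

    hexagonal:  a = d_hk * (2/sqrt(3)) * sqrt(h^2 + h k + k^2)
    cubic:      a = d_hkl * sqrt(h^2 + k^2 + l^2)
    lamellar:   a = d_1 (the layer spacing)

— and reported together with its spread over reflections.  Measured q values
are first corrected against a scattering standard via a linear regression of
measured versus literature-known positions.

Matching rules (documented design choices): lamellar and hexagonal patterns
must match contiguously from the first allowed reflection; cubic matching may
skip allowed reflections (weak orders are often unobserved).  Ties between
cubic space groups are broken by RMS ratio deviation, then by the number of
skipped allowed reflections.  Fewer than two peaks — or no pattern within
tolerance — yields the indeterminate phase, which is a value, not an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Phase",
    "MillerIndex",
    "ScatteringStandard",
    "Calibration",
    "LLCPhaseResult",
    "q_from_d",
    "d_from_q",
    "load_standard",
    "prepare_standard",
    "calibrate",
    "compute_ratios",
    "assign_phase",
    "lattice_parameter",
    "mass_fraction",
    "export_tsv",
    "CUBIC_SPACE_GROUPS",
    "hexagonal_indices",
]

TWO_PI = 2.0 * np.pi


class Phase:
    """Phase identity tokens."""

    HEXAGONAL = "H1"
    CUBIC = "V1"
    LAMELLAR = "La"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class MillerIndex:
    """Miller indices of a lattice plane; ``l`` is None for 2D hexagonal
    indexing and for lamellar orders (where ``h`` is the order n)."""

    h: int
    k: int = 0
    l: int | None = None  # noqa: E741

    def __post_init__(self) -> None:
        if self.h == 0 and self.k == 0 and not self.l:
            raise ValueError("Miller indices cannot all be zero")

    @property
    def N(self) -> int:
        """h^2+hk+k^2 for 2D hexagonal, h^2+k^2+l^2 for cubic, n for lamellar."""
        if self.l is None:
            return self.h**2 + self.h * self.k + self.k**2
        return self.h**2 + self.k**2 + self.l**2

    def __str__(self) -> str:
        if self.l is None:
            return f"{self.h}{self.k}"
        return f"{self.h}{self.k}{self.l}"


# --- allowed reflections ----------------------------------------------------

def hexagonal_indices(k: int) -> list[MillerIndex]:
    """First ``k`` allowed (h k) reflections of the 2D hexagonal lattice,
    ordered by h^2 + h k + k^2 (i.e. 10, 11, 20, 21, 30, ...)."""
    seen: dict[int, MillerIndex] = {}
    for h in range(0, 12):
        for kk in range(0, h + 1):
            if h == 0 and kk == 0:
                continue
            n = h * h + h * kk + kk * kk
            if n not in seen:
                seen[n] = MillerIndex(h, kk)
    ordered = [seen[n] for n in sorted(seen)]
    return ordered[:k]


def _bcc_indices(max_n: int) -> list[MillerIndex]:
    """Allowed reflections of a body-centred cubic lattice (h+k+l even),
    one representative per N = h^2+k^2+l^2, ascending.  Where several index
    triples share an N (e.g. 611 and 532), the largest-h one is used, which
    matches the labels conventional in mesophase work."""
    seen: dict[int, MillerIndex] = {}
    for h in range(8, 0, -1):
        for k in range(0, h + 1):
            for l in range(0, k + 1):  # noqa: E741
                if (h + k + l) % 2 != 0:
                    continue
                n = h * h + k * k + l * l
                if n <= max_n and n not in seen:
                    seen[n] = MillerIndex(h, k, l)
    return [seen[n] for n in sorted(seen)]


# Allowed N = h^2+k^2+l^2 sequences for the bicontinuous-cubic space groups
# commonly met in lyotropic systems, with one representative index per N.
CUBIC_SPACE_GROUPS: dict[str, list[MillerIndex]] = {
    # Ia-3d (gyroid): 211, 220, 321, 400, 420, 332, 422, 431, ...
    "Ia3d": [
        MillerIndex(*hkl)
        for hkl in [
            (2, 1, 1), (2, 2, 0), (3, 2, 1), (4, 0, 0), (4, 2, 0),
            (3, 3, 2), (4, 2, 2), (4, 3, 1), (5, 2, 1), (4, 4, 0),
            (6, 1, 1), (6, 2, 0), (5, 4, 1), (6, 3, 1), (4, 4, 4),
        ]
    ],
    # Pn-3m (diamond): 110, 111, 200, 211, 220, 221, 310, 311, 222, ...
    "Pn3m": [
        MillerIndex(*hkl)
        for hkl in [
            (1, 1, 0), (1, 1, 1), (2, 0, 0), (2, 1, 1), (2, 2, 0),
            (2, 2, 1), (3, 1, 0), (3, 1, 1), (2, 2, 2), (3, 2, 1),
            (4, 0, 0), (3, 2, 2), (3, 3, 0), (3, 3, 1), (4, 2, 0),
            (4, 2, 1), (3, 3, 2), (4, 2, 2), (4, 3, 1), (5, 2, 1),
            (4, 4, 0), (5, 3, 0), (6, 0, 0), (6, 1, 1),
        ]
    ],
    # Im-3m (primitive-looking bcc pattern): every even h+k+l
    "Im3m": _bcc_indices(60),
}

# Space groups whose allowed set coincides with the plain body-centred
# parity rule (h+k+l even); when such a group wins only because of parity,
# the result is labelled "body-centred".
_BODY_CENTRED = {"Ia3d", "Im3m"}


# --- basic conversions ------------------------------------------------------

def q_from_d(d):
    """Scattering vector from lattice-plane distance, q = 2*pi/d."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d must be positive")
    return TWO_PI / d


def d_from_q(q):
    """Lattice-plane distance from scattering vector, d = 2*pi/q."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    return TWO_PI / q


def mass_fraction(m_surfactant: float, m_water: float) -> float:
    """Total surfactant mass fraction w = m_s / (m_s + m_w)."""
    if m_surfactant < 0 or m_water < 0:
        raise ValueError("masses must be non-negative")
    total = m_surfactant + m_water
    if total == 0:
        raise ValueError("at least one mass must be positive")
    return m_surfactant / total


# --- calibration ------------------------------------------------------------

@dataclass
class ScatteringStandard:
    """A calibration standard with literature-known reflections.

    Either the scattering vectors (nm^-1) or the lattice-plane distances (nm)
    may be given; the other is derived via q = 2*pi/d.  Reflections are kept
    sorted by q ascending.
    """

    name: str
    literature_q: np.ndarray | None = None
    literature_d: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.literature_q is None and self.literature_d is None:
            raise ValueError("provide literature_q or literature_d")
        if self.literature_q is None:
            self.literature_q = q_from_d(np.asarray(self.literature_d, float))
        self.literature_q = np.sort(np.asarray(self.literature_q, dtype=float))
        if np.any(self.literature_q <= 0):
            raise ValueError("reference scattering vectors must be positive")
        if len(self.literature_q) < 2:
            raise ValueError("a standard needs >= 2 reference reflections")
        self.literature_d = d_from_q(self.literature_q)


def load_standard(name: str, constants_path: str | Path | None = None) -> ScatteringStandard:
    """Load a named standard from the bundled (or a user-supplied) JSON
    constants file.

    The packaged file ships a nominal entry for cholesteryl palmitate, the
    lamellar standard used to calibrate line-collimation SAXS cameras; its
    d-spacings are data, not code, and can be overridden by pointing
    ``constants_path`` at a file of the same layout.
    """
    if constants_path is None:
        text = (
            resources.files("saxskit").joinpath("data/standards.json").read_text()
        )
    else:
        text = Path(constants_path).read_text()
    table = json.loads(text)
    key = name.lower().replace(" ", "_")
    if key not in table:
        raise KeyError(
            f"unknown standard {name!r}; available: {sorted(table)}"
        )
    entry = table[key]
    return ScatteringStandard(
        name=name,
        literature_d=np.asarray(entry["d_nm"], dtype=float)
        if "d_nm" in entry
        else None,
        literature_q=np.asarray(entry["q_nm-1"], dtype=float)
        if "q_nm-1" in entry
        else None,
    )


@dataclass
class Calibration:
    """Result of regressing measured q against literature q:
    measured = slope * literature + intercept."""

    slope: float
    intercept: float
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


def prepare_standard(
    measured_q: Sequence[float], std: ScatteringStandard
) -> Calibration:
    """Ordinary least squares of measured peak positions (dependent) against
    the standard's literature positions (independent), paired in order."""
    measured = np.asarray(measured_q, dtype=float)
    literature = np.asarray(std.literature_q, dtype=float)
    if len(measured) != len(literature):
        raise ValueError(
            f"{len(measured)} measured peaks cannot be paired with "
            f"{len(literature)} reference reflections"
        )
    if np.ptp(literature) == 0:
        raise ValueError("degenerate standard: all reference q equal")
    if len(measured) == 2:
        # exact interpolating line; linregress r-value is ill-defined for n=2
        slope = (measured[1] - measured[0]) / (literature[1] - literature[0])
        intercept = measured[0] - slope * literature[0]
        return Calibration(slope=slope, intercept=intercept, r_squared=1.0)
    res = stats.linregress(literature, measured)
    return Calibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def calibrate(q_measured, cal: Calibration):
    """Correct measured scattering vectors by inverting the fitted map:
    q_corrected = (q_measured - intercept) / slope."""
    q_measured = np.asarray(q_measured, dtype=float)
    return (q_measured - cal.intercept) / cal.slope


# --- phase assignment -------------------------------------------------------

def compute_ratios(d_spacings) -> np.ndarray:
    """Ratios r_i = d_1/d_i of descending-sorted lattice-plane distances."""
    d = np.asarray(d_spacings, dtype=float)
    if len(d) < 1 or np.any(d <= 0):
        raise ValueError("d_spacings must be positive and non-empty")
    if np.any(np.diff(d) > 0):
        raise ValueError("d_spacings must be sorted descending")
    return d[0] / d


@dataclass
class LLCPhaseResult:
    """Outcome of the ratio-based phase assignment."""

    phase: str
    d_spacings: np.ndarray
    d_ratios: np.ndarray
    indices: list[MillerIndex] = field(default_factory=list)
    space_group: str | None = None
    centering: str | None = None
    rms_deviation: float | None = None
    a: float | None = None
    a_per_reflection: np.ndarray | None = None
    a_spread: float | None = None

    @property
    def is_determinate(self) -> bool:
        return self.phase != Phase.INDETERMINATE


def _match_contiguous(
    ratios: np.ndarray, expected: np.ndarray, tolerance: float
) -> float | None:
    """Relative-deviation RMS if every observed ratio matches the expected
    pattern position-by-position within tolerance, else None."""
    if len(expected) < len(ratios):
        return None
    dev = (ratios - expected[: len(ratios)]) / expected[: len(ratios)]
    if np.all(np.abs(dev) <= tolerance):
        return float(np.sqrt(np.mean(dev**2)))
    return None


def _match_cubic_group(
    ratios: np.ndarray,
    allowed: list[MillerIndex],
    tolerance: float,
    max_first: int = 12,
) -> tuple[float, int, list[MillerIndex]] | None:
    """Best (rms, n_skipped, indices) assignment of observed ratios to a
    space group's allowed reflections, permitting skipped weak orders."""
    ns = np.array([m.N for m in allowed], dtype=float)
    best: tuple[float, int, list[MillerIndex]] | None = None
    for i0 in range(min(max_first, len(allowed))):
        n1 = ns[i0]
        assigned = [allowed[i0]]
        prev = i0
        ok = True
        devs = [0.0]
        for r in ratios[1:]:
            target = n1 * r * r
            # nearest allowed N strictly after the previous assignment
            rest = ns[prev + 1 :]
            if rest.size == 0:
                ok = False
                break
            j = int(np.argmin(np.abs(np.sqrt(rest / n1) - r)))
            cand = prev + 1 + j
            dev = (np.sqrt(ns[cand] / n1) - r) / r
            if abs(dev) > tolerance:
                ok = False
                break
            assigned.append(allowed[cand])
            devs.append(float(dev))
            prev = cand
        if not ok:
            continue
        rms = float(np.sqrt(np.mean(np.asarray(devs) ** 2)))
        skipped = (prev - i0 + 1 + i0) - len(ratios)  # unused allowed orders
        if best is None or (rms, skipped) < (best[0], best[1]):
            best = (rms, skipped, assigned)
    return best


def assign_phase(
    d_spacings, tolerance: float = 0.02, min_cubic_peaks: int = 3
) -> LLCPhaseResult:
    """Assign the lyotropic mesophase from lattice-plane distance ratios.

    Parameters
    ----------
    d_spacings : array-like
        Lattice-plane distances in nm, sorted descending.
    tolerance : float
        Maximum relative deviation per ratio, in (0, 0.1].
    min_cubic_peaks : int
        Minimum observed reflections for a cubic assignment (three or more;
        sparser patterns cannot discriminate cubic space groups).

    Returns the indeterminate phase for fewer than two peaks or when no
    candidate pattern matches within tolerance.
    """
    if not 0 < tolerance <= 0.1:
        raise ValueError("tolerance must be in (0, 0.1]")
    d = np.asarray(d_spacings, dtype=float)
    if d.size < 2:
        return LLCPhaseResult(
            phase=Phase.INDETERMINATE,
            d_spacings=d,
            d_ratios=compute_ratios(d) if d.size else np.array([]),
        )
    ratios = compute_ratios(d)

    # lamellar: 1, 2, 3, ... (contiguous orders)
    lam_expected = np.arange(1, len(ratios) + 1, dtype=float)
    rms = _match_contiguous(ratios, lam_expected, tolerance)
    if rms is not None:
        return LLCPhaseResult(
            phase=Phase.LAMELLAR,
            d_spacings=d,
            d_ratios=ratios,
            indices=[MillerIndex(n, 0, 0) for n in range(1, len(ratios) + 1)],
            rms_deviation=rms,
        )

    # hexagonal: sqrt(1), sqrt(3), sqrt(4), sqrt(7), ... (contiguous)
    hex_idx = hexagonal_indices(len(ratios))
    hex_expected = np.sqrt([m.N for m in hex_idx])
    rms = _match_contiguous(ratios, hex_expected, tolerance)
    if rms is not None:
        return LLCPhaseResult(
            phase=Phase.HEXAGONAL,
            d_spacings=d,
            d_ratios=ratios,
            indices=hex_idx,
            rms_deviation=rms,
        )

    # cubic: sqrt(N_i/N_1) over each space group's allowed list, skips allowed
    if d.size >= min_cubic_peaks:
        scored: list[tuple[float, int, str, list[MillerIndex]]] = []
        for group, allowed in CUBIC_SPACE_GROUPS.items():
            hit = _match_cubic_group(ratios, allowed, tolerance)
            if hit is not None:
                scored.append((hit[0], hit[1], group, hit[2]))
        if scored:
            scored.sort(key=lambda t: (t[0], t[1], t[2]))
            rms_dev, _, group, assigned = scored[0]
            return LLCPhaseResult(
                phase=Phase.CUBIC,
                d_spacings=d,
                d_ratios=ratios,
                indices=assigned,
                space_group=group,
                centering="body-centred" if group in _BODY_CENTRED else None,
                rms_deviation=rms_dev,
            )

    return LLCPhaseResult(
        phase=Phase.INDETERMINATE, d_spacings=d, d_ratios=ratios
    )


def lattice_parameter(result: LLCPhaseResult) -> float:
    """Lattice parameter from assigned indices and d-spacings.

    Fills ``result.a`` (hexagonal/cubic: arithmetic mean over reflections;
    lamellar: the first-order layer spacing), ``result.a_per_reflection``
    and ``result.a_spread`` (max - min), and returns ``result.a``.
    """
    if not result.is_determinate:
        raise ValueError("cannot compute a lattice parameter: phase is indeterminate")
    if not result.indices:
        raise ValueError("phase result has no assigned Miller indices")
    d = result.d_spacings
    n = np.array([m.N for m in result.indices], dtype=float)
    if result.phase == Phase.HEXAGONAL:
        per = d * (2.0 / np.sqrt(3.0)) * np.sqrt(n)
        a = float(np.mean(per))
    elif result.phase == Phase.CUBIC:
        per = d * np.sqrt(n)
        a = float(np.mean(per))
    elif result.phase == Phase.LAMELLAR:
        per = d * np.array([m.h for m in result.indices], dtype=float)
        a = float(per[0])
    else:  # pragma: no cover
        raise ValueError(f"unknown phase {result.phase!r}")
    result.a_per_reflection = per
    result.a_spread = float(np.max(per) - np.min(per))
    result.a = a
    return a


# --- reporting --------------------------------------------------------------

def export_tsv(
    result: LLCPhaseResult,
    path: str | Path,
    q_corrected=None,
) -> Path:
    """Write the analysis outcome as a TSV table, one row per reflection
    (q_corrected, d_measured, d_ratio, hkl, a per reflection) preceded by
    ``#``-commented phase / space-group / lattice-parameter lines."""
    d = result.d_spacings
    table = pd.DataFrame(
        {
            "q_corrected": q_from_d(d) if q_corrected is None else np.asarray(q_corrected),
            "d_measured": d,
            "d_ratio": result.d_ratios,
            "hkl": [str(m) for m in result.indices]
            if result.indices
            else [""] * len(d),
            "a_nm": result.a_per_reflection
            if result.a_per_reflection is not None
            else [np.nan] * len(d),
        }
    )
    header = [f"# phase\t{result.phase}"]
    if result.space_group:
        header.append(f"# space_group\t{result.space_group}")
    if result.centering:
        header.append(f"# centering\t{result.centering}")
    if result.a is not None:
        header.append(f"# lattice_parameter_nm\t{result.a:.6f}")
        header.append(f"# lattice_parameter_spread_nm\t{result.a_spread:.6f}")
    path = Path(path)
    path.write_text(
        "\n".join(header) + "\n" + table.to_csv(sep="\t", index=False)
    )
    return path
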