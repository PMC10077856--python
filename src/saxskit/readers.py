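"""Acquisition of raw SAXS data and external peak-fit tables.

PDH ("Primary Data Handling") is the ASCII format written by Anton Paar
SAXSess-type line-collimation instruments: a short fixed header, two or three
columns of scattering vector / intensity data and, optionally, a trailing XML
metadata block.  This module parses and writes that dialect losslessly, lists
PDH files in a directory, parses peak-fit tables exported from external
fitting software, and infers the value tag used when scalars are written to
AnIML documents.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Diffractogram",
    "PDHHeader",
    "PDHFormatError",
    "read_pdh",
    "write_pdh",
    "enumerate_pdh",
    "read_external_fit_table",
    "read_center_list",
    "infer_value_tag",
]


class PDHFormatError(ValueError):
    """Raised when a PDH file does not follow the expected layout."""


@dataclass
class Diffractogram:
    """A 1D scattering curve: intensity versus scattering vector magnitude.

    Parameters
    ----------
    q : array-like
        Scattering vector magnitudes in nm^-1, monotonically non-decreasing.
    intensity : array-like
        Intensities in arbitrary units, same length as ``q``.
    sigma_I : array-like, optional
        Per-point intensity uncertainties.
    label : str
        Free-text sample description.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma_I: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma_I is not None:
            self.sigma_I = np.asarray(self.sigma_I, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.q.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("q and intensity must be one-dimensional")
        if len(self.q) != len(self.intensity):
            raise ValueError(
                f"length mismatch: {len(self.q)} q values vs "
                f"{len(self.intensity)} intensities"
            )
        if self.sigma_I is not None and len(self.sigma_I) != len(self.q):
            raise ValueError("sigma_I must match the data length")
        for name, arr in (("q", self.q), ("intensity", self.intensity)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if self.sigma_I is not None and not np.all(np.isfinite(self.sigma_I)):
            raise ValueError("non-finite values in sigma_I")
        if np.any(np.diff(self.q) < 0):
            raise ValueError("q must be monotonically non-decreasing")

    def __len__(self) -> int:
        return len(self.q)

    def to_frame(self) -> pd.DataFrame:
        """Return the curve as a DataFrame with columns q, intensity[, sigma_I]."""
        data = {"q": self.q, "intensity": self.intensity}
        if self.sigma_I is not None:
            data["sigma_I"] = self.sigma_I
        return pd.DataFrame(data)


@dataclass
class PDHHeader:
    """The fixed five-line PDH header plus any trailing XML metadata.

    The eight header integers and ten header reals are preserved verbatim;
    only the first integer (the declared point count) is interpreted.
    """

    description: str = ""
    keyword_line: str = "SAXS"
    int_block: list[int] = field(default_factory=lambda: [0] * 8)
    real_blocks: list[float] = field(default_factory=lambda: [0.0] * 10)
    extra_xml: str | None = None

    def __post_init__(self) -> None:
        if len(self.int_block) != 8:
            raise ValueError("int_block must have exactly 8 entries")
        if len(self.real_blocks) != 10:
            raise ValueError("real_blocks must have exactly 10 entries")

    @property
    def point_count(self) -> int:
        return int(self.int_block[0])


def read_pdh(path: str | Path) -> tuple[Diffractogram, PDHHeader]:
    """Parse a PDH file into its data columns and header.

    Layout: line 1 free-text description, line 2 keywords, line 3 eight
    integers (first is the point count), lines 4-5 five reals each, then the
    declared number of data rows (2 or 3 whitespace-separated columns), then
    an optional XML metadata block running to end of file (captured verbatim).

    Raises
    ------
    PDHFormatError
        If the header is short, a data row is non-numeric, or fewer rows than
        declared are present.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if len(lines) < 5:
        raise PDHFormatError(
            f"{path}: header requires 5 lines, file has {len(lines)}"
        )
    description = lines[0].rstrip()
    keyword_line = lines[1].rstrip()
    try:
        int_block = [int(tok) for tok in lines[2].split()]
    except ValueError as exc:
        raise PDHFormatError(f"{path}: line 3 is not an integer block: {exc}")
    if len(int_block) != 8:
        raise PDHFormatError(
            f"{path}: line 3 must hold 8 integers, found {len(int_block)}"
        )
    try:
        reals = [float(tok) for tok in (lines[3].split() + lines[4].split())]
    except ValueError as exc:
        raise PDHFormatError(f"{path}: lines 4-5 are not real blocks: {exc}")
    if len(reals) != 10:
        raise PDHFormatError(
            f"{path}: lines 4-5 must hold 10 reals, found {len(reals)}"
        )

    count = int_block[0]
    if count < 1:
        raise PDHFormatError(f"{path}: declared point count {count} < 1")
    data_rows: list[list[float]] = []
    row_idx = 5
    for row_idx in range(5, 5 + count):
        if row_idx >= len(lines):
            raise PDHFormatError(
                f"{path}: declared {count} data rows but file ends at "
                f"line {len(lines)} (row {row_idx - 4} missing)"
            )
        tokens = lines[row_idx].split()
        if len(tokens) not in (2, 3):
            raise PDHFormatError(
                f"{path}: data row {row_idx - 4} has {len(tokens)} columns "
                "(expected 2 or 3)"
            )
        try:
            data_rows.append([float(tok) for tok in tokens])
        except ValueError:
            raise PDHFormatError(
                f"{path}: non-numeric value in data row {row_idx - 4}: "
                f"{lines[row_idx]!r}"
            )
    ncols = len(data_rows[0])
    if any(len(row) != ncols for row in data_rows):
        raise PDHFormatError(f"{path}: inconsistent column count in data rows")

    trailer = "\n".join(lines[5 + count:]).strip()
    extra_xml = trailer if trailer else None

    arr = np.array(data_rows, dtype=float)
    diffractogram = Diffractogram(
        q=arr[:, 0],
        intensity=arr[:, 1],
        sigma_I=arr[:, 2] if ncols == 3 else None,
        label=description,
    )
    header = PDHHeader(
        description=description,
        keyword_line=keyword_line,
        int_block=int_block,
        real_blocks=reals,
        extra_xml=extra_xml,
    )
    return diffractogram, header


def write_pdh(
    d: Diffractogram, header: PDHHeader | None = None, path: str | Path = "out.pdh"
) -> Path:
    """Write a diffractogram (plus optional header) as a PDH file.

    The declared point count in the header is overwritten with the actual
    data length so the file always round-trips through :func:`read_pdh`.
    Values are written with 9 significant digits.
    """
    d.validate()
    if header is None:
        header = PDHHeader(description=d.label)
    int_block = list(header.int_block)
    int_block[0] = len(d)
    lines = [
        header.description,
        header.keyword_line,
        " ".join(f"{v:9d}" for v in int_block),
        " ".join(f"{v:14.6E}" for v in header.real_blocks[:5]),
        " ".join(f"{v:14.6E}" for v in header.real_blocks[5:]),
    ]
    for i in range(len(d)):
        row = f"{d.q[i]:.9E} {d.intensity[i]:.9E}"
        if d.sigma_I is not None:
            row += f" {d.sigma_I[i]:.9E}"
        lines.append(row)
    if header.extra_xml:
        lines.append(header.extra_xml)
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def enumerate_pdh(directory: str | Path, recursive: bool = False) -> list[Path]:
    """List PDH files (case-insensitive extension), lexicographically sorted.

    Only the top level is searched unless ``recursive`` is set.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise NotADirectoryError(f"not a directory: {directory}")
    it = directory.rglob("*") if recursive else directory.iterdir()
    return sorted(
        p for p in it if p.is_file() and p.suffix.lower() == ".pdh"
    )


# Recognized header spellings for external fit-table columns.  The canonical
# per-peak quantities are the constant offset I0, the peak center qc, the full
# width at half maximum and the integrated area A.
_COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "peak": ("peak", "index", "peak_index", "no", "n", "model"),
    "I0": ("i0", "y0", "offset", "baseline"),
    "qc": ("qc", "xc", "center", "centre", "q_c", "x_c", "position"),
    "fwhm": ("fwhm", "w", "width"),
    "area": ("area", "a", "amplitude"),
}


def _map_columns(headers: Sequence[str]) -> dict[str, int]:
    mapping: dict[str, int] = {}
    normalized = [re.sub(r"[^a-z0-9_]", "", h.lower()) for h in headers]
    for canonical, names in _COLUMN_SYNONYMS.items():
        for i, h in enumerate(normalized):
            if h in names and canonical not in mapping:
                mapping[canonical] = i
                break
    missing = [c for c in ("I0", "qc", "fwhm", "area") if c not in mapping]
    if missing:
        raise ValueError(
            f"cannot map columns {missing}; recognized header names: "
            + "; ".join(
                f"{k}: {', '.join(v)}" for k, v in _COLUMN_SYNONYMS.items()
            )
        )
    return mapping


def read_external_fit_table(path: str | Path) -> pd.DataFrame:
    """Parse a peak-fit table exported from external fitting software.

    Expects whitespace- or tab-delimited text with one header row; columns
    are mapped to (peak, I0, qc, fwhm, area) by header-name matching against
    a synonym list.  Returns a DataFrame with those canonical column names.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty fit table")
    headers = lines[0].split("\t") if "\t" in lines[0] else lines[0].split()
    mapping = _map_columns(headers)
    rows = []
    for i, ln in enumerate(lines[1:], start=1):
        tokens = ln.split("\t") if "\t" in ln else ln.split()
        try:
            rows.append(
                {
                    "peak": int(float(tokens[mapping["peak"]]))
                    if "peak" in mapping
                    else i,
                    "I0": float(tokens[mapping["I0"]]),
                    "qc": float(tokens[mapping["qc"]]),
                    "fwhm": float(tokens[mapping["fwhm"]]),
                    "area": float(tokens[mapping["area"]]),
                }
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: cannot parse data row {i}: {exc}")
    table = pd.DataFrame(rows, columns=["peak", "I0", "qc", "fwhm", "area"])
    if (table["qc"] <= 0).any():
        raise ValueError(f"{path}: peak centers must be positive")
    if (table["fwhm"] <= 0).any():
        raise ValueError(f"{path}: FWHM values must be positive")
    return table


def read_center_list(path: str | Path) -> np.ndarray:
    """Read a plain one-number-per-line peak-center list (TXT)."""
    values = [
        float(ln) for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    return np.asarray(values, dtype=float)


def infer_value_tag(value: object) -> str:
    """Infer the AnIML value tag for a Python scalar.

    Booleans map to ``Boolean``, integers to ``I``, reals to ``F`` and text
    to ``S``.  Any other kind is rejected.
    """
    if isinstance(value, (bool, np.bool_)):
        return "Boolean"
    if isinstance(value, (int, np.integer)):
        return "I"
    if isinstance(value, (float, np.floating)):
        return "F"
    if isinstance(value, str):
        return "S"
    raise TypeError(f"unsupported scalar kind: {type(value).__name__}")
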