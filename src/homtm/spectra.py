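"""Deconvoluted-spectrum containers, parsers and fragment-mass matching.

Spectra are consumed *after* spectral deconvolution: each peak is a neutral
monoisotopic fragment mass with an intensity (charge states and isotope
envelopes already collapsed by upstream tools such as MS-Deconv).  Two text
dialects are supported: the msalign block format emitted by deconvolution
tools, and a single-spectrum TSV.

Theoretical prefix/suffix residue masses are matched to experimental peaks
after adding the fragment-ion-type offset (e.g. +H2O for y ions), within a
symmetric ppm window computed against the theoretical mass.  The raw
intensity of a prefix residue mass pools the intensities of peaks matching
either the mass itself (N-terminal series) or its complementary suffix mass
(C-terminal series).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .masses import WATER_MONO

__all__ = [
    "DeconvPeak",
    "DeconvSpectrum",
    "IonTypeScheme",
    "BY_SCHEME",
    "CZ_SCHEME",
    "scheme_for_activation",
    "read_msalign",
    "write_msalign",
    "read_tsv",
    "write_tsv",
    "ppm_match",
    "raw_intensity",
    "relative_intensities",
]


@dataclass(frozen=True)
class DeconvPeak:
    neutral_mass: float
    intensity: float
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError("peak neutral mass must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be nonnegative")


@dataclass
class DeconvSpectrum:
    """A deconvoluted MS/MS spectrum: precursor neutral mass + peak list.

    Peaks are sorted by mass on construction.
    """

    spectrum_id: str
    precursor_neutral_mass: float
    peaks: list[DeconvPeak]
    activation: str = "CID"

    def __post_init__(self) -> None:
        if self.precursor_neutral_mass <= 0:
            raise ValueError(
                f"spectrum {self.spectrum_id!r}: precursor mass must be positive"
            )
        self.peaks = sorted(self.peaks, key=lambda p: p.neutral_mass)
        self._masses = np.array([p.neutral_mass for p in self.peaks])
        self._intensities = np.array([p.intensity for p in self.peaks])

    @property
    def masses(self) -> np.ndarray:
        return self._masses

    @property
    def intensities(self) -> np.ndarray:
        return self._intensities

    def total_intensity(self) -> float:
        return float(self._intensities.sum())

    def match_window(self, theoretical: float, tol_ppm: float) -> slice:
        """Index slice of peaks within ``tol_ppm`` of a theoretical mass."""
        half = tol_ppm * 1e-6 * theoretical
        lo = bisect.bisect_left(self._masses, theoretical - half)
        hi = bisect.bisect_right(self._masses, theoretical + half)
        return slice(lo, hi)


@dataclass(frozen=True)
class IonTypeScheme:
    """One N-terminal and one C-terminal fragment ion type.

    Offsets are the neutral-mass shifts added to theoretical prefix/suffix
    residue masses before matching experimental fragment masses.
    """

    n_term_label: str
    n_term_offset: float
    c_term_label: str
    c_term_offset: float

    @property
    def name(self) -> str:
        return f"{self.n_term_label}/{self.c_term_label}"


#: b/y ions (CID, HCD): b neutral = prefix residue mass; y = suffix + H2O.
BY_SCHEME = IonTypeScheme("b", 0.0, "y", WATER_MONO)

#: c/z-dot ions (ETD): c = prefix + NH3; z-dot = suffix + (OH - NH2 + NH).
CZ_SCHEME = IonTypeScheme("c", 17.026549, "z", 1.991840)

_ACTIVATION_SCHEMES = {"CID": BY_SCHEME, "HCD": BY_SCHEME, "ETD": CZ_SCHEME}


def scheme_for_activation(activation: str) -> IonTypeScheme:
    try:
        return _ACTIVATION_SCHEMES[activation.upper()]
    except KeyError:
        raise ValueError(f"unknown activation type: {activation!r}") from None


# --------------------------------------------------------------------------
# Parsers
# --------------------------------------------------------------------------


def read_msalign(path: str | Path) -> list[DeconvSpectrum]:
    """Read an msalign-dialect file (BEGIN IONS / END IONS blocks).

    Header lines are ``KEY=VALUE``; recognised keys are ``ID``,
    ``PRECURSOR_MASS`` and ``ACTIVATION`` (others are ignored).  Peak lines
    are ``mass<TAB>intensity[<TAB>charge]``.
    """
    spectra: list[DeconvSpectrum] = []
    headers: dict[str, str] = {}
    peaks: list[DeconvPeak] = []
    in_block = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            in_block, headers, peaks = True, {}, []
        elif line == "END IONS":
            sid = headers.get("ID", f"block_at_line_{lineno}")
            if "PRECURSOR_MASS" not in headers:
                raise ValueError(
                    f"{path}: spectrum {sid!r} (ending line {lineno}) "
                    "is missing PRECURSOR_MASS"
                )
            spectra.append(
                DeconvSpectrum(
                    spectrum_id=sid,
                    precursor_neutral_mass=float(headers["PRECURSOR_MASS"]),
                    activation=headers.get("ACTIVATION", "CID"),
                    peaks=peaks,
                )
            )
            in_block = False
        elif in_block:
            if "=" in line and "\t" not in line:
                key, _, val = line.partition("=")
                headers[key.strip()] = val.strip()
            else:
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: malformed peak line {line!r}"
                    )
                try:
                    mass, inten = float(parts[0]), float(parts[1])
                    charge = int(parts[2]) if len(parts) > 2 else None
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric peak line {line!r}"
                    ) from None
                peaks.append(DeconvPeak(mass, inten, charge))
    if in_block:
        raise ValueError(f"{path}: unterminated BEGIN IONS block")
    return spectra


def write_msalign(spectra: Iterable[DeconvSpectrum], path: str | Path) -> None:
    lines: list[str] = []
    for sp in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"ID={sp.spectrum_id}")
        lines.append(f"PRECURSOR_MASS={sp.precursor_neutral_mass!r}")
        lines.append(f"ACTIVATION={sp.activation}")
        for p in sp.peaks:
            cols = [repr(p.neutral_mass), repr(p.intensity)]
            if p.charge is not None:
                cols.append(str(p.charge))
            lines.append("\t".join(cols))
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_tsv(path: str | Path) -> DeconvSpectrum:
    """Read the single-spectrum TSV dialect.

    ``#KEY=VALUE`` comment lines carry metadata (``PRECURSOR_MASS`` required);
    the header line is ``neutral_mass<TAB>intensity[<TAB>charge]``.
    """
    headers: dict[str, str] = {}
    peaks: list[DeconvPeak] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            headers[key.strip()] = val.strip()
            continue
        if line.lower().startswith("neutral_mass"):
            continue
        parts = line.split("\t")
        try:
            mass, inten = float(parts[0]), float(parts[1])
            charge = int(parts[2]) if len(parts) > 2 else None
        except (ValueError, IndexError):
            raise ValueError(f"{path}:{lineno}: malformed peak line {line!r}") from None
        peaks.append(DeconvPeak(mass, inten, charge))
    if "PRECURSOR_MASS" not in headers:
        raise ValueError(f"{path}: missing #PRECURSOR_MASS= header")
    return DeconvSpectrum(
        spectrum_id=headers.get("ID", Path(path).stem),
        precursor_neutral_mass=float(headers["PRECURSOR_MASS"]),
        activation=headers.get("ACTIVATION", "CID"),
        peaks=peaks,
    )


def write_tsv(spectrum: DeconvSpectrum, path: str | Path) -> None:
    lines = [
        f"#ID={spectrum.spectrum_id}",
        f"#PRECURSOR_MASS={spectrum.precursor_neutral_mass!r}",
        f"#ACTIVATION={spectrum.activation}",
        "neutral_mass\tintensity\tcharge",
    ]
    for p in spectrum.peaks:
        charge = "" if p.charge is None else str(p.charge)
        lines.append(f"{p.neutral_mass!r}\t{p.intensity!r}\t{charge}".rstrip("\t"))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Matching
# --------------------------------------------------------------------------


def ppm_match(observed: float, theoretical: float, tol_ppm: float) -> bool:
    """True iff ``|observed - theoretical| <= tol_ppm * 1e-6 * theoretical``."""
    if observed <= 0 or theoretical <= 0:
        raise ValueError("masses must be positive")
    if tol_ppm < 0:
        raise ValueError("tolerance must be nonnegative")
    return abs(observed - theoretical) <= tol_ppm * 1e-6 * theoretical


def raw_intensity(
    m: float,
    spectrum: DeconvSpectrum,
    total_residue_mass: float,
    scheme: IonTypeScheme = BY_SCHEME,
    tol_ppm: float = 15.0,
) -> float:
    """Pooled raw intensity Inte(m) of a prefix residue mass.

    Sums the intensities of peaks matching the N-terminal fragment mass
    ``m + n_term_offset`` and of peaks matching the C-terminal fragment mass
    of the complementary suffix ``(total - m) + c_term_offset``.  A peak
    matching both theoretical masses contributes to both sums.
    """
    if not 0 <= m <= total_residue_mass + 1e-6:
        raise ValueError("prefix mass outside [0, total residue mass]")
    total = 0.0
    for theo in (m + scheme.n_term_offset, (total_residue_mass - m) + scheme.c_term_offset):
        if theo <= 0:
            continue
        sl = spectrum.match_window(theo, tol_ppm)
        total += float(spectrum.intensities[sl].sum())
    return total


def relative_intensities(
    masses: Sequence[float],
    spectrum: DeconvSpectrum,
    total_residue_mass: float,
    scheme: IonTypeScheme = BY_SCHEME,
    tol_ppm: float = 15.0,
) -> list[float]:
    """Raw intensities scaled by the largest one; all-zero stays all-zero."""
    if not masses:
        raise ValueError("need at least one mass")
    raw = [raw_intensity(m, spectrum, total_residue_mass, scheme, tol_ppm) for m in masses]
    top = max(raw)
    if top == 0:
        return [0.0] * len(raw)
    return [r / top for r in raw]
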