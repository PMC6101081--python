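"""Amino-acid and PTM mass arithmetic, proteoform model, prefix-mass enumeration.

A *proteoform* is a base protein sequence decorated with site-localized
post-translational modifications (PTMs) drawn from a user-declared table of
*expected* PTMs.  Co-fragmented proteoforms of the same protein with (near-)
identical molecular masses produce homogeneous multiplexed tandem mass (HomMTM)
spectra; interpreting such a spectrum requires enumerating, for every prefix
length ``i``, the set of distinct prefix residue masses realisable by any
proteoform consistent with the precursor mass.  That enumeration
(:func:`enumerate_prefix_mass_sets`) is the combinatorial backbone of the
layered mass graph built downstream.

Monoisotopic residue masses come from :mod:`pyteomics`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml
from pyteomics import mass as _pmass

__all__ = [
    "WATER_MONO",
    "ISOTOPE_SPACING",
    "STANDARD_RESIDUES",
    "ResidueMassTable",
    "ExpectedPTM",
    "PTMTable",
    "Proteoform",
    "PrefixMassSets",
    "residue_mass",
    "prefix_residue_masses",
    "proteoform_mass",
    "enumerate_prefix_mass_sets",
    "enumerate_proteoforms",
]

#: Monoisotopic mass of a water molecule (Da); added to the residue-mass total
#: to obtain a neutral molecular mass.
WATER_MONO: float = _pmass.calculate_mass(formula="H2O")

#: Conventional isotope spacing (Da) used for +/-1 Da precursor ambiguity
#: introduced by deconvolution picking the wrong monoisotopic peak.
ISOTOPE_SPACING: float = 1.00235

STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Number of decimals used when merging numerically identical cumulative
#: PTM-shift values (1e-5 Da).  Fine enough to keep acetylation (42.01056)
#: and trimethylation (42.04695) apart; coarse enough that equal-sum PTM
#: combinations (e.g. two methylations vs. one dimethylation) collapse.
SHIFT_KEY_DECIMALS: int = 5

ResidueMassTable = dict[str, float]

#: Monoisotopic residue masses for the 20 standard amino acids.
STD_RESIDUE_MASSES: ResidueMassTable = {
    aa: _pmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES
}


def _shift_key(x: float) -> float:
    return round(x, SHIFT_KEY_DECIMALS)


def residue_mass(aa: str) -> float:
    """Monoisotopic residue mass (Da) of a standard amino-acid letter."""
    try:
        return STD_RESIDUE_MASSES[aa]
    except KeyError:
        raise ValueError(f"unknown amino-acid letter: {aa!r}") from None


def _validate_sequence(sequence: str) -> None:
    bad = set(sequence) - set(STANDARD_RESIDUES)
    if bad:
        raise ValueError(
            f"sequence contains non-standard residue letter(s): {sorted(bad)}"
        )


def prefix_residue_masses(sequence: str) -> list[float]:
    """Prefix residue masses ``p_0 .. p_n`` of an unmodified sequence.

    ``p_i`` is the sum of the residue masses of the first ``i`` amino acids;
    ``p_0 = 0``.  Suffix residue masses follow as ``s_i = p_n - p_{n-i}``.
    """
    _validate_sequence(sequence)
    out = [0.0]
    total = 0.0
    for aa in sequence:
        total += STD_RESIDUE_MASSES[aa]
        out.append(total)
    return out


@dataclass(frozen=True)
class ExpectedPTM:
    """An expected PTM: a named monoisotopic mass shift with residue specificity."""

    name: str
    mass_shift: float
    residues: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", frozenset(self.residues))
        if not self.residues:
            raise ValueError(f"PTM {self.name!r}: residue set must be nonempty")
        if self.mass_shift == 0:
            raise ValueError(f"PTM {self.name!r}: mass shift must be nonzero")
        bad = self.residues - set(STANDARD_RESIDUES)
        if bad:
            raise ValueError(f"PTM {self.name!r}: unknown residues {sorted(bad)}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: Default expected-PTM set for histone work: acetylation, mono/di/tri-
#: methylation and phosphorylation with their conventional residue targets.
DEFAULT_PTMS: tuple[ExpectedPTM, ...] = (
    ExpectedPTM("Acetylation", 42.01056, frozenset("RK")),
    ExpectedPTM("Methylation", 14.01565, frozenset("RK")),
    ExpectedPTM("Dimethylation", 28.03130, frozenset("RK")),
    ExpectedPTM("Trimethylation", 42.04695, frozenset("R")),
    ExpectedPTM("Phosphorylation", 79.96633, frozenset("STY")),
)


class PTMTable:
    """An ordered collection of expected PTMs with residue lookup."""

    def __init__(self, ptms: Iterable[ExpectedPTM]):
        self.ptms: tuple[ExpectedPTM, ...] = tuple(ptms)
        names = [p.name for p in self.ptms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate PTM names in table")
        self._by_residue: dict[str, tuple[ExpectedPTM, ...]] = {}
        for aa in STANDARD_RESIDUES:
            self._by_residue[aa] = tuple(p for p in self.ptms if aa in p.residues)

    @classmethod
    def default(cls) -> "PTMTable":
        return cls(DEFAULT_PTMS)

    def __iter__(self) -> Iterator[ExpectedPTM]:
        return iter(self.ptms)

    def __len__(self) -> int:
        return len(self.ptms)

    def __getitem__(self, name: str) -> ExpectedPTM:
        for p in self.ptms:
            if p.name == name:
                return p
        raise KeyError(name)

    def for_residue(self, aa: str) -> tuple[ExpectedPTM, ...]:
        """PTMs whose residue specificity includes ``aa`` (the set T_i)."""
        return self._by_residue.get(aa, ())

    # ---------------------------------------------------------------- I/O
    @classmethod
    def from_tsv(cls, path: str | Path) -> "PTMTable":
        """Read a TSV with columns ``name``, ``monoisotopic_mass``, ``residues``.

        ``residues`` is a comma- or space-separated list of letters
        (e.g. ``R,K``).  Lines starting with ``#`` are ignored; a header line
        naming the columns is optional.
        """
        ptms = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            if parts[0].lower() == "name":
                continue
            name, shift, residues = parts[0], parts[1], parts[2]
            letters = residues.replace(",", " ").split()
            ptms.append(ExpectedPTM(name, float(shift), frozenset("".join(letters))))
        return cls(ptms)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PTMTable":
        """Read a YAML list of ``{name, monoisotopic_mass, residues}`` mappings."""
        raw = yaml.safe_load(Path(path).read_text())
        ptms = [
            ExpectedPTM(
                entry["name"],
                float(entry["monoisotopic_mass"]),
                frozenset("".join(str(entry["residues"]).replace(",", " ").split())),
            )
            for entry in raw
        ]
        return cls(ptms)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["name\tmonoisotopic_mass\tresidues"]
        for p in self.ptms:
            lines.append(f"{p.name}\t{p.mass_shift}\t{','.join(sorted(p.residues))}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class Proteoform:
    """A base sequence plus site-localized expected PTMs (at most one per site).

    ``mods`` is a tuple of ``(position, ptm)`` pairs with 1-based positions,
    kept sorted by position.
    """

    sequence: str
    mods: tuple[tuple[int, ExpectedPTM], ...] = ()

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        mods = tuple(sorted(self.mods, key=lambda m: m[0]))
        object.__setattr__(self, "mods", mods)
        n = len(self.sequence)
        seen = set()
        for pos, ptm in mods:
            if not 1 <= pos <= n:
                raise ValueError(f"mod position {pos} outside 1..{n}")
            if pos in seen:
                raise ValueError(f"multiple PTMs at position {pos}")
            seen.add(pos)
            aa = self.sequence[pos - 1]
            if aa not in ptm.residues:
                raise ValueError(
                    f"PTM {ptm.name} not allowed on residue {aa} at position {pos}"
                )

    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def shift_total(self) -> float:
        return sum(ptm.mass_shift for _, ptm in self.mods)

    @property
    def mass(self) -> float:
        """Neutral monoisotopic molecular mass (residues + PTM shifts + water)."""
        return prefix_residue_masses(self.sequence)[-1] + self.shift_total + WATER_MONO

    def prefix_masses(self) -> list[float]:
        """Modified prefix residue masses ``0 .. total`` (length n+1)."""
        shifts = {pos: ptm.mass_shift for pos, ptm in self.mods}
        out = [0.0]
        total = 0.0
        for i, aa in enumerate(self.sequence, start=1):
            total += STD_RESIDUE_MASSES[aa] + shifts.get(i, 0.0)
            out.append(total)
        return out

    def __str__(self) -> str:
        shifts = {pos: ptm.name for pos, ptm in self.mods}
        parts = []
        for i, aa in enumerate(self.sequence, start=1):
            parts.append(aa)
            if i in shifts:
                parts.append(f"[{shifts[i]}]")
        return "".join(parts)


def proteoform_mass(pf: Proteoform) -> float:
    """Neutral molecular mass of a proteoform (Da)."""
    return pf.mass


# --------------------------------------------------------------------------
# Prefix-mass set enumeration
# --------------------------------------------------------------------------


def _precursor_shift_targets(
    sequence_residue_mass: float,
    precursor_mass: float,
    precursor_tol_ppm: float,
    allow_pm1da: bool,
) -> tuple[list[float], float]:
    """Acceptable total-PTM-shift targets and the absolute tolerance.

    A proteoform with total shift ``sigma`` matches the precursor iff its
    molecular mass lies within the ppm window around ``M`` (optionally also
    around ``M +/- 1.00235`` to absorb deconvolution isotope errors), i.e.
    ``|sigma - target| <= tol`` for some target returned here.
    """
    delta = (precursor_mass - WATER_MONO) - sequence_residue_mass
    tol = precursor_tol_ppm * 1e-6 * precursor_mass
    offsets = [0.0]
    if allow_pm1da:
        offsets += [-ISOTOPE_SPACING, ISOTOPE_SPACING]
    return [delta + off for off in offsets], tol


@dataclass(frozen=True)
class PrefixMassSets:
    """Per-layer sets of distinct prefix residue masses of matching proteoforms.

    ``shifts[i]`` holds the sorted distinct cumulative PTM shifts achievable on
    positions ``1..i`` that are completable to a precursor-consistent total;
    the corresponding prefix masses are ``p_i + shift``.  ``shifts[n]`` is the
    set of acceptable total shifts.
    """

    sequence: str
    residue_prefix: tuple[float, ...]
    shifts: tuple[tuple[float, ...], ...]
    precursor_mass: float

    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def is_empty(self) -> bool:
        return not self.shifts[self.n]

    def masses(self, i: int) -> list[float]:
        """Sorted prefix residue masses in layer ``i``."""
        return [self.residue_prefix[i] + s for s in self.shifts[i]]


def _forward_shift_sets(
    sequence: str, ptm_table: PTMTable, shift_bound: float
) -> list[dict[float, float]]:
    """``fwd[i]``: cumulative shifts (key -> value) achievable on positions 1..i."""
    fwd: list[dict[float, float]] = [{0.0: 0.0}]
    for aa in sequence:
        cur = dict(fwd[-1])
        for ptm in ptm_table.for_residue(aa):
            for val in fwd[-1].values():
                s = val + ptm.mass_shift
                if s <= shift_bound + 1e-9:
                    cur.setdefault(_shift_key(s), s)
        fwd.append(cur)
    return fwd


def _backward_shift_sets(
    sequence: str, ptm_table: PTMTable, shift_bound: float
) -> list[dict[float, float]]:
    """``bwd[i]``: cumulative shifts achievable on positions i+1..n."""
    n = len(sequence)
    bwd: list[dict[float, float]] = [{0.0: 0.0}]
    for aa in reversed(sequence):
        cur = dict(bwd[-1])
        for ptm in ptm_table.for_residue(aa):
            for val in bwd[-1].values():
                s = val + ptm.mass_shift
                if s <= shift_bound + 1e-9:
                    cur.setdefault(_shift_key(s), s)
        bwd.append(cur)
    bwd.reverse()
    return bwd


def enumerate_prefix_mass_sets(
    sequence: str,
    ptm_table: PTMTable,
    precursor_mass: float,
    precursor_tol_ppm: float = 15.0,
    allow_pm1da: bool = False,
    shift_bound: float = 500.0,
) -> PrefixMassSets:
    """Enumerate the prefix-residue-mass sets P_0..P_n under a precursor constraint.

    A cumulative shift ``d`` survives in layer ``i`` iff it is reachable by
    assigning expected PTMs to positions ``1..i`` (sum of shifts bounded by
    ``shift_bound``) *and* completable: some assignment on positions
    ``i+1..n`` brings the total shift within the precursor tolerance window
    (ppm around the precursor neutral mass, optionally widened by +/-1 Da
    isotope offsets).

    Returns an empty :class:`PrefixMassSets` (all layers empty) when no PTM
    combination explains the precursor.
    """
    _validate_sequence(sequence)
    if not sequence:
        raise ValueError("sequence must be nonempty")
    if precursor_mass <= 0:
        raise ValueError("precursor mass must be positive")
    if shift_bound < 0:
        raise ValueError("shift bound must be nonnegative")

    p = prefix_residue_masses(sequence)
    n = len(sequence)
    targets, tol = _precursor_shift_targets(
        p[n], precursor_mass, precursor_tol_ppm, allow_pm1da
    )

    fwd = _forward_shift_sets(sequence, ptm_table, shift_bound)
    bwd = _backward_shift_sets(sequence, ptm_table, shift_bound)

    layers: list[tuple[float, ...]] = []
    for i in range(n + 1):
        suffix_vals = np.array(sorted(bwd[i].values()))
        kept = []
        for d in fwd[i].values():
            ok = False
            for t in targets:
                lo = t - tol - d
                hi = min(t + tol - d, shift_bound + 1e-9 - d)
                a = np.searchsorted(suffix_vals, lo - 1e-12, side="left")
                b = np.searchsorted(suffix_vals, hi + 1e-12, side="right")
                if b > a:
                    ok = True
                    break
            if ok:
                kept.append(d)
        layers.append(tuple(sorted(kept)))

    if not layers[n]:
        layers = [()] * (n + 1)
    return PrefixMassSets(
        sequence=sequence,
        residue_prefix=tuple(p),
        shifts=tuple(layers),
        precursor_mass=precursor_mass,
    )


def enumerate_proteoforms(
    sequence: str,
    ptm_table: PTMTable,
    precursor_mass: float | None = None,
    precursor_tol_ppm: float = 15.0,
    allow_pm1da: bool = False,
    shift_bound: float = float("inf"),
    max_count: int = 200_000,
) -> list[Proteoform]:
    """Exhaustively enumerate proteoforms with expected PTMs (brute force).

    Every residue independently carries no PTM or one allowed PTM, subject to
    the total-shift bound and, when ``precursor_mass`` is given, the precursor
    tolerance window.  Includes the unmodified proteoform when it qualifies.
    Intended for small sequences (oracle/testing and path decoding checks).
    """
    _validate_sequence(sequence)
    options: list[tuple[ExpectedPTM | None, ...]] = [
        (None,) + ptm_table.for_residue(aa) for aa in sequence
    ]
    targets_tol = None
    if precursor_mass is not None:
        p_n = prefix_residue_masses(sequence)[-1]
        targets_tol = _precursor_shift_targets(
            p_n, precursor_mass, precursor_tol_ppm, allow_pm1da
        )

    out: list[Proteoform] = []

    def rec(pos: int, shift: float, mods: list[tuple[int, ExpectedPTM]]) -> None:
        if len(out) > max_count:
            raise ValueError("proteoform enumeration exceeds max_count")
        if pos == len(sequence):
            if targets_tol is not None:
                targets, tol = targets_tol
                if not any(abs(shift - t) <= tol for t in targets):
                    return
            out.append(Proteoform(sequence, tuple(mods)))
            return
        for opt in options[pos]:
            if opt is None:
                rec(pos + 1, shift, mods)
            else:
                s = shift + opt.mass_shift
                if s <= shift_bound + 1e-9:
                    mods.append((pos + 1, opt))
                    rec(pos + 1, s, mods)
                    mods.pop()

    rec(0, 0.0, [])
    return out
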