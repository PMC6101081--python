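"""End-to-end spectrum identification: graph build, flow solve, decode, score.

For each deconvoluted spectrum the pipeline enumerates precursor-consistent
proteoforms implicitly (as a layered mass graph), solves the minimum-error
2-splittable flow to pick the best-supported proteoform pair with relative
abundances, and scores single-versus-pair explanations by matched fragment
ions and explained peak intensity.  A batch driver processes whole spectrum
files and writes TSV/summary reports.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .masses import PTMTable, Proteoform, WATER_MONO, prefix_residue_masses
from .massgraph import LayeredMassGraph, build_graph
from .me2sf import FlowSolution, solve_me2sf
from .spectra import (
    BY_SCHEME,
    DeconvSpectrum,
    IonTypeScheme,
    read_msalign,
    read_tsv,
    scheme_for_activation,
)

__all__ = [
    "IdentifyParams",
    "IdentificationResult",
    "SpectrumSkipped",
    "score_proteoforms",
    "identify_spectrum",
    "run_batch",
    "read_protein_fasta",
    "load_spectra",
]

logger = logging.getLogger("homtm")


@dataclass(frozen=True)
class IdentifyParams:
    """Run parameters for identification.

    Defaults follow common top-down practice on Orbitrap data: 15 ppm mass
    tolerances, a 200 Da cap on the precursor-versus-unmodified mass
    difference, +/-1 Da precursor ambiguity enabled, total flow 100 (so path
    flows read as percentages), a 10 matched-fragment-ion reporting cutoff,
    and pair-acceptance margins of 10 extra ions or 20% extra intensity.
    """

    frag_tol_ppm: float = 15.0
    prec_tol_ppm: float = 15.0
    max_prec_shift: float = 200.0
    shift_bound: float = 600.0
    total_flow: int = 100
    min_matched_ions: int = 10
    pair_ion_gain: int = 10
    pair_intensity_gain: float = 0.20
    allow_pm1da: bool = True
    scheme: IonTypeScheme | None = None  # None: choose from spectrum activation


class SpectrumSkipped(Exception):
    """A spectrum could not be identified; carries the reason."""

    def __init__(self, spectrum_id: str, reason: str):
        self.spectrum_id = spectrum_id
        self.reason = reason
        super().__init__(f"{spectrum_id}: {reason}")


@dataclass
class IdentificationResult:
    spectrum_id: str
    proteoform1: Proteoform
    abundance1: int
    proteoform2: Proteoform | None
    abundance2: int
    matched_ions_pair: int
    matched_ions_best_single: int
    explained_intensity_pair: float
    explained_intensity_best_single: float
    flow_error: int
    pair_better_ions: bool = False
    pair_better_intensity: bool = False

    @property
    def is_pair(self) -> bool:
        return self.proteoform2 is not None

    def to_row(self) -> dict:
        return {
            "spectrum_id": self.spectrum_id,
            "type": "pair" if self.is_pair else "single",
            "proteoform1": str(self.proteoform1),
            "abundance1": self.abundance1,
            "proteoform2": "" if self.proteoform2 is None else str(self.proteoform2),
            "abundance2": self.abundance2 if self.is_pair else "",
            "matched_ions_pair": self.matched_ions_pair,
            "matched_ions_best_single": self.matched_ions_best_single,
            "explained_intensity_pair": self.explained_intensity_pair,
            "explained_intensity_best_single": self.explained_intensity_best_single,
            "flow_error": self.flow_error,
            "pair_better_ions": self.pair_better_ions,
            "pair_better_intensity": self.pair_better_intensity,
        }


def _theoretical_fragments(pf: Proteoform, scheme: IonTypeScheme) -> np.ndarray:
    """Neutral N-/C-terminal fragment masses of a proteoform (sites 1..n-1)."""
    pm = pf.prefix_masses()
    total = pm[-1]
    frags = [pm[i] + scheme.n_term_offset for i in range(1, pf.n)]
    frags += [(total - pm[i]) + scheme.c_term_offset for i in range(1, pf.n)]
    return np.array(sorted(frags))


def score_proteoforms(
    proteoforms: Sequence[Proteoform],
    spectrum: DeconvSpectrum,
    scheme: IonTypeScheme = BY_SCHEME,
    tol_ppm: float = 15.0,
) -> tuple[int, float]:
    """Matched-ion count and explained intensity of a proteoform (set).

    Counting is at the peak level: an experimental peak matching any
    theoretical fragment mass of any given proteoform counts once, and its
    intensity is explained once.
    """
    if not proteoforms:
        raise ValueError("need at least one proteoform")
    seqs = {pf.sequence for pf in proteoforms}
    if len(seqs) != 1:
        raise ValueError("proteoforms must share the base sequence")
    matched = np.zeros(len(spectrum.peaks), dtype=bool)
    for pf in proteoforms:
        for theo in _theoretical_fragments(pf, scheme):
            sl = spectrum.match_window(theo, tol_ppm)
            matched[sl] = True
    return int(matched.sum()), float(spectrum.intensities[matched].sum())


def identify_spectrum(
    sequence: str,
    spectrum: DeconvSpectrum,
    ptm_table: PTMTable | None = None,
    params: IdentifyParams = IdentifyParams(),
) -> IdentificationResult:
    """Identify (and quantify) one or two proteoforms from one spectrum.

    Raises :class:`SpectrumSkipped` when the precursor shift exceeds the cap,
    no expected-PTM combination explains the precursor, or the matched-ion
    count falls below the reporting cutoff.
    """
    table = ptm_table or PTMTable.default()
    scheme = params.scheme or scheme_for_activation(spectrum.activation)

    unmodified_mass = prefix_residue_masses(sequence)[-1] + WATER_MONO
    shift = spectrum.precursor_neutral_mass - unmodified_mass
    if abs(shift) > params.max_prec_shift:
        raise SpectrumSkipped(
            spectrum.spectrum_id,
            f"precursor shift {shift:.2f} Da exceeds cap {params.max_prec_shift} Da",
        )

    try:
        graph = build_graph(
            sequence,
            table,
            spectrum,
            tol_ppm=params.frag_tol_ppm,
            precursor_tol_ppm=params.prec_tol_ppm,
            allow_pm1da=params.allow_pm1da,
            shift_bound=params.shift_bound,
            total_flow=params.total_flow,
            scheme=scheme,
        )
    except ValueError as exc:
        raise SpectrumSkipped(spectrum.spectrum_id, str(exc)) from None

    sol = solve_me2sf(graph)
    pf1 = graph.decode_path(sol.path1)
    pf2 = graph.decode_path(sol.path2)

    if sol.is_single or pf1 == pf2:
        single, pair = (pf1,), None
        abundance1, abundance2 = params.total_flow, 0
    else:
        single, pair = (pf1,), (pf1, pf2)
        abundance1, abundance2 = sol.f1, sol.f2

    ions_single, inten_single = score_proteoforms(
        single, spectrum, scheme, params.frag_tol_ppm
    )
    if pair is not None:
        ions_pair, inten_pair = score_proteoforms(
            pair, spectrum, scheme, params.frag_tol_ppm
        )
    else:
        ions_pair, inten_pair = ions_single, inten_single

    if ions_pair < params.min_matched_ions:
        raise SpectrumSkipped(
            spectrum.spectrum_id,
            f"only {ions_pair} matched fragment ions "
            f"(cutoff {params.min_matched_ions})",
        )

    return IdentificationResult(
        spectrum_id=spectrum.spectrum_id,
        proteoform1=pf1,
        abundance1=abundance1,
        proteoform2=pair[1] if pair else None,
        abundance2=abundance2,
        matched_ions_pair=ions_pair,
        matched_ions_best_single=ions_single,
        explained_intensity_pair=inten_pair,
        explained_intensity_best_single=inten_single,
        flow_error=sol.error,
        pair_better_ions=bool(
            pair and ions_pair - ions_single >= params.pair_ion_gain
        ),
        pair_better_intensity=bool(
            pair
            and inten_single > 0
            and (inten_pair - inten_single) / inten_single
            >= params.pair_intensity_gain
        ),
    )


# --------------------------------------------------------------------------
# Batch driver
# --------------------------------------------------------------------------


def read_protein_fasta(path: str | Path, record_id: str | None = None) -> str:
    """Read a protein sequence from FASTA (first record unless an ID is given)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if record_id is None:
        return str(records[0].seq).upper()
    for rec in records:
        if rec.id == record_id:
            return str(rec.seq).upper()
    raise ValueError(f"{path}: no record with id {record_id!r}")


def load_spectra(path: str | Path) -> list[DeconvSpectrum]:
    """Load spectra from an msalign or single-spectrum TSV file (by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".tsv", ".txt"}:
        return [read_tsv(path)]
    return read_msalign(path)


RESULT_COLUMNS = [
    "spectrum_id",
    "type",
    "proteoform1",
    "abundance1",
    "proteoform2",
    "abundance2",
    "matched_ions_pair",
    "matched_ions_best_single",
    "explained_intensity_pair",
    "explained_intensity_best_single",
    "flow_error",
    "pair_better_ions",
    "pair_better_intensity",
]


def run_batch(
    protein_fasta: str | Path,
    spectra_file: str | Path,
    ptm_table: PTMTable | None = None,
    params: IdentifyParams = IdentifyParams(),
    out_prefix: str | Path = "homtm_out",
    record_id: str | None = None,
) -> dict:
    """Identify every spectrum in a file; write a results TSV and a summary TXT.

    Spectrum-level failures are logged and counted as skips, never fatal.
    Returns a summary dict (also written to ``<out_prefix>_summary.txt``).
    Output files depend only on the inputs, so reruns are byte-identical.
    """
    sequence = read_protein_fasta(protein_fasta, record_id)
    spectra = load_spectra(spectra_file)
    table = ptm_table or PTMTable.default()

    rows: list[dict] = []
    skips: list[tuple[str, str]] = []
    for sp in spectra:
        t0 = time.perf_counter()
        try:
            res = identify_spectrum(sequence, sp, table, params)
            assert res.matched_ions_pair >= res.matched_ions_best_single
            assert res.explained_intensity_pair >= res.explained_intensity_best_single
            rows.append(res.to_row())
        except SpectrumSkipped as exc:
            skips.append((exc.spectrum_id, exc.reason))
            logger.info("skipped %s: %s", exc.spectrum_id, exc.reason)
        except Exception as exc:  # never fatal to the batch
            skips.append((sp.spectrum_id, f"unexpected error: {exc}"))
            logger.warning("failed %s: %s", sp.spectrum_id, exc)
        logger.info("%s processed in %.3f s", sp.spectrum_id, time.perf_counter() - t0)

    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    results_path = out_prefix.with_name(out_prefix.name + "_results.tsv")
    df.to_csv(results_path, sep="\t", index=False)

    n_pairs = int((df["type"] == "pair").sum()) if len(df) else 0
    summary = {
        "n_spectra": len(spectra),
        "n_identified": len(rows),
        "n_single": len(rows) - n_pairs,
        "n_pair": n_pairs,
        "n_skipped": len(skips),
        "n_pair_better_ions": int(df["pair_better_ions"].sum()) if len(df) else 0,
        "n_pair_better_intensity": int(df["pair_better_intensity"].sum())
        if len(df)
        else 0,
    }
    summary_path = out_prefix.with_name(out_prefix.name + "_summary.txt")
    lines = [f"{k}\t{v}" for k, v in summary.items()]
    lines.append("")
    for sid, reason in skips:
        lines.append(f"skip\t{sid}\t{reason}")
    summary_path.write_text("\n".join(lines) + "\n")
    summary["results_path"] = str(results_path)
    summary["summary_path"] = str(summary_path)
    return summary
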