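"""Synthetic deconvoluted HomMTM spectra and random layered graphs.

The spectrum simulator emulates the *output of deconvolution* for a mixture
of co-isolated proteoforms of one protein: for every backbone cleavage site
it emits the N- and C-terminal fragment neutral masses of each proteoform,
with intensities proportional to proteoform abundance, then degrades the
spectrum with configurable peak dropout, ppm mass jitter, multiplicative
intensity noise and uniform noise peaks.  Isotope envelopes and charge
states are not simulated (they are an upstream concern).

Ground truth travels with every simulated spectrum, so identification and
quantification can be closed-loop tested without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .masses import PTMTable, Proteoform, WATER_MONO
from .massgraph import LayeredMassGraph, MassVertex
from .spectra import BY_SCHEME, DeconvPeak, DeconvSpectrum, IonTypeScheme

__all__ = [
    "SimulationConfig",
    "simulate_spectrum",
    "two_site_acetylation_example",
    "random_layered_graph",
    "HISTONE_H4_HUMAN",
]

#: Mature human histone H4 sequence (UniProt P62805, initiator Met removed).
#: Shipped as the canonical heavily modified reference protein for sizing
#: experiments and examples.
HISTONE_H4_HUMAN: str = (
    "SGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLKVFLENVIRDAV"
    "TYTEHAKRKTVTAMDVVYALKRQGRTLYGFGG"
)

#: Log-uniform range for per-cleavage base fragment intensities.
BASE_INTENSITY_RANGE = (1e3, 1e6)
#: Log-uniform range for noise-peak intensities (low end of the dynamic range).
NOISE_INTENSITY_RANGE = (1e2, 1e3)


@dataclass
class SimulationConfig:
    """Ground-truth recipe for one synthetic HomMTM spectrum."""

    proteoforms: tuple[Proteoform, ...]
    abundances: tuple[int, ...]
    scheme: IonTypeScheme = BY_SCHEME
    dropout: float = 0.0
    jitter_ppm: float = 0.0
    intensity_noise: float = 0.0
    n_noise_peaks: int = 0
    precursor_da_offset: float = 0.0
    spectrum_id: str = "synthetic"
    activation: str = "CID"
    seed: int = 0
    #: proteoform molecular masses must agree within this window (ppm)
    mass_agreement_ppm: float = 15.0

    def __post_init__(self) -> None:
        if not self.proteoforms:
            raise ValueError("need at least one proteoform")
        if len(self.abundances) != len(self.proteoforms):
            raise ValueError("abundances must match proteoforms")
        if any(a <= 0 for a in self.abundances):
            raise ValueError("abundances must be positive")
        if sum(self.abundances) != 100:
            raise ValueError("abundances must sum to 100")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        seqs = {pf.sequence for pf in self.proteoforms}
        if len(seqs) != 1:
            raise ValueError("proteoforms must share the base sequence")

    @classmethod
    def from_yaml(cls, path: str | Path, ptm_table: PTMTable | None = None) -> "SimulationConfig":
        """Load a config from YAML.

        Expected layout::

            sequence: GKGKLKAKE
            proteoforms:
              - mods: [{pos: 2, ptm: Acetylation}, {pos: 4, ptm: Acetylation}]
              - mods: [{pos: 4, ptm: Acetylation}, {pos: 6, ptm: Acetylation}]
            abundances: [70, 30]
            dropout: 0.0
            seed: 1
        """
        raw = yaml.safe_load(Path(path).read_text())
        table = ptm_table or PTMTable.default()
        seq = raw["sequence"]
        pfs = tuple(
            Proteoform(
                seq,
                tuple((m["pos"], table[m["ptm"]]) for m in entry.get("mods", [])),
            )
            for entry in raw["proteoforms"]
        )
        kwargs = {
            k: raw[k]
            for k in (
                "dropout",
                "jitter_ppm",
                "intensity_noise",
                "n_noise_peaks",
                "precursor_da_offset",
                "spectrum_id",
                "activation",
                "seed",
            )
            if k in raw
        }
        return cls(pfs, tuple(raw["abundances"]), **kwargs)

    def truth(self) -> dict:
        return {
            "sequence": self.proteoforms[0].sequence,
            "proteoforms": [str(pf) for pf in self.proteoforms],
            "abundances": list(self.abundances),
            "seed": self.seed,
        }


def simulate_spectrum(config: SimulationConfig) -> tuple[DeconvSpectrum, dict]:
    """Simulate one deconvoluted HomMTM spectrum plus its ground-truth record.

    Per cleavage site and terminal side, one base intensity is drawn; the
    fragment peak of each distinct prefix (or suffix) mass at that site pools
    the abundance shares of the proteoforms producing it.  With zero noise,
    dropout and jitter, within-layer intensity ratios therefore equal
    abundance ratios exactly and the peak set equals the theoretical
    fragment list.
    """
    rng = np.random.default_rng(config.seed)
    pfs = config.proteoforms
    n = pfs[0].n
    scheme = config.scheme

    masses = [pf.mass for pf in pfs]
    m0 = masses[0]
    tol = config.mass_agreement_ppm * 1e-6 * m0
    if any(abs(m - m0) > tol for m in masses):
        raise ValueError(
            "proteoform molecular masses differ beyond tolerance; mixture would "
            "not co-isolate as a homogeneous multiplexed spectrum"
        )

    prefix = [pf.prefix_masses() for pf in pfs]
    lo, hi = np.log(BASE_INTENSITY_RANGE[0]), np.log(BASE_INTENSITY_RANGE[1])

    pooled: dict[float, float] = {}
    entries: list[tuple[float, float]] = []
    for site in range(1, n):
        for side in ("n", "c"):
            base = float(np.exp(rng.uniform(lo, hi)))
            by_mass: dict[float, float] = {}
            for pf_idx, pf in enumerate(pfs):
                if side == "n":
                    frag = prefix[pf_idx][site] + scheme.n_term_offset
                else:
                    frag = (prefix[pf_idx][n] - prefix[pf_idx][site]) + scheme.c_term_offset
                key = round(frag, 5)
                by_mass[key] = by_mass.get(key, 0.0) + config.abundances[pf_idx] / 100.0
            for key, share in sorted(by_mass.items()):
                intensity = share * base
                if config.intensity_noise > 0:
                    intensity *= 1.0 + rng.uniform(
                        -config.intensity_noise, config.intensity_noise
                    )
                if config.dropout > 0 and rng.random() < config.dropout:
                    continue
                entries.append((key, intensity))

    for mass, intensity in entries:
        if config.jitter_ppm > 0:
            mass *= 1.0 + rng.uniform(-config.jitter_ppm, config.jitter_ppm) * 1e-6
        pooled[round(mass, 5)] = pooled.get(round(mass, 5), 0.0) + intensity

    nlo, nhi = np.log(NOISE_INTENSITY_RANGE[0]), np.log(NOISE_INTENSITY_RANGE[1])
    for _ in range(config.n_noise_peaks):
        mass = float(rng.uniform(2 * 57.0, m0))
        pooled[round(mass, 5)] = pooled.get(round(mass, 5), 0.0) + float(
            np.exp(rng.uniform(nlo, nhi))
        )

    peaks = [DeconvPeak(m, i) for m, i in pooled.items() if i > 0]
    spectrum = DeconvSpectrum(
        spectrum_id=config.spectrum_id,
        precursor_neutral_mass=m0 + config.precursor_da_offset,
        activation=config.activation,
        peaks=peaks,
    )
    return spectrum, config.truth()


def two_site_acetylation_example(
    abundances: tuple[int, int] = (70, 30), seed: int = 0, **kwargs
) -> SimulationConfig:
    """Worked example: the lysine-rich 9-mer GKGKLKAKE carrying two acetyl
    groups, mixed as GK[Ac]GK[Ac]LKAKE : GKGK[Ac]LK[Ac]AKE at the given ratio.

    Both proteoforms share one molecular mass, so co-fragmentation yields a
    homogeneous multiplexed spectrum whose graph has 10 layers.
    """
    table = PTMTable.default()
    ac = table["Acetylation"]
    seq = "GKGKLKAKE"
    pf1 = Proteoform(seq, ((2, ac), (4, ac)))
    pf2 = Proteoform(seq, ((4, ac), (6, ac)))
    return SimulationConfig(
        proteoforms=(pf1, pf2),
        abundances=abundances,
        spectrum_id="diacetyl_pair",
        seed=seed,
        **kwargs,
    )


def random_layered_graph(
    seed: int, h: int, max_l: int, f: int, extra_edge_prob: float = 0.4
) -> LayeredMassGraph:
    """Random connected layered graph with integer capacities summing to ``f``.

    Layers 0 and ``h-1`` are singletons (source/sink); interior layers have
    1..``max_l`` vertices.  Every vertex keeps at least one incoming and one
    outgoing edge, so the graph needs no pruning.  Used to drive
    solver-versus-oracle sweeps.
    """
    if h < 2:
        raise ValueError("need at least two layers")
    if max_l < 1 or f < 1:
        raise ValueError("max_l and f must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = [1] + [int(rng.integers(1, max_l + 1)) for _ in range(h - 2)] + [1]

    layers: list[list[MassVertex]] = []
    for i, size in enumerate(sizes):
        if i == 0 or i == h - 1:
            caps = [f]
        else:
            caps = rng.multinomial(f, np.ones(size) / size).tolist()
        layers.append(
            [MassVertex(i, j, float(j), 0.0, 0.0, int(caps[j])) for j in range(size)]
        )

    succs = []
    for i in range(h - 1):
        a, b = sizes[i], sizes[i + 1]
        edges = {
            (int(rng.integers(0, a)), v) for v in range(b)  # every v has a pred
        } | {
            (u, int(rng.integers(0, b))) for u in range(a)  # every u has a succ
        }
        for u in range(a):
            for v in range(b):
                if rng.random() < extra_edge_prob:
                    edges.add((u, v))
        layer_edges: list[list[tuple[int, tuple]]] = [[] for _ in range(a)]
        for u, v in sorted(edges):
            layer_edges[u].append((v, (None,)))
        succs.append(layer_edges)
    succs.append([[]])

    return LayeredMassGraph(layers=layers, succs=succs, total_flow=f)
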