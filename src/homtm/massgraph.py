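"""Layered vertex-capacitated mass graph built from prefix-mass sets + spectrum.

The graph has ``n + 1`` layers for an ``n``-residue protein: layer ``i`` holds
one vertex per distinct ``i``-th prefix residue mass of the proteoforms
consistent with the precursor.  Construction follows five steps:

1. add a vertex per mass in each prefix-mass set;
2. connect layer-``i`` mass ``m1`` to layer-``i+1`` mass ``m2`` iff
   ``m2 - m1`` equals the residue mass of position ``i+1``, optionally plus
   the shift of a PTM allowed on that residue (the *preceding-mass* relation);
3. the single layer-0 vertex is the source, the single layer-``n`` vertex the
   sink (tolerance-equivalent total shifts are merged into one sink);
4. remove vertices not on any source-to-sink path;
5. set each vertex capacity to its share of the pooled fragment intensity in
   its layer, quantized to integers summing to the total flow value.

Every source-to-sink path then decodes to a proteoform, and an integer flow
along it to a relative abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .masses import (
    STD_RESIDUE_MASSES,
    WATER_MONO,
    ExpectedPTM,
    PTMTable,
    PrefixMassSets,
    Proteoform,
    _forward_shift_sets,
    _shift_key,
    enumerate_prefix_mass_sets,
)
from .spectra import BY_SCHEME, DeconvSpectrum, IonTypeScheme, raw_intensity

__all__ = [
    "MassVertex",
    "LayeredMassGraph",
    "build_graph",
    "prune_unreachable",
    "quantize_capacities",
    "graph_stats",
]


@dataclass
class MassVertex:
    layer: int
    index: int
    mass: float
    shift: float | None  # cumulative PTM shift; None for the merged sink
    raw_intensity: float = 0.0
    capacity: int = 0

    @property
    def label(self) -> str:
        return f"{self.layer}:{self.mass:.5f}:{self.capacity}"


@dataclass
class LayeredMassGraph:
    """Layers of capacitated vertices with edges between consecutive layers.

    ``succs[i][u]`` lists ``(v, annotations)`` pairs: an edge from vertex ``u``
    of layer ``i`` to vertex ``v`` of layer ``i+1``, annotated with the PTMs
    (or ``None`` for an unmodified step) that realise the mass difference.
    """

    layers: list[list[MassVertex]]
    succs: list[list[list[tuple[int, tuple[ExpectedPTM | None, ...]]]]]
    total_flow: int
    sequence: str | None = None
    ptm_table: PTMTable | None = None

    # ------------------------------------------------------------- basics
    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_vertices(self) -> int:
        return sum(len(layer) for layer in self.layers)

    @property
    def n_edges(self) -> int:
        return sum(len(out) for layer in self.succs for out in layer)

    @property
    def source(self) -> MassVertex:
        return self.layers[0][0]

    @property
    def sink(self) -> MassVertex:
        return self.layers[-1][0]

    def capacities(self, layer: int) -> list[int]:
        return [v.capacity for v in self.layers[layer]]

    def preds(self, layer: int) -> list[list[int]]:
        """Predecessor indices (in layer-1) of each vertex of ``layer``."""
        out: list[list[int]] = [[] for _ in self.layers[layer]]
        if layer > 0:
            for u, edges in enumerate(self.succs[layer - 1]):
                for v, _ in edges:
                    out[v].append(u)
        return out

    def validate(self) -> None:
        if len(self.layers[0]) != 1 or len(self.layers[-1]) != 1:
            raise ValueError("layers 0 and n must hold exactly one vertex each")
        for i, layer in enumerate(self.layers):
            if 0 < i < self.n_layers and layer and sum(
                v.capacity for v in layer
            ) != self.total_flow:
                raise ValueError(f"layer {i} capacities do not sum to total flow")

    # -------------------------------------------------------------- paths
    def iter_st_paths(self) -> Iterator[tuple[int, ...]]:
        """Yield all source-to-sink paths as per-layer vertex indices."""

        def rec(layer: int, u: int, acc: list[int]) -> Iterator[tuple[int, ...]]:
            acc.append(u)
            if layer == self.n_layers - 1:
                yield tuple(acc)
            else:
                for v, _ in self.succs[layer][u]:
                    yield from rec(layer + 1, v, acc)
            acc.pop()

        yield from rec(0, 0, [])

    def edge_annotations(
        self, layer: int, u: int, v: int
    ) -> tuple[ExpectedPTM | None, ...]:
        for w, ann in self.succs[layer][u]:
            if w == v:
                return ann
        raise KeyError(f"no edge {layer}:{u} -> {layer + 1}:{v}")

    def decode_path(self, path: Sequence[int]) -> Proteoform:
        """Decode a source-to-sink path into a proteoform.

        When an edge carries several PTM annotations with numerically equal
        shifts, the first (table-order) annotation is used.
        """
        if self.sequence is None:
            raise ValueError("graph has no sequence context to decode against")
        mods: list[tuple[int, ExpectedPTM]] = []
        for i in range(self.n_layers - 1):
            ann = self.edge_annotations(i, path[i], path[i + 1])
            ptm = ann[0]
            if ptm is not None:
                mods.append((i + 1, ptm))
        return Proteoform(self.sequence, tuple(mods))

    # ------------------------------------------------------------ exports
    def to_edge_list(self) -> str:
        """Plain-text dump: one ``u -> v [annotation]`` line per edge."""
        lines = []
        for i, layer_edges in enumerate(self.succs):
            for u, edges in enumerate(layer_edges):
                for v, ann in edges:
                    names = ",".join(p.name if p else "unmodified" for p in ann)
                    lines.append(
                        f"{self.layers[i][u].label} -> {self.layers[i + 1][v].label}"
                        f" [{names}]"
                    )
        return "\n".join(lines) + "\n"

    def to_dot(self) -> str:
        lines = ["digraph massgraph {", "  rankdir=LR;"]
        for layer in self.layers:
            for v in layer:
                lines.append(
                    f'  "{v.layer}_{v.index}" [label="{v.mass:.3f}\\nc={v.capacity}"];'
                )
        for i, layer_edges in enumerate(self.succs):
            for u, edges in enumerate(layer_edges):
                for v, ann in edges:
                    names = ",".join(p.name if p else "" for p in ann).strip(",")
                    label = f' [label="{names}"]' if names else ""
                    lines.append(f'  "{i}_{u}" -> "{i + 1}_{v}"{label};')
        lines.append("}")
        return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Construction
# --------------------------------------------------------------------------


def quantize_capacities(raw: Sequence[float], total_flow: int) -> list[int]:
    """Integer capacities proportional to ``raw``, summing exactly to ``total_flow``.

    Largest-remainder (Hamilton) rounding; remainder ties go to the lower
    index (layers sort vertices by mass, so lower index = lower mass).  An
    all-zero layer is treated as uniform shares.
    """
    if total_flow < 1:
        raise ValueError("total flow must be >= 1")
    if any(r < 0 for r in raw):
        raise ValueError("raw intensities must be nonnegative")
    k = len(raw)
    if k == 0:
        return []
    total = sum(raw)
    shares = [r / total * total_flow for r in raw] if total > 0 else [
        total_flow / k
    ] * k
    caps = [int(s) for s in shares]
    remainder = total_flow - sum(caps)
    order = sorted(range(k), key=lambda i: (-(shares[i] - caps[i]), i))
    for i in order[:remainder]:
        caps[i] += 1
    return caps


def prune_unreachable(graph: LayeredMassGraph) -> LayeredMassGraph:
    """Drop vertices not on any source-to-sink path (idempotent, in place)."""
    h = graph.n_layers
    fwd: list[set[int]] = [set() for _ in range(h)]
    fwd[0] = {0} if graph.layers[0] else set()
    for i in range(h - 1):
        for u in fwd[i]:
            for v, _ in graph.succs[i][u]:
                fwd[i + 1].add(v)
    bwd: list[set[int]] = [set() for _ in range(h)]
    bwd[h - 1] = set(range(len(graph.layers[-1]))) & fwd[h - 1]
    for i in range(h - 2, -1, -1):
        for u in range(len(graph.layers[i])):
            if any(v in bwd[i + 1] for v, _ in graph.succs[i][u]):
                bwd[i].add(u)
    keep = [sorted(fwd[i] & bwd[i]) for i in range(h)]
    if not keep[0] or not keep[-1]:
        raise ValueError("source and sink are disconnected")

    remap = [{old: new for new, old in enumerate(idx)} for idx in keep]
    new_layers: list[list[MassVertex]] = []
    for i, idx in enumerate(keep):
        row = []
        for new, old in enumerate(idx):
            v = graph.layers[i][old]
            v.index = new
            row.append(v)
        new_layers.append(row)
    new_succs: list[list[list[tuple[int, tuple[ExpectedPTM | None, ...]]]]] = []
    for i in range(h - 1):
        layer_edges: list[list[tuple[int, tuple[ExpectedPTM | None, ...]]]] = []
        for old_u in keep[i]:
            edges = [
                (remap[i + 1][v], ann)
                for v, ann in graph.succs[i][old_u]
                if v in remap[i + 1]
            ]
            layer_edges.append(edges)
        new_succs.append(layer_edges)
    new_succs.append([[] for _ in keep[h - 1]])
    graph.layers = new_layers
    graph.succs = new_succs
    return graph


def _edge_annotations_for_diff(
    diff: float, residue: str, ptm_table: PTMTable
) -> tuple[ExpectedPTM | None, ...]:
    """Annotations whose shift matches ``diff - Mass(residue)`` (to 1e-5 Da)."""
    step = diff - STD_RESIDUE_MASSES[residue]
    key = _shift_key(step)
    if key == 0.0:
        return (None,)
    ann = tuple(
        ptm for ptm in ptm_table.for_residue(residue) if _shift_key(ptm.mass_shift) == key
    )
    return ann


def build_graph(
    sequence: str,
    ptm_table: PTMTable,
    spectrum: DeconvSpectrum,
    tol_ppm: float = 15.0,
    precursor_tol_ppm: float = 15.0,
    allow_pm1da: bool = False,
    shift_bound: float = 500.0,
    total_flow: int = 100,
    scheme: IonTypeScheme = BY_SCHEME,
    prefix_sets: PrefixMassSets | None = None,
) -> LayeredMassGraph:
    """Build the layered mass graph for one spectrum (the five-step construction)."""
    if prefix_sets is None:
        prefix_sets = enumerate_prefix_mass_sets(
            sequence,
            ptm_table,
            spectrum.precursor_neutral_mass,
            precursor_tol_ppm=precursor_tol_ppm,
            allow_pm1da=allow_pm1da,
            shift_bound=shift_bound,
        )
    if prefix_sets.is_empty:
        raise ValueError(
            f"spectrum {spectrum.spectrum_id!r}: precursor unexplainable by the "
            "expected PTMs within the shift bound"
        )
    n = prefix_sets.n
    total_residue_mass = spectrum.precursor_neutral_mass - WATER_MONO

    # Steps (1) and (3): vertices; the sink merges tolerance-equivalent totals.
    layers: list[list[MassVertex]] = []
    for i in range(n):
        layers.append(
            [
                MassVertex(i, j, prefix_sets.residue_prefix[i] + s, s)
                for j, s in enumerate(prefix_sets.shifts[i])
            ]
        )
    layers.append([MassVertex(n, 0, total_residue_mass, None)])
    sink_shifts = prefix_sets.shifts[n]

    # Step (2): preceding-mass edges between consecutive layers.
    succs: list[list[list[tuple[int, tuple[ExpectedPTM | None, ...]]]]] = []
    for i in range(n):
        residue = sequence[i]
        residue_m = STD_RESIDUE_MASSES[residue]
        targets = (
            {_shift_key(s): j for j, s in enumerate(prefix_sets.shifts[i + 1])}
            if i + 1 < n
            else {_shift_key(s): 0 for s in sink_shifts}
        )
        layer_edges: list[list[tuple[int, tuple[ExpectedPTM | None, ...]]]] = []
        for u, vtx in enumerate(layers[i]):
            edges: dict[int, list[ExpectedPTM | None]] = {}
            for step_ptm in (None,) + tuple(ptm_table.for_residue(residue)):
                step = 0.0 if step_ptm is None else step_ptm.mass_shift
                key = _shift_key(vtx.shift + step)
                v = targets.get(key)
                if v is not None:
                    edges.setdefault(v, []).append(step_ptm)
            layer_edges.append([(v, tuple(ann)) for v, ann in sorted(edges.items())])
        succs.append(layer_edges)
    succs.append([[]])

    graph = LayeredMassGraph(
        layers=layers,
        succs=succs,
        total_flow=total_flow,
        sequence=sequence,
        ptm_table=ptm_table,
    )

    # Step (4): pruning (a no-op when the enumeration already intersected
    # forward-reachable with backward-completable shifts, but kept for safety).
    prune_unreachable(graph)

    # Step (5): capacities from pooled intensities, quantized per layer.
    for i, layer in enumerate(graph.layers):
        for v in layer:
            v.raw_intensity = raw_intensity(
                min(v.mass, total_residue_mass), spectrum, total_residue_mass, scheme, tol_ppm
            )
        if i == 0 or i == n:
            layer[0].capacity = total_flow
        else:
            caps = quantize_capacities([v.raw_intensity for v in layer], total_flow)
            for v, c in zip(layer, caps):
                v.capacity = c
    return graph


def graph_stats(
    sequence: str, ptm_table: PTMTable, shift_bound: float
) -> tuple[int, int]:
    """Vertex and edge counts of the precursor-free mass graph.

    Counts the layered graph spanned by all cumulative PTM shifts reachable
    under ``shift_bound`` (no precursor constraint, no backward pruning):
    one vertex per distinct shift per layer, one edge per realisable
    unmodified or single-PTM step.  Useful for sizing the search space as a
    function of the shift bound.
    """
    fwd = _forward_shift_sets(sequence, ptm_table, shift_bound)
    n_vertices = sum(len(layer) for layer in fwd)
    n_edges = 0
    for i, residue in enumerate(sequence):
        cur = fwd[i]
        nxt = fwd[i + 1]
        shifts = {0.0} | {
            ptm.mass_shift for ptm in ptm_table.for_residue(residue)
        }
        for val in cur.values():
            targets = {
                _shift_key(val + s) for s in shifts if _shift_key(val + s) in nxt
            }
            n_edges += len(targets)
    return n_vertices, n_edges
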