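"""Layered mass-graph construction, pruning and capacity quantization."""

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homtm import (
    WATER_MONO,
    Proteoform,
    build_graph,
    enumerate_proteoforms,
    graph_stats,
    prefix_residue_masses,
    prune_unreachable,
    quantize_capacities,
    random_layered_graph,
    simulate_spectrum,
    two_site_acetylation_example,
)
from homtm.massgraph import LayeredMassGraph, MassVertex


class TestQuantizeCapacities:
    @pytest.mark.parametrize(
        "raw,flow,expected",
        [
            ([70, 30], 100, [70, 30]),
            ([1, 1, 1], 100, [34, 33, 33]),
            ([5], 100, [100]),
            ([0, 0], 100, [50, 50]),
            ([0.2, 0.1, 0.7], 10, [2, 1, 7]),
        ],
    )
    def test_examples(self, raw, flow, expected):
        assert quantize_capacities(raw, flow) == expected

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        raw=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=8),
        flow=st.integers(1, 500),
    )
    def test_conservation_property(self, raw, flow):
        """Quantized capacities are nonnegative integers summing to the flow."""
        caps = quantize_capacities(raw, flow)
        assert sum(caps) == flow
        assert all(isinstance(c, int) and c >= 0 for c in caps)

    @pytest.mark.parametrize("seed", range(20))
    def test_sum_and_proportionality(self, seed):
        import random

        rng = random.Random(seed)
        raw = [rng.random() * rng.choice([0, 1, 100]) for _ in range(rng.randint(1, 6))]
        flow = rng.randint(1, 200)
        caps = quantize_capacities(raw, flow)
        assert sum(caps) == flow
        assert all(c >= 0 for c in caps)
        if sum(raw) > 0:
            # capacity order follows intensity order
            order = sorted(range(len(raw)), key=lambda i: raw[i])
            assert all(
                caps[order[i]] <= caps[order[i + 1]] + 1  # rounding slack
                for i in range(len(order) - 1)
            )


class TestBuildGraph:
    def test_layer_count_and_capacities(self, diacetyl_example, default_table):
        cfg, spectrum, _ = diacetyl_example
        graph = build_graph("GKGKLKAKE", default_table, spectrum)
        assert graph.n_layers == 10
        assert len(graph.layers[0]) == 1 and len(graph.layers[-1]) == 1
        for i in range(graph.n_layers):
            assert sum(graph.capacities(i)) == graph.total_flow
        # the two-proteoform 70:30 mixture shows as 70/30 splits in the layers
        # separating the localizations
        assert sorted(graph.capacities(2)) == [0, 30, 70] or sorted(
            graph.capacities(2)
        ) == [30, 70]

    def test_single_proteoform_precursor_gives_single_path(
        self, acetyl_k_table, default_table
    ):
        from homtm import SimulationConfig

        pf = Proteoform("GKGKLKAKE")
        spectrum, _ = simulate_spectrum(
            SimulationConfig((pf,), (100,), seed=3)
        )
        graph = build_graph("GKGKLKAKE", default_table, spectrum, precursor_tol_ppm=1)
        assert [len(layer) for layer in graph.layers] == [1] * 10
        assert graph.n_edges == 9
        paths = list(graph.iter_st_paths())
        assert paths == [tuple([0] * 10)]

    def test_unexplainable_precursor_rejected(self, acetyl_k_table):
        from homtm import DeconvPeak, DeconvSpectrum

        seq = "AKGKL"
        M = prefix_residue_masses(seq)[-1] + WATER_MONO + 10.0
        sp = DeconvSpectrum("s", M, [DeconvPeak(100.0, 1.0)])
        with pytest.raises(ValueError, match="unexplainable"):
            build_graph(seq, acetyl_k_table, sp)

    def test_path_proteoform_bijection(self, default_table, diacetyl_example):
        """Paths decode bijectively onto the precursor-consistent proteoforms."""
        cfg, spectrum, _ = diacetyl_example
        seq = "GKGKLKAKE"
        graph = build_graph(seq, default_table, spectrum, precursor_tol_ppm=5)
        decoded = [graph.decode_path(p) for p in graph.iter_st_paths()]
        assert len({str(d) for d in decoded}) == len(decoded)
        qm = enumerate_proteoforms(
            seq, default_table, spectrum.precursor_neutral_mass, precursor_tol_ppm=5
        )
        assert {str(d) for d in decoded} == {str(q) for q in qm}
        tol = 5e-6 * spectrum.precursor_neutral_mass
        for d in decoded:
            assert abs(d.mass - spectrum.precursor_neutral_mass) <= tol + 1e-9

    def test_vertex_count_monotone_in_shift_bound(self, default_table):
        seq = "SGRGKGGKGLGKGGAKRH"
        counts = [
            graph_stats(seq, default_table, b)[0] for b in (30, 60, 100, 200, 400)
        ]
        assert counts == sorted(counts)


class TestPrune:
    def _to_nx(self, graph):
        g = nx.DiGraph()
        for i, layer in enumerate(graph.layers):
            for v in layer:
                g.add_node((i, v.index))
        for i, layer_edges in enumerate(graph.succs):
            for u, edges in enumerate(layer_edges):
                for v, _ in edges:
                    g.add_edge((i, u), (i + 1, v))
        return g

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_networkx_reachability_oracle(self, seed):
        graph = random_layered_graph(seed, h=6, max_l=4, f=10, extra_edge_prob=0.2)
        # break the generator's connectivity guarantee by dropping some edges
        import random

        rng = random.Random(seed)
        for layer_edges in graph.succs[:-1]:
            for u in range(len(layer_edges)):
                layer_edges[u] = [e for e in layer_edges[u] if rng.random() > 0.3]
        g = self._to_nx(graph)
        src, snk = (0, 0), (graph.n_layers - 1, 0)
        if not nx.has_path(g, src, snk):
            with pytest.raises(ValueError):
                prune_unreachable(graph)
            return
        expected = nx.descendants(g, src) | {src}
        expected &= nx.ancestors(g, snk) | {snk}
        prune_unreachable(graph)
        kept = {
            (i, v.mass) for i, layer in enumerate(graph.layers) for v in layer
        }
        # compare on (layer, mass) labels since pruning reindexes vertices
        expected_labels = {(i, float(j)) for (i, j) in expected}
        assert kept == expected_labels

    def test_idempotent(self):
        graph = random_layered_graph(7, h=5, max_l=3, f=10)
        prune_unreachable(graph)
        before = [(v.layer, v.mass) for layer in graph.layers for v in layer]
        e_before = graph.n_edges
        prune_unreachable(graph)
        after = [(v.layer, v.mass) for layer in graph.layers for v in layer]
        assert before == after and graph.n_edges == e_before

    def test_dangling_interior_vertex_removed(self):
        layers = [
            [MassVertex(0, 0, 0.0, 0.0)],
            [MassVertex(1, 0, 1.0, 0.0), MassVertex(1, 1, 2.0, 0.0)],
            [MassVertex(2, 0, 3.0, 0.0)],
        ]
        succs = [[[(0, (None,)), (1, (None,))]], [[(0, (None,))], []], [[]]]
        graph = LayeredMassGraph(layers, succs, total_flow=10)
        prune_unreachable(graph)
        assert [len(l) for l in graph.layers] == [1, 1, 1]
        assert graph.layers[1][0].mass == 1.0


def test_exports_render(default_table, diacetyl_example):
    _, spectrum, _ = diacetyl_example
    graph = build_graph("GKGKLKAKE", default_table, spectrum)
    dump = graph.to_edge_list()
    assert "->" in dump and "Acetylation" in dump
    dot = graph.to_dot()
    assert dot.startswith("digraph") and dot.rstrip().endswith("}")
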