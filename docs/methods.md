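# Methods

## Problem and model

A homogeneous multiplexed tandem mass (HomMTM) spectrum is produced when two
or more proteoforms of the *same* protein with (near-)identical molecular
masses are co-isolated and co-fragmented. `homtm` models the identification
and quantification task on such a spectrum as an exact combinatorial
optimization:

* Candidate space: all proteoforms of the known base sequence obtained by
  placing **expected PTMs** (a user table of name, monoisotopic shift,
  allowed residues; default: acetylation 42.01056 on R/K, methylation
  14.01565 on R/K, dimethylation 28.03130 on R/K, trimethylation 42.04695 on
  R, phosphorylation 79.96633 on S/T/Y) with **at most one PTM per site**,
  restricted to molecular masses inside the precursor tolerance window.
* Evidence: deconvoluted neutral monoisotopic fragment masses with
  intensities. One N-terminal and one C-terminal ion series are matched per
  spectrum (b/y for CID/HCD with offsets 0 and +18.010565; c/z• for ETD with
  +17.026549 and +1.991840). The pooled intensity of a prefix residue mass
  sums the peaks matching it and its complementary suffix mass; a peak may
  contribute to every theoretical mass it matches.
* Objective: the layered graph of prefix masses (one layer per prefix
  length, integer vertex capacities = intensity shares × total flow `f`)
  is searched for the 2-splittable source–sink flow of value `f` minimizing
  the summed vertex error `Σ_v |f(v) − c(v)|` over **all** vertices.

The error is summed over every vertex, not only vertices on the two paths:
an untouched vertex contributes its full capacity. The per-layer dynamic
program therefore adds, to the printed pair error
`|c(v1)−f1−f2|` (shared) / `|c(v1)−f1| + |c(v2)−f2|` (distinct), the
capacities of the remaining vertices of the layer. The two objectives are
not equivalent (with layer capacities {5, 4, 0} and packing (2, 0), the
on-path-only objective prefers routing through the zero-capacity vertex);
the all-vertex form is the definition the solver optimizes, and the
exhaustive oracle validates it.

## Solver

Packing step: candidates are `(c(v), f−c(v))` for every vertex with
`c(v) < f`, plus `(f, 0)` — at most `|V| + 1` splits. An exchange argument
(move flow between the paths by the smallest private-vertex error; the
counts of over- and under-flowing private vertices must balance at an
optimum) guarantees the set contains an optimal packing; the test suite
verifies this against all integer splits on 500 random graphs.

Routing step: `D(v1, v2)` = minimum error of partial path pairs ending at
the ordered pair `(v1, v2)` in one layer; transitions range over predecessor
pairs; `D(t, t)` is the optimum for the packing. `O(l⁴)` work per layer.
Backtracking recovers the paths.

Determinism/tie-breaks: packings are routed in f1-descending order and only
strictly better errors replace the incumbent; inside the DP the
lexicographically smallest predecessor pair wins ties. The reported solution
puts the higher flow first, and the special packing `(f, 0)` is collapsed to
a single-path result (with `f2 = 0` the second path carries no flow, so its
choice never affects the all-vertex error). All arithmetic on capacities,
flows and errors is integer, so optimality comparisons are exact.

Degenerate inputs: zero-capacity vertices are allowed (unmatched masses);
an all-zero intensity layer is split uniformly. Several distinct total PTM
shifts can satisfy the precursor window (notably with ±1 Da ambiguity, or
when e.g. acetylation and trimethylation fall inside one ppm window at high
mass); they are merged into the single sink vertex so that layer `n` always
holds exactly one vertex.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `frag_tol_ppm`, `prec_tol_ppm` | 15 ppm | symmetric windows against the theoretical mass |
| `max_prec_shift` | 200 Da | cap on precursor − unmodified-protein mass |
| `shift_bound` | 600 Da | bound on the summed PTM shifts of a proteoform; controls graph size (500–600 Da is advisable with 4–5 PTM types, 1000–1500 Da with 1–2) |
| `allow_pm1da` | on | extra precursor windows at ±1.00235 Da for deconvolution isotope errors |
| `total_flow` | 100 | flow quantum; path flows read as percentages |
| `min_matched_ions` | 10 | peak-level reporting cutoff |
| `pair_ion_gain` / `pair_intensity_gain` | 10 / 20% | margins for flagging a pair as better than its high-abundance member |

Cumulative PTM shifts are keyed after rounding to 1e-5 Da, so equal-sum
combinations (2× methylation = dimethylation, methylation + dimethylation =
trimethylation) merge into one vertex while acetylation (42.01056) and
trimethylation (42.04695) stay distinct. The shift bound is enforced on
prefix partial sums, which is complete for nonnegative shifts (the default
table); with negative shifts it becomes a heuristic prune. Water is the
monoisotopic 18.010565 Da throughout — an average-mass constant would be
incompatible with 15 ppm matching.

Capacity quantization uses largest-remainder (Hamilton) rounding per layer,
ties to the lower mass, so capacities are integers summing exactly to the
total flow — a requirement of the integer flow model that real-valued
intensity ratios do not meet by themselves.

## Synthetic data

The generator (`homtm.fixtures`) emulates *post-deconvolution* spectra of a
1- or 2-proteoform mixture: for each backbone cleavage site and each ion
series it draws one base intensity log-uniform in [1e3, 1e6] (three decades
of dynamic range), and each distinct fragment mass at that site pools the
abundance shares of the proteoforms producing it times that base. Optional
degradations: per-peak dropout probability, uniform ppm mass jitter,
bounded multiplicative intensity noise, and uniform noise peaks at the low
end of the intensity range ([1e2, 1e3]). The precursor is the shared
proteoform mass, optionally offset by ±1.00235 Da to exercise the isotope
path. Everything is reproducible from a single seed.

With zero noise, dropout and jitter, within-layer intensity ratios equal
abundance ratios exactly, so the pipeline recovers the generating
proteoforms and their abundances with zero flow error — the closed-loop
tests rely on this. What the generator does **not** emulate: isotope
envelopes and charge states (removed upstream by deconvolution), systematic
b/y intensity biases, correlated noise, co-isolated contaminant proteins
(the heterogeneous-mixture case is a different problem), and >2-proteoform
mixtures. Passing closed-loop tests therefore demonstrates correctness of
the combinatorial machinery, not robustness to every artifact of real
Orbitrap data.

Because each ion series draws its own base intensity, dropping one side of
a complementary pair can distort a layer's intensity ratio by the full
dynamic range; under up to 20% dropout the recovered abundance split stays
within ±10 flow units of truth in ~90% of seeded replicates, while
site localization may flip when the discriminating ions themselves are
lost.

Random layered graphs for solver sweeps (`random_layered_graph`) have
singleton source/sink layers, 1–4 vertices per interior layer, guaranteed
in/out degree ≥ 1, and per-layer random integer capacities summing to the
flow value.

## Problem sizes and design choices

* The solver/oracle acceptance sweeps use 500 random graphs with ≤ 5
  layers, ≤ 4 vertices per layer and flow ≤ 20 — sizes at which the
  exhaustive oracle (all path pairs × all integer splits, vectorized) is
  itself fast and unquestionably correct; abundance-recovery uses 100
  replicates of the 9-residue worked example.
* `graph_stats` counts the precursor-free graph: all shift values reachable
  under the bound (forward reachability only), merged at 1e-5 Da. This is
  the package's sizing convention; implementations that compare raw
  floating-point sums instead of rounded keys will count equal-sum PTM
  combinations as separate vertices and can report substantially larger
  graphs at large bounds.
* The "best single proteoform" baseline in reports is the higher-abundance
  member of the solved pair; no separate 1-splittable optimization is run.
* Matched-ion counting is peak-level (a peak explained by both proteoforms
  counts once), making single-vs-pair ion counts comparable.
* One spectrum is processed with one ion scheme; paired CID/ETD spectra of
  the same precursor are processed independently, with no evidence fusion.

## Limitations

* `k = 2` only in the production path: the routing DP generalizes to
  `k > 2`, but the candidate-packing argument does not; the brute-force
  oracle covers small `k` for testing. Noisy real spectra rarely support
  confident identification of more than two proteoforms anyway.
* No unexpected/blind PTM search, sequence variants, truncations or
  terminal modifications; the expected-PTM table is the entire hypothesis
  space.
* Layer width `l` enters the routing cost as `l⁴`; with many PTM types and
  a large shift bound the graph (and hence runtime) grows quickly — use the
  shift bound to keep `l` moderate.
* No FDR / decoy machinery; reporting is cutoff-based.
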