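"""Residue/PTM mass arithmetic and precursor-constrained prefix-mass sets."""

import itertools

import pytest

from homtm import (
    ExpectedPTM,
    PTMTable,
    Proteoform,
    WATER_MONO,
    enumerate_prefix_mass_sets,
    enumerate_proteoforms,
    prefix_residue_masses,
    proteoform_mass,
    residue_mass,
)

# Monoisotopic atomic masses (CODATA/NIST), used as an independent oracle for
# residue masses computed from elemental composition.
H, C, N, O, S = 1.0078250319, 12.0, 14.0030740052, 15.9949146221, 31.97207069


@pytest.mark.parametrize(
    "aa,composition",
    [
        ("G", 2 * C + 3 * H + N + O),
        ("K", 6 * C + 12 * H + 2 * N + O),
        ("A", 3 * C + 5 * H + N + O),
        ("S", 3 * C + 5 * H + N + 2 * O),
        ("C", 3 * C + 5 * H + N + O + S),
    ],
)
def test_residue_mass_matches_elemental_composition(aa, composition):
    assert residue_mass(aa) == pytest.approx(composition, abs=1e-4)


def test_residue_mass_rejects_nonstandard_letter():
    with pytest.raises(ValueError, match="B"):
        residue_mass("B")


def test_prefix_residue_masses():
    assert prefix_residue_masses("") == [0.0]
    gg = prefix_residue_masses("GG")
    assert gg == pytest.approx([0.0, 57.02146, 114.04293], abs=1e-4)
    with pytest.raises(ValueError):
        prefix_residue_masses("GXG")


def test_suffix_masses_from_prefix_identity():
    seq = "GKGKLKAKE"
    p = prefix_residue_masses(seq)
    n = len(seq)
    for i in range(n + 1):
        s_i = sum(residue_mass(a) for a in seq[n - i :])
        assert p[n] - p[n - i] == pytest.approx(s_i, abs=1e-9)


class TestProteoform:
    def test_mass_is_residues_plus_shifts_plus_water(self, default_table):
        seq = "AKGKL"
        unmod = Proteoform(seq)
        assert unmod.mass == pytest.approx(
            prefix_residue_masses(seq)[-1] + WATER_MONO
        )
        ac = default_table["Acetylation"]
        ph = default_table["Phosphorylation"]
        one = Proteoform("AKGKL", ((2, ac),))
        assert one.mass == pytest.approx(unmod.mass + 42.01056, abs=1e-4)
        two = Proteoform("SKGKL", ((1, ph), (2, ac)))
        base = Proteoform("SKGKL").mass
        assert proteoform_mass(two) == pytest.approx(
            base + 42.01056 + 79.96633, abs=1e-4
        )

    def test_invariants_enforced(self, default_table):
        ac = default_table["Acetylation"]
        with pytest.raises(ValueError, match="position"):
            Proteoform("AKGKL", ((9, ac),))
        with pytest.raises(ValueError, match="not allowed"):
            Proteoform("AKGKL", ((1, ac),))  # Ala carries no acetylation
        with pytest.raises(ValueError, match="multiple"):
            Proteoform("AKGKL", ((2, ac), (2, default_table["Methylation"])))

    def test_str_marks_sites(self, acetyl_k_table):
        ac = acetyl_k_table["Acetylation"]
        assert str(Proteoform("AKGKL", ((2, ac),))) == "AK[Acetylation]GKL"


class TestPTMTable:
    def test_residue_lookup(self, default_table):
        names = {p.name for p in default_table.for_residue("K")}
        assert names == {"Acetylation", "Methylation", "Dimethylation"}
        assert {p.name for p in default_table.for_residue("R")} >= {"Trimethylation"}
        assert default_table.for_residue("G") == ()

    def test_tsv_round_trip(self, default_table, tmp_path):
        path = tmp_path / "ptms.tsv"
        default_table.to_tsv(path)
        back = PTMTable.from_tsv(path)
        assert [(p.name, p.mass_shift, p.residues) for p in back] == [
            (p.name, p.mass_shift, p.residues) for p in default_table
        ]

    def test_rejects_invalid_ptm(self):
        with pytest.raises(ValueError):
            ExpectedPTM("Nothing", 0.0, frozenset("K"))
        with pytest.raises(ValueError):
            ExpectedPTM("Nowhere", 42.0, frozenset())


class TestEnumeratePrefixMassSets:
    def test_single_acetyl_precursor_keeps_two_proteoforms(self, acetyl_k_table):
        seq = "AKGKL"
        p = prefix_residue_masses(seq)
        M = p[-1] + WATER_MONO + 42.01056
        pms = enumerate_prefix_mass_sets(seq, acetyl_k_table, M, precursor_tol_ppm=1)
        assert pms.masses(2) == pytest.approx([p[2], p[2] + 42.01056])
        assert pms.masses(4) == pytest.approx([p[4] + 42.01056])
        qm = enumerate_proteoforms(seq, acetyl_k_table, M, precursor_tol_ppm=1)
        assert sorted(str(q) for q in qm) == [
            "AKGK[Acetylation]L",
            "AK[Acetylation]GKL",
        ]

    def test_full_q_has_three_modified_proteoforms(self, acetyl_k_table):
        pfs = enumerate_proteoforms("AKGKL", acetyl_k_table)
        assert sum(1 for p in pfs if p.mods) == 3

    def test_zero_tolerance_unmodified_precursor_forces_bare_chain(
        self, default_table
    ):
        seq = "GKGKLKAKE"
        p = prefix_residue_masses(seq)
        pms = enumerate_prefix_mass_sets(
            seq, default_table, p[-1] + WATER_MONO, precursor_tol_ppm=0
        )
        for i in range(len(seq) + 1):
            assert pms.masses(i) == [pytest.approx(p[i])]

    def test_unreachable_precursor_gives_empty_sets(self, acetyl_k_table):
        seq = "AKGKL"
        M = prefix_residue_masses(seq)[-1] + WATER_MONO + 10.0  # no PTM sums to 10
        pms = enumerate_prefix_mass_sets(seq, acetyl_k_table, M, precursor_tol_ppm=5)
        assert pms.is_empty
        # shift bound below the required total also empties the result
        M2 = prefix_residue_masses(seq)[-1] + WATER_MONO + 2 * 42.01056
        pms2 = enumerate_prefix_mass_sets(
            seq, acetyl_k_table, M2, precursor_tol_ppm=5, shift_bound=42.0
        )
        assert pms2.is_empty

    def test_connectivity_each_mass_has_a_preceding_mass(self, default_table):
        seq = "SKRGKT"
        M = prefix_residue_masses(seq)[-1] + WATER_MONO + 42.01056 + 79.96633
        pms = enumerate_prefix_mass_sets(seq, default_table, M, precursor_tol_ppm=10)
        assert not pms.is_empty
        for i in range(len(seq)):
            step = residue_mass(seq[i])
            allowed = [0.0] + [
                t.mass_shift for t in default_table.for_residue(seq[i])
            ]
            for m2 in pms.masses(i + 1):
                assert any(
                    abs(m2 - m1 - step - s) < 1e-6
                    for m1 in pms.masses(i)
                    for s in allowed
                )

    @pytest.mark.parametrize("seed", range(8))
    def test_agreement_with_brute_force_enumeration(self, seed, default_table):
        """P_i from the layer DP equals P_i from exhaustive proteoform listing."""
        import random

        rng = random.Random(seed)
        seq = "".join(rng.choice("GKRSAL") for _ in range(rng.randint(3, 8)))
        table = PTMTable(
            [default_table["Acetylation"], default_table["Phosphorylation"]]
        )
        n_mods = rng.randint(0, 2)
        shift = n_mods * 42.01056
        M = prefix_residue_masses(seq)[-1] + WATER_MONO + shift
        pms = enumerate_prefix_mass_sets(seq, table, M, precursor_tol_ppm=5)
        pfs = enumerate_proteoforms(seq, table, M, precursor_tol_ppm=5)
        for i in range(len(seq) + 1):
            expected = sorted({round(pf.prefix_masses()[i], 5) for pf in pfs})
            assert [round(m, 5) for m in pms.masses(i)] == expected

    def test_pm1da_widens_the_precursor_window(self, acetyl_k_table):
        seq = "AKGKL"
        M = prefix_residue_masses(seq)[-1] + WATER_MONO + 42.01056 + 1.00235
        strict = enumerate_prefix_mass_sets(seq, acetyl_k_table, M, precursor_tol_ppm=1)
        assert strict.is_empty
        wide = enumerate_prefix_mass_sets(
            seq, acetyl_k_table, M, precursor_tol_ppm=1, allow_pm1da=True
        )
        assert not wide.is_empty
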