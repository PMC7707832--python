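"""Contacts, interaction typing, SASA, interface areas, sequons."""

import re

import numpy as np
import pytest

from igageom import (
    classify_interactions,
    contact_residues,
    find_sequons,
    interface_area,
    occlusion_fraction,
    sasa,
)
from igageom.fab_sampler import fibonacci_lattice
from igageom.structure_io import Atom, AtomSet, Structure


def cloud_structure(coords_a, coords_b, element="C", res_name="ALA", atom_name="CA"):
    """Two labelled clouds in one structure; returns (structure, selA, selB)."""
    atoms = []
    for i, p in enumerate(coords_a):
        atoms.append(Atom("A", i + 1, "", res_name, atom_name, element, np.asarray(p, float)))
    for i, p in enumerate(coords_b):
        atoms.append(Atom("B", i + 1, "", res_name, atom_name, element, np.asarray(p, float)))
    st = Structure(atoms)
    na = len(coords_a)
    return st, AtomSet(st, np.arange(na)), AtomSet(st, np.arange(na, na + len(coords_b)))


def two_sphere_sasa_analytic(r1, r2, d, probe):
    """Closed-form accessible area of two intersecting spheres (cap formula)."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * np.pi * (R1**2 + R2**2)
    h1 = R1 - (d**2 + R1**2 - R2**2) / (2 * d)
    h2 = R2 - (d**2 + R2**2 - R1**2) / (2 * d)
    return 4 * np.pi * R1**2 - 2 * np.pi * R1 * h1 + 4 * np.pi * R2**2 - 2 * np.pi * R2 * h2


class TestContacts:
    def test_far_residues_no_contact(self):
        st, a, b = cloud_structure([[0, 0, 0]], [[20, 0, 0]])
        assert contact_residues(a, b, cutoff=7.0) == []

    def test_overlapping_selections_rejected(self):
        st, a, _ = cloud_structure([[0, 0, 0]], [[1, 0, 0]])
        with pytest.raises(ValueError, match="overlap"):
            contact_residues(a, a)

    def test_matches_bruteforce_all_pairs(self):
        """Grid-backed contact search equals the naive N² scan."""
        rng = np.random.default_rng(21)
        for trial in range(20):
            ca = rng.uniform(0, 30, size=(50, 3))
            cb = rng.uniform(0, 30, size=(50, 3))
            st, a, b = cloud_structure(ca, cb)
            got = {
                (c.residue_a.res_seq, c.residue_b.res_seq): c.min_distance
                for c in contact_residues(a, b, cutoff=7.0)
            }
            d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
            want = {
                (i + 1, j + 1): d[i, j].min()
                for i in range(50)
                for j in range(50)
                if d[i, j] <= 7.0
            }
            assert set(got) == set(want)
            for k in got:
                assert got[k] == pytest.approx(want[k], abs=1e-9)


class TestInteractionTyping:
    def test_salt_bridge(self):
        atoms = [
            Atom("A", 1, "", "LYS", "NZ", "N", np.array([0.0, 0, 0])),
            Atom("B", 1, "", "GLU", "OE1", "O", np.array([3.0, 0, 0])),
        ]
        st = Structure(atoms)
        a, b = AtomSet(st, np.array([0])), AtomSet(st, np.array([1]))
        recs = classify_interactions(a, b, contact_residues(a, b))
        assert [r.kind for r in recs] == ["salt_bridge"]
        assert recs[0].distance == pytest.approx(3.0)

    def test_disulfide(self):
        atoms = [
            Atom("A", 1, "", "CYS", "SG", "S", np.array([0.0, 0, 0])),
            Atom("B", 1, "", "CYS", "SG", "S", np.array([2.05, 0, 0])),
        ]
        st = Structure(atoms)
        a, b = AtomSet(st, np.array([0])), AtomSet(st, np.array([1]))
        recs = classify_interactions(a, b, contact_residues(a, b))
        assert recs[0].kind == "disulfide"

    def test_hbond_and_nonspecific(self):
        atoms = [
            Atom("A", 1, "", "SER", "OG", "O", np.array([0.0, 0, 0])),
            Atom("B", 1, "", "THR", "OG1", "O", np.array([3.2, 0, 0])),
            Atom("A", 2, "", "ALA", "CB", "C", np.array([0.0, 5, 0])),
            Atom("B", 2, "", "ALA", "CB", "C", np.array([3.5, 5, 0])),
        ]
        st = Structure(atoms)
        a, b = AtomSet(st, np.array([0, 2])), AtomSet(st, np.array([1, 3]))
        kinds = {(r.residue_a.res_seq, r.kind) for r in
                 classify_interactions(a, b, contact_residues(a, b))}
        assert (1, "hydrogen_bond") in kinds
        assert (2, "nonspecific") in kinds


class TestSASA:
    def test_single_atom_closed_form(self):
        st, a, _ = cloud_structure([[0, 0, 0]], [[99, 99, 99]], element="S",
                                   res_name="CYS", atom_name="SG")
        res = sasa(a)
        exact = 4 * np.pi * (1.8 + 1.4) ** 2
        assert res.total == pytest.approx(exact, rel=1e-12)  # no neighbours: exact

    @pytest.mark.parametrize("d", [2.0, 3.0, 4.0, 5.0])
    def test_two_spheres_match_cap_formula(self, d):
        st, a, b = cloud_structure([[0, 0, 0]], [[d, 0, 0]])
        both = a.union(b)
        got = sasa(both, n_points=2000).total
        want = two_sphere_sasa_analytic(1.7, 1.7, d, 1.4)
        assert got == pytest.approx(want, rel=0.01)

    def test_deterministic_bit_exact(self):
        rng = np.random.default_rng(31)
        pts = rng.uniform(0, 10, size=(40, 3))
        st, a, _ = cloud_structure(pts, [[99, 99, 99]])
        r1 = sasa(a).atom_areas
        r2 = sasa(a).atom_areas
        assert (r1 == r2).all()

    def test_monotone_under_added_context(self):
        """Adding surrounding atoms never increases any atom's area."""
        rng = np.random.default_rng(32)
        for _ in range(20):
            core = rng.uniform(0, 8, size=(15, 3))
            extra = rng.uniform(0, 8, size=(10, 3))
            st, a, b = cloud_structure(core, extra)
            alone = sasa(a).atom_areas
            together = sasa(a.union(b))
            pos = {int(g): k for k, g in enumerate(together.indices)}
            in_ctx = np.array([together.atom_areas[pos[int(g)]] for g in a.indices])
            assert (in_ctx <= alone + 1e-9).all()

    def test_union_subadditive(self):
        rng = np.random.default_rng(33)
        ca = rng.uniform(0, 6, size=(10, 3))
        cb = rng.uniform(3, 9, size=(10, 3))
        st, a, b = cloud_structure(ca, cb)
        assert sasa(a.union(b)).total <= sasa(a).total + sasa(b).total + 1e-9

    def test_matches_independent_implementation(self):
        """Totals agree with biotite's Shrake–Rupley on a random cloud."""
        struc = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(5)
        n = 30
        arr = struc.AtomArray(n)
        arr.coord = rng.uniform(0, 10, (n, 3)).astype(np.float32)
        arr.element = np.array(["C"] * n)
        arr.atom_name = np.array(["CA"] * n)
        arr.res_name = np.array(["ALA"] * n)
        arr.res_id = np.arange(1, n + 1)
        arr.chain_id = np.array(["A"] * n)
        theirs = struc.sasa(arr, vdw_radii="Single", point_number=960).sum()
        st, a, _ = cloud_structure(arr.coord.astype(float), [[99, 99, 99]])
        assert sasa(a).total == pytest.approx(theirs, rel=1e-3)

    def test_unknown_element_raises_without_fallback(self):
        st, a, _ = cloud_structure([[0, 0, 0]], [[9, 9, 9]], element="Xx")
        with pytest.raises(ValueError, match="Xx"):
            sasa(a)
        assert sasa(a, fallback_radius=1.8).total > 0


class TestInterfaceArea:
    def test_distant_bodies_zero(self):
        st, a, b = cloud_structure([[0, 0, 0]], [[50, 0, 0]])
        assert interface_area(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(34)
        ca = rng.uniform(0, 6, size=(12, 3))
        cb = rng.uniform(4, 10, size=(12, 3))
        st, a, b = cloud_structure(ca, cb)
        ab = interface_area(a, b)
        ba = interface_area(b, a)
        assert ab == pytest.approx(ba, abs=1e-9)
        assert ab >= 0


class TestOcclusion:
    def test_distant_occluder_zero(self):
        st, core, occ = cloud_structure([[0, 0, 0]], [[500, 0, 0]])
        assert occlusion_fraction(core, occ) == pytest.approx(0.0, abs=1e-9)

    def test_engulfing_shell_fully_occludes(self):
        """A closed shell of atoms around a single atom buries it entirely."""
        shell_dirs = fibonacci_lattice(400)
        shell = 3.2 * shell_dirs  # shell spheres overlap: no probe can pass
        st, core, occ = cloud_structure([[0, 0, 0]], shell)
        frac = occlusion_fraction(core, occ)
        assert frac == pytest.approx(1.0, abs=0.01)


class TestSequons:
    def test_basic_and_proline_exclusion(self):
        assert find_sequons("NGS") == [0]
        assert find_sequons("NPS") == []
        assert find_sequons("NXT") == [0]

    def test_invalid_characters(self):
        with pytest.raises(ValueError):
            find_sequons("NG1")

    def test_matches_regex_oracle(self):
        rng = np.random.default_rng(35)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        pat = re.compile(r"(?=N[^P][ST])")
        for _ in range(25):
            seq = "".join(rng.choice(alphabet, size=200))
            assert find_sequons(seq) == [m.start() for m in pat.finditer(seq)]
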