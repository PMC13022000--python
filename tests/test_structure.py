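"""Pocket extraction, clash QC and amino-acid enrichment."""

import math

import numpy as np
import pytest

from erepoc import fixtures
from erepoc.structure import (
    AtomRecord,
    ClashReport,
    NoLigandError,
    PDB_AA_FREQUENCIES,
    PocketDefinition,
    aa_enrichment,
    clash_report,
    extract_pocket_distance,
    extract_pocket_vdw,
    ligand_groups,
    parse_structure,
    passes_clash_filter,
    vdw_radius,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   5.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   5.000   0.000  1.00  0.00           C
ATOM      3  N   GLY A   2       0.000   8.000   0.000  1.00  0.00           N
ATOM      4  CA  GLY A   2       1.000   8.000   0.000  1.00  0.00           C
HETATM    5  C1  LIG A   3       0.000   0.000   0.000  1.00  0.00           C
HETATM    6  C2  LIG A   3       1.500   0.000   0.000  1.00  0.00           C
END
"""

WATER_ONLY_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
HETATM    3  O   HOH A   3       6.000   0.000   0.000  1.00  0.00           O
END
"""


def _atom(x, y, z, element="C", chain="A", resnum=1, resname="ALA",
          is_ligand=False, is_hydrogen=False):
    return AtomRecord(element=element, coords=(float(x), float(y), float(z)),
                      residue_key=(chain, resnum, ""), residue_name=resname,
                      is_ligand=is_ligand, is_hydrogen=is_hydrogen)


def _brute_force_distance_pocket(atoms, cutoff):
    """All-pairs scan, independent of the vectorised implementation."""
    lig = [a for a in atoms if a.is_ligand and not a.is_hydrogen]
    members = set()
    for a in atoms:
        if a.is_ligand or a.is_hydrogen or a.residue_name in ("HOH", "WAT"):
            continue
        for b in lig:
            d = math.dist(a.coords, b.coords)
            if d <= cutoff:
                members.add(a.residue_key)
                break
    return members


def _brute_force_vdw_pocket(atoms, pad, min_contacts):
    lig = [a for a in atoms if a.is_ligand and not a.is_hydrogen]
    counts = {}
    for a in atoms:
        if a.is_ligand or a.is_hydrogen or a.residue_name in ("HOH", "WAT"):
            continue
        for b in lig:
            if math.dist(a.coords, b.coords) <= vdw_radius(a.element) + vdw_radius(b.element) + pad:
                counts[a.residue_key] = counts.get(a.residue_key, 0) + 1
    return {k for k, c in counts.items() if c >= min_contacts}


class TestParsing:
    def test_minimal_structure_counts(self):
        atoms = parse_structure(MINIMAL_PDB, fmt="pdb")
        polymer_residues = {a.residue_key for a in atoms if not a.is_ligand}
        assert len(polymer_residues) == 2
        assert len(ligand_groups(atoms)) == 1
        assert sum(a.is_ligand for a in atoms) == 2

    def test_waters_are_not_ligands(self):
        atoms = parse_structure(WATER_ONLY_PDB, fmt="pdb")
        assert ligand_groups(atoms) == {}
        with pytest.raises(NoLigandError):
            extract_pocket_distance(atoms)

    def test_fixture_round_trip_preserves_coordinates(self):
        fx = fixtures.make_structure(n_residues=20, seed=11)
        atoms = parse_structure(fx.pdb_text, fmt="pdb")
        assert len(atoms) == 20 * 3 + 4
        lig = [a for a in atoms if a.is_ligand]
        np.testing.assert_allclose(
            sorted(tuple(a.coords) for a in lig),
            sorted(map(tuple, fx.ligand_coords.round(3))),
            atol=1e-3,
        )

    def test_unparseable_input_raises_format_error(self):
        from erepoc.structure import StructureFormatError

        with pytest.raises((StructureFormatError, ValueError)):
            parse_structure("", fmt="pdb")


class TestDistanceRule:
    def test_boundary_residues(self):
        atoms = [
            _atom(0, 0, 0, is_ligand=True, resname="LIG", resnum=10),
            _atom(4.9, 0, 0, resnum=1),
            _atom(5.1, 0, 0, resnum=2),
        ]
        pocket = extract_pocket_distance(atoms, ("LIG", "A", 10), cutoff=5.0)
        assert pocket.residue_keys == (("A", 1, ""),)

    def test_monotone_in_cutoff(self):
        fx = fixtures.make_structure(n_residues=30, seed=3)
        atoms = parse_structure(fx.pdb_text, fmt="pdb")
        p5 = set(extract_pocket_distance(atoms, fx.ligand_id, cutoff=5.0).residue_keys)
        p6 = set(extract_pocket_distance(atoms, fx.ligand_id, cutoff=6.0).residue_keys)
        assert p5 <= p6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("cutoff", [4.0, 5.0, 7.5])
    def test_matches_brute_force_oracle(self, seed, cutoff):
        fx = fixtures.make_structure(n_residues=50, seed=seed)
        atoms = parse_structure(fx.pdb_text, fmt="pdb")
        pocket = extract_pocket_distance(atoms, fx.ligand_id, cutoff=cutoff)
        assert set(pocket.residue_keys) == _brute_force_distance_pocket(atoms, cutoff)

    def test_rigid_motion_invariance(self):
        fx = fixtures.make_structure(n_residues=40, seed=5)
        atoms = parse_structure(fx.pdb_text, fmt="pdb")
        before = extract_pocket_distance(atoms, fx.ligand_id).residue_keys

        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)  # random rotation (up to reflection)
        t = rng.normal(scale=50.0, size=3)
        moved = [
            AtomRecord(element=a.element, coords=tuple(Q @ np.array(a.coords) + t),
                       residue_key=a.residue_key, residue_name=a.residue_name,
                       is_ligand=a.is_ligand, is_hydrogen=a.is_hydrogen)
            for a in atoms
        ]
        assert extract_pocket_distance(moved, fx.ligand_id).residue_keys == before

    def test_empty_pocket_is_returned_not_raised(self):
        atoms = [
            _atom(0, 0, 0, is_ligand=True, resname="LIG", resnum=10),
            _atom(50, 0, 0, resnum=1),
            _atom(60, 0, 0, resnum=2),
        ]
        pocket = extract_pocket_distance(atoms, ("LIG", "A", 10))
        assert len(pocket) == 0


class TestVdwRule:
    def test_min_contacts_boundary(self):
        # two C–C contacts at 3.8 Å (limit 1.70+1.70+0.5 = 3.90) -> included
        lig = [_atom(0, 0, 0, is_ligand=True, resname="LIG", resnum=10)]
        res_two = [_atom(3.8, 0, 0, resnum=1), _atom(-3.8, 0, 0, resnum=1)]
        pocket = extract_pocket_vdw(lig + res_two, ("LIG", "A", 10))
        assert pocket.residue_keys == (("A", 1, ""),)

        res_one = [_atom(3.8, 0, 0, resnum=1), _atom(0, 30, 0, resnum=1)]
        pocket = extract_pocket_vdw(lig + res_one, ("LIG", "A", 10))
        assert len(pocket) == 0

    def test_closed_boundary_at_zero_pad(self):
        # exactly at r_C + r_C = 3.40 Å with pad 0: counted (closed boundary)
        atoms = [
            _atom(0, 0, 0, is_ligand=True, resname="LIG", resnum=10),
            _atom(3.4, 0, 0, resnum=1),
            _atom(-3.4, 0, 0, resnum=1),
        ]
        pocket = extract_pocket_vdw(atoms, ("LIG", "A", 10), pad=0.0)
        assert pocket.residue_keys == (("A", 1, ""),)

    def test_unknown_element_is_named_in_error(self):
        atoms = [
            _atom(0, 0, 0, is_ligand=True, resname="LIG", resnum=10),
            _atom(3, 0, 0, element="XQ", resnum=1),
        ]
        with pytest.raises(KeyError, match="XQ"):
            extract_pocket_vdw(atoms, ("LIG", "A", 10))

    @pytest.mark.parametrize("seed", [7, 8])
    def test_matches_brute_force_oracle(self, seed):
        fx = fixtures.make_structure(n_residues=50, seed=seed, min_distance=2.5,
                                     max_distance=6.0)
        atoms = parse_structure(fx.pdb_text, fmt="pdb")
        pocket = extract_pocket_vdw(atoms, fx.ligand_id)
        assert set(pocket.residue_keys) == _brute_force_vdw_pocket(atoms, 0.5, 2)


class TestClash:
    def test_single_pair_clash(self):
        lig = [_atom(0, 0, 0, is_ligand=True), _atom(1.0, 0, 0, is_ligand=True)]
        poc = [_atom(10, 0, 0), _atom(14, 0, 0, resnum=2)]
        rep = clash_report(poc, lig)
        assert rep.ligand_clash_fraction == 1.0
        assert rep.pocket_clash_fraction == 0.0
        assert rep.cross_clash_count == 0

    def test_no_clashes(self):
        lig = [_atom(0, 0, 0, is_ligand=True), _atom(2.0, 0, 0, is_ligand=True)]
        poc = [_atom(10, 0, 0), _atom(14, 0, 0, resnum=2)]
        rep = clash_report(poc, lig)
        assert (rep.pocket_clash_fraction, rep.ligand_clash_fraction,
                rep.cross_clash_count) == (0.0, 0.0, 0)

    def test_matches_pair_count_oracle_and_permutation_invariance(self):
        rng = np.random.default_rng(42)
        coords = rng.uniform(0, 4, size=(20, 3))
        poc = [_atom(*c, resnum=i) for i, c in enumerate(coords[:12])]
        lig = [_atom(*c, is_ligand=True, resname="LIG", resnum=99) for c in coords[12:]]
        rep = clash_report(poc, lig)

        def n_close(group_a, group_b=None):
            if group_b is None:
                pts = [a.coords for a in group_a]
                return sum(math.dist(pts[i], pts[j]) < 1.2
                           for i in range(len(pts)) for j in range(i + 1, len(pts)))
            return sum(math.dist(a.coords, b.coords) < 1.2
                       for a in group_a for b in group_b)

        n_pocket_pairs = 12 * 11 // 2
        n_ligand_pairs = 8 * 7 // 2
        assert rep.pocket_clash_fraction == n_close(poc) / n_pocket_pairs
        assert rep.ligand_clash_fraction == n_close(lig) / n_ligand_pairs
        assert rep.cross_clash_count == n_close(poc, lig)

        shuffled = clash_report(poc[::-1], lig[::-1])
        assert shuffled == rep

    def test_hydrogens_excluded(self):
        lig = [_atom(0, 0, 0, is_ligand=True), _atom(2.0, 0, 0, is_ligand=True),
               _atom(0.5, 0, 0, element="H", is_ligand=True, is_hydrogen=True)]
        poc = [_atom(10, 0, 0), _atom(14, 0, 0, resnum=2)]
        assert clash_report(poc, lig).ligand_clash_fraction == 0.0


class TestClashFilter:
    @pytest.mark.parametrize("report,expected", [
        ((0.004, 0.009, 4), True),    # strictly below all thresholds
        ((0.005, 0.0, 0), False),     # pocket fraction at the boundary
        ((0.0, 0.01, 0), False),      # ligand fraction at the boundary
        ((0.0, 0.0, 5), False),       # cross count at the boundary
        ((0.0, 0.0, 0), True),
        ((0.0049, 0.0099, 4), True),
    ])
    def test_boundaries(self, report, expected):
        rep = ClashReport(*report)
        assert passes_clash_filter(rep) is expected


class TestAaEnrichment:
    def _pocket(self, names):
        residues = tuple((("A", i + 1, ""), n) for i, n in enumerate(names))
        return PocketDefinition("s", ("LIG", "A", 99), residues, "distance_5A")

    def test_identity_composition(self):
        # composition proportional to the reference -> all ratios 1
        counts = {aa: max(1, round(f * 1000)) for aa, f in PDB_AA_FREQUENCIES.items()}
        names = [aa for aa, c in counts.items() for _ in range(c)]
        ref = {aa: c / len(names) for aa, c in counts.items()}
        ratios = aa_enrichment([self._pocket(names)], ref)
        for aa in ratios:
            assert ratios[aa] == pytest.approx(1.0)

    def test_degenerate_single_aa(self):
        ref = dict.fromkeys(PDB_AA_FREQUENCIES, (1.0 - 0.02) / 19)
        ref["MET"] = 0.02  # reference MET frequency 2%
        ratios = aa_enrichment([self._pocket(["MET"] * 5)], ref)
        assert ratios["MET"] == pytest.approx(50.0)
        assert all(ratios[aa] == 0.0 for aa in ratios if aa != "MET")

    def test_matches_hand_tally(self):
        rng = np.random.default_rng(1)
        aas = list(PDB_AA_FREQUENCIES)
        names = [aas[i] for i in rng.integers(0, 20, size=200)]
        pockets = [self._pocket(names[:120]), self._pocket(names[120:])]
        ratios = aa_enrichment(pockets)
        from collections import Counter

        tally = Counter(names)
        for aa in aas:
            expected = (tally[aa] / 200) / PDB_AA_FREQUENCIES[aa]
            assert ratios[aa] == pytest.approx(expected)

    def test_nonstandard_residues_excluded(self):
        ratios = aa_enrichment([self._pocket(["MET", "MSE", "ALA"])])
        total = sum(r * PDB_AA_FREQUENCIES[aa] for aa, r in ratios.items())
        assert total == pytest.approx(1.0)  # frequencies over the 2 standard residues
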