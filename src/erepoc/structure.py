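"""Binding-pocket extraction from protein–ligand complex structures.

A binding pocket is the set of protein residues in spatial proximity to a
bound ligand.  Two extraction rules are supported:

* ``distance``: a residue belongs to the pocket if any of its non-hydrogen
  atoms lies within a fixed cutoff (default 5.0 Å) of any non-hydrogen
  ligand atom.
* ``vdw``: a residue belongs to the pocket if at least ``min_contacts``
  (default 2) atom pairs (residue atom, ligand atom) are separated by no
  more than the sum of their van der Waals radii plus a pad (default
  0.5 Å) — the BioLiP-style binding-residue criterion.

The module also implements a steric-clash quality filter for computationally
transplanted complexes: clash fractions within the pocket and within the
ligand, plus the count of pocket–ligand clashes, with discard thresholds
0.005 / 0.01 / 5 respectively.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Bondi-style van der Waals radii in Å.  Elements absent from the table
#: fall back to METAL_FALLBACK_RADIUS only when ``strict=False``.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "B": 1.92, "SE": 1.90,
    "SI": 2.10,
}
METAL_FALLBACK_RADIUS = 2.0

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: Single-element HET groups treated as metals / ions, never ligands.
METAL_NAMES = {
    "NA", "K", "MG", "CA", "ZN", "FE", "MN", "CU", "CO", "NI", "CD", "HG",
    "CL", "BR", "IOD", "F", "LI", "SR", "BA", "CS", "RB", "AL", "PB", "PT",
    "AU", "AG", "MO", "W", "V",
}

STANDARD_AA = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: Default background amino-acid proportions (PDB-wide composition) used to
#: normalise pocket composition into enrichment ratios.
PDB_AA_FREQUENCIES: dict[str, float] = {
    "ALA": 0.0826, "ARG": 0.0553, "ASN": 0.0406, "ASP": 0.0546,
    "CYS": 0.0137, "GLN": 0.0393, "GLU": 0.0675, "GLY": 0.0707,
    "HIS": 0.0227, "ILE": 0.0596, "LEU": 0.0966, "LYS": 0.0584,
    "MET": 0.0242, "PHE": 0.0386, "PRO": 0.0470, "SER": 0.0657,
    "THR": 0.0534, "TRP": 0.0109, "TYR": 0.0292, "VAL": 0.0687,
}


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


class NoLigandError(ValueError):
    """Raised when an operation requires a ligand that is absent."""


ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a parsed structure."""

    element: str
    coords: tuple[float, float, float]
    residue_key: ResidueKey  # (chain id, author residue number, insertion code)
    residue_name: str
    is_ligand: bool = False
    is_hydrogen: bool = False
    atom_name: str = ""

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError("atom coordinates must be finite")


@dataclass(frozen=True)
class PocketDefinition:
    """A structure's ligand-proximal residue set under a named rule."""

    structure_id: str
    ligand_id: tuple[str, str, int]  # (HET code, chain, residue number)
    residues: tuple[tuple[ResidueKey, str], ...]  # ordered, unique
    rule: str  # "distance_5A"-style tag
    params: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        keys = [k for k, _ in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("pocket residues must be unique")

    @property
    def residue_keys(self) -> tuple[ResidueKey, ...]:
        return tuple(k for k, _ in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ClashReport:
    """Steric-clash summary for one pocket–ligand complex."""

    pocket_clash_fraction: float
    ligand_clash_fraction: float
    cross_clash_count: int
    threshold: float = 1.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.pocket_clash_fraction <= 1.0):
            raise ValueError("pocket_clash_fraction outside [0, 1]")
        if not (0.0 <= self.ligand_clash_fraction <= 1.0):
            raise ValueError("ligand_clash_fraction outside [0, 1]")
        if self.cross_clash_count < 0:
            raise ValueError("cross_clash_count must be >= 0")


def _is_water(name: str) -> bool:
    return name.strip().upper() in WATER_NAMES


def _is_metal_group(name: str) -> bool:
    return name.strip().upper() in METAL_NAMES


def parse_structure(path_or_text, fmt: str | None = None) -> list[AtomRecord]:
    """Parse a PDB or mmCIF structure into a flat list of :class:`AtomRecord`.

    Parameters
    ----------
    path_or_text
        Path to a structure file, or raw PDB/mmCIF text.
    fmt
        ``"pdb"`` or ``"mmcif"``.  Required when raw text is given; guessed
        from the file suffix otherwise.

    Notes
    -----
    HETATM groups are flagged ``is_ligand`` unless they are waters or
    single-atom metal/ion groups.  For alternate locations only the
    highest-occupancy conformer is kept.
    """
    text, fmt = _read_structure_input(path_or_text, fmt)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        else:
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {fmt} input: {exc}") from exc

    st.setup_entities()
    if len(st) == 0 or len(st[0]) == 0:
        raise StructureFormatError("structure contains no chains")

    records: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            water = _is_water(res.name)
            is_ligand = het and not water and not _is_metal_group(res.name)
            key = (chain.name, res.seqid.num, res.seqid.icode.strip() or "")
            for atom in _best_altloc(res):
                element = atom.element.name.upper()
                records.append(AtomRecord(
                    element=element or atom.name[:1].upper(),
                    coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                    residue_key=key,
                    residue_name=res.name.strip(),
                    is_ligand=is_ligand,
                    is_hydrogen=element in ("H", "D"),
                    atom_name=atom.name,
                ))
    if not records:
        raise StructureFormatError("structure contains no atoms")
    return records


def _read_structure_input(path_or_text, fmt):
    import os

    s = str(path_or_text)
    looks_like_path = "\n" not in s and len(s) < 4096
    if looks_like_path and os.path.exists(s):
        with open(s) as fh:
            text = fh.read()
        if fmt is None:
            low = s.lower()
            fmt = "mmcif" if low.endswith((".cif", ".mmcif", ".cif.gz")) else "pdb"
    else:
        text = s
        if fmt is None:
            raise ValueError("format must be given for raw structure text")
    fmt = fmt.lower()
    if fmt in ("cif", "mmcif"):
        fmt = "mmcif"
    if fmt not in ("pdb", "mmcif"):
        raise ValueError(f"unknown structure format {fmt!r}")
    return text, fmt


def _best_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > prev.occ:
            best[atom.name] = atom
    return [best[n] for n in order]


def ligand_groups(atoms: Sequence[AtomRecord]) -> dict[tuple[str, str, int], list[AtomRecord]]:
    """Group ligand atoms by (HET code, chain, residue number)."""
    groups: dict[tuple[str, str, int], list[AtomRecord]] = {}
    for a in atoms:
        if a.is_ligand:
            lid = (a.residue_name, a.residue_key[0], a.residue_key[1])
            groups.setdefault(lid, []).append(a)
    return groups


def _select_ligand(atoms: Sequence[AtomRecord], ligand_id) -> list[AtomRecord]:
    groups = ligand_groups(atoms)
    if not groups:
        raise NoLigandError("structure contains no candidate ligand (HET) groups")
    if ligand_id is None:
        if len(groups) > 1:
            raise NoLigandError(
                f"ambiguous: {len(groups)} ligand groups present, specify ligand_id"
            )
        return next(iter(groups.values()))
    if ligand_id not in groups:
        raise NoLigandError(f"ligand {ligand_id} not found; present: {sorted(groups)}")
    return groups[ligand_id]


def _protein_heavy_atoms(atoms, ligand_key):
    return [
        a for a in atoms
        if not a.is_ligand and not a.is_hydrogen
        and not _is_water(a.residue_name) and not _is_metal_group(a.residue_name)
        and a.residue_key != ligand_key
    ]


def extract_pocket_distance(
    atoms: Sequence[AtomRecord],
    ligand_id=None,
    cutoff: float = 5.0,
    structure_id: str = "",
) -> PocketDefinition:
    """Extract the pocket of all residues within ``cutoff`` Å of the ligand.

    A residue is included iff any of its non-hydrogen atoms lies within
    ``cutoff`` (closed boundary, d <= cutoff) of any non-hydrogen ligand
    atom.  Residue order is deterministic (sorted by residue key).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig = [a for a in _select_ligand(atoms, ligand_id) if not a.is_hydrogen]
    lig_key = lig[0].residue_key
    lid = (lig[0].residue_name, lig_key[0], lig_key[1])
    prot = _protein_heavy_atoms(atoms, lig_key)

    members: dict[ResidueKey, str] = {}
    if prot and lig:
        pcoords = np.asarray([a.coords for a in prot])
        lcoords = np.asarray([a.coords for a in lig])
        d2 = np.sum((pcoords[:, None, :] - lcoords[None, :, :]) ** 2, axis=2)
        near = np.min(d2, axis=1) <= cutoff * cutoff
        for a, hit in zip(prot, near):
            if hit:
                members.setdefault(a.residue_key, a.residue_name)
    if not members:
        logger.warning("empty pocket for ligand %s at cutoff %.2f Å", lid, cutoff)
    residues = tuple(sorted(members.items()))
    return PocketDefinition(
        structure_id=structure_id,
        ligand_id=lid,
        residues=residues,
        rule="distance_5A" if cutoff == 5.0 else f"distance_{cutoff:g}A",
        params={"cutoff": cutoff},
    )


def vdw_radius(element: str, strict: bool = True) -> float:
    el = element.strip().upper()
    if el in VDW_RADII:
        return VDW_RADII[el]
    if strict:
        raise KeyError(f"element {element!r} has no van der Waals radius in the bundled table")
    return METAL_FALLBACK_RADIUS


def extract_pocket_vdw(
    atoms: Sequence[AtomRecord],
    ligand_id=None,
    pad: float = 0.5,
    min_contacts: int = 2,
    structure_id: str = "",
) -> PocketDefinition:
    """Extract a pocket under the van-der-Waals-contact binding-residue rule.

    A residue is included iff at least ``min_contacts`` distinct atom pairs
    (residue atom, ligand atom) satisfy d <= r_vdw(a) + r_vdw(b) + pad.
    Comparisons use non-hydrogen atoms on both sides; the boundary is closed.
    """
    if pad < 0:
        raise ValueError("pad must be non-negative")
    if min_contacts < 1:
        raise ValueError("min_contacts must be >= 1")
    lig = [a for a in _select_ligand(atoms, ligand_id) if not a.is_hydrogen]
    lig_key = lig[0].residue_key
    lid = (lig[0].residue_name, lig_key[0], lig_key[1])
    prot = _protein_heavy_atoms(atoms, lig_key)

    members: dict[ResidueKey, str] = {}
    if prot and lig:
        pcoords = np.asarray([a.coords for a in prot])
        lcoords = np.asarray([a.coords for a in lig])
        pr = np.asarray([vdw_radius(a.element) for a in prot])
        lr = np.asarray([vdw_radius(a.element) for a in lig])
        d = np.sqrt(np.sum((pcoords[:, None, :] - lcoords[None, :, :]) ** 2, axis=2))
        contact = d <= (pr[:, None] + lr[None, :] + pad)
        counts: dict[ResidueKey, int] = {}
        names: dict[ResidueKey, str] = {}
        for a, n in zip(prot, contact.sum(axis=1)):
            counts[a.residue_key] = counts.get(a.residue_key, 0) + int(n)
            names[a.residue_key] = a.residue_name
        members = {k: names[k] for k, c in counts.items() if c >= min_contacts}
    residues = tuple(sorted(members.items()))
    return PocketDefinition(
        structure_id=structure_id,
        ligand_id=lid,
        residues=residues,
        rule="vdw_pad",
        params={"pad": pad, "min_contacts": min_contacts},
    )


def _clash_fraction(coords: np.ndarray, threshold: float) -> float:
    n = len(coords)
    if n < 2:
        return 0.0  # single-atom group: no pairs, fraction 0 by convention
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    iu = np.triu_indices(n, k=1)
    clashes = int(np.count_nonzero(d2[iu] < threshold * threshold))
    return clashes / len(iu[0])


def clash_report(
    pocket_atoms: Sequence[AtomRecord],
    ligand_atoms: Sequence[AtomRecord],
    threshold: float = 1.2,
) -> ClashReport:
    """Count steric clashes (non-hydrogen pairs closer than ``threshold`` Å).

    The pocket and ligand clash fractions are the fraction of intra-group
    atom pairs closer than the threshold; the cross count is the number of
    pocket–ligand pairs closer than the threshold.
    """
    pocket = [a for a in pocket_atoms if not a.is_hydrogen]
    ligand = [a for a in ligand_atoms if not a.is_hydrogen]
    if not pocket or not ligand:
        raise ValueError("pocket and ligand atom lists must be non-empty")
    pc = np.asarray([a.coords for a in pocket])
    lc = np.asarray([a.coords for a in ligand])
    cross_d2 = np.sum((pc[:, None, :] - lc[None, :, :]) ** 2, axis=2)
    return ClashReport(
        pocket_clash_fraction=_clash_fraction(pc, threshold),
        ligand_clash_fraction=_clash_fraction(lc, threshold),
        cross_clash_count=int(np.count_nonzero(cross_d2 < threshold * threshold)),
        threshold=threshold,
    )


def passes_clash_filter(
    report: ClashReport,
    max_pocket_fraction: float = 0.005,
    max_ligand_fraction: float = 0.01,
    max_cross_count: int = 5,
) -> bool:
    """Quality filter for transplanted complexes.

    A complex is kept iff its pocket clash fraction is strictly below 0.005,
    its ligand clash fraction strictly below 0.01 and its pocket–ligand
    clash count strictly below 5 (values at a threshold are discarded).
    """
    return (
        report.pocket_clash_fraction < max_pocket_fraction
        and report.ligand_clash_fraction < max_ligand_fraction
        and report.cross_clash_count < max_cross_count
    )


def aa_enrichment(
    pockets: Iterable[PocketDefinition],
    reference_freq: dict[str, float] | None = None,
) -> dict[str, float]:
    """Amino-acid enrichment ratios of pooled pocket composition.

    For each of the 20 standard amino acids the ratio is the pooled pocket
    frequency divided by the background frequency (default: PDB-wide
    composition).  Non-standard residue names are excluded with a logged
    count.
    """
    ref = dict(reference_freq) if reference_freq is not None else dict(PDB_AA_FREQUENCIES)
    total_ref = sum(ref.values())
    if any(v <= 0 for v in ref.values()) or not (0.98 <= total_ref <= 1.02):
        raise ValueError("reference frequencies must be positive and sum to ~1")

    counts = {aa: 0 for aa in STANDARD_AA}
    skipped = 0
    for pocket in pockets:
        for _, name in pocket.residues:
            if name in counts:
                counts[name] += 1
            else:
                skipped += 1
    if skipped:
        logger.info("aa_enrichment: excluded %d non-standard residues", skipped)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no standard residues in the supplied pockets")
    return {aa: (counts[aa] / n) / ref[aa] for aa in STANDARD_AA}
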