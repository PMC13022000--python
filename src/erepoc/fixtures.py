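"""Synthetic inputs for fully offline pipelines and tests.

Three generator families, all pure functions of their parameters + seed:

* toy PDB structures with analytically known pocket membership and
  (optionally) planted steric clashes;
* pocket-embedding datasets with planted ligand-class cluster structure and
  matching binary fingerprints, emulating the statistical shape of the
  seven-ligand-type benchmark (7 classes, 1280-d features, 2048-bit
  fingerprints);
* two-group docking-score pools with a stated location shift, emulating an
  enriched-vs-neutral virtual-screening comparison.

The generators emulate cluster structure and noise, not real protein or
chemical geometry; see the methods note for what that implies.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .chem import N_BITS
from .benchmark import LIGAND_TYPES

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


# ---------------------------------------------------------------------------
# toy structures


@dataclass
class StructureFixture:
    pdb_text: str
    #: residue key -> minimum heavy-atom distance to any ligand atom (Å),
    #: computed from the generating coordinates
    residue_min_distance: dict[tuple[str, int, str], float]
    ligand_id: tuple[str, str, int]
    ligand_coords: np.ndarray
    residue_names: dict[tuple[str, int, str], str]

    def pocket_members(self, cutoff: float = 5.0) -> set[tuple[str, int, str]]:
        """Ground-truth membership under the distance rule (closed boundary)."""
        return {k for k, d in self.residue_min_distance.items() if d <= cutoff}


def _pdb_atom_line(serial, name, resname, chain, resnum, x, y, z, element, hetatm=False):
    record = "HETATM" if hetatm else "ATOM  "
    # PDB fixed columns: serial 7-11, name 13-16, altLoc 17, resName 18-20,
    # chain 22, resSeq 23-26, iCode 27, x/y/z 31-54, occ 55-60, B 61-66,
    # element 77-78
    return (f"{record}{serial:>5} {name:<4} {resname:>3} {chain}{resnum:>4} "
            f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}")


def make_structure(n_residues: int = 10, ligand_atoms: int = 4, seed: int = 0,
                   min_distance: float = 3.0, max_distance: float = 12.0,
                   clash_pair_distance: float | None = None) -> StructureFixture:
    """Generate a minimal PDB with known pocket geometry.

    The ligand is a small carbon cluster near the origin; each residue is a
    three-atom (N, CA, C) group whose nearest atom sits at a known distance
    from the ligand, drawn uniformly from [min_distance, max_distance].
    With ``clash_pair_distance`` set, two ligand atoms are planted exactly
    that far apart (for clash-detection tests).
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if ligand_atoms < 1:
        raise ValueError("need at least 1 ligand atom")
    rng = np.random.default_rng(seed)

    # ligand: a jittered carbon chain with ~1.5 Å bonds (no accidental clashes)
    lig = np.column_stack([
        1.5 * np.arange(ligand_atoms),
        rng.uniform(-0.2, 0.2, size=ligand_atoms),
        rng.uniform(-0.2, 0.2, size=ligand_atoms),
    ]).astype(float)
    lig -= lig.mean(axis=0)
    if clash_pair_distance is not None:
        if ligand_atoms < 2:
            raise ValueError("clash pair needs at least 2 ligand atoms")
        lig[1] = lig[0] + (clash_pair_distance, 0.0, 0.0)

    lines = []
    serial = 1
    residue_min_distance: dict[tuple[str, int, str], float] = {}
    residue_names: dict[tuple[str, int, str], str] = {}
    for i in range(n_residues):
        target_d = rng.uniform(min_distance, max_distance)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        # place CA so that the *nearest* residue atom realizes target_d:
        # the nearest ligand atom along `direction` from the centroid
        centroid = lig.mean(axis=0)
        base = centroid + direction * (target_d + 8.0)  # provisional
        # local residue geometry: N, CA, C offsets (~1.5 Å spacing)
        offsets = np.array([[-1.2, 0.3, 0.0], [0.0, 0.0, 0.0], [1.2, -0.3, 0.0]])
        # shift the residue along `direction` until min distance == target_d
        atoms = base + offsets
        d = np.min(np.linalg.norm(atoms[:, None, :] - lig[None, :, :], axis=2))
        atoms = atoms - direction * (d - target_d)
        d_real = float(np.min(np.linalg.norm(atoms[:, None, :] - lig[None, :, :], axis=2)))

        letter = AA_LETTERS[int(rng.integers(len(AA_LETTERS)))]
        resname = _ONE_TO_THREE[letter]
        key = ("A", i + 1, "")
        residue_min_distance[key] = d_real
        residue_names[key] = resname
        for name, el, pos in zip(("N", "CA", "C"), ("N", "C", "C"), atoms):
            lines.append(_pdb_atom_line(serial, name, resname, "A", i + 1,
                                        pos[0], pos[1], pos[2], el))
            serial += 1

    for j, pos in enumerate(lig):
        lines.append(_pdb_atom_line(serial, f"C{j + 1}", "LIG", "A", n_residues + 1,
                                    pos[0], pos[1], pos[2], "C", hetatm=True))
        serial += 1
    lines.append("END")

    return StructureFixture(
        pdb_text="\n".join(lines) + "\n",
        residue_min_distance=residue_min_distance,
        ligand_id=("LIG", "A", n_residues + 1),
        ligand_coords=lig,
        residue_names=residue_names,
    )


# ---------------------------------------------------------------------------
# embedding datasets with planted ligand-class structure


@dataclass
class FixtureSpec:
    """Parameters of the planted-cluster embedding/fingerprint generator.

    Defaults emulate the seven-ligand-type benchmark at desk scale:
    7 classes of 200 pockets each in 1280 dimensions, unit-norm class
    centers with per-coordinate noise sigma 1/sqrt(dim) (within-class raw
    cosine ≈ 0.5), fingerprints built from 64 class-specific + 32 shared
    bits with a 1% per-bit flip rate.
    """

    n_pockets: int = 1400
    n_classes: int = 7
    embedding_dim: int = 1280
    class_center_scale: float = 1.0
    noise_sigma: float | None = None  # default 1/sqrt(embedding_dim)
    bits_per_class: int = 64
    shared_bits: int = 32
    flip_rate: float = 0.01
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.embedding_dim <= 0 or self.n_pockets <= 0:
            raise ValueError("dimensions must be positive")
        if self.shared_bits + self.n_classes * self.bits_per_class > N_BITS:
            raise ValueError("fingerprint templates exceed the bit vector; "
                             "reduce bits_per_class or shared_bits")

    @property
    def sigma(self) -> float:
        return self.noise_sigma if self.noise_sigma is not None \
            else 1.0 / np.sqrt(self.embedding_dim)


@dataclass
class EmbeddingDataset:
    embeddings: np.ndarray  # n × dim
    fingerprints: np.ndarray  # n × 2048 uint8
    labels: np.ndarray  # n class names
    spec: FixtureSpec
    metadata: dict = field(default_factory=dict)


def make_embedding_dataset(spec: FixtureSpec) -> EmbeddingDataset:
    """Planted-cluster pocket embeddings with matching fingerprints.

    Class k draws embeddings from a Gaussian cloud around a random
    unit-norm center (scaled by ``class_center_scale``) and fingerprints
    from a class bit template (``bits_per_class`` class-specific bits plus
    ``shared_bits`` bits common to all classes) with independent per-bit
    flips at ``flip_rate``.  Within-class fingerprint similarity exceeds
    between-class similarity by construction; the realized gap is reported
    in ``metadata`` (mean within minus mean between cosine).
    """
    rng = np.random.default_rng(spec.seed)
    dim, K = spec.embedding_dim, spec.n_classes

    centers = rng.normal(size=(K, dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= spec.class_center_scale

    templates = np.zeros((K, N_BITS), dtype=np.uint8)
    templates[:, :spec.shared_bits] = 1
    for k in range(K):
        lo = spec.shared_bits + k * spec.bits_per_class
        templates[k, lo:lo + spec.bits_per_class] = 1

    counts = np.full(K, spec.n_pockets // K)
    counts[: spec.n_pockets % K] += 1
    names = list(LIGAND_TYPES) if K <= len(LIGAND_TYPES) else [f"class{k}" for k in range(K)]

    embeddings = np.empty((spec.n_pockets, dim))
    fingerprints = np.empty((spec.n_pockets, N_BITS), dtype=np.uint8)
    labels = np.empty(spec.n_pockets, dtype=object)
    row = 0
    for k in range(K):
        nk = counts[k]
        embeddings[row:row + nk] = centers[k] + rng.normal(0.0, spec.sigma, size=(nk, dim))
        fp = np.tile(templates[k], (nk, 1))
        if spec.flip_rate > 0:
            flips = rng.random((nk, N_BITS)) < spec.flip_rate
            fp = fp ^ flips.astype(np.uint8)
        fingerprints[row:row + nk] = fp
        labels[row:row + nk] = names[k]
        row += nk

    perm = rng.permutation(spec.n_pockets)
    embeddings, fingerprints, labels = embeddings[perm], fingerprints[perm], labels[perm]

    gap = _similarity_gap(fingerprints, labels)
    return EmbeddingDataset(embeddings=embeddings, fingerprints=fingerprints,
                            labels=np.asarray(labels),
                            spec=spec, metadata={"fingerprint_cosine_gap": gap})


def _similarity_gap(fingerprints: np.ndarray, labels) -> float:
    from .chem import similarity_matrix

    sim = similarity_matrix(fingerprints, metric="cosine")
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    return float(sim[same & off].mean() - sim[~same].mean())


class SyntheticEmbeddingProvider:
    """Deterministic per-residue embedding provider for offline pipelines.

    Each residue's vector is a seeded function of the residue letter plus a
    positional perturbation derived from a hash of the full sequence, so
    identical sequences always embed identically.
    """

    def __init__(self, dim: int = 1280, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self.tag = f"synthetic-d{dim}-s{seed}"
        rng = np.random.default_rng(seed)
        self._letter_vectors = {
            letter: rng.normal(size=dim) for letter in AA_LETTERS + "X"
        }

    def embed(self, sequence: str) -> np.ndarray:
        digest = hashlib.blake2b(f"{self.tag}:{sequence}".encode(),
                                 digest_size=8).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "big"))
        rows = np.stack([self._letter_vectors[ch.upper()] for ch in sequence])
        return rows + 0.1 * rng.normal(size=rows.shape)


# ---------------------------------------------------------------------------
# docking-score pools


def make_docking_scores(n_per_group: int = 5000, shift: float = 1.3,
                        sigma: float = 1.5, mu0: float = -6.15, seed: int = 0):
    """Two-group docking-score table with a planted location shift.

    The neutral group is Normal(mu0, sigma); the enriched group is
    Normal(mu0 − shift, sigma) — more negative, i.e. better predicted
    binding.  Defaults emulate an enriched-vs-neutral screening comparison
    (neutral mean −6.15 kcal/mol, shift 1.3 kcal/mol).
    """
    if n_per_group < 10:
        raise ValueError("need at least 10 compounds per group")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    import pandas as pd

    rng = np.random.default_rng(seed)
    neutral = rng.normal(mu0, sigma, size=n_per_group)
    enriched = rng.normal(mu0 - shift, sigma, size=n_per_group)
    return pd.DataFrame({
        "compound_id": [f"c{i}" for i in range(2 * n_per_group)],
        "target_id": ["enriched_target"] * n_per_group + ["neutral_target"] * n_per_group,
        "score": np.concatenate([enriched, neutral]),
        "group": ["enriched"] * n_per_group + ["neutral"] * n_per_group,
    })
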