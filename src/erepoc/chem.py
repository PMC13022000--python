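"""Ligand fingerprints and pairwise chemical similarity.

Molecules are encoded as 2048-bit radius-2 circular (Morgan/ECFP4)
fingerprints.  Two similarity functions are provided: Tanimoto
(|A∩B| / |A∪B|) and cosine on the binary bit vectors.  The distillation
loss uses cosine by default; Tanimoto is used for the ligand–pocket
correlation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

N_BITS = 2048
RADIUS = 2

_generator = rdFingerprintGenerator.GetMorganGenerator(radius=RADIUS, fpSize=N_BITS)


class SmilesParseError(ValueError):
    pass


@dataclass(frozen=True)
class LigandFingerprint:
    """A 2048-bit circular fingerprint with its canonical SMILES."""

    bits: np.ndarray  # uint8 vector of length 2048
    smiles: str
    ligand_id: str = ""

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.shape != (N_BITS,):
            raise ValueError(f"fingerprint must have exactly {N_BITS} bits")
        object.__setattr__(self, "bits", bits)

    @property
    def on_bits(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.bits).tolist())

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_hex(cls, hexstr: str, smiles: str = "", ligand_id: str = "") -> "LigandFingerprint":
        bits = np.unpackbits(np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8))
        return cls(bits=bits[:N_BITS], smiles=smiles, ligand_id=ligand_id)


def fingerprint(smiles: str, ligand_id: str = "") -> LigandFingerprint:
    """Compute the 2048-bit radius-2 Morgan fingerprint of a SMILES string.

    The molecule is canonicalized first, so any SMILES of the same molecule
    yields a bitwise-identical vector.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    fp = _generator.GetFingerprint(mol)
    bits = np.zeros(N_BITS, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return LigandFingerprint(bits=bits, smiles=canonical, ligand_id=ligand_id)


def _bit_arrays(a, b) -> tuple[np.ndarray, np.ndarray]:
    va = a.bits if isinstance(a, LigandFingerprint) else np.asarray(a, dtype=np.uint8)
    vb = b.bits if isinstance(b, LigandFingerprint) else np.asarray(b, dtype=np.uint8)
    if va.shape != vb.shape:
        raise ValueError("fingerprint lengths differ")
    return va, vb


def tanimoto(a, b) -> float:
    """Tanimoto similarity |A∧B| / |A∨B| of two binary fingerprints.

    Equals 1.0 iff the non-empty bit sets are identical.  Two all-zero
    vectors are defined to have similarity 0 (with a warning).
    """
    va, vb = _bit_arrays(a, b)
    inter = int(np.count_nonzero(va & vb))
    union = int(np.count_nonzero(va | vb))
    if union == 0:
        logger.warning("tanimoto of two empty fingerprints defined as 0")
        return 0.0
    return inter / union


def fp_cosine(a, b) -> float:
    """Cosine similarity of two binary fingerprints (in [0, 1])."""
    va, vb = _bit_arrays(a, b)
    na = int(np.count_nonzero(va))
    nb = int(np.count_nonzero(vb))
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for an all-zero fingerprint")
    inter = int(np.count_nonzero(va & vb))
    return inter / float(np.sqrt(na * nb))


def similarity_matrix(fps, metric: str = "cosine") -> np.ndarray:
    """Pairwise similarity matrix over a list of fingerprints.

    Vectorised over the stacked bit matrix; symmetric with unit diagonal
    (for non-empty fingerprints).
    """
    B = np.stack([fp.bits if isinstance(fp, LigandFingerprint) else np.asarray(fp, dtype=np.uint8)
                  for fp in fps]).astype(np.float64)
    inter = B @ B.T
    popcount = B.sum(axis=1)
    if metric == "cosine":
        denom = np.sqrt(np.outer(popcount, popcount))
    elif metric == "tanimoto":
        denom = popcount[:, None] + popcount[None, :] - inter
    else:
        raise ValueError(f"unknown metric {metric!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, inter / denom, 0.0)
    return sim
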