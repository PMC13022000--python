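"""Per-residue protein embeddings and pocket-level mean pooling.

An embedding provider maps an amino-acid sequence to an L × d matrix of
per-residue features (d = 1280 for the reference 650M protein-language-model
checkpoint).  Providers are pluggable behind a small contract; the package
ships a deterministic synthetic provider (see :mod:`erepoc.fixtures`) for
fully offline pipelines.  Pocket features are the arithmetic mean of the
rows belonging to the pocket residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

EMBED_DIM = 1280

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class ProviderUnavailableError(RuntimeError):
    pass


class EmbeddingProvider(Protocol):
    """Contract for per-residue embedding providers."""

    tag: str
    dim: int

    def embed(self, sequence: str) -> np.ndarray:  # (L, dim)
        ...


@dataclass(frozen=True)
class ResidueEmbeddingMatrix:
    """L × d per-residue embedding matrix for one sequence."""

    values: np.ndarray
    sequence: str
    provider_tag: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[0] != len(self.sequence):
            raise ValueError("row count must equal sequence length")
        if not np.all(np.isfinite(values)):
            raise ValueError("embedding matrix contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PocketEmbedding:
    """Mean-pooled pocket feature vector."""

    vector: np.ndarray
    pocket_id: str
    n_pooled: int

    def __post_init__(self) -> None:
        vector = np.asarray(self.vector, dtype=np.float64)
        if vector.ndim != 1 or not np.all(np.isfinite(vector)):
            raise ValueError("pocket embedding must be a finite 1-d vector")
        if self.n_pooled < 1:
            raise ValueError("n_pooled must be >= 1")
        object.__setattr__(self, "vector", vector)


class Esm2Provider:
    """Reference provider: final-layer representations of the 650M-parameter
    ESM-2 checkpoint (1280-d per residue).

    Requires the ``torch`` and ``fair-esm`` packages and the downloaded
    checkpoint; when they are absent, :meth:`embed` raises with a pointer to
    the synthetic provider for offline use.
    """

    tag = "esm2_t33_650M"
    dim = EMBED_DIM

    def __init__(self) -> None:
        try:
            import esm  # noqa: F401
            import torch  # noqa: F401
        except ImportError as exc:
            raise ProviderUnavailableError(
                "the ESM-2 provider needs the 'torch' and 'fair-esm' packages; "
                "for offline use switch to the synthetic provider "
                "(erepoc.fixtures.SyntheticEmbeddingProvider)"
            ) from exc
        import esm as _esm
        self._model, self._alphabet = _esm.pretrained.esm2_t33_650M_UR50D()
        self._model.eval()

    def embed(self, sequence: str) -> np.ndarray:
        import torch

        _validate_sequence(sequence)
        converter = self._alphabet.get_batch_converter()
        _, _, tokens = converter([("seq", sequence)])
        with torch.no_grad():
            out = self._model(tokens, repr_layers=[33])
        # strip BOS/EOS before residue alignment
        return out["representations"][33][0, 1 : len(sequence) + 1].numpy()


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence cannot be embedded")
    bad = set(sequence.upper()) - set(AA_ALPHABET + "X")
    if bad:
        raise ValueError(f"sequence contains invalid residue letters: {sorted(bad)}")


def embed_sequence(sequence: str, provider: EmbeddingProvider) -> ResidueEmbeddingMatrix:
    """Embed a sequence with the given provider (one row per residue)."""
    _validate_sequence(sequence)
    values = provider.embed(sequence)
    return ResidueEmbeddingMatrix(values=values, sequence=sequence, provider_tag=provider.tag)


def pool_pocket(
    emb: ResidueEmbeddingMatrix,
    residue_indices: Sequence[int],
    pocket_id: str = "",
) -> PocketEmbedding:
    """Mean-pool the selected residues into a pocket feature vector.

    ``residue_indices`` are 1-based sequence positions.  The result is the
    arithmetic mean of the selected rows; it is invariant to index order.
    """
    idx = sorted(set(int(i) for i in residue_indices))
    if not idx:
        raise ValueError("empty pocket cannot be pooled")
    L = len(emb.sequence)
    if idx[0] < 1 or idx[-1] > L:
        raise IndexError(f"residue indices must lie in [1, {L}]")
    rows = emb.values[np.asarray(idx) - 1]
    return PocketEmbedding(vector=rows.mean(axis=0), pocket_id=pocket_id, n_pooled=len(idx))


def map_pocket_to_sequence(
    pocket_residues: Sequence[tuple[tuple[str, int, str], str]],
    numbering: dict[tuple[str, int, str], int],
    sequence: str,
    strict_names: bool = True,
) -> list[int]:
    """Map author-numbered pocket residues to 1-based sequence positions.

    ``numbering`` maps (chain, author number, insertion code) to sequence
    position.  Residues missing from the map are dropped with a warning;
    a residue whose 3-letter name disagrees with the sequence letter at the
    mapped position raises (``strict_names``).
    """
    import logging

    logger = logging.getLogger(__name__)
    out: list[int] = []
    dropped = 0
    for key, name in pocket_residues:
        pos = numbering.get(key)
        if pos is None:
            dropped += 1
            continue
        if not (1 <= pos <= len(sequence)):
            raise IndexError(f"mapped position {pos} outside sequence of length {len(sequence)}")
        expected = THREE_TO_ONE.get(name.upper())
        if strict_names and expected is not None and sequence[pos - 1].upper() not in (expected, "X"):
            raise ValueError(
                f"residue {key} named {name} maps to sequence letter "
                f"{sequence[pos - 1]!r} at position {pos}"
            )
        out.append(pos)
    if dropped:
        logger.warning("map_pocket_to_sequence: dropped %d unmapped residues", dropped)
    if not out:
        raise ValueError("no pocket residues could be mapped to the sequence")
    return sorted(set(out))
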