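"""Cosine-similarity search and proteome-screening filters over latents.

Exhaustive (exact) k-nearest-neighbor search, strict-threshold neighbor
sets, the pocket screening filter (volume ≥ 800 Å³, pocket pLDDT ≥ 0.7,
max reference cosine > 0.8, deduplicated by protein accession), and the
ligand-vs-pocket similarity correlation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chem import similarity_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NeighborHit:
    query_id: str
    reference_id: str
    cosine: float
    rank: int


@dataclass(frozen=True)
class ScreeningRecord:
    """One candidate pocket from a proteome screen."""

    accession: str
    pocket_id: str
    volume: float | None  # Å³
    pocket_plddt: float | None  # accepts 0–1 or 0–100 scale
    max_cosine_to_reference: float

    @property
    def plddt_unit(self) -> float | None:
        """pLDDT normalized to the 0–1 scale."""
        if self.pocket_plddt is None:
            return None
        return self.pocket_plddt / 100.0 if self.pocket_plddt > 1.0 else self.pocket_plddt


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero vector in latent matrix")
    return X / norms


def knn(query_latents: np.ndarray, reference_latents: np.ndarray, k: int = 5,
        query_ids=None, reference_ids=None, exclude_self: bool = True) -> list[list[NeighborHit]]:
    """Exact top-k cosine neighbors of each query among the references.

    Ties are broken by reference id (lexicographic), making the hit lists
    deterministic.  When query and reference sets share pocket ids, exact
    self-matches are excluded (``exclude_self``).
    """
    Q = _normalize_rows(np.atleast_2d(query_latents))
    R = _normalize_rows(np.atleast_2d(reference_latents))
    nq, nr = Q.shape[0], R.shape[0]
    qids = list(query_ids) if query_ids is not None else [f"q{i}" for i in range(nq)]
    rids = list(reference_ids) if reference_ids is not None else [f"r{i}" for i in range(nr)]

    sims = Q @ R.T
    results: list[list[NeighborHit]] = []
    for i in range(nq):
        candidates = [
            (-sims[i, j], rids[j], j) for j in range(nr)
            if not (exclude_self and qids[i] == rids[j])
        ]
        if k > len(candidates):
            raise ValueError(f"k={k} exceeds reference size {len(candidates)}")
        candidates.sort()
        results.append([
            NeighborHit(query_id=qids[i], reference_id=rid,
                        cosine=float(-negsim), rank=rank + 1)
            for rank, (negsim, rid, _) in enumerate(candidates[:k])
        ])
    return results


def threshold_neighbors(similarities: dict | np.ndarray, tau: float = 0.8):
    """Hits with cosine similarity strictly greater than ``tau``.

    Accepts a mapping id → similarity (returns the passing ids) or an
    array (returns the passing indices).
    """
    if not (-1.0 < tau < 1.0):
        raise ValueError("tau must lie in (-1, 1)")
    if isinstance(similarities, dict):
        return {key for key, s in similarities.items() if s > tau}
    sims = np.asarray(similarities, dtype=np.float64)
    return set(np.flatnonzero(sims > tau).tolist())


def screen_pockets(records, min_volume: float = 800.0, min_plddt: float = 0.7,
                   tau: float = 0.8) -> tuple[list[ScreeningRecord], list[str]]:
    """Filter proteome pockets for DEL-screening compatibility.

    A pocket passes iff its volume is at least ``min_volume`` Å³, its mean
    pocket pLDDT at least ``min_plddt`` (0–1 scale) and its best cosine to
    the reference panel strictly greater than ``tau``.  The accession list
    is deduplicated keeping the maximal-cosine pocket per accession.
    Records with missing volume or pLDDT are skipped with a logged count.
    """
    passing: list[ScreeningRecord] = []
    skipped = 0
    for rec in records:
        if rec.volume is None or rec.pocket_plddt is None:
            skipped += 1
            continue
        if (rec.volume >= min_volume and rec.plddt_unit >= min_plddt
                and rec.max_cosine_to_reference > tau):
            passing.append(rec)
    if skipped:
        logger.info("screen_pockets: skipped %d records with missing fields", skipped)

    best: dict[str, ScreeningRecord] = {}
    for rec in passing:
        cur = best.get(rec.accession)
        if cur is None or rec.max_cosine_to_reference > cur.max_cosine_to_reference:
            best[rec.accession] = rec
    accessions = sorted(best, key=lambda acc: (-best[acc].max_cosine_to_reference, acc))
    return passing, accessions


def cosine_gap(latents: np.ndarray, labels, subset_classes=None) -> float:
    """Mean within-class cosine minus mean cross-class cosine.

    With ``subset_classes`` given, within-class pairs are taken inside each
    listed class and cross-class pairs between a listed class and any other
    class (used by the held-out-ligand ablation analysis).
    """
    U = _normalize_rows(np.atleast_2d(latents))
    sim = U @ U.T
    labels = np.asarray(labels)
    off = ~np.eye(len(labels), dtype=bool)
    same = labels[:, None] == labels[None, :]
    if subset_classes is None:
        in_subset = np.ones(len(labels), dtype=bool)
    else:
        in_subset = np.isin(labels, list(subset_classes))
    row_subset = in_subset[:, None] & off
    within = sim[row_subset & same & in_subset[None, :]]
    cross = sim[in_subset[:, None] & ~same]
    if within.size == 0 or cross.size == 0:
        raise ValueError("need both within- and cross-class pairs")
    return float(within.mean() - cross.mean())


def ligand_pocket_correlation(latents: np.ndarray, fingerprints, n_sample: int,
                              seed: int, ligand_metric: str = "tanimoto") -> float:
    """Pearson r between ligand similarity and latent pocket cosine.

    Samples ``n_sample`` pockets with the seeded generator, computes all
    pairwise (ligand similarity, pocket cosine) pairs and returns their
    Pearson correlation.
    """
    latents = np.atleast_2d(np.asarray(latents, dtype=np.float64))
    n = latents.shape[0]
    if n_sample > n:
        raise ValueError(f"n_sample={n_sample} exceeds population {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_sample, replace=False)

    U = _normalize_rows(latents[idx])
    pocket_sim = U @ U.T
    fps = [fingerprints[i] for i in idx]
    lig_sim = similarity_matrix(fps, metric=ligand_metric)

    iu = np.triu_indices(n_sample, k=1)
    x, y = lig_sim[iu], pocket_sim[iu]
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("Pearson correlation undefined for a constant axis")
    r, _ = stats.pearsonr(x, y)
    return float(r)
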