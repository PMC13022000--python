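"""Hypergeometric over-representation analysis of protein classes.

For a hit subset M of an annotated background, the enrichment score of a
class i is the ratio of proportions

    ES_i = (N_i_M / N_i_total) / (N_M / N_total)

and significance is the upper tail of the hypergeometric distribution,
P(X >= N_i_M) with X ~ Hypergeom(N_total, N_i_total, N_M) — a one-sided
test for over-representation.  Multifunctional proteins contribute to every
class they are annotated with, while background totals count each protein
once.  P-values are reported raw (no multiple-testing correction) by
default; Benjamini–Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class ClassCounts:
    """Hit and background counts for one protein class."""

    label: str
    n_class_hits: int  # N_i_M
    n_class_total: int  # N_i_total
    n_hits: int  # N_M
    n_total: int  # N_total

    def __post_init__(self) -> None:
        ok = (
            0 <= self.n_class_hits <= min(self.n_class_total, self.n_hits)
            and self.n_hits <= self.n_total
            and self.n_class_total <= self.n_total
        )
        if not ok:
            raise ValueError(f"inconsistent counts for class {self.label!r}: {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    label: str
    enrichment_score: float
    p_value: float
    counts: ClassCounts
    significant: bool = False


def enrichment_score(c: ClassCounts) -> float:
    """Ratio of the class proportion among hits to its background proportion."""
    if c.n_class_total == 0:
        raise ValueError(f"class {c.label!r} has zero background members")
    if c.n_hits == 0:
        raise ValueError("hit set is empty")
    return (c.n_class_hits / c.n_class_total) / (c.n_hits / c.n_total)


def hypergeom_p(c: ClassCounts, point_mass: bool = False) -> float:
    """Upper-tail hypergeometric p-value P(X >= n_class_hits).

    With ``point_mass=True`` returns the point probability P(X = n_class_hits)
    instead (debug mode; not a hypothesis test).
    """
    dist = stats.hypergeom(c.n_total, c.n_class_total, c.n_hits)
    if point_mass:
        return float(dist.pmf(c.n_class_hits))
    return float(min(1.0, dist.sf(c.n_class_hits - 1)))


def enrich_classes(hits, annotations: dict[str, set[str]] | list[tuple[str, str]],
                   alpha: float = 0.05, bh_correction: bool = False,
                   point_mass: bool = False) -> list[EnrichmentResult]:
    """Enrichment of every annotated class among the hit accessions.

    Parameters
    ----------
    hits
        Iterable of hit accessions (must all appear in the background).
    annotations
        Either accession → set of class labels, or (accession, class) rows.
    alpha
        Significance threshold for the ``significant`` flag.
    bh_correction
        Apply Benjamini–Hochberg to the p-values before flagging (off by
        default; raw p-values are always reported).

    Returns one result per class, sorted by enrichment score descending.
    """
    if not isinstance(annotations, dict):
        ann: dict[str, set[str]] = {}
        for acc, cls in annotations:
            ann.setdefault(acc, set()).add(cls)
    else:
        ann = {acc: set(classes) for acc, classes in annotations.items()}

    hit_set = set(hits)
    missing = hit_set - set(ann)
    if missing:
        raise ValueError(f"hit accessions missing from background: {sorted(missing)}")

    n_total = len(ann)
    n_hits = len(hit_set)
    classes: dict[str, tuple[int, int]] = {}
    for acc, labels in ann.items():
        for cls in labels:
            tot, hit = classes.get(cls, (0, 0))
            classes[cls] = (tot + 1, hit + (1 if acc in hit_set else 0))

    results = []
    for cls, (tot, hit) in classes.items():
        counts = ClassCounts(label=cls, n_class_hits=hit, n_class_total=tot,
                             n_hits=n_hits, n_total=n_total)
        results.append((counts, enrichment_score(counts), hypergeom_p(counts, point_mass)))

    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        _, adjusted, _, _ = multipletests([p for _, _, p in results], method="fdr_bh")
        flags = [p <= alpha for p in adjusted]
    else:
        flags = [p < alpha for _, _, p in results]

    out = [
        EnrichmentResult(label=c.label, enrichment_score=es, p_value=p,
                         counts=c, significant=flag)
        for (c, es, p), flag in zip(results, flags)
    ]
    out.sort(key=lambda r: (-r.enrichment_score, r.label))
    return out
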