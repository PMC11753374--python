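"""Fisher's-exact cluster enrichment and top-partner frequency analysis.

Each (cluster, term) pair yields a 2x2 table over the feature universe:

                 in term    out of term
    in cluster      a            b
    out cluster     c            d

with a two-sided Fisher exact p (probability-mass rule) and Benjamini-
Hochberg q across all tested pairs.  Lipid-class enrichment reuses the same
machinery with parsed lipid classes standing in for annotation terms.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from crossome.correlation import ClusterAssignment, CrossCorrelationMatrix
from crossome.io import AnnotationMap
from crossome.lipids import LipidSpecies

__all__ = [
    "EnrichmentResult",
    "TopPartnerTable",
    "fisher_exact_2x2",
    "enrich_clusters",
    "enrich_lipid_classes",
    "top_partner_frequency",
]


@dataclass
class EnrichmentResult:
    cluster_id: int
    term_id: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    q_value: float = math.nan


@dataclass
class TopPartnerTable:
    """Per-lipid ranked top-|tau| protein partners plus aggregate frequencies."""

    n: int
    ranked: dict[str, list[tuple[str, float]]]
    frequency: Counter = field(default_factory=Counter)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of a 2x2 table.

    Returns ``(odds_ratio, p_value)`` with the sample odds ratio ad/bc
    (infinite when bc = 0 and ad > 0, NaN when both products vanish).  The
    two-sided p sums hypergeometric probabilities of all same-margin tables
    whose probability does not exceed the observed one (standard relative
    tolerance 1e-7).
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("table total must be positive")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.inf if ad > 0 else math.nan
    else:
        odds = ad / bc
    p = float(scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    return odds, min(p, 1.0)


def _bh_qvalues(pvals: Sequence[float]) -> np.ndarray:
    if len(pvals) == 0:
        return np.array([])
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def enrich_clusters(
    assignment: ClusterAssignment,
    terms: Iterable[AnnotationMap],
    universe: set[str],
    min_overlap_count: int = 2,
) -> list[EnrichmentResult]:
    """Fisher enrichment of every cluster against every annotation term.

    Term member sets are intersected with ``universe`` before counting;
    terms disjoint from the universe are skipped with a warning.  Pairs
    with overlap ``a`` below ``min_overlap_count`` are not tested.  q-values
    are BH across all tested (cluster, term) pairs.
    """
    if not universe:
        raise ValueError("empty universe")
    missing = [f for f in assignment.feature_ids if f not in universe]
    if missing:
        raise ValueError(f"clustered features outside universe: {missing[:5]}")
    n_universe = len(universe)

    clusters = {
        cid: set(assignment.members(cid)) for cid in range(1, assignment.n_clusters + 1)
    }
    results: list[EnrichmentResult] = []
    for term in terms:
        members = term.feature_ids & universe
        if not members:
            warnings.warn(f"term {term.term_id!r} disjoint from universe; skipped")
            continue
        for cid, cluster in clusters.items():
            a = len(cluster & members)
            if a < min_overlap_count:
                continue
            b = len(cluster) - a
            c = len(members) - a
            d = n_universe - a - b - c
            odds, p = fisher_exact_2x2(a, b, c, d)
            results.append(EnrichmentResult(cid, term.term_id, a, b, c, d, odds, p))

    qvals = _bh_qvalues([r.p_value for r in results])
    for r, q in zip(results, qvals):
        r.q_value = float(q)
    return results


def enrich_lipid_classes(
    assignment: ClusterAssignment,
    species: Sequence[LipidSpecies],
    min_overlap_count: int = 2,
) -> list[EnrichmentResult]:
    """Enrichment of lipid clusters in lipid classes (classes act as terms)."""
    by_name = {s.raw_name: s for s in species}
    missing = [f for f in assignment.feature_ids if f not in by_name]
    if missing:
        raise ValueError(f"clustered lipids without parsed species: {missing[:5]}")
    universe = set(assignment.feature_ids)
    class_members: dict[str, set[str]] = {}
    for f in assignment.feature_ids:
        class_members.setdefault(by_name[f].lipid_class, set()).add(f)
    terms = [
        AnnotationMap(cls, cls, members) for cls, members in sorted(class_members.items())
    ]
    return enrich_clusters(assignment, terms, universe, min_overlap_count)


def top_partner_frequency(
    m: CrossCorrelationMatrix,
    lipid_subset: Sequence[str],
    n: int = 10,
) -> TopPartnerTable:
    """Per lipid, the n largest-|tau| protein partners; counts over the subset.

    Ties in |tau| break lexicographically by protein id, so the ranking is
    deterministic.  Lipids with all-missing tau are excluded with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    row_of = {f: i for i, f in enumerate(m.lipid_ids)}
    unknown = [f for f in lipid_subset if f not in row_of]
    if unknown:
        raise ValueError(f"lipids not in matrix: {unknown[:5]}")

    proteins = np.asarray(m.protein_ids, dtype=object)
    ranked: dict[str, list[tuple[str, float]]] = {}
    freq: Counter = Counter()
    for lipid in lipid_subset:
        row = m.tau[row_of[lipid]]
        ok = ~np.isnan(row)
        if not ok.any():
            warnings.warn(f"lipid {lipid!r} has no defined tau; excluded")
            continue
        cand = sorted(zip(proteins[ok], row[ok]), key=lambda t: (-abs(t[1]), t[0]))
        top = [(str(p), float(t)) for p, t in cand[:n]]
        ranked[lipid] = top
        freq.update(p for p, _ in top)
    return TopPartnerTable(n=n, ranked=ranked, frequency=freq)
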