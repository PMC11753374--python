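"""Kendall tau-b cross-ome correlation, degree filtering, dual clustering.

The all-pairs lipid x protein matrix is computed with an exact vectorized
tau-b: for every unordered sample pair (i, j) and feature f we take the
sign of the difference ``x_i - x_j`` (0 when tied or either value missing).
For a lipid l and protein p over jointly observed samples,

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2))

with C - D the sum of sign products over sample pairs valid in both
features, n0 the number of valid pairs, and n1/n2 the tied valid pairs in
each feature.  All four quantities are matrix products of per-ome sign /
validity / tie indicator matrices, so the full matrix costs a handful of
BLAS calls instead of one statistic call per feature pair.  Missingness is
handled pairwise-complete per feature pair; the tau of a constant vector is
undefined (NaN), as is any pair with fewer than ``min_overlap`` complete
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from sklearn.cluster import KMeans

from crossome.io import AbundanceMatrix

__all__ = [
    "CrossCorrelationMatrix",
    "ClusterAssignment",
    "kendall_tau_b",
    "cross_correlation",
    "degree_filter",
    "cluster_crossome",
]


@dataclass
class CrossCorrelationMatrix:
    """Lipid x protein tau-b values with per-pair complete sample counts."""

    lipid_ids: list[str]
    protein_ids: list[str]
    tau: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        shape = (len(self.lipid_ids), len(self.protein_ids))
        if self.tau.shape != shape or self.n_pairs.shape != shape:
            raise ValueError("tau / n_pairs shape does not match id lists")
        finite = self.tau[~np.isnan(self.tau)]
        if finite.size and np.abs(finite).max() > 1 + 1e-9:
            raise ValueError("|tau| exceeds 1")

    def subset(self, lipids: Sequence[str], proteins: Sequence[str]) -> "CrossCorrelationMatrix":
        li = {f: i for i, f in enumerate(self.lipid_ids)}
        pi = {f: i for i, f in enumerate(self.protein_ids)}
        rows = [li[f] for f in lipids]
        cols = [pi[f] for f in proteins]
        return CrossCorrelationMatrix(
            list(lipids), list(proteins),
            self.tau[np.ix_(rows, cols)], self.n_pairs[np.ix_(rows, cols)],
        )


@dataclass
class ClusterAssignment:
    """Per-feature cluster labels (1..k) plus hierarchical leaf order."""

    ome: str
    feature_ids: list[str]
    labels: np.ndarray
    leaf_order: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.leaf_order = np.asarray(self.leaf_order, dtype=int)
        n = len(self.feature_ids)
        if self.labels.shape != (n,) or self.leaf_order.shape != (n,):
            raise ValueError("labels / leaf_order length mismatch")
        k = self.labels.max(initial=0)
        present = set(np.unique(self.labels))
        if present != set(range(1, k + 1)):
            raise ValueError(f"labels must cover 1..{k} with no empty cluster")
        if set(self.leaf_order) != set(range(n)):
            raise ValueError("leaf_order is not a permutation")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max(initial=0))

    def members(self, cluster_id: int) -> list[str]:
        return [f for f, l in zip(self.feature_ids, self.labels) if l == cluster_id]


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected Kendall tau-b between two vectors.

    Positions missing (NaN) in either vector are dropped jointly.  Returns
    NaN when fewer than 2 complete pairs remain or either vector is
    constant on the complete positions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    tau = scipy.stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def _sign_blocks(values: np.ndarray, ii: np.ndarray, jj: np.ndarray):
    """Sign / valid / tie matrices over sample pairs for one ome block.

    values: samples x features (column-major per feature).  Returns float32
    (pairs x features) matrices: S (sign of difference, 0 if invalid or
    tied), V (1 if both samples observed), T (1 if valid and tied).
    """
    a = values[ii]
    b = values[jj]
    valid = ~(np.isnan(a) | np.isnan(b))
    diff = np.where(valid, a - b, 0.0)
    s = np.sign(diff).astype(np.float32)
    v = valid.astype(np.float32)
    t = v - np.abs(s)
    return s, v, t


def cross_correlation(
    lipids: AbundanceMatrix,
    proteins: AbundanceMatrix,
    min_overlap: int = 8,
    pair_chunk: int = 8192,
    genotype_of: Mapping[str, str] | None = None,
) -> CrossCorrelationMatrix:
    """All-pairs lipid x protein Kendall tau-b across shared samples.

    Correlation is computed over the intersection of sample ids, pairwise-
    complete per feature pair.  ``n_pairs`` records the complete sample
    count per pair; tau is NaN wherever ``n_pairs < min_overlap`` or either
    marginal is constant.  ``pair_chunk`` bounds memory by accumulating the
    sample-pair matrices in blocks.  With ``genotype_of`` (sample id ->
    genotype) profiles are first averaged within genotype and tau is
    computed over genotype means instead of replicate-level columns.
    """
    shared = [s for s in lipids.sample_ids if s in set(proteins.sample_ids)]
    if genotype_of is not None:
        missing = [s for s in shared if s not in genotype_of]
        if missing:
            raise ValueError(f"samples without genotype: {missing[:5]}")
    if len(shared) < max(2, min_overlap):
        raise ValueError(
            f"only {len(shared)} shared samples; need at least {max(2, min_overlap)}"
        )
    lf = lipids.to_frame()[shared]
    pf = proteins.to_frame()[shared]
    if genotype_of is not None:
        groups = pd.Series({s: genotype_of[s] for s in shared})
        lf = lf.T.groupby(groups).mean().T
        pf = pf.T.groupby(groups).mean().T
    lv = lf.to_numpy(dtype=float).T  # samples (or genotypes) x lipids
    pv = pf.to_numpy(dtype=float).T

    n = lv.shape[0]
    ii, jj = _pair_indices(n)

    nl, npro = lv.shape[1], pv.shape[1]
    cd = np.zeros((nl, npro), dtype=np.float64)
    n0 = np.zeros((nl, npro), dtype=np.float64)
    t1 = np.zeros((nl, npro), dtype=np.float64)
    t2 = np.zeros((nl, npro), dtype=np.float64)
    for start in range(0, len(ii), pair_chunk):
        sl_i, sl_j = ii[start:start + pair_chunk], jj[start:start + pair_chunk]
        Sl, Vl, Tl = _sign_blocks(lv, sl_i, sl_j)
        Sp, Vp, Tp = _sign_blocks(pv, sl_i, sl_j)
        cd += (Sl.T @ Sp).astype(np.float64)
        n0 += (Vl.T @ Vp).astype(np.float64)
        t1 += (Tl.T @ Vp).astype(np.float64)
        t2 += (Vl.T @ Tp).astype(np.float64)

    # complete-sample counts per feature pair
    ml = (~np.isnan(lv)).astype(np.float32)
    mp = (~np.isnan(pv)).astype(np.float32)
    n_pairs = (ml.T @ mp).astype(int)

    denom = (n0 - t1) * (n0 - t2)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(denom > 0, cd / np.sqrt(np.where(denom > 0, denom, 1.0)), np.nan)
    tau[n_pairs < min_overlap] = np.nan
    np.clip(tau, -1.0, 1.0, out=tau)

    return CrossCorrelationMatrix(
        lipid_ids=list(lipids.feature_ids),
        protein_ids=list(proteins.feature_ids),
        tau=tau,
        n_pairs=n_pairs,
    )


def degree_filter(
    m: CrossCorrelationMatrix,
    tau_min: float = 0.4,
    min_partners: int = 2,
) -> tuple[CrossCorrelationMatrix, list[str], list[str]]:
    """Keep features with at least ``min_partners`` cross-ome partners at |tau| > tau_min.

    Both ome filters are evaluated on the FULL matrix and applied
    simultaneously in one pass (no iterative re-filtering).  The inequality
    is strict, matching the convention of at least two correlations with
    absolute tau above the threshold.
    """
    if not (0 < tau_min < 1):
        raise ValueError("tau_min must be in (0, 1)")
    if min_partners < 1:
        raise ValueError("min_partners must be >= 1")
    hits = np.abs(np.nan_to_num(m.tau, nan=0.0)) > tau_min
    lipid_deg = hits.sum(axis=1)
    prot_deg = hits.sum(axis=0)
    keep_l = lipid_deg >= min_partners
    keep_p = prot_deg >= min_partners
    retained_lipids = [f for f, k in zip(m.lipid_ids, keep_l) if k]
    retained_proteins = [f for f, k in zip(m.protein_ids, keep_p) if k]
    if not retained_lipids or not retained_proteins:
        warnings.warn("degree filter retained an empty feature set on one ome")
    filtered = CrossCorrelationMatrix(
        retained_lipids,
        retained_proteins,
        m.tau[np.ix_(keep_l.nonzero()[0], keep_p.nonzero()[0])],
        m.n_pairs[np.ix_(keep_l.nonzero()[0], keep_p.nonzero()[0])],
    )
    return filtered, retained_lipids, retained_proteins


def _cluster_one(
    profiles: np.ndarray, feature_ids: list[str], ome: str, k: int, seed: int
) -> ClusterAssignment:
    n = profiles.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} {ome} features")
    if n == 1:
        return ClusterAssignment(ome, feature_ids, np.array([1]), np.array([0]))

    link = sch.linkage(profiles, method="average", metric="euclidean")
    leaf_order = np.asarray(sch.leaves_list(link), dtype=int)

    if k == 1:
        labels = np.ones(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=25, random_state=seed)
        raw = km.fit_predict(profiles)
        # renumber clusters by the leaf position of each cluster's medoid
        leaf_rank = np.empty(n, dtype=int)
        leaf_rank[leaf_order] = np.arange(n)
        order_keys = []
        for c in range(k):
            idx = np.nonzero(raw == c)[0]
            sub = profiles[idx]
            d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1).sum(-1)
            medoid = idx[int(np.argmin(d2))]
            order_keys.append(leaf_rank[medoid])
        relabel = {c: r + 1 for r, c in enumerate(np.argsort(order_keys, kind="stable"))}
        labels = np.array([relabel[c] for c in raw], dtype=int)
    return ClusterAssignment(ome, feature_ids, labels, leaf_order)


def cluster_crossome(
    m: CrossCorrelationMatrix,
    k_protein: int = 18,
    k_lipid: int = 13,
    seed: int = 0,
) -> tuple[ClusterAssignment, ClusterAssignment]:
    """Cluster proteins and lipids by their cross-ome tau profiles.

    Each protein's profile is its tau vector over the retained lipids and
    vice versa; missing tau become 0 (absence of association) for distance
    purposes only.  Average-linkage hierarchical clustering supplies the
    leaf order; seeded k-means (25 restarts) supplies the labels, renumbered
    by medoid leaf order so the output is deterministic for a fixed seed.
    """
    tau0 = np.nan_to_num(m.tau, nan=0.0)
    proteins = _cluster_one(tau0.T, list(m.protein_ids), "protein", k_protein, seed)
    lipids = _cluster_one(tau0, list(m.lipid_ids), "lipid", k_lipid, seed)
    return proteins, lipids
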