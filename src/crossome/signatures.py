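"""Genotype fingerprints: cluster signatures, panel k-means, outliers, networks.

A cluster signature is the log2 ratio of summed linear-scale cluster
abundance in a knockout genotype over the same sum in the control — a
single number per (cluster, genotype) that fingerprints how strongly the
mutant shifts that module.  Outlier calls use a median/MAD robust z per
feature across genotypes.  Marker networks are bipartite protein-lipid
graphs thresholded on |tau|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from crossome.correlation import ClusterAssignment, CrossCorrelationMatrix
from crossome.io import AbundanceMatrix, AnnotationMap
from crossome.lipids import LipidSpecies

__all__ = [
    "GenotypeSignature",
    "OutlierReport",
    "BipartiteNetwork",
    "cluster_signature",
    "organelle_panel_kmeans",
    "detect_outlier_genotypes",
    "extract_network",
    "class_chain_summary",
]

MAD_SCALE = 1.4826  # consistency factor for Gaussian data
MAD_FLOOR = 1e-9


@dataclass
class GenotypeSignature:
    cluster_id: int
    genotype: str
    signature: float  # log2(sum cluster abundance in genotype / in control)
    n_features: int


@dataclass
class OutlierReport:
    feature_id: str
    genotype: str
    robust_z: float
    is_outlier: bool


@dataclass
class BipartiteNetwork:
    """Protein-lipid edges above an absolute-tau threshold, with annotations."""

    edges: list[tuple[str, str, float]]
    node_annotations: dict[str, dict] = field(default_factory=dict)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for node, attrs in self.node_annotations.items():
            g.add_node(node, **{k: v for k, v in attrs.items() if v is not None})
        for prot, lip, tau in self.edges:
            g.add_edge(prot, lip, tau=tau)
        return g


def cluster_signature(
    abund: AbundanceMatrix,
    assignment: ClusterAssignment,
    meta: pd.DataFrame,
    control_genotype: str,
) -> list[GenotypeSignature]:
    """Summed-cluster log2 fold change of every genotype versus control.

    Per feature and genotype, the replicate mean of the log2 values is
    de-logged (geometric mean on the linear scale); these are summed over
    cluster features and the log2 ratio to the control sum is the
    signature.  A feature enters a (cluster, genotype) sum only if it is
    observed (>=1 replicate) in both that genotype and the control;
    ``n_features`` records how many were used.
    """
    genotypes = meta.set_index("sample_id")["genotype"]
    if control_genotype not in set(genotypes):
        raise ValueError(f"control genotype {control_genotype!r} not in metadata")
    frame = abund.to_frame()
    missing_meta = [s for s in frame.columns if s not in genotypes.index]
    if missing_meta:
        raise ValueError(f"samples without metadata: {missing_meta[:5]}")

    # feature x genotype matrix of de-logged replicate means
    by_geno = frame.T.groupby(genotypes.loc[frame.columns]).mean()  # genotype x feature
    linear = np.power(2.0, by_geno).T  # feature x genotype, NaN where unobserved

    control = linear[control_genotype]
    out: list[GenotypeSignature] = []
    for cid in range(1, assignment.n_clusters + 1):
        members = [f for f in assignment.members(cid) if f in linear.index]
        sub = linear.loc[members]
        for geno in by_geno.index:
            usable = sub[geno].notna() & control.loc[members].notna()
            n_used = int(usable.sum())
            if n_used == 0:
                warnings.warn(
                    f"cluster {cid}, genotype {geno!r}: no usable features; signature missing"
                )
                out.append(GenotypeSignature(cid, str(geno), float("nan"), 0))
                continue
            num = float(sub.loc[usable.values, geno].sum())
            den = float(control.loc[members][usable.values].sum())
            sig = float(np.log2(num / den)) if num > 0 and den > 0 else float("nan")
            out.append(GenotypeSignature(cid, str(geno), sig, n_used))
    return out


def _relabel_first_occurrence(raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    for lab in raw:
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
    return np.array([mapping[l] for l in raw], dtype=int)


def organelle_panel_kmeans(
    log2fc: pd.DataFrame,
    panel: Sequence[AnnotationMap],
    k_genotype: int,
    k_feature: int,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Seeded k-means over genotypes and over a curated feature panel.

    ``log2fc`` is genotype x feature (fold changes versus a control).  The
    matrix is restricted to panel members, a genotype x annotation-group
    mean matrix is computed, genotypes are k-means clustered on those group
    means and features on their genotype profiles.  Labels are renumbered
    by first occurrence in input order, so a fixed seed gives identical
    output.  Missing fold changes contribute 0 to the profiles.
    """
    panel_features = sorted(set().union(*(p.feature_ids for p in panel)) & set(log2fc.columns))
    if not panel_features:
        raise ValueError("no panel features present in the fold-change matrix")
    sub = log2fc[panel_features]

    group_means = pd.DataFrame(
        {
            p.term_id: sub[sorted(p.feature_ids & set(panel_features))].mean(axis=1)
            for p in panel
            if p.feature_ids & set(panel_features)
        }
    )
    if k_genotype > len(group_means.index):
        raise ValueError(f"k_genotype={k_genotype} exceeds {len(group_means.index)} genotypes")
    if k_feature > len(panel_features):
        raise ValueError(f"k_feature={k_feature} exceeds {len(panel_features)} panel features")

    km_g = KMeans(n_clusters=k_genotype, n_init=25, random_state=seed)
    g_raw = km_g.fit_predict(np.nan_to_num(group_means.to_numpy(), nan=0.0))
    km_f = KMeans(n_clusters=k_feature, n_init=25, random_state=seed)
    f_raw = km_f.fit_predict(np.nan_to_num(sub.to_numpy().T, nan=0.0))

    genotype_labels = pd.Series(
        _relabel_first_occurrence(g_raw), index=group_means.index, name="genotype_cluster"
    )
    feature_labels = pd.Series(
        _relabel_first_occurrence(f_raw), index=panel_features, name="feature_cluster"
    )
    return genotype_labels, feature_labels, group_means


def detect_outlier_genotypes(
    values: Mapping[str, float] | pd.Series,
    z_threshold: float = 2.5,
    feature_id: str = "",
) -> list[OutlierReport]:
    """Median/MAD robust-z outlier calls for one feature across genotypes.

    robust_z = (value - median) / (1.4826 * MAD), with the MAD floored at
    1e-9 so constant vectors give z = 0 for every genotype rather than a
    division error.  Requires at least 5 genotypes with non-missing
    summaries.
    """
    series = pd.Series(values, dtype=float).dropna()
    if len(series) < 5:
        raise ValueError(f"need >= 5 genotypes with values, got {len(series)}")
    med = float(series.median())
    mad = float((series - med).abs().median())
    if mad < MAD_FLOOR:
        warnings.warn(
            f"feature {feature_id!r}: MAD below floor; z-scores use floored scale"
        )
    scale = MAD_SCALE * max(mad, MAD_FLOOR)
    out = []
    for geno, v in series.items():
        z = (v - med) / scale
        if mad < MAD_FLOOR and v == med:
            z = 0.0
        out.append(OutlierReport(feature_id, str(geno), float(z), bool(abs(z) >= z_threshold)))
    return out


def extract_network(
    m: CrossCorrelationMatrix,
    marker_proteins: Sequence[str],
    lipid_clusters: Sequence[int],
    protein_assignment: ClusterAssignment | None = None,
    lipid_assignment: ClusterAssignment | None = None,
    edge_tau_min: float = 0.4,
    species: Sequence[LipidSpecies] | None = None,
) -> BipartiteNetwork:
    """Bipartite marker-protein x lipid network from selected lipid clusters.

    Edges connect each marker to every lipid in the named lipid clusters
    with |tau| above ``edge_tau_min`` (with threshold 0, every defined tau
    qualifies).  Unknown markers are skipped with a warning; isolated nodes
    are omitted.  Nodes carry cluster ids and, for lipids, the parsed class.
    """
    col_of = {p: i for i, p in enumerate(m.protein_ids)}
    row_of = {l: i for i, l in enumerate(m.lipid_ids)}

    if lipid_assignment is not None:
        wanted = set(lipid_clusters)
        lipid_pool = [
            f
            for f, lab in zip(lipid_assignment.feature_ids, lipid_assignment.labels)
            if lab in wanted and f in row_of
        ]
    else:
        lipid_pool = list(m.lipid_ids)

    prot_cluster = (
        dict(zip(protein_assignment.feature_ids, protein_assignment.labels))
        if protein_assignment is not None
        else {}
    )
    lip_cluster = (
        dict(zip(lipid_assignment.feature_ids, lipid_assignment.labels))
        if lipid_assignment is not None
        else {}
    )
    lip_class = {s.raw_name: s.lipid_class for s in species} if species else {}

    edges: list[tuple[str, str, float]] = []
    annotations: dict[str, dict] = {}
    for marker in marker_proteins:
        if marker not in col_of:
            warnings.warn(f"marker {marker!r} not in correlation matrix; skipped")
            continue
        col = m.tau[:, col_of[marker]]
        for lipid in lipid_pool:
            tau = col[row_of[lipid]]
            if np.isnan(tau):
                continue
            if edge_tau_min > 0 and abs(tau) <= edge_tau_min:
                continue
            edges.append((marker, lipid, float(tau)))
            annotations.setdefault(
                marker, {"kind": "protein", "cluster": prot_cluster.get(marker)}
            )
            annotations.setdefault(
                lipid,
                {
                    "kind": "lipid",
                    "cluster": lip_cluster.get(lipid),
                    "lipid_class": lip_class.get(lipid),
                },
            )
    return BipartiteNetwork(edges=edges, node_annotations=annotations)


def class_chain_summary(
    log2fc: pd.Series,
    species: Sequence[LipidSpecies],
    carbon_cutoff: int = 20,
) -> pd.DataFrame:
    """Per-lipid-class medians of fold change and rank percentile, split by chain length.

    Lipids are ranked ascending by log2FC (mid-ranks for ties) and the
    percentile is rank/n.  Per class the table reports the median log2FC,
    the median percentile, and median log2FC split at ``carbon_cutoff``
    total carbons (short < cutoff <= long); species with unknown carbon
    counts are excluded from the split and counted.
    """
    from scipy.stats import rankdata

    by_name = {s.raw_name: s for s in species}
    values = log2fc.dropna()
    unknown_names = [n for n in values.index if n not in by_name]
    if unknown_names:
        raise ValueError(f"lipids without parsed species: {unknown_names[:5]}")
    pct = pd.Series(rankdata(values.to_numpy()) / len(values), index=values.index)

    rows = []
    classes = sorted({by_name[n].lipid_class for n in values.index})
    for cls in classes:
        names = [n for n in values.index if by_name[n].lipid_class == cls]
        carbons = {n: by_name[n].total_carbons for n in names}
        known = [n for n in names if carbons[n] is not None]
        short = [n for n in known if carbons[n] < carbon_cutoff]
        long_ = [n for n in known if carbons[n] >= carbon_cutoff]
        if not names:
            continue
        rows.append(
            {
                "lipid_class": cls,
                "n_species": len(names),
                "median_log2fc": float(values[names].median()),
                "median_percentile": float(pct[names].median()),
                "short_chain_median": float(values[short].median()) if short else np.nan,
                "long_chain_median": float(values[long_].median()) if long_ else np.nan,
                "n_unknown_carbons": len(names) - len(known),
            }
        )
    return pd.DataFrame(rows).set_index("lipid_class")
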