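"""End-to-end orchestration: correlate -> filter -> cluster -> enrich -> fingerprints.

``run_pipeline`` consumes a :class:`RunConfig` (YAML-serialisable, CLI-
overridable), validates the inputs, executes every stage, writes plain TSV
outputs plus a JSON manifest (stage list, input SHA-256 hashes, per-stage
feature counts, package version, seed) that allows an exact re-run.  All
randomness is controlled by the single config seed, so a fixed config and
fixed inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from crossome._version import __version__ as _version
from crossome.correlation import cluster_crossome, cross_correlation, degree_filter
from crossome.enrichment import enrich_clusters, enrich_lipid_classes, top_partner_frequency
from crossome.io import (
    read_abundance_table,
    read_annotation_gmt,
    read_sample_meta,
    validate_meta,
)
from crossome.lipids import parse_lipid_name
from crossome.signatures import (
    class_chain_summary,
    cluster_signature,
    detect_outlier_genotypes,
    extract_network,
)

log = logging.getLogger("crossome")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths, thresholds and seed for one pipeline run."""

    lipids_path: str
    proteins_path: str
    meta_path: str
    out_dir: str
    gmt_path: str | None = None
    markers_path: str | None = None
    control_genotype: str = "control"
    tau_min: float = 0.4
    min_partners: int = 2
    min_overlap: int = 8
    k_protein: int = 18
    k_lipid: int = 13
    top_n: int = 10
    z_threshold: float = 2.5
    carbon_cutoff: int = 20
    alpha: float = 0.05
    lipid_network_clusters: list[int] = field(default_factory=list)
    summary_genotype: str | None = None
    correlate_on: str = "replicates"  # or "genotype_means"
    seed: int = 0

    def validate(self) -> None:
        if self.correlate_on not in ("replicates", "genotype_means"):
            raise ValueError("correlate_on must be 'replicates' or 'genotype_means'")
        if not (0 < self.tau_min < 1):
            raise ValueError("tau_min must be in (0, 1)")
        if self.min_partners < 1 or self.min_overlap < 2:
            raise ValueError("min_partners >= 1 and min_overlap >= 2 required")
        if self.k_protein < 1 or self.k_lipid < 1 or self.top_n < 1:
            raise ValueError("k_protein, k_lipid and top_n must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.z_threshold <= 0 or self.carbon_cutoff < 1:
            raise ValueError("z_threshold > 0 and carbon_cutoff >= 1 required")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rt") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _write_tau(m, path: Path) -> None:
    pd.DataFrame(m.tau, index=m.lipid_ids, columns=m.protein_ids).to_csv(
        path, sep="\t", float_format="%.6g", index_label="lipid_id"
    )


def _write_assignments(protein_assign, lipid_assign, path: Path) -> None:
    rows = []
    for assign in (protein_assign, lipid_assign):
        leaf_rank = np.empty(len(assign.feature_ids), dtype=int)
        leaf_rank[assign.leaf_order] = np.arange(len(assign.feature_ids))
        for f, lab, rank in zip(assign.feature_ids, assign.labels, leaf_rank):
            rows.append((f, assign.ome, int(lab), int(rank)))
    pd.DataFrame(rows, columns=["feature_id", "ome", "cluster", "leaf_rank"]).to_csv(
        path, sep="\t", index=False
    )


def _write_enrichment(results, path: Path) -> None:
    pd.DataFrame(
        [
            (r.cluster_id, r.term_id, r.a, r.b, r.c, r.d, r.odds_ratio, r.p_value, r.q_value)
            for r in results
        ],
        columns=["cluster_id", "term_id", "a", "b", "c", "d", "odds_ratio", "p", "q"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to out_dir)."""
    cfg.validate()
    for name in ("lipids_path", "proteins_path", "meta_path", "gmt_path", "markers_path"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{name.replace('_path', '')} input missing: {p}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": _version,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "inputs": {},
        "stages": [],
        "outputs": {},
        "counts": {},
    }
    for name in ("lipids_path", "proteins_path", "meta_path", "gmt_path", "markers_path"):
        p = getattr(cfg, name)
        if p is not None:
            manifest["inputs"][name] = _sha256(Path(p))

    def stage(name: str) -> None:
        manifest["stages"].append(name)
        log.info("stage %s", name)

    stage("load")
    lipids = read_abundance_table(cfg.lipids_path, ome="lipid")
    proteins = read_abundance_table(cfg.proteins_path, ome="protein")
    meta = read_sample_meta(cfg.meta_path)
    validate_meta(lipids, meta)
    validate_meta(proteins, meta)
    manifest["counts"]["loaded"] = {
        "lipids": lipids.n_features,
        "proteins": proteins.n_features,
        "samples": lipids.n_samples,
    }
    log.info("loaded %d lipids, %d proteins", lipids.n_features, proteins.n_features)

    stage("correlate")
    genotype_of = (
        meta.set_index("sample_id")["genotype"].to_dict()
        if cfg.correlate_on == "genotype_means"
        else None
    )
    xc = cross_correlation(
        lipids, proteins, min_overlap=cfg.min_overlap, genotype_of=genotype_of
    )
    _write_tau(xc, out / "tau_matrix.tsv")
    manifest["outputs"]["tau_matrix"] = str(out / "tau_matrix.tsv")

    stage("filter")
    filtered, kept_lipids, kept_proteins = degree_filter(
        xc, tau_min=cfg.tau_min, min_partners=cfg.min_partners
    )
    (out / "retained_lipids.txt").write_text("\n".join(kept_lipids) + "\n")
    (out / "retained_proteins.txt").write_text("\n".join(kept_proteins) + "\n")
    manifest["counts"]["retained"] = {
        "lipids": len(kept_lipids),
        "proteins": len(kept_proteins),
    }
    log.info("retained %d lipids and %d proteins", len(kept_lipids), len(kept_proteins))
    manifest["outputs"]["retained_lipids"] = str(out / "retained_lipids.txt")
    manifest["outputs"]["retained_proteins"] = str(out / "retained_proteins.txt")

    stage("cluster")
    k_protein = min(cfg.k_protein, max(1, len(kept_proteins)))
    k_lipid = min(cfg.k_lipid, max(1, len(kept_lipids)))
    prot_assign, lip_assign = cluster_crossome(
        filtered, k_protein=k_protein, k_lipid=k_lipid, seed=cfg.seed
    )
    _write_assignments(prot_assign, lip_assign, out / "clusters.tsv")
    manifest["outputs"]["clusters"] = str(out / "clusters.tsv")
    manifest["counts"]["clustered"] = {"k_protein": k_protein, "k_lipid": k_lipid}

    species = [parse_lipid_name(n) for n in kept_lipids]

    stage("enrich")
    if cfg.gmt_path is not None:
        terms = read_annotation_gmt(cfg.gmt_path)
        prot_enrich = enrich_clusters(prot_assign, terms, universe=set(kept_proteins))
        _write_enrichment(prot_enrich, out / "protein_enrichment.tsv")
        manifest["outputs"]["protein_enrichment"] = str(out / "protein_enrichment.tsv")
    lip_enrich = enrich_lipid_classes(lip_assign, species)
    _write_enrichment(lip_enrich, out / "lipid_class_enrichment.tsv")
    manifest["outputs"]["lipid_class_enrichment"] = str(out / "lipid_class_enrichment.tsv")

    stage("top_partners")
    top = top_partner_frequency(filtered, kept_lipids, n=min(cfg.top_n, len(kept_proteins)))
    rows = [
        (lip, rank + 1, prot, tau)
        for lip, pairs in top.ranked.items()
        for rank, (prot, tau) in enumerate(pairs)
    ]
    pd.DataFrame(rows, columns=["lipid_id", "rank", "protein_id", "tau"]).to_csv(
        out / "top_partners.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame(
        sorted(top.frequency.items(), key=lambda t: (-t[1], t[0])),
        columns=["protein_id", "count"],
    ).to_csv(out / "top_partner_frequency.tsv", sep="\t", index=False)
    manifest["outputs"]["top_partners"] = str(out / "top_partners.tsv")
    manifest["outputs"]["top_partner_frequency"] = str(out / "top_partner_frequency.tsv")

    stage("signature")
    prot_sub = proteins.subset_features(kept_proteins)
    sigs = cluster_signature(prot_sub, prot_assign, meta, cfg.control_genotype)
    pd.DataFrame(
        [(s.cluster_id, s.genotype, s.signature, s.n_features) for s in sigs],
        columns=["cluster_id", "genotype", "signature", "n_features"],
    ).to_csv(out / "cluster_signatures.tsv", sep="\t", index=False, float_format="%.6g")
    manifest["outputs"]["cluster_signatures"] = str(out / "cluster_signatures.tsv")

    stage("outliers")
    lip_frame = lipids.subset_features(kept_lipids).to_frame()
    geno = meta.set_index("sample_id")["genotype"]
    geno_means = lip_frame.T.groupby(geno.loc[lip_frame.columns]).mean().T
    outlier_rows = []
    for lipid in kept_lipids:
        summaries = geno_means.loc[lipid].dropna()
        if len(summaries) < 5:
            continue
        for rep in detect_outlier_genotypes(summaries, cfg.z_threshold, feature_id=lipid):
            if rep.is_outlier:
                outlier_rows.append((rep.feature_id, rep.genotype, rep.robust_z))
    pd.DataFrame(outlier_rows, columns=["feature_id", "genotype", "robust_z"]).to_csv(
        out / "outliers.tsv", sep="\t", index=False, float_format="%.6g"
    )
    manifest["outputs"]["outliers"] = str(out / "outliers.tsv")

    if cfg.markers_path is not None:
        stage("network")
        markers = [
            ln.strip() for ln in Path(cfg.markers_path).read_text().splitlines() if ln.strip()
        ]
        net_clusters = cfg.lipid_network_clusters or list(range(1, lip_assign.n_clusters + 1))
        net = extract_network(
            filtered,
            markers,
            net_clusters,
            protein_assignment=prot_assign,
            lipid_assignment=lip_assign,
            edge_tau_min=cfg.tau_min,
            species=species,
        )
        pd.DataFrame(net.edges, columns=["protein_id", "lipid_id", "tau"]).to_csv(
            out / "network_edges.tsv", sep="\t", index=False, float_format="%.6g"
        )
        import networkx as nx

        nx.write_graphml(net.to_networkx(), out / "network.graphml")
        manifest["outputs"]["network_edges"] = str(out / "network_edges.tsv")
        manifest["outputs"]["network_graphml"] = str(out / "network.graphml")

    if cfg.summary_genotype is not None:
        stage("class_chain_summary")
        if cfg.summary_genotype not in geno_means.columns:
            raise ValueError(f"summary genotype {cfg.summary_genotype!r} not in metadata")
        log2fc = geno_means[cfg.summary_genotype] - geno_means[cfg.control_genotype]
        summary = class_chain_summary(log2fc, species, carbon_cutoff=cfg.carbon_cutoff)
        summary.to_csv(out / "class_chain_summary.tsv", sep="\t", float_format="%.6g")
        manifest["outputs"]["class_chain_summary"] = str(out / "class_chain_summary.tsv")

    cfg.to_yaml(out / "config.yaml")
    manifest["outputs"]["config"] = str(out / "config.yaml")
    with open(out / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
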