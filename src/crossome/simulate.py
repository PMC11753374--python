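"""Planted-module synthetic multi-omics generator.

Emulates a knockout-panel design (by default 33 genotypes x 4 replicate
cultures) measured on two omes: thousands of proteins and hundreds of
lipids on a log2 intensity scale.  Each of ``n_modules`` planted modules is
driven by one latent activity per sample,

    z[m, s] = genotype_effect * 1[genotype(s) affected by m] + N(0, latent_sd)

and every feature assigned to module m reads

    value[f, s] = base[f] + loading[f] * z[m, s] + N(0, noise_sd)

with positive loadings, so within-module features co-vary monotonically
across omes (visible to Kendall correlation).  Background features are
independent noise around their baseline.  Missing entries are dropped
completely at random.  Module lipids are drawn with a per-module lipid-
class bias and protein annotation terms aligned to modules (plus decoys),
so class/term enrichment is recoverable against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import pandas as pd
import numpy as np

from crossome.io import AbundanceMatrix, AnnotationMap

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_lipid_names",
    "generate_crossome_dataset",
]

CONTROL = "control"
LIPID_CLASSES = ["PC", "LPC", "PE", "CE", "DG", "TG", "SM", "Cer[NS]", "GM3", "PI"]


@dataclass
class GeneratorConfig:
    """Stated world for the synthetic panel; defaults mirror the study design."""

    n_genotypes: int = 33            # incl. the control line
    n_replicates: int = 4            # quadruplicate cultures
    n_proteins: int = 2000
    n_lipids: int = 600
    n_modules: int = 5
    module_size_protein: int = 100
    module_size_lipid: int = 40
    latent_sd: float = 0.5           # per-sample module-driver spread, log2
    noise_sd: float = 0.3            # log2 measurement noise
    genotype_effect: float = 1.0     # log2 shift for affected genotype x module
    loading_range: tuple[float, float] = (1.0, 1.0)
    affected_per_module: int = 3
    affected_map: dict[int, set[str]] | None = None
    missing_rate: float = 0.05
    module_class_purity: float = 0.8  # fraction of module lipids from its class
    n_decoy_terms: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules * self.module_size_protein > self.n_proteins:
            raise ValueError("module proteins exceed n_proteins")
        if self.n_modules * self.module_size_lipid > self.n_lipids:
            raise ValueError("module lipids exceed n_lipids")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_genotypes < 2:
            raise ValueError("need the control plus at least one knockout genotype")
        if self.affected_map is not None:
            genos = set(self.genotypes())
            for m, gs in self.affected_map.items():
                if CONTROL in gs:
                    raise ValueError("control genotype may not be affected")
                if not gs <= genos:
                    raise ValueError(f"module {m}: affected genotypes outside panel")

    def genotypes(self) -> list[str]:
        return [CONTROL] + [f"KO{i:02d}" for i in range(1, self.n_genotypes)]

    @classmethod
    def ci_preset(cls, seed: int = 0) -> "GeneratorConfig":
        """Scaled-down world (same noise model) for fast test runs."""
        return cls(
            n_genotypes=8,
            n_replicates=3,
            n_proteins=300,
            n_lipids=120,
            n_modules=3,
            module_size_protein=30,
            module_size_lipid=15,
            affected_per_module=2,
            n_decoy_terms=5,
            seed=seed,
        )


@dataclass
class GroundTruth:
    """Planted structure: module labels (0 = background), effects, latents."""

    protein_module: np.ndarray
    lipid_module: np.ndarray
    affected_map: dict[int, set[str]]
    latent: pd.DataFrame              # module x sample activities
    lipid_truth: dict[str, tuple[str, int, int]] = field(default_factory=dict)


def generate_lipid_names(
    classes: list[str],
    counts: list[int],
    chain_range: tuple[int, int] = (12, 44),
    db_range: tuple[int, int] = (0, 6),
    seed: int = 0,
) -> tuple[list[str], list[tuple[str, int, int]]]:
    """Unique sum-composition shorthand names with recorded ground truth.

    Returns (names, truth) where truth[i] = (class, carbons, double_bonds)
    for names[i].  Names follow ``CLASS C:D`` and are unique.
    """
    if chain_range[0] > chain_range[1] or db_range[0] > db_range[1]:
        raise ValueError("empty chain or double-bond range")
    rng = np.random.default_rng(seed)
    names: list[str] = []
    truth: list[tuple[str, int, int]] = []
    used: set[str] = set()
    for cls, count in zip(classes, counts):
        n_combos = (chain_range[1] - chain_range[0] + 1) * (db_range[1] - db_range[0] + 1)
        if count > n_combos:
            raise ValueError(f"cannot draw {count} unique {cls} names from {n_combos} combos")
        for _ in range(count):
            while True:
                c = int(rng.integers(chain_range[0], chain_range[1] + 1))
                d = int(rng.integers(db_range[0], db_range[1] + 1))
                name = f"{cls} {c}:{d}"
                if name not in used:
                    break
            used.add(name)
            names.append(name)
            truth.append((cls, c, d))
    return names, truth


def _default_affected_map(cfg: GeneratorConfig, rng: np.random.Generator) -> dict[int, set[str]]:
    kos = cfg.genotypes()[1:]
    need = cfg.n_modules * cfg.affected_per_module
    if need > len(kos):
        raise ValueError("not enough knockout genotypes for disjoint affected sets")
    chosen = rng.permutation(kos)[:need]
    return {
        m + 1: set(chosen[m * cfg.affected_per_module:(m + 1) * cfg.affected_per_module])
        for m in range(cfg.n_modules)
    }


def generate_crossome_dataset(
    cfg: GeneratorConfig,
) -> tuple[AbundanceMatrix, AbundanceMatrix, pd.DataFrame, GroundTruth, list[AnnotationMap], list[str]]:
    """Draw one synthetic panel: (proteins, lipids, meta, truth, terms, lipid names)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genotypes = cfg.genotypes()
    sample_ids = [f"{g}_r{r}" for g in genotypes for r in range(1, cfg.n_replicates + 1)]
    sample_geno = np.repeat(genotypes, cfg.n_replicates)
    n_samples = len(sample_ids)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "genotype": sample_geno,
            "condition": "fed",
            "replicate": list(range(1, cfg.n_replicates + 1)) * len(genotypes),
        }
    )

    affected = (
        cfg.affected_map if cfg.affected_map is not None else _default_affected_map(cfg, rng)
    )

    # latent module activities per sample
    latent = np.empty((cfg.n_modules, n_samples))
    for m in range(1, cfg.n_modules + 1):
        shift = np.isin(sample_geno, list(affected.get(m, set()))) * cfg.genotype_effect
        latent[m - 1] = shift + rng.normal(0.0, cfg.latent_sd, n_samples)

    # module membership: first blocks of each ome are planted, rest background
    prot_module = np.zeros(cfg.n_proteins, dtype=int)
    lip_module = np.zeros(cfg.n_lipids, dtype=int)
    for m in range(1, cfg.n_modules + 1):
        prot_module[(m - 1) * cfg.module_size_protein: m * cfg.module_size_protein] = m
        lip_module[(m - 1) * cfg.module_size_lipid: m * cfg.module_size_lipid] = m

    def _ome_values(n_feat: int, module: np.ndarray, base_mean: float) -> np.ndarray:
        base = rng.normal(base_mean, 2.0, n_feat)
        loading = rng.uniform(*cfg.loading_range, n_feat)
        vals = base[:, None] + rng.normal(0.0, cfg.noise_sd, (n_feat, n_samples))
        planted = module > 0
        vals[planted] += loading[planted, None] * latent[module[planted] - 1]
        return vals

    prot_vals = _ome_values(cfg.n_proteins, prot_module, 20.0)
    lip_vals = _ome_values(cfg.n_lipids, lip_module, 18.0)

    # lipid names: per-module class bias, background uniform over classes
    module_classes = [LIPID_CLASSES[m % len(LIPID_CLASSES)] for m in range(cfg.n_modules)]
    class_need: dict[str, int] = {c: 0 for c in LIPID_CLASSES}
    lipid_class_plan: list[str] = []
    for i in range(cfg.n_lipids):
        m = lip_module[i]
        if m > 0 and rng.random() < cfg.module_class_purity:
            cls = module_classes[m - 1]
        else:
            cls = LIPID_CLASSES[int(rng.integers(len(LIPID_CLASSES)))]
        lipid_class_plan.append(cls)
        class_need[cls] += 1
    name_seed = int(rng.integers(2**31 - 1))
    pool_names, pool_truth = generate_lipid_names(
        list(class_need), [class_need[c] for c in class_need], seed=name_seed
    )
    by_class: dict[str, list[int]] = {}
    for idx, (cls, _, _) in enumerate(pool_truth):
        by_class.setdefault(cls, []).append(idx)
    lipid_names: list[str] = []
    lipid_truth: dict[str, tuple[str, int, int]] = {}
    for cls in lipid_class_plan:
        idx = by_class[cls].pop()
        lipid_names.append(pool_names[idx])
        lipid_truth[pool_names[idx]] = pool_truth[idx]

    protein_names = [f"P{i:05d}" for i in range(cfg.n_proteins)]

    # annotation terms aligned to modules, plus random decoys
    terms: list[AnnotationMap] = []
    for m in range(1, cfg.n_modules + 1):
        members = {protein_names[i] for i in np.nonzero(prot_module == m)[0]}
        terms.append(AnnotationMap(f"TERM_M{m:02d}", f"planted module {m} proteins", members))
    for t in range(cfg.n_decoy_terms):
        size = int(rng.integers(max(2, cfg.module_size_protein // 2), cfg.module_size_protein + 1))
        members = set(rng.choice(protein_names, size=size, replace=False))
        terms.append(AnnotationMap(f"TERM_D{t:02d}", f"decoy set {t}", members))

    if cfg.missing_rate > 0:
        prot_vals[rng.random(prot_vals.shape) < cfg.missing_rate] = np.nan
        lip_vals[rng.random(lip_vals.shape) < cfg.missing_rate] = np.nan

    proteins = AbundanceMatrix(protein_names, sample_ids, prot_vals, "protein")
    lipids = AbundanceMatrix(lipid_names, sample_ids, lip_vals, "lipid")
    truth = GroundTruth(
        protein_module=prot_module,
        lipid_module=lip_module,
        affected_map=affected,
        latent=pd.DataFrame(
            latent, index=[f"module_{m}" for m in range(1, cfg.n_modules + 1)], columns=sample_ids
        ),
        lipid_truth=lipid_truth,
    )
    return proteins, lipids, meta, truth, terms, lipid_names
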