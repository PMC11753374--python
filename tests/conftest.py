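import numpy as np
import pandas as pd
import pytest

from crossome.correlation import ClusterAssignment
from crossome.io import AbundanceMatrix
from crossome.simulate import GeneratorConfig, generate_crossome_dataset


@pytest.fixture(scope="session")
def ci_dataset():
    """One scaled-down synthetic panel shared across tests (seed 7)."""
    cfg = GeneratorConfig.ci_preset(seed=7)
    proteins, lipids, meta, truth, terms, names = generate_crossome_dataset(cfg)
    return {
        "cfg": cfg,
        "proteins": proteins,
        "lipids": lipids,
        "meta": meta,
        "truth": truth,
        "terms": terms,
        "names": names,
    }


@pytest.fixture
def tiny_matrix():
    """3 features x 4 samples with one missing cell."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 3.0, np.nan, 1.0],
            [0.5, 0.5, 0.5, 0.5],
        ]
    )
    return AbundanceMatrix(["F1", "F2", "F3"], ["s1", "s2", "s3", "s4"], values, "protein")


def truth_assignment(feature_ids, module_labels, ome):
    """ClusterAssignment from planted module labels (background -> own cluster)."""
    labels = np.asarray(module_labels, dtype=int)
    k = labels.max()
    labels = np.where(labels > 0, labels, k + 1)
    if (labels == k + 1).sum() == 0:
        labels = np.asarray(module_labels, dtype=int)
    return ClusterAssignment(ome, list(feature_ids), labels, np.arange(len(feature_ids)))


@pytest.fixture
def meta_two_genotypes():
    rows = []
    for geno in ("control", "KO01"):
        for rep in (1, 2, 3):
            rows.append((f"{geno}_r{rep}", geno, "fed", rep))
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "condition", "replicate"])
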