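import numpy as np
import pandas as pd
import pytest

from crossome.correlation import ClusterAssignment, CrossCorrelationMatrix
from crossome.io import AbundanceMatrix, AnnotationMap
from crossome.lipids import parse_lipid_name
from crossome.signatures import (
    class_chain_summary,
    cluster_signature,
    detect_outlier_genotypes,
    extract_network,
    organelle_panel_kmeans,
)


def _abundance(values, features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return AbundanceMatrix(features, samples, values, "protein")


def _assign(features, labels):
    return ClusterAssignment("protein", features, np.asarray(labels), np.arange(len(features)))


class TestClusterSignature:
    def test_control_vs_itself_zero(self, meta_two_genotypes):
        rng = np.random.default_rng(1)
        values = rng.normal(20, 1, size=(6, 6))
        m = _abundance(values, samples=list(meta_two_genotypes["sample_id"]))
        assign = _assign(m.feature_ids, [1, 1, 1, 2, 2, 2])
        sigs = cluster_signature(m, assign, meta_two_genotypes, "control")
        for s in sigs:
            if s.genotype == "control":
                assert s.signature == 0.0

    def test_doubled_ko_gives_signature_one(self, meta_two_genotypes):
        base = np.tile(np.array([18.0, 20.0, 22.0])[:, None], (1, 6))
        base[:, 3:] += 1.0  # KO replicates exactly doubled on the linear scale
        m = _abundance(base, samples=list(meta_two_genotypes["sample_id"]))
        assign = _assign(m.feature_ids, [1, 1, 1])
        sigs = cluster_signature(m, assign, meta_two_genotypes, "control")
        ko = next(s for s in sigs if s.genotype == "KO01")
        assert ko.signature == pytest.approx(1.0, abs=1e-12)
        assert ko.n_features == 3

    def test_global_scaling_cancels(self, meta_two_genotypes):
        rng = np.random.default_rng(2)
        values = rng.normal(20, 1, size=(4, 6))
        samples = list(meta_two_genotypes["sample_id"])
        assign = _assign([f"F{i}" for i in range(4)], [1, 1, 2, 2])
        sigs_a = cluster_signature(_abundance(values, samples=samples), assign,
                                   meta_two_genotypes, "control")
        sigs_b = cluster_signature(_abundance(values + 3.0, samples=samples), assign,
                                   meta_two_genotypes, "control")
        # adding a constant in log2 space scales all intensities by 8x; ratios cancel
        for a, b in zip(sigs_a, sigs_b):
            assert b.signature == pytest.approx(a.signature, abs=1e-9)

    def test_feature_order_invariance(self, meta_two_genotypes):
        rng = np.random.default_rng(3)
        values = rng.normal(20, 1, size=(4, 6))
        samples = list(meta_two_genotypes["sample_id"])
        m = _abundance(values, samples=samples)
        assign = _assign(m.feature_ids, [1, 2, 1, 2])
        perm = [2, 0, 3, 1]
        m_perm = _abundance(values[perm], features=[m.feature_ids[i] for i in perm],
                            samples=samples)
        assign_perm = _assign(m_perm.feature_ids, [1, 1, 2, 2])
        a = {(s.cluster_id, s.genotype): s.signature
             for s in cluster_signature(m, assign, meta_two_genotypes, "control")}
        b = {(s.cluster_id, s.genotype): s.signature
             for s in cluster_signature(m_perm, assign_perm, meta_two_genotypes, "control")}
        for key in a:
            assert b[key] == pytest.approx(a[key], abs=1e-9)

    def test_pairwise_missing_feature_dropped(self, meta_two_genotypes):
        values = np.full((2, 6), 20.0)
        values[1, 3:] = np.nan  # F1 unobserved in the KO genotype
        values[0, 3:] = 21.0
        m = _abundance(values, samples=list(meta_two_genotypes["sample_id"]))
        assign = _assign(m.feature_ids, [1, 1])
        sigs = cluster_signature(m, assign, meta_two_genotypes, "control")
        ko = next(s for s in sigs if s.genotype == "KO01")
        assert ko.n_features == 1
        assert ko.signature == pytest.approx(1.0, abs=1e-12)

    def test_unknown_control_error(self, meta_two_genotypes):
        m = _abundance(np.full((1, 6), 20.0), samples=list(meta_two_genotypes["sample_id"]))
        with pytest.raises(ValueError, match="control"):
            cluster_signature(m, _assign(m.feature_ids, [1]), meta_two_genotypes, "WT")


class TestOrganellePanelKmeans:
    def test_opposite_effects_split_perfectly(self):
        genotypes = [f"G{i}" for i in range(6)]
        features = [f"F{i}" for i in range(10)]
        fc = np.zeros((6, 10))
        fc[:3] = 2.0   # first genotype group up, second down
        fc[3:] = -2.0
        log2fc = pd.DataFrame(fc, index=genotypes, columns=features)
        panel = [AnnotationMap("lysosome", "lyso", set(features[:5])),
                 AnnotationMap("mito", "mito", set(features[5:]))]
        glabels, flabels, means = organelle_panel_kmeans(log2fc, panel, 2, 2, seed=0)
        assert len(set(glabels[:3])) == 1 and len(set(glabels[3:])) == 1
        assert glabels.iloc[0] != glabels.iloc[3]
        assert means.shape == (6, 2)

    def test_single_group_mean_matrix_one_column(self):
        log2fc = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)),
                              index=list("abcde"), columns=["F0", "F1", "F2", "F3"])
        panel = [AnnotationMap("only", "only", {"F0", "F1"})]
        _, _, means = organelle_panel_kmeans(log2fc, panel, 2, 2, seed=0)
        assert list(means.columns) == ["only"]

    def test_k_exceeding_count_error(self):
        log2fc = pd.DataFrame(np.zeros((3, 2)), index=list("abc"), columns=["F0", "F1"])
        panel = [AnnotationMap("g", "g", {"F0", "F1"})]
        with pytest.raises(ValueError, match="exceeds"):
            organelle_panel_kmeans(log2fc, panel, 4, 2, seed=0)


class TestOutliers:
    def test_constant_values_no_outliers(self):
        vals = {f"G{i}": 5.0 for i in range(8)}
        with pytest.warns(UserWarning, match="MAD"):
            reps = detect_outlier_genotypes(vals, 2.5)
        assert all(r.robust_z == 0.0 and not r.is_outlier for r in reps)

    def test_large_deviation_flagged(self):
        vals = {f"G{i}": float(i % 3) for i in range(10)}
        vals["G_out"] = 50.0
        reps = {r.genotype: r for r in detect_outlier_genotypes(vals, 2.5)}
        assert reps["G_out"].is_outlier
        assert not reps["G0"].is_outlier

    def test_shift_equivariance(self):
        rng = np.random.default_rng(5)
        vals = dict(zip([f"G{i}" for i in range(12)], rng.normal(size=12)))
        base = {r.genotype: r.robust_z for r in detect_outlier_genotypes(vals, 2.5)}
        shifted = {r.genotype: r.robust_z for r in detect_outlier_genotypes(
            {g: v + 7.5 for g, v in vals.items()}, 2.5)}
        for g in base:
            assert shifted[g] == pytest.approx(base[g], abs=1e-9)

    def test_too_few_genotypes_error(self):
        with pytest.raises(ValueError, match=">= 5"):
            detect_outlier_genotypes({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}, 2.5)


class TestExtractNetwork:
    @staticmethod
    def _matrix(tau):
        nl, npro = tau.shape
        return CrossCorrelationMatrix(
            [f"L{i}" for i in range(nl)], [f"P{j}" for j in range(npro)],
            tau, np.full(tau.shape, 9),
        )

    def test_marker_without_edges_omitted(self):
        tau = np.array([[0.1, 0.9], [0.2, 0.8]])
        net = extract_network(self._matrix(tau), ["P0", "P1"], [], edge_tau_min=0.4)
        nodes = {e[0] for e in net.edges}
        assert nodes == {"P1"}
        assert "P0" not in net.node_annotations

    def test_threshold_zero_counts_non_missing(self):
        rng = np.random.default_rng(6)
        tau = rng.uniform(-1, 1, size=(5, 4))
        tau[rng.random(tau.shape) < 0.2] = np.nan
        m = self._matrix(tau)
        net = extract_network(m, list(m.protein_ids), [], edge_tau_min=0.0)
        assert len(net.edges) == int((~np.isnan(tau)).sum())

    def test_unknown_marker_warns_and_skips(self):
        tau = np.array([[0.9]])
        with pytest.warns(UserWarning, match="not in correlation matrix"):
            net = extract_network(self._matrix(tau), ["NOPE", "P0"], [], edge_tau_min=0.4)
        assert [e[0] for e in net.edges] == ["P0"]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        tau = rng.uniform(-1, 1, size=(6, 8))
        m = self._matrix(tau)
        lip_assign = ClusterAssignment("lipid", list(m.lipid_ids),
                                       np.array([1, 1, 2, 2, 3, 3]), np.arange(6))
        net = extract_network(m, ["P1", "P5"], [1, 3], lipid_assignment=lip_assign,
                              edge_tau_min=0.4)
        expected = set()
        for j, prot in [(1, "P1"), (5, "P5")]:
            for i, lip in enumerate(m.lipid_ids):
                if lip_assign.labels[i] in (1, 3) and abs(tau[i, j]) > 0.4:
                    expected.add((prot, lip))
        assert {(p, l) for p, l, _ in net.edges} == expected


class TestClassChainSummary:
    def test_top_ranked_class_high_percentile(self):
        names = [f"CE {14 + i}:0" for i in range(5)] + [f"PC {30 + i}:1" for i in range(45)]
        species = [parse_lipid_name(n) for n in names]
        fc = pd.Series(
            np.concatenate([np.linspace(3, 4, 5), np.linspace(-1, 1, 45)]), index=names
        )
        table = class_chain_summary(fc, species)
        assert table.loc["CE", "median_percentile"] >= 0.9

    def test_all_zero_fc_percentiles_half(self):
        names = ["PC 32:0", "PC 34:1", "CE 16:0", "CE 18:1"]
        species = [parse_lipid_name(n) for n in names]
        table = class_chain_summary(pd.Series(0.0, index=names), species)
        assert np.allclose(table["median_percentile"], 0.5 + 1 / 8)  # mid-rank of 4 ties

    def test_short_vs_long_chain_split(self):
        names = ["CE 16:0", "CE 18:0", "CE 22:0", "CE 24:0"]
        species = [parse_lipid_name(n) for n in names]
        fc = pd.Series([2.0, 2.2, -0.5, -0.4], index=names)
        table = class_chain_summary(fc, species, carbon_cutoff=20)
        assert table.loc["CE", "short_chain_median"] > table.loc["CE", "long_chain_median"]

    def test_unknown_carbons_excluded_and_counted(self):
        import warnings
        names = ["CE 16:0", "CE 18:0"]
        species = [parse_lipid_name(n) for n in names]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            species.append(parse_lipid_name("Cholesterol"))
        fc = pd.Series([1.0, 2.0, 3.0], index=names + ["Cholesterol"])
        table = class_chain_summary(fc, species, carbon_cutoff=20)
        assert table.loc["CE", "n_unknown_carbons"] == 0
        assert table.loc["Cholesterol", "n_unknown_carbons"] == 1
        assert np.isnan(table.loc["Cholesterol", "short_chain_median"])
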