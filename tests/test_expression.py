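"""QC filtering, normalization, cluster profiling, and phenotype rules."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from clonaltrack import (QCParams, assign_phenotypes, cluster_mean_expression,
                         correlate_with_reference, normalize_log1p, qc_filter,
                         score_signatures, signature_score)
from clonaltrack.expression import ClusterProfile, EmptyMatrixError, read_expression
from clonaltrack.signatures import GeneSignature, default_signatures


def build_adata(X, genes, barcodes=None, **obs_cols):
    X = np.asarray(X)
    barcodes = barcodes or [f"c{i}" for i in range(X.shape[0])]
    obs = pd.DataFrame(obs_cols if obs_cols else None,
                       index=pd.Index(barcodes, name="barcode"))
    return ad.AnnData(X=sp.csr_matrix(np.asarray(X)),
                      obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


class TestQCFilter:
    def qc_fixture(self):
        # cellA: only 1 gene detected; cellB: 3/13 mito UMIs (23%);
        # cellC/cellD: clean.  GDEAD is expressed nowhere.
        genes = ["G1", "G2", "G3", "MT-ND1", "GDEAD"]
        X = np.array([
            [5, 0, 0, 0, 0],    # cellA, 1 gene
            [4, 3, 3, 3, 0],    # cellB, high mito
            [4, 4, 3, 0, 0],    # cellC
            [2, 5, 4, 0, 0],    # cellD
        ])
        return build_adata(X, genes)

    def test_cells_straddling_both_thresholds_removed(self):
        params = QCParams(min_genes_per_cell=2, max_mito_fraction=0.10,
                          min_gene_prevalence=0.0)
        out = qc_filter(self.qc_fixture(), params)
        assert list(out.obs_names) == ["c2", "c3"]

    def test_never_expressed_gene_removed(self):
        params = QCParams(min_genes_per_cell=0, max_mito_fraction=1.0)
        out = qc_filter(self.qc_fixture(), params)
        assert "GDEAD" not in out.var_names

    def test_clean_matrix_unchanged(self):
        X = np.full((3, 4), 5)
        adata = build_adata(X, ["G1", "G2", "G3", "G4"])
        out = qc_filter(adata, QCParams(min_genes_per_cell=2))
        assert out.shape == (3, 4)

    def test_idempotent(self):
        params = QCParams(min_genes_per_cell=2, max_mito_fraction=0.10)
        once = qc_filter(self.qc_fixture(), params)
        twice = qc_filter(once, params)
        assert list(once.obs_names) == list(twice.obs_names)
        assert list(once.var_names) == list(twice.var_names)

    def test_all_cells_removed_signalled(self):
        adata = build_adata(np.eye(3, dtype=int), ["G1", "G2", "G3"])
        with pytest.raises(EmptyMatrixError):
            qc_filter(adata, QCParams(min_genes_per_cell=2))


class TestNormalization:
    def test_cells_scaled_to_target_then_logged(self):
        adata = build_adata([[10, 10], [1, 3]], ["G1", "G2"])
        normalize_log1p(adata, target_sum=100)
        dense = adata.layers["lognorm"].toarray()
        np.testing.assert_allclose(dense[0], np.log1p([50, 50]))
        np.testing.assert_allclose(dense[1], np.log1p([25, 75]))


class TestClusterProfiles:
    def make(self):
        adata = build_adata([[2, 0], [4, 0], [0, 6]], ["G1", "G2"],
                            cluster=["A", "A", "B"],
                            timepoint=["pre", "d14", "pre"])
        adata.layers["lognorm"] = sp.csr_matrix(adata.X, dtype=float)
        return adata

    def test_mean_is_arithmetic_over_cells(self):
        profiles = cluster_mean_expression(self.make())
        byid = {p.cluster_id: p for p in profiles}
        assert byid["A"].mean_expression["G1"] == pytest.approx(3.0)
        assert byid["B"].mean_expression["G2"] == pytest.approx(6.0)  # singleton

    def test_timepoint_frequencies_sum_to_one(self, rng):
        n = 60
        adata = build_adata(rng.integers(0, 5, (n, 3)), ["G1", "G2", "G3"],
                            cluster=list(rng.choice(["A", "B", "C"], n)),
                            timepoint=list(rng.choice(["pre", "d14"], n)))
        adata.layers["lognorm"] = sp.csr_matrix(adata.X, dtype=float)
        profiles = cluster_mean_expression(adata)
        for tp in ("pre", "d14"):
            total = sum(p.timepoint_frequency.get(tp, 0.0) for p in profiles)
            assert total == pytest.approx(1.0)

    def test_unlabeled_cells_reported(self):
        adata = self.make()
        adata.obs.loc["c1", "cluster"] = None
        with pytest.raises(ValueError, match="c1"):
            cluster_mean_expression(adata)


class TestSignatureScore:
    def profile(self, values):
        return ClusterProfile("X", pd.Series(values), n_cells=1)

    def test_mean_over_signature_genes(self):
        p = self.profile({"A": 1.0, "B": 2.0, "C": 6.0, "D": 99.0})
        assert signature_score(p, GeneSignature("s", ("A", "B", "C"))) == 3.0

    def test_single_gene_and_constant_signatures(self):
        p = self.profile({"A": 2.5, "B": 2.5})
        assert signature_score(p, GeneSignature("s", ("A",))) == 2.5
        assert signature_score(p, GeneSignature("s", ("A", "B"))) == 2.5

    def test_empty_intersection_signalled(self):
        p = self.profile({"A": 1.0})
        with pytest.raises(ValueError):
            signature_score(p, GeneSignature("s", ("Z",)))


class TestCorrelation:
    def test_identical_and_anti_patterns(self):
        genes = list("ABC")
        p = ClusterProfile("p", pd.Series([1.0, 2.0, 3.0], index=genes), 1)
        ref_same = ClusterProfile("same", pd.Series([2.0, 4.0, 6.0], index=genes), 1)
        ref_anti = ClusterProfile("anti", pd.Series([3.0, 2.0, 1.0], index=genes), 1)
        mat = correlate_with_reference([p], [ref_same, ref_anti], genes)
        assert mat.loc["p", "same"] == pytest.approx(1.0)
        assert mat.loc["p", "anti"] == pytest.approx(-1.0)

    def test_matches_bruteforce_covariance(self, rng):
        genes = [f"G{i}" for i in range(10)]
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        p = ClusterProfile("p", pd.Series(x, index=genes), 1)
        r = ClusterProfile("r", pd.Series(y, index=genes), 1)
        got = correlate_with_reference([p], [r], genes).loc["p", "r"]
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert got == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_yields_nan_with_warning(self):
        genes = list("ABC")
        p = ClusterProfile("p", pd.Series([1.0, 1.0, 1.0], index=genes), 1)
        r = ClusterProfile("r", pd.Series([1.0, 2.0, 3.0], index=genes), 1)
        with pytest.warns(RuntimeWarning):
            mat = correlate_with_reference([p], [r], genes)
        assert np.isnan(mat.loc["p", "r"])


class TestPhenotypeRules:
    @staticmethod
    def profiles_from_scores(score_table):
        profiles = []
        for cid, scores in score_table.items():
            p = ClusterProfile(cid, pd.Series(dtype=float), 1)
            p.signature_scores = dict(scores)
            profiles.append(p)
        return profiles

    def test_marker_rules_fire_in_order(self):
        base = {s: 0.0 for s in ("cytotoxic", "IFN_response", "exhaustion",
                                 "TPEX", "TRM_pos", "TRM_neg", "Treg", "TN",
                                 "TFH")}
        table = {}
        for cid, high in [("c_teff", ("cytotoxic",)),
                          ("c_ifn", ("IFN_response",)),
                          ("c_treg", ("Treg",)),
                          ("c_tfh", ("TFH",)),
                          ("c_tn", ("TN",))]:
            scores = dict(base)
            for sig in high:
                scores[sig] = 5.0
            table[cid] = scores
        tpex = dict(base); tpex["TPEX"] = 5.0; tpex["exhaustion"] = 2.0
        table["c_tpex"] = tpex
        trm = dict(base)
        trm["TRM_pos"] = 5.0; trm["exhaustion"] = 2.0; trm["TRM_neg"] = -5.0
        # give TRM_neg spread so z-scores separate
        for cid in ("c_teff", "c_ifn", "c_tn"):
            table[cid]["TRM_neg"] = 3.0
        table["c_trm"] = trm
        table["c_null"] = dict(base)
        labels = assign_phenotypes(self.profiles_from_scores(table))
        assert labels["c_teff"] == "FGFBP2_TEFF"
        assert labels["c_ifn"] == "IFN_TEFF"
        assert labels["c_treg"] == "TREG"
        assert labels["c_tfh"] == "TFH_like"
        assert labels["c_tn"] == "TN"
        assert labels["c_tpex"] == "TPEX"
        assert labels["c_trm"] == "preexhausted_TRM"
        assert labels["c_null"] == "unclassified"

    def test_scores_required(self):
        p = ClusterProfile("c", pd.Series(dtype=float), 1)
        with pytest.raises(ValueError):
            assign_phenotypes([p])


def test_mtx_round_trip(tmp_path, rng):
    import scipy.io
    X = sp.random(8, 5, density=0.5, random_state=42, dtype=np.float64)
    X = sp.csr_matrix(np.rint(X.toarray() * 10).astype(np.int64))
    genes = [f"G{i}" for i in range(5)]
    barcodes = [f"BC{i}" for i in range(8)]
    scipy.io.mmwrite(str(tmp_path / "m.mtx"), X.T.tocoo(), field="integer")
    (tmp_path / "features.tsv").write_text("\n".join(genes) + "\n")
    (tmp_path / "barcodes.tsv").write_text("\n".join(barcodes) + "\n")
    adata = read_expression(tmp_path / "m.mtx", tmp_path / "features.tsv",
                            tmp_path / "barcodes.tsv")
    assert adata.shape == (8, 5)
    np.testing.assert_array_equal(adata.X.toarray(), X.toarray())


def test_default_signatures_cover_rule_requirements():
    sigs = default_signatures()
    needed = {"cytotoxic", "IFN_response", "exhaustion", "TPEX", "TRM_pos",
              "TRM_neg", "Treg", "TN", "TFH"}
    assert needed <= set(sigs)
    assert all(len(s.genes) >= 1 for s in sigs.values())
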