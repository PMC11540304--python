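"""Primitive-cell merging, signature scoring, and BCR::ABL1 status calls."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cmlcite import status as st
from cmlcite import synthetic as syn
from cmlcite.signature import GeneSignature


def _primitive_patient(profiles, signature, seed, n=200, fraction=0.5,
                       effect=1.0):
    design = syn.PatientDesign(
        patient_id=f"P{seed}", composition={"Primitive": 1.0},
        bcr_abl1_fraction=fraction, signature_effect=effect,
        n_cells=n, seed=seed,
    )
    return syn.generate_patient(design, profiles, signature)


def _control(profiles, n=100, seed=99):
    primitive = [p for p in profiles if p.name == "Primitive"]
    return syn.generate_reference(primitive, n, seed=seed, cell_prefix="ctl")[0]


class TestMergePrimitive:
    def test_provenance_bookkeeping(self, profiles, lsc_signature):
        mats = {
            f"P{i}": _primitive_patient(profiles, lsc_signature, i, n=100)[0]
            for i in range(3)
        }
        control = _control(profiles, n=50)
        merged = st.merge_primitive(mats, control)
        assert merged.n_obs == 350
        assert merged.obs["patient"].value_counts().to_dict() == {
            "P0": 100, "P1": 100, "P2": 100, "control": 50
        }
        assert (merged.obs["is_control"].sum()) == 50
        assert merged.obs["origin_id"].iloc[0] in mats["P0"].obs_names

    def test_empty_patient_skipped(self, profiles, lsc_signature):
        rna = _primitive_patient(profiles, lsc_signature, 1, n=100)[0]
        merged = st.merge_primitive({"P1": rna, "P2": rna[:0].copy()}, None)
        assert merged.n_obs == 100

    def test_sex_linked_gene_excluded_from_hvgs(self, rng):
        n, g = 120, 60
        counts = rng.poisson(5, size=(n, g))
        hot = rng.random(n) < 0.5
        counts[hot, 0] += 80  # top dispersion by construction
        genes = ["XIST"] + [f"G{i}" for i in range(1, g)]
        merged = ad.AnnData(
            X=sp.csr_matrix(counts),
            obs=pd.DataFrame({"is_control": False,
                              "patient": "P1",
                              "origin_id": [f"c{i}" for i in range(n)]},
                             index=[f"c{i}" for i in range(n)]),
            var=pd.DataFrame(index=genes),
        )
        hvgs = st.select_hvgs(merged, 20, 5, exclude=st.DEFAULT_SEX_GENES)
        assert "XIST" not in hvgs

    def test_graph_without_control_matches_fit_on_all(self, profiles,
                                                      lsc_signature):
        rna = _primitive_patient(profiles, lsc_signature, 5, n=150)[0]
        merged = st.merge_primitive({"P5": rna}, None)
        graph = st.primitive_merge_graph(merged)
        from cmlcite.embed import PRIMITIVE_MERGE_PARAMS, build_graph

        hvgs = st.select_hvgs(merged, 500, 30, exclude=st.DEFAULT_SEX_GENES)
        unrestricted = build_graph(merged, hvgs, PRIMITIVE_MERGE_PARAMS,
                                   mp_denoise=True)
        np.testing.assert_allclose(graph.pcs, unrestricted.pcs, atol=1e-8)


class TestScoreSignature:
    def test_constant_genes_score_zero(self):
        counts = np.full((10, 4), 5)
        rna = ad.AnnData(
            X=sp.csr_matrix(counts),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(10)]),
            var=pd.DataFrame(index=["A", "B", "C", "D"]),
        )
        sig = GeneSignature("s", up_genes=["A", "B"])
        scores = st.score_signature(rna, sig, "up")
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_one_sd_spike_scores_near_one(self, rng):
        """Cells displaced by +1 within-sample sd on every up-gene score ~1
        (equal sequencing depths, so normalization is a fixed rescaling)."""
        p = rng.dirichlet(np.ones(30))
        counts = rng.multinomial(3000, p, size=200).astype(float)
        rna0 = ad.AnnData(
            X=sp.csr_matrix(counts),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(200)]),
            var=pd.DataFrame(index=[f"G{i}" for i in range(30)]),
        )
        from cmlcite._norm import normalize_log

        norm, _ = normalize_log(rna0.X)
        up = [0, 1, 2]
        shifted = norm.copy()
        shifted[:20, up] += norm[:, up].std(axis=0)
        lin = np.expm1(shifted)
        rna = ad.AnnData(
            X=sp.csr_matrix(lin),
            obs=rna0.obs.copy(), var=rna0.var.copy(),
        )
        sig = GeneSignature("s", up_genes=[f"G{i}" for i in up])
        scores = st.score_signature(rna, sig, "up")
        assert scores[:20].mean() == pytest.approx(1.0, abs=0.25)

    def test_invariant_to_adding_constant_gene(self, rng):
        """A gene constant on the normalized scale contributes a zero
        z-score, so adding it to the signature only rescales the mean."""
        p = rng.dirichlet(np.ones(20))
        counts = rng.multinomial(1000, p, size=50).astype(float)
        counts = np.hstack([counts, np.full((50, 1), 3.0)])  # equal totals
        genes = [f"G{i}" for i in range(20)] + ["CONST"]
        rna = ad.AnnData(
            X=sp.csr_matrix(counts),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(50)]),
            var=pd.DataFrame(index=genes),
        )
        base = GeneSignature("s", up_genes=[f"G{i}" for i in range(5)])
        extended = GeneSignature("s", up_genes=base.up_genes + ["CONST"])
        a = st.score_signature(rna, base, "up")
        b = st.score_signature(rna, extended, "up")
        scale = len(base.up_genes) / len(extended.up_genes)
        np.testing.assert_allclose(b, a * scale, atol=1e-9)

    def test_no_signature_genes_rejected(self, profiles, lsc_signature):
        rna = _primitive_patient(profiles, lsc_signature, 7, n=50)[0]
        sig = GeneSignature("s", up_genes=["NOT_A_GENE"])
        with pytest.raises(ValueError, match="no genes"):
            st.score_signature(rna, sig, "up")


class TestAssignStatus:
    def test_identical_scores_call_everything_negative(self):
        clusters = pd.Series(["a"] * 20 + ["b"] * 20 + ["ctl"] * 20,
                             index=[f"c{i}" for i in range(60)])
        flat = pd.Series(0.5, index=clusters.index)
        control_ids = clusters.index[40:]
        call = st.assign_status(clusters, flat, flat, control_ids)
        assert call.cluster_status["a"] == st.STATUS_NEG
        assert call.cluster_status["b"] == st.STATUS_NEG
        assert call.cluster_status["ctl"] == st.STATUS_CONTROL

    def test_control_cluster_is_majority_control(self, rng):
        clusters = pd.Series(["x"] * 30 + ["z"] * 30 + ["y"] * 30,
                             index=[f"c{i}" for i in range(90)])
        lsc = pd.Series(
            np.r_[rng.normal(2, 0.1, 30), rng.normal(0, 0.1, 60)],
            index=clusters.index,
        )
        hsc = pd.Series(0.0, index=clusters.index)
        control_ids = clusters.index[60:80]  # 20 of cluster y's 30 cells
        call = st.assign_status(clusters, lsc, hsc, control_ids)
        assert call.cluster_status["y"] == st.STATUS_CONTROL
        assert call.cluster_status["x"] == st.STATUS_POS
        assert call.cluster_status["z"] == st.STATUS_NEG

    def test_status_counts_conserved(self, profiles, lsc_signature):
        rna = _primitive_patient(profiles, lsc_signature, 3, n=400)[0]
        control = _control(profiles)
        merged = st.merge_primitive({"P3": rna}, control)
        graph = st.primitive_merge_graph(merged)
        clusters = st.coarse_cluster(graph, seed=3)
        lsc = st.score_signature(merged, lsc_signature, "up")
        hsc = st.score_signature(merged, lsc_signature, "down")
        call = st.assign_status(clusters, lsc, hsc,
                                merged.obs_names[merged.obs["is_control"]])
        counts = call.cell_status.value_counts()
        assert counts.sum() == merged.n_obs


class TestCoarseCluster:
    def test_uniform_profiles_give_single_cluster(self, rng):
        counts = rng.poisson(5, size=(150, 600))
        merged = ad.AnnData(
            X=sp.csr_matrix(counts),
            obs=pd.DataFrame({"is_control": False, "patient": "P",
                              "origin_id": [f"c{i}" for i in range(150)]},
                             index=[f"c{i}" for i in range(150)]),
            var=pd.DataFrame(index=[f"G{i}" for i in range(600)]),
        )
        graph = st.primitive_merge_graph(merged)
        clusters = st.coarse_cluster(graph, seed=0)
        assert clusters.nunique() == 1

    def test_singleton_rejected(self, profiles, lsc_signature):
        rna = _primitive_patient(profiles, lsc_signature, 1, n=50)[0]
        merged = st.merge_primitive({"P1": rna}, None)
        graph = st.primitive_merge_graph(merged)
        graph.pcs = graph.pcs[:1]
        with pytest.raises(ValueError, match="fewer than 2"):
            st.coarse_cluster(graph, seed=0)


class TestLinkStatus:
    def _table(self):
        return pd.DataFrame(
            {"label": ["Primitive", "Primitive", "MEP"]},
            index=["c1", "c2", "c3"],
        )

    def test_all_ids_match(self):
        statuses = pd.Series([st.STATUS_POS, st.STATUS_NEG],
                             index=["c1", "c2"])
        table, unmatched = st.link_status(self._table(), statuses)
        assert unmatched == []
        assert table.loc["c1", "status"] == st.STATUS_POS
        assert table.loc["c3", "status"] == "MEP"

    def test_fabricated_id_reported(self):
        statuses = pd.Series([st.STATUS_POS], index=["ghost"])
        _, unmatched = st.link_status(self._table(), statuses)
        assert unmatched == ["ghost"]

    def test_round_trip_through_tsv(self, tmp_path):
        statuses = pd.Series([st.STATUS_POS, st.STATUS_NEG],
                             index=["c1", "c2"], name="status")
        path = tmp_path / "status.tsv"
        statuses.to_frame().to_csv(path, sep="\t")
        reloaded = pd.read_csv(path, sep="\t", index_col=0)["status"]
        a, _ = st.link_status(self._table(), statuses)
        b, _ = st.link_status(self._table(), reloaded)
        pd.testing.assert_frame_equal(a, b)
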