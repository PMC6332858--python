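"""Module-trait association, candidate genes, hubs, and edge export."""

import numpy as np
import pandas as pd
import pytest

from flavornet.coexpr import module_eigengenes, soft_adjacency
from flavornet.traits import (
    correlation_test,
    export_network_edges,
    identify_hubs,
    module_trait_matrix,
    select_candidate_genes,
    significant_modules,
)

from .oracles import pearson_p_incomplete_beta


class TestCorrelationTest:
    def test_perfect_and_null_extremes(self):
        u = np.arange(9.0)
        r, p = correlation_test(u, 2 * u + 3)
        assert (r, p) == (1.0, 0.0)
        # an exactly orthogonal pair: r = 0 -> p = 1
        v = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        w = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])
        r, p = correlation_test(v, w)
        assert r == pytest.approx(0.0, abs=1e-15)
        assert p == pytest.approx(1.0)

    def test_printed_fructose_cell(self):
        """r = -0.97 at n = 9 gives p ~ 1.5e-5, i.e. 1e-5 at one
        significant figure."""
        rng = np.random.default_rng(0)
        # build a 9-sample pair with correlation -0.97 to double precision
        u = rng.normal(size=9)
        v = rng.normal(size=9)
        uz = (u - u.mean()) / u.std()
        resid = v - np.polyval(np.polyfit(uz, v, 1), uz)
        rz = (resid - resid.mean()) / resid.std()
        target = -0.97
        pair = target * uz + np.sqrt(1 - target**2) * rz
        r, p = correlation_test(u, pair)
        assert r == pytest.approx(-0.97, abs=1e-12)
        assert p == pytest.approx(1.495291766609222e-05, rel=1e-9)
        assert float(f"{p:.0e}") == 1e-5

    @pytest.mark.parametrize("n", [4, 6, 9, 15, 30])
    def test_incomplete_beta_oracle_sweep(self, n):
        rng = np.random.default_rng(n)
        base = rng.normal(size=n)
        bz = (base - base.mean()) / base.std()
        noise = rng.normal(size=n)
        resid = noise - np.polyval(np.polyfit(bz, noise, 1), bz)
        rz = (resid - resid.mean()) / resid.std()
        for target in np.arange(-0.99, 1.0, 0.11):
            pair = target * bz + np.sqrt(1 - target**2) * rz
            r, p = correlation_test(base, pair)
            assert r == pytest.approx(target, abs=1e-10)
            assert p == pytest.approx(pearson_p_incomplete_beta(r, n), rel=1e-10, abs=1e-300)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_test(np.ones(9), np.arange(9.0))
        with pytest.raises(ValueError, match="mismatch"):
            correlation_test(np.arange(9.0), np.arange(8.0))
        with pytest.raises(ValueError, match="at least 4"):
            correlation_test(np.arange(3.0), np.arange(3.0))


def _eig_traits(seed=0, n=9):
    rng = np.random.default_rng(seed)
    eig = pd.DataFrame(
        {1: rng.normal(size=n), 2: rng.normal(size=n)},
        index=pd.Index([f"L{i}" for i in range(n)], name="library_id"),
    )
    traits = pd.DataFrame(
        {"sucrose": eig[1].to_numpy(), "noise": rng.normal(size=n)}, index=eig.index
    )
    return eig, traits


class TestModuleTraitMatrix:
    def test_trait_equal_to_eigengene(self):
        eig, traits = _eig_traits()
        r, p = module_trait_matrix(eig, traits)
        assert r.loc[1, "sucrose"] == pytest.approx(1.0)
        assert p.loc[1, "sucrose"] == 0.0
        assert significant_modules(r, p) == [1]

    def test_library_mismatch_rejected(self):
        eig, traits = _eig_traits()
        with pytest.raises(ValueError, match="library"):
            module_trait_matrix(eig, traits.iloc[::-1])

    def test_planted_loading_dominates(self, default_dataset):
        """The module carrying a trait's loading shows the largest |r|."""
        from flavornet import PipelineConfig, run_pipeline

        ds = default_dataset
        res = run_pipeline(ds.counts, ds.traits, PipelineConfig(outdir="scratch/t_mtm"))
        part = res["modules"].reindex(ds.truth.module_label_per_gene.index, fill_value=0)
        mt_r = res["module_trait_r"]
        genes1 = ds.truth.module_label_per_gene[ds.truth.module_label_per_gene == 1].index
        det = part.loc[genes1][part.loc[genes1] > 0].mode()[0]
        col = mt_r["sucrose"].abs()
        assert col.idxmax() == det
        assert col[det] >= 0.9

    def test_permuted_traits_rarely_reach_high_r(self):
        """Permutation null at n=9: max module |r| < 0.8 in >= 95%."""
        rng = np.random.default_rng(123)
        eig = pd.DataFrame(
            {1: rng.normal(size=9), 2: rng.normal(size=9), 3: rng.normal(size=9)},
            index=[f"L{i}" for i in range(9)],
        )
        trait = rng.normal(size=9)
        hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            tp = pd.DataFrame({"t": rng.permutation(trait)}, index=eig.index)
            r, _ = module_trait_matrix(eig, tp)
            if r["t"].abs().max() > 0.8:
                hits += 1
        assert hits / n_perm < 0.05


def _candidate_fixture():
    rng = np.random.default_rng(42)
    n = 9
    latent = rng.normal(size=n)
    lz = (latent - latent.mean()) / latent.std()

    def gene_with_r(target, seed):
        g = np.random.default_rng(seed).normal(size=n)
        resid = g - np.polyval(np.polyfit(lz, g, 1), lz)
        rz = (resid - resid.mean()) / resid.std()
        return 50 + 10 * (target * lz + np.sqrt(1 - target**2) * rz)

    fpkm = pd.DataFrame(
        {
            "hi": gene_with_r(0.95, 1),
            "edge": gene_with_r(0.91, 2),
            "lo": gene_with_r(0.5, 3),
            "outside": gene_with_r(0.99, 4),
        },
        index=[f"L{i}" for i in range(n)],
    ).T
    traits = pd.DataFrame({"sucrose": latent}, index=fpkm.columns)
    part = pd.Series({"hi": 1, "edge": 1, "lo": 1, "outside": 2})
    return fpkm, traits, part


class TestSelectCandidateGenes:
    def test_strict_threshold_and_module_restriction(self):
        fpkm, traits, part = _candidate_fixture()
        # a gene sitting exactly at the threshold is NOT selected (strict >):
        # use the realised correlation of the boundary gene as the threshold
        r_edge = abs(
            np.corrcoef(fpkm.loc["edge"], traits["sucrose"])[0, 1]
        )
        out = select_candidate_genes(
            fpkm, traits, part, [1], r_threshold=r_edge, log_transform=False
        )
        assert list(out.index) == ["hi"]
        assert out.loc["hi", "best_trait"] == "sucrose"
        assert "edge" not in out.index
        # high-r gene outside the significant modules is not selected
        out91 = select_candidate_genes(fpkm, traits, part, [1], log_transform=False)
        assert "outside" not in out91.index
        assert "lo" not in out91.index
        assert "hi" in out91.index

    def test_raising_threshold_never_adds_genes(self):
        fpkm, traits, part = _candidate_fixture()
        lo = set(select_candidate_genes(fpkm, traits, part, [1, 2], 0.5, log_transform=False).index)
        hi = set(select_candidate_genes(fpkm, traits, part, [1, 2], 0.91, log_transform=False).index)
        assert hi <= lo

    def test_empty_module_list_rejected(self):
        fpkm, traits, part = _candidate_fixture()
        with pytest.raises(ValueError, match="empty"):
            select_candidate_genes(fpkm, traits, part, [])


class TestIdentifyHubs:
    def _module(self, seed=21, n_genes=40, noise=(0.0,) + (0.5,) * 39):
        rng = np.random.default_rng(seed)
        latent = rng.normal(size=9)
        rows = [latent + rng.normal(scale=s, size=9) for s in noise]
        expr = pd.DataFrame(
            rows, index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
            columns=[f"L{i}" for i in range(9)],
        )
        part = pd.Series(1, index=expr.index)
        eig, _ = module_eigengenes(expr, part)
        adj = soft_adjacency(expr, beta=6)
        return expr, eig, part, adj

    def test_noise_free_gene_outranks_noisy_ones(self):
        expr, eig, part, adj = self._module()
        hubs = identify_hubs(expr, eig, part, adj)
        assert hubs.loc["g0", "is_hub"]
        assert hubs["is_hub"].sum() <= 5
        assert hubs.loc["g0", "kME"] == hubs["kME"].max()

    def test_gene_order_invariance(self):
        expr, eig, part, adj = self._module()
        perm = np.random.default_rng(0).permutation(len(expr))
        hubs1 = identify_hubs(expr, eig, part, adj)
        hubs2 = identify_hubs(
            expr.iloc[perm], eig, part.iloc[perm], adj.iloc[perm, perm]
        )
        assert set(hubs1.index[hubs1.is_hub]) == set(hubs2.index[hubs2.is_hub])

    def test_no_hubs_below_kme_threshold(self):
        expr, eig, part, adj = self._module(noise=(3.0,) * 40)
        hubs = identify_hubs(expr, eig, part, adj, kme_threshold=0.99)
        assert not hubs["is_hub"].any()


class TestExportNetworkEdges:
    def _weights(self):
        w = pd.DataFrame(
            [[1.0, 0.5, 0.2], [0.5, 1.0, 0.05], [0.2, 0.05, 1.0]],
            index=["a", "b", "c"], columns=["a", "b", "c"],
        )
        return w

    def test_threshold_enumeration(self):
        out = export_network_edges(self._weights(), ["a", "b", "c"], 0.1)
        assert len(out) == 2
        assert set(map(tuple, out[["source", "target"]].to_numpy())) == {("a", "b"), ("a", "c")}

    def test_threshold_one_gives_empty_list(self):
        out = export_network_edges(self._weights() * 0.99, ["a", "b", "c"], 1.0)
        assert len(out) == 0

    def test_sif_dialect_and_no_duplicates(self, tmp_path):
        lines = export_network_edges(
            self._weights(), ["c", "b", "a"], 0.01, fmt="sif", path=tmp_path / "e.sif"
        )
        assert lines == ["a\tcoexp\tb", "a\tcoexp\tc", "b\tcoexp\tc"]
        assert (tmp_path / "e.sif").read_text().strip().splitlines() == lines
        pairs = [tuple(l.split("\t")[::2]) for l in lines]
        assert len(pairs) == len({frozenset(p) for p in pairs})

    def test_random_matrices_have_no_duplicate_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            m = rng.uniform(size=(8, 8))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            names = [f"g{i}" for i in range(8)]
            df = pd.DataFrame(m, index=names, columns=names)
            out = export_network_edges(df, names, 0.3)
            keys = {frozenset((s, t)) for s, t in out[["source", "target"]].to_numpy()}
            assert len(keys) == len(out)
            assert (out["source"] < out["target"]).all()

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            export_network_edges(self._weights(), ["a"], 1.5)
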