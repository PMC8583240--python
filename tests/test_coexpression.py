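"""Network construction, TOM oracle, module recovery, eigengenes, hubs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lncforge.coexpression import (
    adjacency,
    correlation_matrix,
    detect_modules,
    eigengene_matrix,
    export_edge_list,
    hub_genes,
    module_eigengene,
    module_membership,
    module_trait_correlation,
    pick_soft_threshold,
    scale_free_fit,
    topological_overlap,
)
from lncforge.simulate import rng_stream


def frame(x, prefix="g"):
    return pd.DataFrame(
        x, index=[f"{prefix}{i}" for i in range(x.shape[0])],
        columns=[f"s{j}" for j in range(x.shape[1])],
    )


def factor_block(rng, n_genes, n_samples, loading, latent=None):
    if latent is None:
        latent = rng.normal(size=n_samples)
    noise = rng.normal(size=(n_genes, n_samples))
    return loading * latent[None, :] + np.sqrt(1 - loading ** 2) * noise, latent


class TestAdjacency:
    def test_identical_and_orthogonal_genes(self):
        rng = rng_stream(40, "adj")
        base = rng.normal(size=50)
        x = np.vstack([base, base, rng.normal(size=50)])
        a = adjacency(frame(x), beta=6)
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] < 0.05  # |noise cor|^6 is tiny

    def test_beta_one_is_abs_correlation(self):
        rng = rng_stream(41, "adj1")
        x = rng.normal(size=(10, 30))
        a = adjacency(frame(x), beta=1)
        c = np.abs(correlation_matrix(frame(x)))
        np.fill_diagonal(c, 1.0)
        assert np.allclose(a, c)

    def test_entries_bounded_and_beta_monotone(self):
        rng = rng_stream(42, "adjmono")
        x = rng.normal(size=(15, 25))
        a3 = adjacency(frame(x), beta=3)
        a6 = adjacency(frame(x), beta=6)
        assert ((a3 >= 0) & (a3 <= 1)).all()
        off = ~np.eye(15, dtype=bool)
        assert (a6[off] <= a3[off] + 1e-12).all()

    def test_rejects_bad_beta_and_drops_constant(self):
        with pytest.raises(ValueError):
            adjacency(frame(np.random.default_rng(0).normal(size=(4, 10))), beta=0)
        x = np.vstack([np.ones(10), np.random.default_rng(1).normal(size=(3, 10))])
        a = adjacency(frame(x), beta=2)
        assert a.shape == (3, 3)  # constant gene removed


class TestPickSoftThreshold:
    def test_single_power_returned(self):
        rng = rng_stream(43, "one-power")
        expr = frame(rng.normal(size=(20, 12)))
        beta, diag = pick_soft_threshold(expr, powers=[1])
        assert beta == 1 and len(diag) == 1

    def test_independent_noise_triggers_fallback(self, caplog):
        # low powers cannot make independent noise look scale-free (very
        # high powers can, spuriously, via each gene's maximal chance
        # correlation, which is why the fallback exists)
        rng = rng_stream(44, "null-power")
        expr = frame(rng.normal(size=(40, 30)))
        with caplog.at_level("WARNING"):
            beta, diag = pick_soft_threshold(expr, powers=[1, 2, 3, 4])
        assert beta == 6
        assert (diag["r_squared"] < 0.8).all()
        assert "falling back" in caplog.text

    def test_needs_eight_samples(self):
        expr = frame(np.random.default_rng(2).normal(size=(10, 7)))
        with pytest.raises(ValueError):
            pick_soft_threshold(expr)

    def test_scale_free_fixture_agrees_with_grid_oracle(self):
        # geometric block sizes give a heavy-tailed connectivity
        # distribution; the chosen power must land within +-2 of an
        # independent grid search for the best scale-free fit
        rng = rng_stream(23, "scale-free")
        rows = []
        for b in (64, 32, 16, 8, 4, 2):
            block, _ = factor_block(rng, b, 120, 0.95)
            rows.append(block)
        expr = frame(np.vstack(rows))
        powers = list(range(1, 13))
        beta, diag = pick_soft_threshold(expr, powers=powers)
        cor = np.abs(correlation_matrix(expr))
        np.fill_diagonal(cor, 0.0)
        r2 = {p: scale_free_fit((cor ** p).sum(axis=1)) for p in powers}
        oracle = max(r2, key=r2.get)
        assert abs(beta - oracle) <= 2
        assert r2[oracle] >= 0.8


class TestTopologicalOverlap:
    def test_two_gene_network(self):
        a12 = 0.37
        a = np.array([[1.0, a12], [a12, 1.0]])
        tom = topological_overlap(a)
        # empty shared-neighbour sum; min(k) = a12 so TOM_12 = a12
        assert tom[0, 1] == pytest.approx(a12, abs=1e-12)
        assert tom[0, 0] == 1.0

    def test_identity_adjacency(self):
        tom = topological_overlap(np.eye(5))
        assert np.allclose(tom, np.eye(5))

    def test_matches_triple_loop_oracle(self):
        rng = rng_stream(45, "tom-oracle")
        for n in (5, 17, 30, 50):
            c = rng.uniform(size=(n, n))
            a = (c + c.T) / 2.0
            np.fill_diagonal(a, 1.0)
            tom = topological_overlap(a)
            assert np.allclose(tom, tom.T)
            assert ((tom >= 0) & (tom <= 1)).all()
            # direct O(n^3) evaluation of the published formula
            for i in range(n):
                for j in range(n):
                    if i == j:
                        assert tom[i, j] == 1.0
                        continue
                    shared = sum(
                        a[i, u] * a[u, j]
                        for u in range(n) if u != i and u != j
                    )
                    ki = sum(a[i, u] for u in range(n) if u != i)
                    kj = sum(a[j, u] for u in range(n) if u != j)
                    expected = (shared + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
                    assert tom[i, j] == pytest.approx(expected, abs=1e-10)

    def test_rejects_asymmetric_or_nonsquare(self):
        with pytest.raises(ValueError):
            topological_overlap(np.ones((2, 3)))
        bad = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError):
            topological_overlap(bad)


def two_block_expr(seed, n_per_block=30, n_samples=40, within_cor=0.9):
    rng = rng_stream(seed, "two-block")
    loading = np.sqrt(within_cor)  # pairwise cor = loading^2
    b1, _ = factor_block(rng, n_per_block, n_samples, loading)
    b2, _ = factor_block(rng, n_per_block, n_samples, loading)
    truth = [1] * n_per_block + [2] * n_per_block
    return frame(np.vstack([b1, b2])), truth


class TestDetectModules:
    def test_two_planted_blocks_exact_recovery(self):
        expr, truth = two_block_expr(29)
        tom = topological_overlap(adjacency(expr, beta=6))
        assignment = detect_modules(tom, expr.index)
        assert adjusted_rand_score(truth, assignment.to_numpy()) == 1.0
        assert set(assignment) == {1, 2}

    def test_min_size_larger_than_n(self, caplog):
        expr, _ = two_block_expr(30, n_per_block=5)
        tom = topological_overlap(adjacency(expr, beta=6))
        with caplog.at_level("WARNING"):
            assignment = detect_modules(tom, expr.index, min_size=100)
        assert (assignment == 0).all()

    def test_single_block(self):
        rng = rng_stream(46, "one-block")
        block, _ = factor_block(rng, 40, 40, 0.95)
        expr = frame(block)
        tom = topological_overlap(adjacency(expr, beta=6))
        assignment = detect_modules(tom, expr.index)
        assert (assignment == 1).all()

    def test_labels_by_decreasing_size(self):
        rng = rng_stream(47, "sizes")
        big, _ = factor_block(rng, 50, 60, 0.95)
        small, _ = factor_block(rng, 32, 60, 0.95)
        expr = frame(np.vstack([small, big]))
        tom = topological_overlap(adjacency(expr, beta=6))
        assignment = detect_modules(tom, expr.index)
        # module 1 is the larger block even though it appears second
        assert (assignment == 1).sum() == 50
        assert (assignment.iloc[:32] == 2).all()


class TestModuleEigengene:
    def test_identical_members(self):
        rng = rng_stream(48, "ident-eg")
        profile = rng.normal(size=30)
        expr = frame(np.vstack([profile * 2 + 5, profile * -1 + 1, profile]))
        # all rows are affine images of one profile: standardized they are
        # +-z; eigengene must match the mean-oriented standardized profile
        eg, explained = module_eigengene(expr, expr.index)
        assert explained == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        assert abs(np.corrcoef(eg, z)[0, 1]) == pytest.approx(1.0)
        assert eg.std(ddof=0) == pytest.approx(1.0)

    def test_factor_recovery_loading_09(self):
        rng = rng_stream(31, "eg-recovery")
        block, latent = factor_block(rng, 50, 60, 0.9)
        expr = frame(block)
        eg, _ = module_eigengene(expr, expr.index)
        assert abs(np.corrcoef(eg, latent)[0, 1]) >= 0.95

    def test_factor_recovery_loading_08_bound(self):
        rng = rng_stream(49, "eg-08")
        block, latent = factor_block(rng, 30, 40, 0.8)
        expr = frame(block)
        eg, _ = module_eigengene(expr, expr.index)
        assert abs(np.corrcoef(eg, latent)[0, 1]) >= 0.9

    def test_sign_orientation_contract(self):
        rng = rng_stream(50, "eg-sign")
        block, _ = factor_block(rng, 20, 30, 0.9)
        expr = frame(block)
        for data in (block, -block):
            eg, _ = module_eigengene(frame(data), expr.index)
            x = data
            z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
            assert np.dot(eg.to_numpy(), z.mean(axis=0)) >= 0

    def test_requires_two_members(self):
        expr = frame(np.random.default_rng(3).normal(size=(3, 10)))
        with pytest.raises(ValueError):
            module_eigengene(expr, ["g0"])


class TestModuleTrait:
    def test_trait_equals_eigengene(self):
        rng = rng_stream(51, "trait-id")
        eg = pd.DataFrame({1: rng.normal(size=20)})
        out = module_trait_correlation(eg, eg[1].to_numpy())
        assert out.at[0, "pcc"] == pytest.approx(1.0)

    def test_permutation_null(self):
        rng = rng_stream(37, "trait-null")
        n = 60
        eg = pd.DataFrame({1: rng.normal(size=n)})
        trait = np.array([0.0, 1.0] * (n // 2))
        pccs = []
        for _ in range(500):
            rng.shuffle(trait)
            pccs.append(abs(module_trait_correlation(eg, trait).at[0, "pcc"]))
        assert np.quantile(pccs, 0.95) <= 2.1 / np.sqrt(n)

    def test_planted_trait_correlation_recovered(self):
        # latent = trait + N(0, 0.5); with a balanced 0/1 trait the
        # generating correlation is 0.5 / sqrt(0.25 + 0.25) = 0.7071
        rng = rng_stream(52, "trait-planted")
        n = 162
        trait = np.array([0.0, 1.0] * (n // 2))
        latent = trait + rng.normal(0.0, 0.5, size=n)
        block, _ = factor_block(rng, 40, n, 0.9, latent=(latent - latent.mean()) / latent.std())
        expr = frame(block)
        eg, _ = module_eigengene(expr, expr.index)
        pcc = module_trait_correlation(pd.DataFrame({1: eg}), trait).at[0, "pcc"]
        assert abs(abs(pcc) - 0.7071) <= 0.1

    def test_zero_variance_trait_and_length_mismatch(self):
        eg = pd.DataFrame({1: np.arange(10.0)})
        with pytest.raises(ValueError):
            module_trait_correlation(eg, np.ones(10))
        with pytest.raises(ValueError):
            module_trait_correlation(eg, np.ones(5))


class TestModuleMembership:
    def test_gene_identical_to_eigengene(self):
        rng = rng_stream(53, "kme-id")
        block, _ = factor_block(rng, 30, 40, 0.9)
        expr = frame(block)
        assignment = pd.Series(1, index=expr.index)
        egs = eigengene_matrix(expr, assignment)
        probe = expr.copy()
        probe.loc["probe"] = egs[1].to_numpy()
        kme = module_membership(probe, egs)
        assert kme.at["probe", 1] == pytest.approx(1.0)

    def test_noise_gene_small_kme(self):
        rng = rng_stream(54, "kme-null")
        n = 50
        block, _ = factor_block(rng, 30, n, 0.9)
        expr = frame(block)
        egs = eigengene_matrix(expr, pd.Series(1, index=expr.index))
        hits = 0
        reps = 100
        for _ in range(reps):
            probe = pd.DataFrame(rng.normal(size=(1, n)), index=["noise"],
                                 columns=expr.columns)
            if abs(module_membership(probe, egs).at["noise", 1]) <= 2.1 / np.sqrt(n):
                hits += 1
        assert hits / reps >= 0.95

    def test_hub_kme_exceeds_peripheral_every_seed(self):
        for seed in range(100):
            rng = rng_stream(seed, "kme-hub-vs-peripheral")
            latent = rng.normal(size=40)
            hub = 0.95 * latent + np.sqrt(1 - 0.95 ** 2) * rng.normal(size=40)
            per = 0.50 * latent + np.sqrt(1 - 0.50 ** 2) * rng.normal(size=40)
            block, _ = factor_block(rng, 28, 40, 0.85, latent=latent)
            expr = frame(np.vstack([block, hub, per]))
            ids = list(expr.index)
            expr.index = ids[:-2] + ["hub", "per"]
            egs = eigengene_matrix(expr, pd.Series(1, index=expr.index))
            kme = module_membership(expr, egs)
            assert kme.at["hub", 1] > kme.at["per", 1]


class TestHubGenes:
    @staticmethod
    def planted_hub_fixture(seed=41, n_samples=80):
        rng = rng_stream(seed, "hub-fixture")
        latent = rng.normal(size=n_samples)
        hubs = [0.9 * latent + np.sqrt(1 - 0.81) * rng.normal(size=n_samples)
                for _ in range(3)]
        others = [0.45 * latent + np.sqrt(1 - 0.45 ** 2) * rng.normal(size=n_samples)
                  for _ in range(30)]
        x = np.vstack(hubs + others)
        expr = frame(x)
        names = [f"hub{i}" for i in range(3)] + [f"mem{i}" for i in range(30)]
        expr.index = names
        assignment = pd.Series(1, index=expr.index)
        egs = eigengene_matrix(expr, assignment)
        kme = module_membership(expr, egs)
        return expr, assignment, kme

    def test_exact_threshold_excluded(self):
        kme = pd.DataFrame({1: [0.7, 0.71]}, index=["edge", "in"])
        assignment = pd.Series(1, index=kme.index)
        hubs = hub_genes(kme, assignment)
        assert hubs["gene_id"].tolist() == ["in"]

    def test_unassigned_genes_never_hubs(self):
        kme = pd.DataFrame({1: [0.99]}, index=["g"])
        assert hub_genes(kme, pd.Series(0, index=["g"])).empty

    def test_planted_hubs_exactly_recovered(self):
        _, assignment, kme = self.planted_hub_fixture()
        hubs = hub_genes(kme, assignment)
        assert sorted(hubs["gene_id"]) == ["hub0", "hub1", "hub2"]

    def test_restrict_to_filters(self):
        _, assignment, kme = self.planted_hub_fixture()
        hubs = hub_genes(kme, assignment, restrict_to=["hub1", "mem0"])
        assert hubs["gene_id"].tolist() == ["hub1"]

    def test_threshold_validation(self):
        kme = pd.DataFrame({1: [0.9]}, index=["g"])
        with pytest.raises(ValueError):
            hub_genes(kme, pd.Series(1, index=["g"]), threshold=1.0)


def test_export_edge_list(tmp_path):
    a = np.array([[1.0, 0.5, 0.1], [0.5, 1.0, 0.2], [0.1, 0.2, 1.0]])
    path = tmp_path / "edges.tsv"
    export_edge_list(a, ["a", "b", "c"], str(path), min_weight=0.15)
    lines = path.read_text().splitlines()
    assert lines[0] == "gene_i\tgene_j\ttom"
    assert lines[1:] == ["a\tb\t0.5", "b\tc\t0.2"]
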