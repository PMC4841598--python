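"""Coexpression network construction, module detection and statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from ripenet.network import (
    UNASSIGNED,
    NetworkConfig,
    NetworkError,
    WGCNA,
    adjacency_unsigned,
    compute_kme_gs,
    detect_modules,
    filter_expressed,
    hub_screen,
    module_eigengene,
    module_trait_correlation,
    permute_module_to,
    pick_soft_threshold,
    tom_similarity,
)


def _expr(rows, genes=None, samples=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=genes, columns=samples)


class TestFilter:
    def test_floor_rule(self):
        expr = _expr([[0, 0, 0], [0.31, 0.0, 0.0], [0.2, 0.25, 0.1]])
        kept = filter_expressed(expr, floor=0.3)
        assert list(kept.index) == ["g1"]  # max-across-samples rule

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.exponential(0.5, (40, 6)))
        kept = filter_expressed(expr, 0.3)
        expected = [g for g in expr.index if expr.loc[g].max() > 0.3]
        assert list(kept.index) == expected

    def test_mean_variant_and_empty(self):
        expr = _expr([[0.5, 0.0], [0.0, 0.1]])
        assert list(filter_expressed(expr, 0.2, how="mean").index) == ["g0"]
        with pytest.raises(NetworkError):
            filter_expressed(expr, floor=10.0)


class TestAdjacency:
    def test_perfect_and_zero_correlation(self):
        expr = _expr([[1, 2, 3, 4], [2, 4, 6, 8], [-1, -2, -3, -4]])
        a = adjacency_unsigned(expr, beta=6)
        assert a.at["g0", "g1"] == pytest.approx(1.0)
        assert a.at["g0", "g2"] == pytest.approx(1.0)  # unsigned: |cor|
        assert np.diag(a).sum() == 0.0

    def test_matches_per_pair_oracle(self):
        rng = np.random.default_rng(2)
        expr = _expr(rng.standard_normal((4, 8)))
        a = adjacency_unsigned(expr, beta=3)
        for i in range(4):
            for j in range(i + 1, 4):
                r = np.corrcoef(expr.iloc[i], expr.iloc[j])[0, 1]
                assert a.iloc[i, j] == pytest.approx(abs(r) ** 3, rel=1e-10)

    def test_zero_variance_named(self):
        expr = _expr([[1, 1, 1, 1], [1, 2, 3, 4]], genes=["flat", "ok"])
        with pytest.raises(NetworkError, match="flat"):
            adjacency_unsigned(expr)


class TestTOM:
    def test_closed_forms(self):
        # n-clique at full weight: l = n-2, k = n-1 -> tom = 1
        n = 5
        a = pd.DataFrame(1.0 - np.eye(n))
        np.fill_diagonal(a.to_numpy(), 0.0)
        tom = tom_similarity(a)
        off = tom.to_numpy()[~np.eye(n, dtype=bool)]
        assert off == pytest.approx(np.ones(n * (n - 1)))
        # disconnected pair with no shared neighbours
        b = pd.DataFrame(np.zeros((3, 3)))
        assert tom_similarity(b).iloc[0, 1] == 0.0

    def test_three_node_hand_computation(self):
        a = pd.DataFrame(
            [[0.0, 0.5, 0.2], [0.5, 0.0, 0.8], [0.2, 0.8, 0.0]]
        )
        tom = tom_similarity(a)
        # hand evaluation: l_01 = 0.2*0.8, k = (0.7, 1.3), denom = 0.7+1-0.5
        assert tom.iloc[0, 1] == pytest.approx((0.16 + 0.5) / 1.2)
        assert tom.iloc[0, 2] == pytest.approx((0.4 + 0.2) / (0.7 + 1 - 0.2))

    @settings(max_examples=50, deadline=None)
    @given(
        hnp.arrays(
            float, (6, 6), elements=st.floats(0, 1, allow_nan=False)
        )
    )
    def test_entries_bounded(self, raw):
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        assert (tom >= 0).all() and (tom <= 1).all()
        assert tom == pytest.approx(tom.T)


class TestSoftThreshold:
    def test_correlated_blocks_take_smallest_power(self):
        # two perfectly correlated blocks: every power fits, smallest returned
        rng = np.random.default_rng(2)
        f1, f2 = rng.standard_normal((2, 10))
        expr = _expr([f1] * 20 + [f2] * 20)
        power, report = pick_soft_threshold(expr, candidate_powers=(2, 4, 6))
        assert power == 2
        assert report.loc[2, "fit_r2"] >= 0.8

    def test_noise_falls_back_with_warning(self):
        rng = np.random.default_rng(0)
        expr = _expr(rng.standard_normal((30, 8)))
        with pytest.warns(UserWarning, match="falling back"):
            power, report = pick_soft_threshold(expr, candidate_powers=(2, 4))
        assert power == int(report["fit_r2"].idxmax())

    def test_too_few_genes(self):
        with pytest.raises(NetworkError):
            pick_soft_threshold(_expr(np.ones((2, 6))))


class TestEigengene:
    def test_identical_profiles_recovered(self):
        profile = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 0.2])
        expr = _expr(np.tile(profile, (4, 1)))
        e = module_eigengene(expr, expr.index)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert e.to_numpy() == pytest.approx(z)  # sign-aligned with members
        assert e.std(ddof=1) == pytest.approx(1.0)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(4)
        expr = _expr(rng.standard_normal((3, 7)))
        e = module_eigengene(expr, expr.index)
        z = stats.zscore(expr.to_numpy(), axis=1, ddof=1)
        u, s, vt = np.linalg.svd(z)
        ref = vt[0] / np.std(vt[0], ddof=1)
        assert np.abs(np.corrcoef(e, ref)[0, 1]) == pytest.approx(1.0)

    def test_degenerate_inputs(self):
        expr = _expr(np.ones((3, 6)) + np.arange(6))
        with pytest.raises(NetworkError):
            module_eigengene(expr, ["g0"])


class TestDetectModules:
    def test_two_planted_blocks(self, module_expression):
        expr, truth = module_expression
        cfg = NetworkConfig(min_module_size=30)
        tom = tom_similarity(adjacency_unsigned(expr, 6))
        part = detect_modules(tom, cfg, expr=expr)
        blocks = part.labels.groupby(truth).value_counts()
        # the two planted blocks map to exactly two distinct modules
        mod_a = part.labels[truth == "A"].mode()[0]
        mod_b = part.labels[truth == "B"].mode()[0]
        assert mod_a != mod_b and UNASSIGNED not in (mod_a, mod_b)
        assert (part.labels[truth == "A"] == mod_a).mean() >= 0.9
        assert part.sizes.min() >= cfg.min_module_size

    def test_small_group_goes_grey(self, module_expression):
        # a coherent 10-gene group below minModuleSize 30 gets no module
        expr, truth = module_expression
        rng = np.random.default_rng(8)
        f = rng.standard_normal(expr.shape[1])
        small = _expr(
            [0.95 * f + rng.normal(0, 0.1, expr.shape[1]) for _ in range(10)],
            genes=[f"tiny{i}" for i in range(10)],
            samples=list(expr.columns),
        )
        full = pd.concat([expr, small])
        tom = tom_similarity(adjacency_unsigned(full, 6))
        part = detect_modules(tom, NetworkConfig(min_module_size=30), expr=full)
        assert (part.labels.loc[small.index] == UNASSIGNED).all()
        assert part.sizes.size == 2  # only the two big blocks form modules

    def test_block_size_limit(self):
        tom = pd.DataFrame(np.eye(5))
        with pytest.raises(NetworkError, match="max_block_size"):
            detect_modules(tom, NetworkConfig(max_block_size=4, min_module_size=2))

    def test_merge_fixed_point(self):
        # after merging, no eigengene pair is closer than merge_cut_height
        rng = np.random.default_rng(12)
        f = rng.standard_normal(14)
        rows = [0.95 * f + rng.normal(0, 0.3, 14) for _ in range(80)]
        expr = _expr(rows)
        model = WGCNA(min_module_size=10, merge_cut_height=0.25).fit(expr.T)
        eig = model.eigengenes_
        if eig.shape[1] > 1:
            d = 1 - np.corrcoef(eig.to_numpy().T)
            np.fill_diagonal(d, 1.0)
            assert d.min() >= 0.25


class TestCorrelationLayer:
    def test_kme_gs_textbook_oracle(self):
        rng = np.random.default_rng(6)
        expr = _expr(rng.standard_normal((5, 9)))
        eig = pd.DataFrame(
            rng.standard_normal((9, 2)), index=expr.columns, columns=["m1", "m2"]
        )
        traits = pd.DataFrame(
            rng.standard_normal((9, 1)), index=expr.columns, columns=["acid"]
        )
        kme, kme_p, gs, gs_p = compute_kme_gs(expr, eig, traits)
        for g in expr.index:
            for m in eig.columns:
                r, p = stats.pearsonr(expr.loc[g], eig[m])
                assert kme.at[g, m] == pytest.approx(r)
                assert kme_p.at[g, m] == pytest.approx(p)
            r, p = stats.pearsonr(expr.loc[g], traits["acid"])
            assert gs.at[g, "acid"] == pytest.approx(r)
            assert gs_p.at[g, "acid"] == pytest.approx(p)

    def test_self_and_orthogonal_vectors(self):
        e = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        # centered dot product of "orth" with trait "t" is exactly zero
        expr = _expr([e, [1, 0, -1, 1, 0, -1]], genes=["self", "orth"])
        eig = pd.DataFrame({"m": e}, index=expr.columns)
        trait = pd.DataFrame(
            {"t": np.array([1, -2, 1, 1, -2, 1], dtype=float)}, index=expr.columns
        )
        kme, _, gs, _ = compute_kme_gs(expr, eig, trait)
        assert kme.at["self", "m"] == pytest.approx(1.0)
        assert np.dot(trait["t"] - trait["t"].mean(),
                      expr.loc["orth"] - expr.loc["orth"].mean()) == 0
        assert gs.at["orth", "t"] == pytest.approx(0.0)


class TestModuleTrait:
    def test_trait_equal_to_eigengene(self):
        rng = np.random.default_rng(10)
        eig = pd.DataFrame({"blue": rng.standard_normal(8)})
        traits = pd.DataFrame({"acid": eig["blue"]})
        out = module_trait_correlation(eig, traits)
        row = out.iloc[0]
        assert row["r"] == pytest.approx(1.0) and row["significant"]

    def test_cutoff_rule_needs_both_r_and_p(self):
        # |r| = 0.85 with n = 6 gives p ~ 0.03 -> significant
        rng = np.random.default_rng(3)
        for _ in range(20):
            e = rng.standard_normal(6)
            t = 0.9 * e + rng.normal(0, 0.55, 6)
            r = np.corrcoef(e, t)[0, 1]
            if 0.82 < abs(r) < 0.88:
                break
        eig = pd.DataFrame({"m": e})
        out = module_trait_correlation(eig, pd.DataFrame({"t": t}, index=eig.index))
        assert out.iloc[0]["significant"] == (
            abs(out.iloc[0]["r"]) > 0.8 and out.iloc[0]["p"] < 0.05
        )
        # |r| = 0.85 at n = 4 has p ~ 0.15 -> fails the p arm of the rule
        e4, t4 = e[:4], t[:4]
        out4 = module_trait_correlation(
            pd.DataFrame({"m": e4}), pd.DataFrame({"t": t4})
        )
        if abs(out4.iloc[0]["r"]) < 0.95:
            assert not out4.iloc[0]["significant"]

    def test_permuted_trait_type_i_error(self):
        rng = np.random.default_rng(77)
        n_perm, n = 1000, 10
        eig = pd.DataFrame({"m": rng.standard_normal(n)})
        hits = 0
        for _ in range(n_perm):
            t = pd.DataFrame({"t": rng.permutation(np.arange(n, dtype=float))},
                             index=eig.index)
            p = module_trait_correlation(eig, t).iloc[0]["p"]
            hits += p < 0.05
        frac = hits / n_perm
        se = np.sqrt(0.05 * 0.95 / n_perm)
        assert frac <= 0.05 + 3 * se

    def test_misaligned_samples(self):
        eig = pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        tr = pd.DataFrame({"t": [1.0, 2.0, 3.0]}, index=["a", "b", "x"])
        with pytest.raises(NetworkError):
            module_trait_correlation(eig, tr)


class TestHubScreen:
    def _tables(self, gs_val, gs_p, mm_val, mm_p):
        labels = pd.Series({"g": "blue"})
        kme = pd.DataFrame({"blue": [mm_val]}, index=["g"])
        kme_p = pd.DataFrame({"blue": [mm_p]}, index=["g"])
        gs = pd.DataFrame({"acid": [gs_val]}, index=["g"])
        gsp = pd.DataFrame({"acid": [gs_p]}, index=["g"])
        return hub_screen(labels, kme, kme_p, gs, gsp)

    def test_rule(self):
        assert len(self._tables(0.9, 0.01, 0.9, 0.01)) == 1
        assert self._tables(0.9, 0.01, 0.5, 0.01).empty
        assert self._tables(0.9, 0.2, 0.9, 0.01).empty

    def test_planted_hub_recovery(self):
        rng = np.random.default_rng(15)
        f = rng.standard_normal(20)
        hub_rows = [0.99 * f + rng.normal(0, 0.05, 20) for _ in range(5)]
        loose_rows = [0.5 * f + rng.normal(0, 0.9, 20) for _ in range(5)]
        expr = _expr(hub_rows + loose_rows,
                     genes=[f"hub{i}" for i in range(5)] + [f"ls{i}" for i in range(5)])
        eig = pd.DataFrame({"blue": (f - f.mean()) / f.std(ddof=1)},
                           index=expr.columns)
        traits = pd.DataFrame({"acid": f + rng.normal(0, 0.1, 20)},
                              index=expr.columns)
        labels = pd.Series("blue", index=expr.index)
        kme, kme_p, gs, gs_p = compute_kme_gs(expr, eig, traits)
        hubs = set(hub_screen(labels, kme, kme_p, gs, gs_p)["gene_id"])
        assert {f"hub{i}" for i in range(5)} <= hubs
        assert not any(g.startswith("ls") and gs.at[g, "acid"] < 0.8 for g in hubs)


class TestPermutation:
    def test_planted_module_beats_all_nulls(self, module_expression):
        expr, truth = module_expression
        tom = tom_similarity(adjacency_unsigned(expr, 6))
        rep = permute_module_to(tom, expr.index[truth == "A"], b=999, seed=0)
        assert rep.p_value == pytest.approx(1 / 1000)
        assert rep.observed_mean_to > rep.null_mean_to.max()

    def test_random_set_p_roughly_uniform(self, module_expression):
        expr, _ = module_expression
        tom = tom_similarity(adjacency_unsigned(expr, 6))
        rng = np.random.default_rng(1)
        ps = []
        for s in range(40):
            members = rng.choice(expr.index, 10, replace=False)
            ps.append(permute_module_to(tom, members, b=99, seed=s).p_value)
        ps = np.array(ps)
        # roughly uniform: spread across (0, 1], not piled at either end
        assert 0.25 < np.mean(ps) < 0.75
        assert (ps > 0.5).mean() > 0.2 and (ps < 0.5).mean() > 0.2

    def test_degenerate_inputs(self, module_expression):
        expr, _ = module_expression
        tom = tom_similarity(adjacency_unsigned(expr, 6))
        with pytest.raises(NetworkError):
            permute_module_to(tom, expr.index[:1], b=99)
        with pytest.raises(NetworkError):
            permute_module_to(tom, expr.index[:5], b=0)


def test_wgcna_estimator_sklearn_contract(module_expression):
    expr, truth = module_expression
    model = WGCNA(min_module_size=20)
    params = model.get_params()
    assert params["min_module_size"] == 20
    model.set_params(min_module_size=30)
    labels = model.fit_predict(expr.T)
    assert len(labels) == len(expr)
    assert model.eigengenes_.shape == (expr.shape[1], model.n_modules_)
    # kME of a gene with its own module agrees with the independent pearson
    kme, _, _, _ = compute_kme_gs(expr, model.eigengenes_)
    g = expr.index[0]
    own = model.module_labels_[g]
    r, _ = stats.pearsonr(expr.loc[g], model.eigengenes_[own])
    assert kme.at[g, own] == pytest.approx(r)
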