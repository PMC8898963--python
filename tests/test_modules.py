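import numpy as np
import pandas as pd
import pytest

import regscore as rs
from regscore.modules import scale_free_fit, tom_similarity


def _two_block_expr(n_per_block=40, n_samples=60, noise=0.3, seed=0):
    """Two tight co-expression blocks driven by independent latent factors."""
    rng = np.random.default_rng(seed)
    f1 = rng.normal(size=n_samples)
    f2 = rng.normal(size=n_samples)
    rows = {}
    for i in range(n_per_block):
        rows[f"a{i}"] = f1 + rng.normal(0, noise, n_samples)
    for i in range(n_per_block):
        rows[f"b{i}"] = f2 + rng.normal(0, noise, n_samples)
    df = pd.DataFrame(rows, index=[f"s{j}" for j in range(n_samples)]).T
    return rs.ExpressionMatrix(df)


class TestSoftThreshold:
    def test_mean_connectivity_monotone_in_power(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(60, 40)),
                          index=[f"g{i}" for i in range(60)],
                          columns=[f"s{i}" for i in range(40)])
        _, tab = rs.pick_soft_threshold(rs.ExpressionMatrix(df),
                                        powers=[1, 2, 4, 6, 8])
        k = tab["mean_k"].to_numpy()
        assert (np.diff(k) < 0).all()

    def test_fit_table_matches_independent_recompute(self):
        """Fit statistics recomputed directly from the adjacency definition."""
        expr = _two_block_expr(20, 30, seed=2)
        beta, tab = rs.pick_soft_threshold(expr, powers=[2, 6])
        x = expr.values
        for _, row in tab.iterrows():
            c = np.corrcoef(x)
            a = np.abs(c) ** row["power"]
            np.fill_diagonal(a, 0.0)
            k = a.sum(axis=1)
            r2, slope = scale_free_fit(k)
            assert row["sft_r2"] == pytest.approx(r2, abs=1e-12)
            assert row["mean_k"] == pytest.approx(k.mean(), abs=1e-9)

    def test_forced_single_power(self):
        expr = _two_block_expr(10, 20, seed=3)
        beta, tab = rs.pick_soft_threshold(expr, powers=[12])
        assert beta == 12
        assert list(tab["power"]) == [12]

    def test_selection_deterministic_and_bounded(self):
        """The selection rule is deterministic given the data and always
        returns a power from the candidate list; across seeds the median
        choice stays in the conventional range for small panels. (Desk-scale
        panels rarely reach the 0.85 scale-free target, so the argmax
        fallback governs; per-seed scatter is inherent to it.)"""
        betas = []
        for seed in range(10):
            expr = _two_block_expr(25, 40, seed=seed)
            b1, _ = rs.pick_soft_threshold(expr)
            b2, _ = rs.pick_soft_threshold(expr)
            assert b1 == b2
            betas.append(b1)
        powers = set(range(1, 13)) | {14, 16, 18, 20}
        assert set(betas) <= powers
        assert 1 <= np.median(betas) <= 20


class TestTOM:
    def test_matches_formula_transcription(self):
        """10-gene toy: TOM equals the direct formula
        (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
        expr = _two_block_expr(5, 15, seed=4)
        x = expr.values
        a = np.abs(np.corrcoef(x)) ** 2
        np.fill_diagonal(a, 0.0)
        tom = tom_similarity(a)
        n = a.shape[0]
        k = a.sum(axis=1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                l_ij = sum(a[i, u] * a[u, j] for u in range(n)
                           if u != i and u != j)
                expected = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_unit_interval(self):
        expr = _two_block_expr(10, 25, seed=5)
        a = np.abs(np.corrcoef(expr.values)) ** 3
        np.fill_diagonal(a, 0.0)
        tom = tom_similarity(a)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12


class TestDetectModules:
    def test_two_blocks_two_modules(self):
        expr = _two_block_expr(40, 60, noise=0.2, seed=6)
        mr = rs.detect_modules(expr, beta=6, min_module_size=10)
        assert len(mr.modules) == 2
        labels = mr.module_of
        a_mods = set(labels[[g for g in labels.index if g.startswith("a")]])
        b_mods = set(labels[[g for g in labels.index if g.startswith("b")]])
        assert len(a_mods) == 1 and len(b_mods) == 1 and a_mods != b_mods

    def test_merge_cut_one_no_merging(self):
        expr = _two_block_expr(40, 60, noise=0.2, seed=7)
        mr_nomerge = rs.detect_modules(expr, beta=6, min_module_size=10,
                                       merge_cut=1.0)
        mr_merge = rs.detect_modules(expr, beta=6, min_module_size=10,
                                     merge_cut=0.75)
        assert len(mr_nomerge.modules) >= len(mr_merge.modules)

    def test_correlated_blocks_merge_below_cut(self):
        """Blocks driven by near-identical factors merge at cut 0.75."""
        rng = np.random.default_rng(8)
        f = rng.normal(size=50)
        rows = {}
        for i in range(20):
            rows[f"a{i}"] = f + rng.normal(0, 0.2, 50)
        for i in range(20):
            rows[f"b{i}"] = 0.95 * f + rng.normal(0, 0.25, 50)
        expr = rs.ExpressionMatrix(
            pd.DataFrame(rows, index=[f"s{j}" for j in range(50)]).T)
        mr = rs.detect_modules(expr, beta=6, min_module_size=10,
                               merge_cut=0.75)
        assert len(mr.modules) == 1

    def test_eigengene_unit_variance_and_orientation(self):
        expr = _two_block_expr(30, 50, seed=9)
        mr = rs.detect_modules(expr, beta=6, min_module_size=10)
        for m in mr.modules:
            e = mr.eigengenes.loc[m]
            assert e.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
            members = mr.module_of[mr.module_of == m].index
            mean_prof = expr.data.loc[members].mean(axis=0)
            assert np.corrcoef(e, mean_prof)[0, 1] > 0

    def test_programs_land_in_distinct_modules(self, small_cohort):
        """Immune and stemness programs separate into different modules at
        delta=3 (unsigned network, power 12); deliberately shared overlap
        genes are excluded from the comparison."""
        from sklearn.metrics import adjusted_rand_score
        expr, truth, _ = small_cohort
        shared = (set(truth.program_genes["immune"])
                  & set(truth.program_genes["stemness"]))
        all_genes = sorted(set().union(*truth.program_genes.values()))
        mr = rs.detect_modules(expr.subset_genes(all_genes), beta=12,
                               min_module_size=8)
        prog = {g: name for name, gl in truth.program_genes.items()
                for g in gl if g not in shared}
        genes = sorted(prog)
        labels = mr.module_of.loc[genes]
        truth_labels = [prog[g] for g in genes]
        assert adjusted_rand_score(truth_labels, labels) > 0.8


class TestModuleTrait:
    def test_trait_equal_to_eigengene_r_one(self):
        expr = _two_block_expr(20, 40, seed=10)
        mr = rs.detect_modules(expr, beta=6, min_module_size=10)
        m0 = mr.modules[0]
        traits = pd.DataFrame({"t": mr.eigengenes.loc[m0]},
                              index=expr.sample_ids)
        mr = rs.module_trait(mr, traits)
        assert mr.module_trait_r.loc[m0, "t"] == pytest.approx(1.0, abs=1e-9)
        assert mr.module_trait_p.loc[m0, "t"] < 1e-10

    def test_pearson_matches_covariance_formula(self):
        """5-sample toy eigengene-trait r against the covariance formula."""
        expr = _two_block_expr(20, 5, seed=11)
        mr = rs.detect_modules(expr, beta=2, min_module_size=5)
        tv = np.array([0.3, -1.2, 0.5, 2.0, -0.4])
        traits = pd.DataFrame({"t": tv}, index=expr.sample_ids)
        mr = rs.module_trait(mr, traits)
        for m in mr.modules:
            e = mr.eigengenes.loc[m].to_numpy()
            r_hand = (np.sum((e - e.mean()) * (tv - tv.mean()))
                      / np.sqrt(np.sum((e - e.mean()) ** 2)
                                * np.sum((tv - tv.mean()) ** 2)))
            assert mr.module_trait_r.loc[m, "t"] == pytest.approx(r_hand,
                                                                  abs=1e-12)

    def test_constant_trait_flagged_not_error(self):
        expr = _two_block_expr(20, 30, seed=12)
        mr = rs.detect_modules(expr, beta=6, min_module_size=10)
        traits = pd.DataFrame({"c": np.ones(30)}, index=expr.sample_ids)
        mr = rs.module_trait(mr, traits)
        assert mr.module_trait_r["c"].isna().all()


class TestHubGenes:
    def test_thresholds_zero_returns_module(self):
        expr = _two_block_expr(20, 40, seed=13)
        mr = rs.detect_modules(expr, beta=6, min_module_size=10)
        traits = pd.DataFrame({"t": np.random.default_rng(0).normal(size=40)},
                              index=expr.sample_ids)
        mr = rs.module_trait(mr, traits)
        m0 = mr.modules[0]
        all_members = set(mr.module_of[mr.module_of == m0].index)
        assert set(rs.hub_genes(mr, m0, "t", 0.0, -1.0)) == all_members
        assert rs.hub_genes(mr, m0, "t", 1.01, 1.01) == []

    def test_planted_hub_always_selected(self):
        """A gene equal to the module eigengene plus tiny noise is a hub for
        a trait aligned with that eigengene."""
        rng = np.random.default_rng(14)
        f = rng.normal(size=50)
        rows = {f"a{i}": f + rng.normal(0, 0.4, 50) for i in range(20)}
        rows["hub"] = f + rng.normal(0, 0.01, 50)
        expr = rs.ExpressionMatrix(
            pd.DataFrame(rows, index=[f"s{j}" for j in range(50)]).T)
        mr = rs.detect_modules(expr, beta=6, min_module_size=10)
        m = mr.module_of["hub"]
        assert m != "grey"
        traits = pd.DataFrame({"t": f + rng.normal(0, 0.3, 50)},
                              index=expr.sample_ids)
        mr = rs.module_trait(mr, traits)
        assert "hub" in rs.hub_genes(mr, m, "t", gs_min=0.2, mm_min=0.8)
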