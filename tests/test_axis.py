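import itertools
import math

import numpy as np
import pandas as pd
import pytest

import stcomm as st
from stcomm.axis import (
    ap_pattern_genes,
    ap_regulon_selection,
    binarize_scores,
    cell_cycle_phase,
    dv_domain_genes,
    dv_regulon_selection,
    enumerate_section_patterns,
    module_score,
    wilcoxon_rank_sum,
)
from stcomm.datatypes import LOGNORM
from stcomm.io import lognormalize


def exact_rank_sum_p(x, y, alternative):
    """Rank-sum p by enumeration of all label assignments of the pooled sample."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2  # observed U of x
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[pooled[i]] for i in combo) - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.array(us)
    if alternative == "less":
        return np.mean(us <= obs)
    if alternative == "greater":
        return np.mean(us >= obs)
    return min(1.0, 2 * min(np.mean(us <= obs), np.mean(us >= obs)))


class TestSectionPatterns:
    def test_nine_sections_give_35(self):
        assert len(enumerate_section_patterns(9)) == 35

    def test_three_sections_defaults(self):
        pats = enumerate_section_patterns(3)
        assert [(p.start, p.length) for p in pats] == [(0, 2), (1, 2)]

    def test_four_sections_defaults(self):
        assert len(enumerate_section_patterns(4)) == 5

    @pytest.mark.parametrize("n", range(3, 16))
    def test_count_formula_matches_enumeration(self, n):
        pats = enumerate_section_patterns(n)
        expected = sum(n - l + 1 for l in range(2, n))
        assert len(pats) == expected
        # every pattern is one contiguous run
        for p in pats:
            runs = np.flatnonzero(np.diff(p.mask.astype(int)) != 0)
            assert p.mask.sum() == p.length and len(runs) <= 2

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            enumerate_section_patterns(5, min_len=4, max_len=2)
        with pytest.raises(ValueError):
            enumerate_section_patterns(2)


def _axis_matrix(values, ann_sections, genes=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    obs = [f"s{j}" for j in range(values.shape[1])]
    em = st.ExpressionMatrix(values, genes, obs, layer=LOGNORM)
    ann = st.SpotAnnotations(
        obs_ids=obs,
        section_index=np.asarray(ann_sections),
        array_x=np.zeros(len(obs)),
        array_y=np.arange(len(obs), dtype=float),
    )
    return em, ann


class TestApPatternGenes:
    def test_perfect_indicator_gene_selected(self):
        sections = np.repeat([1, 2, 3, 4], 4)
        vals = np.vstack([
            np.isin(sections, [2, 3]).astype(float),
            np.linspace(0, 1, 16) % 0.31,
        ])
        em, ann = _axis_matrix(vals, sections)
        table = ap_pattern_genes(em, ann, ["g0", "g1"], top_k=1)
        sub = table.table[(table.table.gene == "g0")
                          & (table.table.pattern_id == "S2-3")]
        assert sub["pcc"].iloc[0] == pytest.approx(
            table.table[table.table.pattern_id == "S2-3"]["pcc"].max()
        )
        assert "g0" in table.selected_genes

    def test_top_k_clamped_to_candidates(self):
        sections = np.repeat([1, 2, 3], 4)
        rng = np.random.default_rng(0)
        em, ann = _axis_matrix(rng.random((3, 12)), sections)
        table = ap_pattern_genes(em, ann, ["g0", "g1", "g2"], top_k=50)
        assert table.selected_genes == {"g0", "g1", "g2"}

    def test_invariant_to_spot_permutation(self):
        rng = np.random.default_rng(3)
        sections = np.repeat([1, 2, 3, 4, 5], 6)
        vals = rng.random((8, 30))
        em, ann = _axis_matrix(vals, sections)
        base = ap_pattern_genes(em, ann, list(em.gene_ids), top_k=3)
        perm = rng.permutation(30)
        obs_p = [em.obs_ids[i] for i in perm]
        em2 = st.ExpressionMatrix(vals[:, perm], list(em.gene_ids), obs_p,
                                  layer=LOGNORM)
        ann2 = st.SpotAnnotations(obs_p, sections[perm], ann.array_x,
                                  ann.array_y)
        permuted = ap_pattern_genes(em2, ann2, list(em.gene_ids), top_k=3)
        assert base.selected_genes == permuted.selected_genes
        merged = base.table.merge(permuted.table, on=["gene", "pattern_id"])
        assert np.allclose(merged["pcc_x"], merged["pcc_y"])

    def test_gradient_recovery(self):
        """Planted gradient genes are selected and >= 90% of flat decoys are
        rejected across seeds of the gradient preset."""
        seeds = range(25)
        all_planted_found = 0
        decoy_sel = decoy_total = 0
        for seed in seeds:
            atlas = st.simulate_preset("gradient", seed=seed)
            em = lognormalize(atlas.expression)
            planted = set(atlas.truth.planted_gradient_genes)
            decoys = set(atlas.truth.decoy_genes)
            table = ap_pattern_genes(em, atlas.annotations,
                                     sorted(planted | decoys))
            sel = table.selected_genes
            all_planted_found += planted <= sel
            decoy_sel += len(sel & decoys)
            decoy_total += len(decoys)
        assert all_planted_found / len(seeds) >= 0.9
        assert decoy_sel / decoy_total <= 0.10


class TestBinarizeScores:
    def test_zscore_spike_survives(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 400)
        v = (v - v.mean()) / v.std()
        spike = np.flatnonzero(v > 3.2)[:1]
        v[spike] = 3.2
        scores = pd.DataFrame({"s": v})
        out = binarize_scores(scores, method="zscore", z_min=2.5)
        survivors = np.flatnonzero(out["s"].to_numpy() != 0)
        assert np.all(v[survivors] >= 2.5 * v.std() + v.mean() - 1e-9)
        assert len(survivors) >= 1

    def test_zscore_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            binarize_scores(pd.DataFrame({"s": [1.0, 1.0]}), method="zscore")

    def test_bimodal_degenerate_passes_through_with_warning(self):
        scores = pd.DataFrame({"s": [0.5] * 6})
        with pytest.warns(UserWarning, match="bimodal"):
            out = binarize_scores(scores, method="bimodal")
        assert np.allclose(out["s"], 0.5)

    def test_bimodal_splits_two_groups(self):
        scores = pd.DataFrame({"s": [0.1, 0.12, 0.11, 0.9, 0.95, 0.88]})
        out = binarize_scores(scores, method="bimodal")
        assert (out["s"][:3] == 0).all() and (out["s"][3:] > 0).all()

    def test_dmv_band_recovery(self):
        """Per-spot region assignment by top activity matches the planted
        dorsal/middle/ventral bands for >= 90% of spots across seeds."""
        from stcomm.axis import region_activity_scores

        accs = []
        for seed in range(25):
            em, labels, sigs = st.simulate_dmv_cord(seed=seed)
            scores = region_activity_scores(lognormalize(em), sigs, seed=0)
            acc = (scores.idxmax(axis=1).to_numpy() == np.array(labels)).mean()
            accs.append(acc)
        assert np.mean(accs) >= 0.9


class TestWilcoxonRankSum:
    def test_small_one_sided(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4], alternative="less")
        assert p == pytest.approx(1 / 6)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 6)
                                       for n2 in range(1, 6) if n1 + n2 <= 10])
    def test_matches_exact_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2) + 0.5
        for alt in ("two-sided", "less", "greater"):
            _, p = wilcoxon_rank_sum(x, y, alternative=alt)
            assert p == pytest.approx(exact_rank_sum_p(x, y, alt), abs=1e-10)

    def test_approximation_close_to_exact(self):
        rng = np.random.default_rng(42)
        diffs = []
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            _, p_exact = wilcoxon_rank_sum(x, y)
            res = __import__("scipy.stats", fromlist=["mannwhitneyu"]).mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            )
            diffs.append(abs(p_exact - res.pvalue))
        assert max(diffs) <= 0.02 + 0.03  # continuity-corrected approx at n=10

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestDvSelection:
    def test_dv_domain_genes_null_calibrated(self):
        """Under label-independent expression <= 5% + 3 SE of (gene, region)
        tests come out significant."""
        sig = total = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vals = rng.poisson(3.0, size=(50, 60)).astype(float)
            em = st.ExpressionMatrix(
                vals, [f"g{i}" for i in range(50)],
                [f"s{j}" for j in range(60)], layer="lognorm",
            )
            labels = rng.permutation(np.repeat(["D", "M", "V"], 20))
            table = dv_domain_genes(em, labels)
            sig += int(table["significant"].sum())
            total += len(table)
        se = math.sqrt(0.05 * 0.95 / total)
        assert sig / total <= 0.05 + 3 * se

    def test_small_region_is_error(self):
        em = st.ExpressionMatrix(np.ones((2, 5)), ["a", "b"],
                                 [f"s{i}" for i in range(5)], layer="lognorm")
        with pytest.raises(ValueError, match="fewer than 3"):
            dv_domain_genes(em, ["D", "D", "D", "M", "M"])


class TestAxisRegulonSelection:
    def test_monotone_regulon_selected(self):
        order = np.arange(100, dtype=float)
        rng = np.random.default_rng(0)
        vals = np.column_stack([
            np.linspace(0.05, 0.9, 100),              # monotone, max 0.9
            np.clip(0.1 + rng.normal(0, 0.02, 100), 0, 1),
            np.clip(0.1 + rng.normal(0, 0.02, 100), 0, 1),
        ])
        ras = st.RegulonActivityMatrix(vals, [f"s{i}" for i in range(100)],
                                       ["mono", "flat1", "flat2"])
        table = ap_regulon_selection(ras, order)
        assert table.set_index("regulon").loc["mono", "selected"]

    def test_low_max_activity_excluded(self):
        order = np.arange(50, dtype=float)
        vals = np.column_stack([
            np.linspace(0.0, 0.1, 50),   # perfectly monotone but max 0.1
            np.full(50, 0.05) + np.sin(np.arange(50)) * 0.01,
            np.full(50, 0.05) + np.cos(np.arange(50)) * 0.01,
        ])
        ras = st.RegulonActivityMatrix(vals, [f"s{i}" for i in range(50)],
                                       ["lowmax", "f1", "f2"])
        table = ap_regulon_selection(ras, order, min_max_ras=0.2)
        assert not table.set_index("regulon").loc["lowmax", "selected"]

    def test_planted_gradient_regulons_recovered(self):
        """Planted monotone regulons pass the |PCC| > 1.5 SD and max activity
        > 0.2 rule, and >= 90% of flat decoys are excluded, across seeds."""
        order = np.arange(400, dtype=float)
        ok_seeds = 0
        decoy_sel = decoy_total = 0
        for seed in range(25):
            ras, planted = st.simulate_gradient_regulons(order, seed=seed)
            table = ap_regulon_selection(ras, order).set_index("regulon")
            ok_seeds += all(table.loc[r, "selected"] for r in planted)
            decoys = [r for r in ras.regulon_names if r not in planted]
            decoy_sel += int(table.loc[decoys, "selected"].sum())
            decoy_total += len(decoys)
        assert ok_seeds / 25 >= 0.9
        assert decoy_sel / decoy_total <= 0.10

    def test_dv_regulon_selection_recovers_band_regulon(self):
        rng = np.random.default_rng(1)
        labels = np.repeat(["D", "M", "V"], 40)
        vals = np.column_stack([
            np.clip(np.where(labels == "D", 0.7, 0.05)
                    + rng.normal(0, 0.03, 120), 0, 1),
            np.clip(0.1 + rng.normal(0, 0.03, 120), 0, 1),
            np.clip(np.where(labels == "V", 0.15, 0.05)   # max below 0.2
                    + rng.normal(0, 0.01, 120), 0, 0.19),
        ])
        ras = st.RegulonActivityMatrix(vals, [f"s{i}" for i in range(120)],
                                       ["d_reg", "flat", "low"])
        table = dv_regulon_selection(ras, labels)
        sel = set(table[table["selected"]]["regulon"])
        assert "d_reg" in sel and "low" not in sel


class TestModuleScore:
    def test_self_control_bins_give_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.random((12, 8)) + np.arange(12)[:, None]
        em = st.ExpressionMatrix(vals, [f"g{i}" for i in range(12)],
                                 [f"s{j}" for j in range(8)], layer="lognorm")
        # one gene per bin: each signature gene's bin holds only itself
        score = module_score(em, ["g3", "g7"], n_bins=12, n_ctrl=50, seed=0)
        assert np.allclose(score, 0.0)

    def test_random_signature_null_centered(self, small_lognorm):
        rng = np.random.default_rng(1)
        means = []
        for _ in range(200):
            sig = list(rng.choice(small_lognorm.gene_ids, size=4, replace=False))
            means.append(module_score(small_lognorm, sig, n_bins=5, seed=3).mean())
        means = np.array(means)
        se = means.std(ddof=1) / math.sqrt(len(means))
        assert abs(means.mean()) < 3 * se + 1e-12

    def test_n_bins_exceeding_genes_is_error(self, small_lognorm):
        with pytest.raises(ValueError, match="n_bins"):
            module_score(small_lognorm, ["g0"], n_bins=1000)

    def test_cell_cycle_phase_rule(self, small_lognorm):
        df = cell_cycle_phase(small_lognorm, ["g0", "g1"], ["g2", "g3"], seed=2)
        s, g2m = df["s_score"].to_numpy(), df["g2m_score"].to_numpy()
        expected = np.where((s <= 0) & (g2m <= 0), "G1",
                            np.where(s > g2m, "S", "G2M"))
        assert (df["phase"].to_numpy() == expected).all()
        assert set(df.columns) == {"s_score", "g2m_score", "phase"}
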