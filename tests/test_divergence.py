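"""ANOVA decomposition, permutation p/FDR, lineage classification and the
divergence regression, checked against enumeration and closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaevol import divergence as dv
from metaevol.phylo import Phylogeny

from conftest import make_meta, make_table


def grid_meta(species, tissues, n_per_cell, prefix=""):
    rows = []
    for sp in species:
        for t in tissues:
            for k in range(n_per_cell):
                rows.append(dict(sample_id=f"{prefix}{sp}_{t}_{k}", species=sp,
                                 tissue=t))
    return make_meta(rows)


class TestAnovaDecompose:
    def test_planted_tissue_shift_detected(self):
        rng = np.random.default_rng(0)
        meta = grid_meta(["human", "macaque"], ["PFC", "muscle"], 8)
        vals = rng.normal(10, 0.5, (20, len(meta)))
        muscle = (meta["tissue"] == "muscle").to_numpy()
        vals[0, muscle] += 4.0
        table = make_table(vals, list(meta.index), log_scale=True)
        res = dv.anova_decompose(table, meta, factors=("tissue", "species"))
        assert res.frame["p_tissue"].iloc[0] < 1e-6
        assert res.frame["p_species"].iloc[0] > 1e-4

    def test_constant_peak_gets_missing_p(self):
        meta = grid_meta(["human", "macaque"], ["PFC"], 5)
        vals = np.vstack([np.ones(len(meta)),
                          np.random.default_rng(1).normal(0, 1, len(meta))])
        table = make_table(vals, list(meta.index), log_scale=True)
        res = dv.anova_decompose(table, meta, factors=("tissue", "species"))
        assert np.isnan(res.frame["p_species"].iloc[0])
        assert np.isfinite(res.frame["p_species"].iloc[1])

    def test_null_parametric_p_uniform(self):
        rng = np.random.default_rng(2)
        meta = grid_meta(["human", "chimpanzee", "macaque"], ["PFC", "muscle"], 7)
        vals = rng.normal(0, 1, (400, len(meta)))
        table = make_table(vals, list(meta.index), log_scale=True)
        res = dv.anova_decompose(table, meta, factors=("tissue", "species"))
        stat, p = stats.kstest(res.frame["p_species"], "uniform")
        assert p > 0.01


class TestPermutationTest:
    def test_extreme_effect_gives_minimum_p(self):
        rng = np.random.default_rng(3)
        meta = grid_meta(["human", "macaque"], ["PFC"], 8)
        vals = rng.normal(0, 0.1, (5, len(meta)))
        vals[0, (meta["species"] == "human").to_numpy()] += 50.0
        table = make_table(vals, list(meta.index), log_scale=True)
        res = dv.permutation_fdr(table, meta, factor="species", n_perm=100,
                                 seed=4)
        assert res.perm_p.iloc[0] == pytest.approx(1 / 101)

    def test_zero_between_group_difference_gives_p_one(self):
        # identical per-species value patterns: observed species F is 0,
        # every permuted F >= 0, so the add-one estimator returns 1
        meta = grid_meta(["human", "macaque"], ["PFC"], 3)
        pattern = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        vals = np.vstack([pattern, pattern + 1.0])
        table = make_table(vals, list(meta.index), log_scale=True)
        res = dv.permutation_fdr(table, meta, factor="species", n_perm=100,
                                 seed=5)
        assert res.perm_p.iloc[0] == 1.0

    def test_matches_exhaustive_enumeration_on_toy(self):
        # 6 samples, one tissue, two species of 3: compare the sampled
        # permutation p with enumeration over all 20 label assignments
        rng = np.random.default_rng(6)
        meta = grid_meta(["human", "macaque"], ["PFC"], 3)
        vals = rng.normal(0, 1, (5, 6))
        table = make_table(vals, list(meta.index), log_scale=True)
        n_perm = 4000
        res = dv.permutation_fdr(table, meta, factor="species", n_perm=n_perm,
                                 seed=7)

        def f_stat(y, mask):
            g1, g2 = y[mask], y[~mask]
            rss1 = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
            rss0 = ((y - y.mean()) ** 2).sum()
            return ((rss0 - rss1) / 1) / (rss1 / 4)

        obs_mask = (meta["species"] == "human").to_numpy()
        for j in range(5):
            y = vals[j]
            f_obs = f_stat(y, obs_mask)
            count = total = 0
            for combo in itertools.combinations(range(6), 3):
                mask = np.zeros(6, dtype=bool)
                mask[list(combo)] = True
                total += 1
                if f_stat(y, mask) >= f_obs - 1e-12:
                    count += 1
            exact = count / total
            mc_sd = np.sqrt(exact * (1 - exact) / n_perm)
            assert abs(res.perm_p.iloc[j] - exact) <= 3 * mc_sd + 2 / n_perm

    def test_n_perm_minimum_enforced(self):
        meta = grid_meta(["human", "macaque"], ["PFC"], 3)
        table = make_table(np.ones((2, 6)), list(meta.index), log_scale=True)
        with pytest.raises(ValueError):
            dv.permutation_fdr(table, meta, factor="species", n_perm=50)

    def test_fdr_monotone_in_cutoff(self):
        rng = np.random.default_rng(8)
        meta = grid_meta(["human", "chimpanzee", "macaque"], ["PFC"], 6)
        vals = rng.normal(0, 1, (150, len(meta)))
        vals[:20, (meta["species"] == "human").to_numpy()] += 2.0
        table = make_table(vals, list(meta.index), log_scale=True)
        fdrs = []
        for cutoff in (0.05, 0.01):
            res = dv.permutation_fdr(table, meta, factor="species",
                                     cutoff=cutoff, n_perm=100, seed=9)
            fdrs.append(res.fdr_at_cutoff)
        assert fdrs[1] <= fdrs[0] + 1e-9


class TestCompositeTissues:
    def test_unions(self):
        meta = grid_meta(["human"], ["PFC", "V1", "CBC", "kidney", "muscle"], 14)
        groups = dv.build_composite_tissues(meta)
        assert len(groups["cortex"]) == 28
        assert len(groups["brain"]) == 42
        assert len(groups["kidney"]) == 14
        assert set(groups["cortex"]) == set(groups["PFC"]) | set(groups["V1"])

    def test_brain_equals_cortex_without_cbc(self):
        meta = grid_meta(["human"], ["PFC", "V1", "kidney", "muscle"], 5)
        groups = dv.build_composite_tissues(meta)
        assert set(groups["brain"]) == set(groups["cortex"])


def classify_fixture(effects, n_null=60, n_per_cell=10, seed=0, sigma=0.5):
    """Small 4-species x 1-tissue dataset with planted shifts.

    ``effects``: dict peak index -> dict species -> shift.
    """
    rng = np.random.default_rng(seed)
    meta = grid_meta(["human", "chimpanzee", "macaque", "mouse"], ["muscle"],
                     n_per_cell)
    vals = rng.normal(10, sigma, (n_null, len(meta)))
    sp = meta["species"].to_numpy()
    for j, shifts in effects.items():
        for species, delta in shifts.items():
            vals[j, sp == species] += delta
    table = make_table(vals, list(meta.index), log_scale=True)
    return table, meta


class TestClassify:
    def test_planted_human_up_called(self):
        table, meta = classify_fixture({0: {"human": 3.0}, 1: {"human": -3.0}})
        gate = set(table.peak_ids)
        assign = dv.classify_species_specific(
            table, meta, gate_primate=gate, gate_all=gate, n_perm=100, seed=1,
            tissue_categories=("muscle",))
        a = assign.assignments
        up = a[(a["peak_id"] == "p000")]
        assert list(up["lineage"]) == ["human"] and list(up["direction"]) == ["up"]
        down = a[(a["peak_id"] == "p001")]
        assert list(down["lineage"]) == ["human"] and list(down["direction"]) == ["down"]

    def test_shared_human_chimp_shift_assigned_to_macaque_lineage(self):
        # elevated in both human and chimp vs macaque: the change happened on
        # the macaque lineage (macaque differs from the other primates) and
        # the direction is macaque-relative
        table, meta = classify_fixture({0: {"human": 3.0, "chimpanzee": 3.0}})
        gate = set(table.peak_ids)
        assign = dv.classify_species_specific(
            table, meta, gate_primate=gate, gate_all=gate, n_perm=100, seed=2,
            tissue_categories=("muscle",))
        calls = assign.assignments
        calls = calls[calls["peak_id"] == "p000"]
        primate_calls = calls[calls["lineage"] != "mouse_anc"]
        assert list(primate_calls["lineage"]) == ["macaque_anc"]
        assert list(primate_calls["direction"]) == ["down"]

    def test_shuffled_labels_discovery_rate_at_most_nominal(self):
        rng = np.random.default_rng(3)
        table, meta = classify_fixture({}, n_null=300, seed=4)
        meta = meta.copy()
        perm = rng.permutation(len(meta))
        meta["species"] = meta["species"].to_numpy()[perm]
        gate = set(table.peak_ids)
        assign = dv.classify_species_specific(
            table, meta, gate_primate=gate, gate_all=gate, n_perm=100, seed=5,
            tissue_categories=("muscle",))
        n_tests = 4 * 300
        bound = 0.01 * n_tests + 3 * np.sqrt(n_tests * 0.01 * 0.99)
        assert len(assign.assignments) <= bound


class TestExcludeMultitissue:
    def _assign(self, entries):
        frame = pd.DataFrame(entries, columns=["peak_id", "tissue", "lineage",
                                               "direction", "p", "q"])
        return dv.LineageAssignment(assignments=frame, tested={})

    def test_same_direction_in_pfc_and_v1_both_removed(self):
        a = self._assign([("pk", "PFC", "human", "up", 1e-4, 0.01),
                          ("pk", "V1", "human", "up", 1e-4, 0.01)])
        out = dv.exclude_multitissue(a)
        assert len(out.assignments) == 0

    def test_opposite_directions_retained(self):
        a = self._assign([("pk", "PFC", "human", "up", 1e-4, 0.01),
                          ("pk", "V1", "human", "down", 1e-4, 0.01)])
        out = dv.exclude_multitissue(a)
        assert len(out.assignments) == 2

    def test_single_tissue_call_retained(self):
        a = self._assign([("pk", "muscle", "human", "up", 1e-4, 0.01)])
        out = dv.exclude_multitissue(a)
        assert len(out.assignments) == 1

    def test_composite_counterpart_removes_individual_but_not_composite(self):
        a = self._assign([("pk", "cortex", "human", "up", 1e-4, 0.01),
                          ("pk", "CBC", "human", "up", 1e-4, 0.01)])
        out = dv.exclude_multitissue(a)
        assert list(out.assignments["tissue"]) == ["cortex"]

    def test_matches_brute_force_on_random_assignments(self):
        rng = np.random.default_rng(6)
        tissues = list(dv.TISSUE_CATEGORIES)
        entries = [(f"pk{rng.integers(8)}", tissues[rng.integers(len(tissues))],
                    ["human", "chimp"][rng.integers(2)],
                    ["up", "down"][rng.integers(2)], 1e-4, 0.01)
                   for _ in range(60)]
        frame = pd.DataFrame(entries, columns=["peak_id", "tissue", "lineage",
                                               "direction", "p", "q"]
                             ).drop_duplicates(["peak_id", "tissue", "lineage"])
        a = dv.LineageAssignment(assignments=frame.reset_index(drop=True),
                                 tested={})
        out = dv.exclude_multitissue(a)
        kept = set(map(tuple, out.assignments[["peak_id", "tissue", "lineage",
                                               "direction"]].to_numpy()))
        composite = set(dv.COMPOSITE_TISSUES)
        present = set(map(tuple, frame[["peak_id", "tissue", "lineage",
                                        "direction"]].to_numpy()))
        for pid, t, lin, d in present:
            should_drop = t not in composite and any(
                (pid, other, lin, d) in present
                for grp in dv.MULTITISSUE_GROUPS if t in grp
                for other in grp if other != t)
            assert ((pid, t, lin, d) in kept) == (not should_drop)


class TestDivergenceRegression:
    def _assignment_with_proportions(self, prop):
        """Build a LineageAssignment whose per-category proportions are
        exactly ``prop[(tissue, lineage)]`` with denominator 1000."""
        rows = []
        tested = {}
        for (t, lin), p in prop.items():
            tested[(t, lin)] = 1000
            for i in range(int(round(p * 1000))):
                rows.append((f"pk{i}", t, lin, "up", 1e-4, 0.01))
        frame = pd.DataFrame(rows, columns=["peak_id", "tissue", "lineage",
                                            "direction", "p", "q"])
        return dv.LineageAssignment(assignments=frame, tested=tested)

    def test_perfectly_linear_proportions(self):
        phylo = Phylogeny()
        slope, intercept = 0.002, 0.01
        prop = {}
        for t in dv.TISSUE_CATEGORIES:
            for lin in ("human", "chimp", "macaque_anc", "mouse_anc"):
                prop[(t, lin)] = intercept + slope * phylo[lin]
        summ = dv.divergence_regression(self._assignment_with_proportions(prop))
        assert summ.r_squared == pytest.approx(1.0, abs=1e-9)
        assert summ.slope == pytest.approx(slope, abs=1e-9)
        for t in dv.TISSUE_CATEGORIES:
            assert summ.per_tissue.loc[t, "excess"] == pytest.approx(1.0, abs=1e-6)

    def test_equal_human_chimp_proportion_fold_one(self):
        prop = {(t, lin): 0.05 for t in dv.TISSUE_CATEGORIES
                for lin in ("human", "chimp")}
        prop.update({(t, "macaque_anc"): 0.10 for t in dv.TISSUE_CATEGORIES})
        prop.update({(t, "mouse_anc"): 0.30 for t in dv.TISSUE_CATEGORIES})
        summ = dv.divergence_regression(self._assignment_with_proportions(prop))
        for t in dv.TISSUE_CATEGORIES:
            assert summ.per_tissue.loc[t, "fold_excess_vs_chimp"] == \
                pytest.approx(1.0)

    def test_zero_chimp_proportion_flagged_infinite(self):
        prop = {(t, "chimp"): 0.0 for t in dv.TISSUE_CATEGORIES}
        prop.update({(t, "human"): 0.05 for t in dv.TISSUE_CATEGORIES})
        prop.update({(t, "macaque_anc"): 0.10 for t in dv.TISSUE_CATEGORIES})
        prop.update({(t, "mouse_anc"): 0.30 for t in dv.TISSUE_CATEGORIES})
        summ = dv.divergence_regression(self._assignment_with_proportions(prop))
        assert np.isinf(summ.per_tissue.loc["PFC", "fold_excess_vs_chimp"])
        assert bool(summ.per_tissue.loc["PFC", "infinite_fold"])

    def test_matches_closed_form_ols_oracle(self):
        rng = np.random.default_rng(7)
        prop = {}
        for t in dv.TISSUE_CATEGORIES:
            prop[(t, "chimp")] = round(float(rng.uniform(0.01, 0.10)), 2)
            prop[(t, "macaque_anc")] = round(float(rng.uniform(0.05, 0.20)), 2)
            prop[(t, "mouse_anc")] = round(float(rng.uniform(0.20, 0.50)), 2)
            prop[(t, "human")] = round(float(rng.uniform(0.01, 0.30)), 2)
        phylo = Phylogeny()
        summ = dv.divergence_regression(self._assignment_with_proportions(prop))
        x = np.array([phylo[lin] for t in dv.TISSUE_CATEGORIES
                      for lin in ("chimp", "macaque_anc", "mouse_anc")])
        y = np.array([prop[(t, lin)] for t in dv.TISSUE_CATEGORIES
                      for lin in ("chimp", "macaque_anc", "mouse_anc")])
        # closed-form least squares
        b = ((x * y).mean() - x.mean() * y.mean()) / ((x**2).mean() - x.mean()**2)
        a = y.mean() - b * x.mean()
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert summ.slope == pytest.approx(b, abs=1e-10)
        assert summ.intercept == pytest.approx(a, abs=1e-10)
        assert summ.r_squared == pytest.approx(r2, abs=1e-10)
        assert summ.n_points == 21


class TestRelativeConcentration:
    def test_three_species_toy_matches_hand_computation(self):
        meta = grid_meta(["human", "chimpanzee", "macaque"], ["PFC"], 1)
        # linear values: human 8, chimp 4, macaque 4 -> other mean for human = 4
        vals = np.array([[8.0, 4.0, 4.0]])
        table = make_table(vals, list(meta.index))
        out = dv.relative_concentration_matrix(table, meta, log_input=False)
        human_col = [c for c in out.columns if c.startswith("human")][0]
        chimp_col = [c for c in out.columns if c.startswith("chimpanzee")][0]
        assert out[human_col].iloc[0] == pytest.approx(1.0)   # twice the mean
        assert out[chimp_col].iloc[0] == pytest.approx(np.log2(4 / 6))

    def test_sample_equal_to_other_mean_gives_zero(self):
        meta = grid_meta(["human", "chimpanzee", "macaque"], ["PFC"], 1)
        vals = np.array([[4.0, 4.0, 4.0]])
        table = make_table(vals, list(meta.index))
        out = dv.relative_concentration_matrix(table, meta, log_input=False)
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-12)

    def test_empty_comparison_errors(self):
        meta = grid_meta(["human"], ["PFC"], 2)
        table = make_table(np.ones((3, 2)), list(meta.index))
        with pytest.raises(ValueError):
            dv.relative_concentration_matrix(table, meta, log_input=False)


class TestPooledVarianceOption:
    def test_pooled_variance_matches_scipy(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 14)
        s1, ss1, n1 = a.sum(), (a**2).sum(), len(a)
        s2, ss2, n2 = b.sum(), (b**2).sum(), len(b)
        t, p, _ = dv._welch_from_moments(np.array([s1]), np.array([ss1]),
                                         np.array([n1]), np.array([s2]),
                                         np.array([ss2]), np.array([n2]),
                                         equal_var=True)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t[0] == pytest.approx(ref.statistic, rel=1e-10)
        assert p[0] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 9), rng.normal(0.5, 2, 13)
        t, p, _ = dv._welch_from_moments(
            np.array([a.sum()]), np.array([(a**2).sum()]), np.array([len(a)]),
            np.array([b.sum()]), np.array([(b**2).sum()]), np.array([len(b)]))
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t[0] == pytest.approx(ref.statistic, rel=1e-10)
        assert p[0] == pytest.approx(ref.pvalue, rel=1e-10)
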