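"""Matching, t tests, GLM, permutation inference, TFCE, BH, effect sizes."""

import numpy as np
import pandas as pd
import pytest

from bundlekit import stats, synthetic
from conftest import brute_force_bh, brute_max_matching_size


def make_table(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "sex": rng.choice(["M", "F"], n),
            "age": rng.uniform(50, 66, n),
            "icv_ml": rng.normal(1550, 130, n),
        }
    )


def icv_frame(ids, icvs):
    return pd.DataFrame({"subject_id": ids, "icv_ml": icvs})


class TestMatchByICV:
    def test_single_feasible_pair(self):
        men = icv_frame(["m1", "m2"], [1500.0, 1600.0])
        women = icv_frame(["w1", "w2"], [1505.0, 1800.0])
        pairs = stats.match_by_icv(men, women, tolerance=10)
        assert pairs.pairs == [("m1", "w1")]

    def test_no_pair_within_tolerance(self):
        men = icv_frame(["m1"], [1500.0])
        women = icv_frame(["w1"], [1520.0])
        assert len(stats.match_by_icv(men, women, tolerance=10)) == 0

    def test_identical_icvs_pair_everyone(self):
        men = icv_frame([f"m{i}" for i in range(4)], [1500.0, 1510, 1520, 1530])
        women = icv_frame([f"w{i}" for i in range(3)], [1500.0, 1510, 1520])
        pairs = stats.match_by_icv(men, women, tolerance=10)
        assert len(pairs) == 3
        for m, w in pairs.pairs:
            mi = men.set_index("subject_id")["icv_ml"][m]
            wi = women.set_index("subject_id")["icv_ml"][w]
            assert abs(mi - wi) < 10

    def test_cardinality_matches_brute_force(self, rng):
        for _ in range(100):
            nm, nw = rng.integers(1, 9, size=2)
            men_icv = rng.uniform(1400, 1500, nm).round(1)
            women_icv = rng.uniform(1400, 1500, nw).round(1)
            men = icv_frame([f"m{i}" for i in range(nm)], men_icv)
            women = icv_frame([f"w{i}" for i in range(nw)], women_icv)
            tol = float(rng.uniform(2, 30))
            pairs = stats.match_by_icv(men, women, tolerance=tol)
            assert len(pairs) == brute_max_matching_size(men_icv, women_icv, tol)
            used_m = [m for m, _ in pairs.pairs]
            used_w = [w for _, w in pairs.pairs]
            assert len(set(used_m)) == len(used_m)
            assert len(set(used_w)) == len(used_w)

    def test_matching_collapses_the_icv_group_difference(self):
        # unmatched groups differ by ~212 ml (|t| ~ 25); after matching, the
        # pooled t is near zero (a small positive residual remains because
        # cardinality-maximal matching must stretch pairs at the edge of the
        # ICV overlap region)
        table = synthetic.generate_cohort(synthetic.CohortSpec(seed=11))
        men = table[table.sex == "M"]
        women = table[table.sex == "F"]
        t_all = stats.two_sample_t(
            men["icv_ml"].to_numpy(), women["icv_ml"].to_numpy()
        )
        pairs = stats.match_by_icv(men, women, tolerance=10)
        assert len(pairs) > 100
        mi = men.set_index("subject_id").loc[[p[0] for p in pairs.pairs], "icv_ml"]
        wi = women.set_index("subject_id").loc[[p[1] for p in pairs.pairs], "icv_ml"]
        assert (np.abs(mi.to_numpy() - wi.to_numpy()) < 10).all()
        t_matched = stats.two_sample_t(mi.to_numpy(), wi.to_numpy())
        assert abs(t_all) > 20
        assert abs(t_matched) < 0.3


class TestTwoSampleT:
    def test_printed_icv_summaries_give_25_6(self):
        t = stats.two_sample_t((383, 1667.9, 120.2), (429, 1455.9, 115.8))
        assert round(t, 1) == 25.6

    def test_identical_summaries_give_zero(self):
        assert stats.two_sample_t((10, 5.0, 1.0), (10, 5.0, 1.0)) == 0.0

    def test_raw_groups_match_hand_computation(self):
        assert stats.two_sample_t([1, 2, 3], [1, 2, 3]) == 0.0
        # pooled sd = 1, diff = -1, t = -1 / sqrt(2/3)
        t = stats.two_sample_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1 / np.sqrt(2 / 3))

    def test_agrees_with_scipy(self, rng):
        a, b = rng.normal(size=30), rng.normal(0.5, 1.2, size=25)
        from scipy.stats import ttest_ind

        assert stats.two_sample_t(a, b) == pytest.approx(ttest_ind(a, b).statistic)
        assert stats.two_sample_t(a, b, "welch") == pytest.approx(
            ttest_ind(a, b, equal_var=False).statistic
        )

    def test_zero_pooled_sd_with_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            stats.two_sample_t((5, 1.0, 0.0), (5, 2.0, 0.0))


class TestCohenD:
    def test_trivial_values(self):
        assert stats.cohen_d((10, 1.0, 1.0), (10, 1.0, 1.0)) == 0.0
        assert stats.cohen_d((10, 1.0, 1.0), (10, 0.0, 1.0)) == pytest.approx(1.0)

    def test_printed_fa_summaries(self):
        d = stats.cohen_d((429, 0.361, 0.011), (383, 0.359, 0.011))
        assert d == pytest.approx(0.18, abs=0.005)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            stats.cohen_d((5, 1.0, 0.0), (5, 2.0, 0.0))


class TestFitGLM:
    def test_noiseless_recovery_to_1e_10(self):
        spec = synthetic.CohortSpec(n_men=60, n_women=60, noise_sd=0.0, seed=5)
        table = synthetic.generate_cohort(spec)
        design = stats.build_design(table)
        fit = stats.fit_glm(table["CC_fa"].to_numpy(), design)
        assert fit.params["icv"] == pytest.approx(spec.beta_icv, abs=1e-10)
        assert fit.params["age"] == pytest.approx(spec.beta_age, abs=1e-10)
        assert fit.params["sex"] == pytest.approx(spec.sex_offset, abs=1e-10)

    def test_generator_betas_within_2_se_at_n_2000(self):
        spec = synthetic.CohortSpec(n_men=1000, n_women=1000, noise_sd=0.011, seed=17)
        table = synthetic.generate_cohort(spec)
        design = stats.build_design(table)
        fit = stats.fit_glm(table["CC_fa"].to_numpy(), design)
        for term, truth in [
            ("age", spec.beta_age),
            ("icv", spec.beta_icv),
            ("sex", spec.sex_offset),
        ]:
            assert abs(fit.params[term] - truth) < 2 * fit.bse[term]

    def test_centering_invariance_of_slopes_t_p_eta(self):
        table = make_table(80, seed=3)
        y = np.random.default_rng(4).normal(size=80)
        centered = stats.fit_glm(y, stats.build_design(table, center=True))
        raw = stats.fit_glm(y, stats.build_design(table, center=False))
        for term in ("icv", "age", "sex"):
            assert centered.params[term] == pytest.approx(raw.params[term], rel=1e-9)
            assert centered.tvalues[term] == pytest.approx(raw.tvalues[term], rel=1e-9)
            assert centered.pvalues[term] == pytest.approx(raw.pvalues[term], rel=1e-9)
            assert centered.partial_eta_sq[term] == pytest.approx(
                raw.partial_eta_sq[term], rel=1e-9
            )
        assert centered.params["intercept"] != pytest.approx(
            raw.params["intercept"], rel=1e-3
        )

    def test_rank_deficient_design_named(self):
        table = make_table(30, seed=1)
        table["age2"] = table["age"]
        design = stats.build_design(table, ("icv", "age", "age2"))
        with pytest.raises(ValueError, match="collinear"):
            stats.fit_glm(np.zeros(30), design)

    def test_null_partial_eta_sq_mean_near_1_over_df(self):
        # under a pure-noise term, E[partial eta^2] ~ 1/(n - p)
        rng = np.random.default_rng(8)
        table = make_table(50, seed=8)
        design = stats.build_design(table)
        n, p = 50, 4
        etas = []
        for _ in range(400):
            fit = stats.fit_glm(rng.normal(size=n), design)
            etas.append(fit.partial_eta_sq["icv"])
        assert np.mean(etas) == pytest.approx(1 / (n - p), rel=0.25)

    def test_partial_eta_sq_equals_type3_ss_ratio(self, rng):
        table = make_table(40, seed=2)
        y = rng.normal(size=40)
        design = stats.build_design(table)
        fit = stats.fit_glm(y, design)
        # independent route: SS drop when removing the term
        reduced = stats.build_design(table, ("age", "sex"))
        fit_red = stats.fit_glm(y, reduced)
        ss_term = fit_red.ssr - fit.ssr
        assert fit.partial_eta_sq["icv"] == pytest.approx(
            ss_term / (ss_term + fit.ssr), rel=1e-9
        )


class TestBHCorrect:
    def test_three_small_pvalues_all_rejected(self):
        reject, _ = stats.bh_correct([0.01, 0.02, 0.04], alpha=0.05)
        assert reject.all()

    def test_all_ones_none_rejected(self):
        reject, adjusted = stats.bh_correct([1.0, 1.0, 1.0], alpha=0.05)
        assert not reject.any()
        assert np.allclose(adjusted, 1.0)

    def test_families_are_independent(self):
        p = [0.01, 0.02, 0.04, 0.01, 0.02, 0.04]
        joint, _ = stats.bh_correct(p, alpha=0.05)
        split, _ = stats.bh_correct(p, alpha=0.05, families=[0, 0, 0, 1, 1, 1])
        per_family, _ = stats.bh_correct(p[:3], alpha=0.05)
        assert np.array_equal(split[:3], per_family)
        assert np.array_equal(split[3:], per_family)

    def test_matches_brute_force_step_up(self, rng):
        for _ in range(300):
            m = int(rng.integers(1, 9))
            p = rng.integers(0, 101, size=m) / 100.0
            reject, _ = stats.bh_correct(p, alpha=0.05)
            assert np.array_equal(reject, brute_force_bh(p, 0.05))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            stats.bh_correct([0.5, 1.2])


class TestTFCE:
    def _line_adjacency(self, n):
        return stats.grid_adjacency(np.ones((1, 1, n), dtype=bool))

    def test_zero_map_stays_zero(self):
        out = stats.tfce_enhance(np.zeros(10), self._line_adjacency(10))
        assert np.allclose(out, 0.0)

    def test_single_voxel_closed_form_and_monotone_in_height(self):
        adj = self._line_adjacency(5)
        values = []
        for height in (1.0, 2.0, 3.0):
            stat = np.zeros(5)
            stat[2] = height
            dh = 0.01
            out = stats.tfce_enhance(stat, adj, dh=dh)
            hs = np.arange(dh, height + 1e-12, dh)
            assert out[2] == pytest.approx((hs**2 * dh).sum(), rel=1e-6)
            values.append(out[2])
        assert values[0] < values[1] < values[2]

    def test_double_extent_plateau_enhanced_by_sqrt2(self):
        adj = self._line_adjacency(12)
        stat = np.zeros(12)
        stat[0:2] = 1.0
        stat[5:9] = 1.0
        out = stats.tfce_enhance(stat, adj, dh=0.01)
        assert out[6] / out[0] == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_monotone_under_raising_a_voxel(self, rng):
        adj = self._line_adjacency(15)
        stat = rng.uniform(0, 2, size=15)
        base = stats.tfce_enhance(stat, adj, dh=0.02)
        bumped = stat.copy()
        bumped[7] += 0.5
        out = stats.tfce_enhance(bumped, adj, dh=0.02)
        assert (out >= base - 1e-9).all()

    def test_bad_dh_rejected(self):
        with pytest.raises(ValueError):
            stats.tfce_enhance(np.ones(3), self._line_adjacency(3), dh=0.0)
        with pytest.raises(ValueError):
            stats.tfce_enhance(np.array([-1.0, 0.0]), self._line_adjacency(2))


class TestPermutationInference:
    def test_single_permutation_two_point_pvalues(self):
        table = make_table(20, seed=0)
        design = stats.build_design(table)
        Y = np.random.default_rng(1).normal(size=(10, 20))
        res = stats.permutation_inference(Y, design, "sex", n_perm=1, seed=0)
        assert set(np.round(res.corrected_p, 6)) <= {0.5, 1.0}

    def test_strong_effect_hits_the_floor(self):
        table = make_table(40, seed=2)
        design = stats.build_design(table)
        female = (table["sex"] == "F").to_numpy(float)
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(20, 40))
        Y[5] += 10.0 * female  # effect 10x noise SD
        res = stats.permutation_inference(Y, design, "sex", n_perm=499, seed=1)
        assert res.corrected_p[5] == pytest.approx(1 / 500)

    def test_corrected_dominates_uncorrected(self, rng):
        table = make_table(30, seed=5)
        design = stats.build_design(table)
        Y = rng.normal(size=(50, 30))
        res = stats.permutation_inference(Y, design, "age", n_perm=199, seed=2)
        assert (res.corrected_p >= res.uncorrected_p - 1e-12).all()

    def test_unknown_term_rejected(self):
        table = make_table(20, seed=0)
        design = stats.build_design(table)
        with pytest.raises(ValueError):
            stats.permutation_inference(
                np.zeros((3, 20)), design, "height", n_perm=10
            )

    def test_tfce_method_runs_and_flags_real_effect(self):
        table = make_table(40, seed=7)
        design = stats.build_design(table)
        female = (table["sex"] == "F").to_numpy(float)
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(30, 40))
        Y[10:15] += 8.0 * female  # spatially contiguous strong effect
        adj = stats.grid_adjacency(np.ones((1, 1, 30), dtype=bool))
        res = stats.permutation_inference(
            Y, design, "sex", n_perm=199, method="tfce", seed=3, adjacency=adj
        )
        assert res.corrected_p[10:15].max() <= 0.05
        assert res.method == "tfce"


class TestInteractionScreen:
    def test_alpha_zero_drops_everything(self):
        table = make_table(100, seed=1)
        y = np.random.default_rng(2).normal(size=100)
        reduced, report = stats.interaction_screen(y, table, alpha=0.0)
        assert all(info["dropped"] for info in report.values())
        assert list(reduced.matrix.columns) == ["intercept", "icv", "age", "sex"]

    def test_null_interactions_usually_dropped(self):
        drops = 0
        reps = 100
        for r in range(reps):
            spec = synthetic.CohortSpec(n_men=400, n_women=400, seed=1000 + r)
            table = synthetic.generate_cohort(spec)
            _, report = stats.interaction_screen(table["CC_fa"].to_numpy(), table)
            if all(info["dropped"] for info in report.values()):
                drops += 1
        assert drops / reps >= 0.9

    def test_strong_interaction_retained(self):
        table = make_table(300, seed=4)
        rng = np.random.default_rng(5)
        female = (table["sex"] == "F").to_numpy(float)
        icv_c = table["icv_ml"].to_numpy() - table["icv_ml"].mean()
        y = 0.002 * icv_c * female + rng.normal(0, 0.01, 300)
        reduced, report = stats.interaction_screen(y, table)
        assert not report["icv:sex"]["dropped"]
        assert "icv:sex" in reduced.matrix.columns
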