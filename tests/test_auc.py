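"""AUC statistic, nonparametric tests, AICc machinery and the mixed model."""

import math

import numpy as np
import pandas as pd
import pytest

import rangeselect as rs
from rangeselect.auc import (
    LmmFit,
    logit_clamped,
    n_locations_class,
    fit_lmm_random_intercept,
)
from rangeselect.core_io import CellScoreField, ReferenceGrid


def brute_force_auc(scores, presence):
    """Pair-counting oracle: (wins + 0.5 ties) / (n1 * n0)."""
    s = np.asarray(scores, float).ravel()
    p = np.asarray(presence, bool).ravel()
    pres = s[p]
    abs_ = s[~p]
    wins = ties = 0
    for a in pres:
        for b in abs_:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pres) * len(abs_))


def field_and_traj(scores, fix_cells, grain=10.0):
    scores = np.asarray(scores, float)
    nr, nc = scores.shape
    grid = ReferenceGrid(0.0, 0.0, grain, nc, nr)
    xs = [(c + 0.5) * grain for r, c in fix_cells]
    ys = [(r + 0.5) * grain for r, c in fix_cells]
    traj = rs.Trajectory("a", t=np.arange(len(xs)) * 60.0, x=xs, y=ys)
    return CellScoreField(grid=grid, score=scores), traj


class TestComputeAuc:
    def test_uniform_scores_half(self):
        fld, traj = field_and_traj(np.ones((3, 3)), [(0, 0), (2, 2)])
        assert rs.compute_auc(fld, traj) == 0.5

    def test_perfect_ranking_one(self):
        s = np.zeros((3, 3))
        s[0, 0] = s[2, 2] = 5.0
        fld, traj = field_and_traj(s, [(0, 0), (2, 2)])
        assert rs.compute_auc(fld, traj) == 1.0

    def test_crafted_grid_matches_pair_oracle(self):
        s = np.array([[3.0, 1.0, 4.0], [1.0, 5.0, 9.0], [2.0, 6.0, 5.0]])
        cells = [(1, 2), (0, 0), (2, 1)]
        fld, traj = field_and_traj(s, cells)
        presence = np.zeros((3, 3), bool)
        for r, c in cells:
            presence[r, c] = True
        assert rs.compute_auc(fld, traj) == pytest.approx(
            brute_force_auc(s, presence), abs=1e-15
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_random_grids_match_pair_oracle(self, seed):
        r = np.random.default_rng(seed)
        nr, nc = r.integers(2, 12, 2)
        scores = r.integers(0, 6, (nr, nc)).astype(float)  # many ties
        n_fix = int(r.integers(1, nr * nc))
        cells = {(int(r.integers(nr)), int(r.integers(nc))) for _ in range(n_fix)}
        if len(cells) == nr * nc:
            cells.pop()
        fld, traj = field_and_traj(scores, sorted(cells))
        presence = np.zeros((nr, nc), bool)
        for rr, cc in cells:
            presence[rr, cc] = True
        assert abs(rs.compute_auc(fld, traj) - brute_force_auc(scores, presence)) < 1e-12

    def test_invariant_under_monotone_transforms(self, rng):
        import scipy.stats

        scores = rng.normal(size=(6, 6))
        cells = [(0, 0), (3, 4), (5, 5)]
        fld, traj = field_and_traj(scores, cells)
        base = rs.compute_auc(fld, traj)
        exp_fld = CellScoreField(grid=fld.grid, score=np.exp(scores))
        rank_fld = CellScoreField(
            grid=fld.grid, score=scipy.stats.rankdata(scores).reshape(scores.shape)
        )
        assert abs(rs.compute_auc(exp_fld, traj) - base) < 1e-12
        assert abs(rs.compute_auc(rank_fld, traj) - base) < 1e-12

    def test_all_presence_undefined(self):
        fld, traj = field_and_traj(np.ones((1, 2)), [(0, 0), (0, 1)])
        with pytest.raises(ValueError, match="undefined"):
            rs.compute_auc(fld, traj)


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        H, df, p = rs.kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert H == 0.0 and df == 2

    def test_fifteen_groups_df_14(self, rng):
        groups = [rng.normal(size=5).tolist() for _ in range(15)]
        _, df, _ = rs.kruskal_wallis(groups)
        assert df == 14

    def test_matches_manual_rank_computation(self):
        import scipy.stats

        a = [1.2, 3.4, 2.2]
        b = [4.5, 6.7, 5.5, 8.0]
        H, df, p = rs.kruskal_wallis([a, b])
        ranks = scipy.stats.rankdata(a + b)
        ra, rb = ranks[:3], ranks[3:]
        n = 7
        h_manual = 12.0 / (n * (n + 1)) * (
            3 * (ra.mean() ** 2) + 4 * (rb.mean() ** 2)
        ) - 3 * (n + 1)
        assert H == pytest.approx(h_manual, rel=1e-12)
        assert df == 1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            rs.kruskal_wallis([[1.0, 2.0]])


class TestPairwiseT:
    def test_identical_groups_p_one(self):
        g = [1.0, 1.0, 1.0]
        m = rs.pairwise_t_bonferroni([g, g, g])
        off = m[~np.isnan(m)]
        assert np.all(off == 1.0)

    def test_three_groups_multiplier_three(self, rng):
        import scipy.stats

        gs = [rng.normal(loc, 1.0, 10) for loc in (0.0, 0.5, 3.0)]
        m = rs.pairwise_t_bonferroni(gs)
        raw = scipy.stats.ttest_ind(gs[0], gs[1], equal_var=False).pvalue
        assert m[0, 1] == pytest.approx(min(1.0, raw * 3), rel=1e-12)

    def test_welch_statistic_hand_computed(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        se = math.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 5)
        t = (a.mean() - b.mean()) / se
        nu = (a.var(ddof=1) / 4 + b.var(ddof=1) / 5) ** 2 / (
            (a.var(ddof=1) / 4) ** 2 / 3 + (b.var(ddof=1) / 5) ** 2 / 4
        )
        import scipy.stats

        p_manual = 2 * scipy.stats.t.sf(abs(t), nu)
        m = rs.pairwise_t_bonferroni([a, b])
        assert m[0, 1] == pytest.approx(min(1.0, p_manual), rel=1e-10)


class TestLogitAicc:
    def test_logit_values(self):
        assert rs.logit(0.5) == 0.0
        assert rs.logit(0.9) == pytest.approx(2.1972, abs=1e-4)
        assert rs.logit(0.3) == pytest.approx(-rs.logit(0.7), rel=1e-12)

    def test_logit_boundary_rejected_and_clamped(self):
        with pytest.raises(ValueError):
            rs.logit(1.0)
        with pytest.warns(UserWarning):
            v = logit_clamped(1.0, n_cells=50)
        assert v == pytest.approx(math.log((1 - 0.01) / 0.01))

    def test_aicc_arithmetic(self):
        assert rs.aicc(-390.0, 10, 200) == pytest.approx(780 + 20 + 220 / 189, rel=1e-12)

    def test_aicc_approaches_aic_for_large_n(self):
        aic = -2 * (-100.0) + 2 * 3
        assert abs(rs.aicc(-100.0, 3, 10**6) - aic) < 0.01

    def test_aicc_correction_decreasing_in_n(self):
        vals = [rs.aicc(0.0, 5, n) for n in (20, 50, 200, 1000)]
        assert np.all(np.diff(vals) < 0)

    def test_aicc_needs_enough_data(self):
        with pytest.raises(ValueError):
            rs.aicc(0.0, 10, 11)

    def test_n_locations_bins(self):
        assert n_locations_class(99) == "<100"
        assert n_locations_class(100) == "<100"
        assert n_locations_class(101) == "101-500"
        assert n_locations_class(750) == "501-1000"
        assert n_locations_class(1200) == ">1000"


class TestModelSelection:
    def test_single_model_weight_one(self):
        rows = rs.model_selection([("m1", 3, 100.0)])
        assert rows[0].weight == 1.0 and rows[0].delta == 0.0

    def test_printed_delta_pair(self):
        rows = rs.model_selection([("best", 10, 786.06), ("global", 22, 807.98)])
        assert rows[1].delta == pytest.approx(21.92, abs=1e-9)
        assert rows[0].weight == pytest.approx(1.0, abs=1e-4)
        assert rows[1].weight == pytest.approx(math.exp(-21.92 / 2), rel=1e-3)

    def test_weights_sum_to_one_and_shift_invariant(self, rng):
        aiccs = rng.uniform(100, 130, 8)
        rows = rs.model_selection([(f"m{i}", 3, a) for i, a in enumerate(aiccs)])
        assert sum(r.weight for r in rows) == pytest.approx(1.0, abs=1e-9)
        shifted = rs.model_selection([(f"m{i}", 3, a + 55.5) for i, a in enumerate(aiccs)])
        assert [r.terms for r in shifted] == [r.terms for r in rows]
        assert np.allclose([r.weight for r in shifted], [r.weight for r in rows])


def simulate_records(seed, n_animals=15, sd_animal=0.3, sd_resid=0.3, betas=None):
    """Synthetic logit-AUC records with a known estimator effect structure."""
    r = np.random.default_rng(seed)
    tags = list(rs.ESTIMATOR_TAGS)
    if betas is None:
        betas = {t: 0.0 for t in tags}
        betas.update({"bbmm": 1.8, "dbbmm": 1.5, "mkde": 1.8, "locoh": -0.1})
    rows = []
    for i in range(n_animals):
        a_eff = r.normal(0, sd_animal)
        for tag in tags:
            y = 2.5 + betas[tag] + a_eff + r.normal(0, sd_resid)
            rows.append(
                {
                    "animal_id": f"A{i:02d}",
                    "estimator": tag,
                    "logit_auc": y,
                    "fix_success": 0.74,
                    "schedule_class": "hourly",
                    "n_locations_class": "501-1000",
                    "study_area": "south",
                }
            )
    return pd.DataFrame(rows), betas


class TestLmm:
    def test_balanced_anova_closed_form(self):
        """Variance components match the one-way ANOVA estimators."""
        r = np.random.default_rng(4)
        g, m = 12, 6
        a_eff = r.normal(0, 0.5, g)
        y = (a_eff[:, None] + r.normal(0, 0.3, (g, m))).ravel()
        df = pd.DataFrame(
            {"animal_id": np.repeat([f"A{i}" for i in range(g)], m), "y": y}
        )
        fit = fit_lmm_random_intercept(df, [], response="y")
        grand = y.reshape(g, m)
        msw = ((grand - grand.mean(1, keepdims=True)) ** 2).sum() / (g * (m - 1))
        msb = m * ((grand.mean(1) - grand.mean()) ** 2).sum() / (g - 1)
        assert fit.resid_sd**2 == pytest.approx(msw, rel=1e-6)
        assert fit.re_sd**2 == pytest.approx((msb - msw) / m, rel=1e-6)
        assert fit.params["Intercept"] == pytest.approx(grand.mean(), rel=1e-9)

    def test_zero_variance_reduces_to_ols(self):
        """Independent records (no animal effect) select the OLS boundary."""
        r = np.random.default_rng(11)
        df = pd.DataFrame(
            {
                "animal_id": np.repeat([f"A{i}" for i in range(10)], 4),
                "x": r.normal(size=40),
                "y": r.normal(size=40),
            }
        )
        df["y"] = 1.0 + 0.5 * df["x"] + r.normal(0, 1.0, 40)
        fit = fit_lmm_random_intercept(df, ["x"], response="y")
        X = np.column_stack([np.ones(40), df["x"]])
        beta_ols = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        if fit.re_sd == 0.0:
            assert np.allclose(fit.params.to_numpy(), beta_ols, atol=1e-6)
        else:  # boundary not selected on this draw; estimates still close
            assert np.allclose(fit.params.to_numpy(), beta_ols, atol=1e-2)

    def test_matches_statsmodels_mixedlm(self):
        """Independent oracle: statsmodels MixedLM on the same data."""
        import statsmodels.formula.api as smf

        df, _ = simulate_records(99)
        fit = fit_lmm_random_intercept(df, ["estimator"])
        sm_fit = smf.mixedlm(
            "logit_auc ~ C(estimator, Treatment('slca'))", df, groups=df["animal_id"]
        ).fit(reml=True)
        assert fit.params["Intercept"] == pytest.approx(
            sm_fit.params["Intercept"], abs=1e-4
        )
        assert fit.params["estimator[bbmm]"] == pytest.approx(
            sm_fit.params["C(estimator, Treatment('slca'))[T.bbmm]"], abs=1e-4
        )
        assert fit.se["estimator[bbmm]"] == pytest.approx(
            sm_fit.bse["C(estimator, Treatment('slca'))[T.bbmm]"], abs=1e-4
        )
        assert fit.re_sd == pytest.approx(
            math.sqrt(sm_fit.cov_re.iloc[0, 0]), abs=1e-3
        )

    def test_singular_design_lists_aliased_terms(self):
        df, _ = simulate_records(5)
        df["dup"] = df["fix_success"]
        with pytest.raises(ValueError, match="aliased"):
            fit_lmm_random_intercept(df, ["fix_success", "dup"], response="logit_auc")

    def test_reference_level_is_slca(self):
        df, _ = simulate_records(7)
        fit = fit_lmm_random_intercept(df, ["estimator"])
        assert "estimator[slca]" not in fit.params.index
        assert "estimator[bbmm]" in fit.params.index


class TestRunComparison:
    def _records(self, seed=3):
        r = np.random.default_rng(seed)
        records = []
        scheds = ["hourly", "four", "seven"]
        areas = ["south", "central", "north"]
        nlocs = ["<100", "101-500", "501-1000", ">1000"]
        for i in range(12):
            a_eff = r.normal(0, 0.2)
            for tech in ("GPS", "VHF"):
                for j, tag in enumerate(rs.ESTIMATOR_TAGS):
                    if tech == "VHF" and tag == "mkde":
                        auc = None
                    else:
                        base = 0.95 if tech == "GPS" else 0.90
                        auc = min(
                            0.999, max(0.6, base + 0.02 * (tag in ("bbmm", "dbbmm"))
                                       + 0.05 * a_eff + r.normal(0, 0.01))
                        )
                    records.append(
                        rs.AUCRecord(
                            animal_id=f"A{i:02d}",
                            estimator=tag,
                            technology=tech,
                            auc=auc,
                            n_locations=900,
                            n_locations_class=nlocs[i % 4],
                            fix_success=0.5 + 0.04 * (i % 10),
                            schedule_class=scheds[i % 3] if tech == "GPS" else "vhf",
                            study_area=areas[(i // 4) % 3],
                            n_cells=400,
                            status="ok" if auc is not None else "failed",
                        )
                    )
        return records

    def test_twelve_models_emitted_with_intercept(self):
        report = rs.run_comparison(self._records())
        assert len(report.model_rows) == 12
        assert any(m.terms.startswith("Intercept") for m in report.model_rows)
        assert report.model_rows[0].delta == 0.0

    def test_fifteen_groups_give_df_14(self):
        report = rs.run_comparison(self._records())
        H, df, p = report.kruskal
        assert df == 14

    def test_missing_records_not_counted_as_zero(self):
        report = rs.run_comparison(self._records())
        vhf_mkde = report.means[
            (report.means.technology == "VHF") & (report.means.estimator == "mkde")
        ]
        assert vhf_mkde.empty
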