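"""Success tables, block rates, repeated-measures ANOVA and improvement test."""

import numpy as np
import pandas as pd
import pytest

from barrelcross import stats as st
from barrelcross.cohort import simulate_cohort_frame


def _log(rows):
    return pd.DataFrame(
        rows, columns=["mouse_id", "genotype", "session", "trial_index", "distance_cm", "outcome"]
    )


class TestBuildSuccessTable:
    def test_single_trial(self):
        log = _log([("m1", "WT", 1, 1, 3.0, "success")])
        table = st.build_success_table(log)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row.n_trials, row.n_success) == (1, 1)

    def test_empty_log_gives_empty_table_and_downstream_refuses(self):
        table = st.build_success_table(_log([]))
        assert table.empty
        with pytest.raises(ValueError, match="empty"):
            st.block_rates(table)
        with pytest.raises(ValueError, match="empty"):
            st.cohort_totals(table)

    def test_duplicate_trial_keys_rejected(self):
        log = _log([("m1", "WT", 1, 1, 3.0, "success"), ("m1", "WT", 1, 1, 3.5, "failure")])
        with pytest.raises(ValueError, match="duplicate"):
            st.build_success_table(log)

    def test_unknown_outcome_rejected(self):
        log = _log([("m1", "WT", 1, 1, 3.0, "escaped")])
        with pytest.raises(ValueError, match="outcome"):
            st.build_success_table(log)

    def test_accounting_identity_on_simulated_cohort(self):
        trials = simulate_cohort_frame(n_wt=2, n_ko=3, seed=3)
        table = st.build_success_table(trials)
        for mouse, sub in trials.groupby("mouse_id"):
            assert table.loc[table.mouse_id == mouse, "n_trials"].sum() == len(sub)
            assert (
                table.loc[table.mouse_id == mouse, "n_success"].sum()
                == (sub.outcome == "success").sum()
            )


def _two_mouse_table():
    # hand-built: mouse m1 improves at 3.0 (50% -> 65%), m2 is flat
    rows = []
    for mouse, rates in (("m1", {1: (20, 10), 7: (20, 13)}), ("m2", {1: (10, 6), 7: (10, 6)})):
        for session, (n, k) in rates.items():
            rows.append(("%s" % mouse, "WT", session, 3.0, n, k))
            rows.append(("%s" % mouse, "WT", session, 3.5, n, k))
    return pd.DataFrame(rows, columns=st.TABLE_COLUMNS)


class TestBlockRates:
    def test_hand_computed_rates_and_improvement(self):
        summary = st.block_rates(_two_mouse_table())
        m1 = summary.rates[(summary.rates.mouse_id == "m1") & (summary.rates.distance_cm == 3.0)]
        assert sorted(m1.rate) == [50.0, 65.0]
        imp = summary.improvements
        m1_nose = imp[(imp.mouse_id == "m1") & (imp.class_label == "nose")].improvement.iloc[0]
        m2_nose = imp[(imp.mouse_id == "m2") & (imp.class_label == "nose")].improvement.iloc[0]
        assert m1_nose == pytest.approx(15.0)
        assert m2_nose == pytest.approx(0.0)

    def test_pooled_vs_per_session_modes(self):
        # unequal trial counts across sessions separate the two conventions
        rows = [
            ("m1", "WT", 1, 3.0, 10, 5),  # 50%
            ("m1", "WT", 2, 3.0, 90, 9),  # 10%
            ("m1", "WT", 7, 3.0, 10, 10),
        ]
        table = pd.DataFrame(rows, columns=st.TABLE_COLUMNS)
        pooled = st.block_rates(table, pool="pooled")
        per = st.block_rates(table, pool="per_session")
        b1 = pooled.blocks[0]
        r_pooled = pooled.rates[(pooled.rates.block == b1)].rate.iloc[0]
        r_per = per.rates[(per.rates.block == b1)].rate.iloc[0]
        assert r_pooled == pytest.approx(100.0 * 14 / 100)
        assert r_per == pytest.approx(30.0)

    def test_improvement_invariant_to_session_permutation_within_block(self):
        rng = np.random.default_rng(0)
        trials = simulate_cohort_frame(n_wt=2, n_ko=2, seed=9)
        table = st.build_success_table(trials)
        base = st.block_rates(table).improvements.set_index(["mouse_id", "class_label"])
        # permute session labels within each block
        perm = {1: 4, 4: 1, 2: 6, 6: 2, 3: 3, 5: 5, 7: 11, 11: 7, 8: 8, 9: 10, 10: 9, 12: 12}
        shuffled = table.assign(session=table.session.map(perm))
        out = st.block_rates(shuffled).improvements.set_index(["mouse_id", "class_label"])
        pd.testing.assert_frame_equal(base.sort_index(), out.sort_index())

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            st.block_rates(_two_mouse_table(),
                           blocks=(("a", (1, 2)), ("b", (2, 3))))


def _rm_anova_loop_oracle(Y: np.ndarray):
    """From-scratch sums of squares with explicit loops (independent oracle)."""
    n, k, b = Y.shape
    mu = Y.mean()
    ss_block = 0.0
    for j in range(b):
        ss_block += n * k * (Y[:, :, j].mean() - mu) ** 2
    ss_bs = 0.0
    for m in range(n):
        for j in range(b):
            ss_bs += k * (Y[m, :, j].mean() - Y[m].mean() - Y[:, :, j].mean() + mu) ** 2
    ss_bds = 0.0
    for m in range(n):
        for d in range(k):
            for j in range(b):
                resid = (
                    Y[m, d, j]
                    - Y[m, d, :].mean()
                    - Y[m, :, j].mean()
                    - Y[:, d, j].mean()
                    + Y[m].mean()
                    + Y[:, d, :].mean()
                    + Y[:, :, j].mean()
                    - mu
                )
                ss_bds += resid**2
    df2 = (n - 1) * k
    F = ss_block / ((ss_bs + ss_bds) / df2)
    return F, df2, ss_block, ss_bs, ss_bds


def _summary_from_cube(Y: np.ndarray, genotype="WT", dists=(5.0, 5.5, 6.0)):
    rows = []
    blocks = ("sessions_1_6", "sessions_7_12")
    for m in range(Y.shape[0]):
        for d, dist in enumerate(dists):
            for j, block in enumerate(blocks):
                rows.append(
                    {"mouse_id": f"m{m}", "genotype": genotype, "distance_cm": dist,
                     "block": block, "n_trials": 10, "n_success": 5, "rate": Y[m, d, j]}
                )
    rates = pd.DataFrame(rows)
    return st.BlockSummary(rates=rates, improvements=pd.DataFrame(
        columns=["mouse_id", "genotype", "class_label", "improvement", "n_distances"]),
        blocks=blocks, classes={"whisker": tuple(dists), "nose": (3.0, 3.5, 4.0, 4.5)})


class TestRmAnova:
    def test_all_rates_equal_gives_zero_F(self):
        Y = np.full((4, 3, 2), 70.0)
        res = st.rm_anova_block_by_distance(_summary_from_cube(Y), "WT", "whisker")
        assert res.F == 0.0 and res.p == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Y = rng.uniform(20, 90, size=(6, 3, 2))
        res = st.rm_anova_block_by_distance(_summary_from_cube(Y), "WT", "whisker")
        F, df2, ss_block, ss_bs, ss_bds = _rm_anova_loop_oracle(Y)
        assert res.F == pytest.approx(F, rel=1e-8)
        assert res.df2 == df2 == 15
        assert res.ss_block == pytest.approx(ss_block, rel=1e-8)
        assert res.ss_error == pytest.approx(ss_bs + ss_bds, rel=1e-8)

    def test_unpooled_variant_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        Y = rng.uniform(20, 90, size=(6, 3, 2))
        res = st.rm_anova_block_by_distance(_summary_from_cube(Y), "WT", "whisker")
        rows = []
        for m in range(6):
            for d in range(3):
                for j in range(2):
                    rows.append({"mouse": m, "dist": d, "block": j, "rate": Y[m, d, j]})
        df = pd.DataFrame(rows)
        table = pg.rm_anova(data=df, dv="rate", within=["block", "dist"], subject="mouse")
        row = table[table.Source == "block"].iloc[0]
        assert res.F_unpooled == pytest.approx(float(row.F), rel=1e-6)
        assert res.df2_unpooled == int(row.ddof2)

    def test_refuses_insufficient_design(self):
        Y = np.random.default_rng(0).uniform(20, 90, size=(1, 3, 2))
        with pytest.raises(ValueError, match=">= 2 mice"):
            st.rm_anova_block_by_distance(_summary_from_cube(Y), "WT", "whisker")
        with pytest.raises(ValueError, match="unknown distance class"):
            st.rm_anova_block_by_distance(_summary_from_cube(np.ones((3, 3, 2))), "WT", "paw")

    def test_missing_distance_dropped_listwise(self):
        Y = np.random.default_rng(1).uniform(20, 90, size=(4, 3, 2))
        summary = _summary_from_cube(Y)
        rates = summary.rates
        # remove one mouse's 6.0 cm block-2 cell
        drop = (rates.mouse_id == "m0") & (rates.distance_cm == 6.0) & (rates.block == "sessions_7_12")
        summary.rates = rates[~drop]
        res = st.rm_anova_block_by_distance(summary, "WT", "whisker")
        assert res.n_distances == 2
        oracle_F, oracle_df2, *_ = _rm_anova_loop_oracle(Y[:, :2, :])
        assert res.F == pytest.approx(oracle_F, rel=1e-8)

    def test_df_convention_reproduces_published_pattern(self):
        # six mice over a three-distance class: block effect tested on (1, 15)
        Y = np.random.default_rng(2).uniform(20, 90, size=(6, 3, 2))
        res = st.rm_anova_block_by_distance(_summary_from_cube(Y), "WT", "whisker")
        assert (res.df1, res.df2) == (1, 15)
        Y9 = np.random.default_rng(3).uniform(20, 90, size=(9, 3, 2))
        res9 = st.rm_anova_block_by_distance(_summary_from_cube(Y9), "WT", "whisker")
        assert (res9.df1, res9.df2) == (1, 24)


def _improvement_summary(wt, ko):
    rows = [
        {"mouse_id": f"w{i}", "genotype": "WT", "class_label": "whisker",
         "improvement": v, "n_distances": 3}
        for i, v in enumerate(wt)
    ] + [
        {"mouse_id": f"k{i}", "genotype": "KO", "class_label": "whisker",
         "improvement": v, "n_distances": 3}
        for i, v in enumerate(ko)
    ]
    return st.BlockSummary(
        rates=pd.DataFrame(), improvements=pd.DataFrame(rows),
        blocks=("sessions_1_6", "sessions_7_12"),
        classes=st.distance_classes(),
    )


class TestCompareImprovement:
    def test_identical_vectors(self):
        res = st.compare_improvement(_improvement_summary([5, 5, 5], [5, 5, 5]), "whisker")
        assert (res.t, res.p) == (0.0, 1.0)

    def test_matches_scipy_on_real_data(self):
        from scipy import stats as sps

        wt, ko = [15.0, 18.0, 12.0, 20.0], [1.0, -2.0, 4.0]
        res = st.compare_improvement(_improvement_summary(wt, ko), "whisker")
        t, p = sps.ttest_ind(wt, ko)
        assert res.t == pytest.approx(t) and res.p == pytest.approx(p)
        assert res.mean_difference == pytest.approx(np.mean(wt) - np.mean(ko))
        assert res.df == 5

    def test_p_shrinks_with_separation(self):
        rng = np.random.default_rng(0)
        last_p = 1.1
        for jitter in (8.0, 2.0, 0.5):
            wt = 15.0 + jitter * rng.standard_normal(6)
            ko = 0.0 + jitter * rng.standard_normal(9)
            res = st.compare_improvement(_improvement_summary(wt, ko), "whisker")
            assert res.p < last_p
            last_p = res.p

    def test_single_mouse_genotype_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            st.compare_improvement(_improvement_summary([5.0, 6.0], [3.0]), "whisker")


class TestCohortTotals:
    def test_single_mouse_sem_unavailable(self):
        table = pd.DataFrame([("m1", "WT", 1, 3.0, 10, 7)], columns=st.TABLE_COLUMNS)
        out = st.cohort_totals(table)
        assert out.loc["WT", "total_trials"] == 10
        assert out.loc["WT", "total_successes"] == 7
        assert np.isnan(out.loc["WT", "sem_successes"])

    def test_two_equal_mice(self):
        table = pd.DataFrame(
            [("m1", "WT", 1, 3.0, 12, 10), ("m2", "WT", 1, 3.0, 12, 10)],
            columns=st.TABLE_COLUMNS,
        )
        out = st.cohort_totals(table)
        assert out.loc["WT", "mean_successes_per_mouse"] == 10
        assert out.loc["WT", "sem_successes"] == 0.0

    def test_totals_equal_raw_log_counts(self):
        trials = simulate_cohort_frame(n_wt=2, n_ko=2, seed=5)
        out = st.cohort_totals(st.build_success_table(trials))
        for g in ("WT", "KO"):
            sub = trials[trials.genotype == g]
            assert out.loc[g, "total_trials"] == len(sub)
            assert out.loc[g, "total_successes"] == (sub.outcome == "success").sum()
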