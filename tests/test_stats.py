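"""t-tests, repeated-measures and mixed ANOVA, post hocs, dose summaries.

Oracles: scipy for the t-tests, exact sign-flip permutation for the paired
p-value, and pingouin / statsmodels AnovaRM as independent reference
implementations for the F statistics.
"""

import itertools

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from photopipe.stats import (
    ZeroVarianceError,
    bonferroni_posthocs,
    dose_response_summary,
    mixed_anova,
    paired_t,
    rm_anova,
    unpaired_t,
)
from photopipe.stats import mixed_anova_matrix, rm_anova_matrix


def _rm_table(Y):
    n, k = Y.shape
    return pd.DataFrame([dict(subject_id=f"s{i}", level=j, peak_dff=Y[i, j])
                         for i in range(n) for j in range(k)])


def _mixed_table(Y, groups):
    rows = []
    for i in range(Y.shape[0]):
        for j in range(Y.shape[1]):
            rows.append(dict(subject_id=f"s{i}", group=groups[i], day=j,
                             peak_dff=Y[i, j]))
    return pd.DataFrame(rows)


class TestPairedT:
    def test_hand_arithmetic(self):
        # diffs (1,2,3): mean 2, SD 1, SE 1/sqrt(3) -> t = 2*sqrt(3), df 2
        res = paired_t([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2.0 * np.sqrt(3.0), abs=1e-12)
        assert res.df == 2

    def test_identical_arrays_error_not_inf(self):
        with pytest.raises(ZeroVarianceError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ZeroVarianceError):
            paired_t([1.0, 2.0], [2.0, 3.0])  # constant nonzero diffs

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=9), rng.normal(size=9)
        res = paired_t(a, b)
        ref = sps.ttest_rel(b, a)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_p_close_to_exact_sign_flip_permutation(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.normal(0.3, 1.0, 8)
        res = paired_t(np.zeros_like(d), d)
        # exact permutation: all 2^8 sign assignments of the differences
        t_obs = abs(res.t)
        count = 0
        n_perm = 0
        for signs in itertools.product([1.0, -1.0], repeat=len(d)):
            ds = d * np.array(signs)
            t = ds.mean() / (ds.std(ddof=1) / np.sqrt(len(ds)))
            count += abs(t) >= t_obs - 1e-12
            n_perm += 1
        p_perm = count / n_perm
        assert abs(res.p - p_perm) < 0.06

    def test_unpaired_matches_scipy(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=6), rng.normal(0.5, 1.0, size=8)
        res = unpaired_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)
        assert res.df == 12


class TestRmAnova:
    def test_df_algebra_five_levels_four_subjects(self):
        rng = np.random.default_rng(1)
        res = rm_anova(_rm_table(rng.normal(size=(4, 5))), "peak_dff",
                       "level", "subject_id")
        assert (res.df_num, res.df_den) == (4, 12)

    def test_constant_dv_gives_zero_f(self):
        res = rm_anova(_rm_table(np.full((4, 3), 2.0)), "peak_dff",
                       "level", "subject_id")
        assert res.F == 0.0 and res.p == 1.0

    @pytest.mark.parametrize("n,k,seed", [(4, 3, 0), (6, 4, 1), (8, 5, 2), (5, 3, 3)])
    def test_matches_pingouin_and_statsmodels(self, n, k, seed):
        rng = np.random.default_rng(seed)
        Y = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
        res = rm_anova_matrix(Y)
        table = _rm_table(Y)
        ref = pg.rm_anova(data=table, dv="peak_dff", within="level",
                          subject="subject_id")
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-8)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)
        from statsmodels.stats.anova import AnovaRM
        sm = AnovaRM(table, "peak_dff", "subject_id", within=["level"]).fit()
        assert res.F == pytest.approx(float(sm.anova_table["F Value"].iloc[0]),
                                      rel=1e-8)

    def test_trials_averaged_to_subject_scores(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(5, 3))
        # duplicate each cell as two "trials" straddling the cell mean
        rows = []
        for i in range(5):
            for j in range(3):
                rows.append(dict(subject_id=f"s{i}", level=j,
                                 peak_dff=Y[i, j] + 0.5))
                rows.append(dict(subject_id=f"s{i}", level=j,
                                 peak_dff=Y[i, j] - 0.5))
        res = rm_anova(pd.DataFrame(rows), "peak_dff", "level", "subject_id")
        ref = rm_anova_matrix(Y)
        assert res.F == pytest.approx(ref.F, rel=1e-12)

    def test_missing_cell_listed(self):
        t = _rm_table(np.zeros((3, 3)))
        t = t[~((t["subject_id"] == "s1") & (t["level"] == 2))]
        with pytest.raises(ValueError, match="missing"):
            rm_anova(t, "peak_dff", "level", "subject_id")


class TestMixedAnova:
    def test_interaction_df_for_unbalanced_groups(self):
        rng = np.random.default_rng(2)
        groups = ["a"] * 4 + ["b"] * 5
        res = mixed_anova(_mixed_table(rng.normal(size=(9, 3)), groups),
                          "peak_dff", "day", "group", "subject_id")
        inter = res[2]
        assert inter.effect == "interaction"
        assert (inter.df_num, inter.df_den) == (2, 14)

    def test_constant_dv_gives_zero_f(self):
        res = mixed_anova(_mixed_table(np.full((6, 3), 1.0), ["a"] * 3 + ["b"] * 3),
                          "peak_dff", "day", "group", "subject_id")
        assert all(r.F == 0.0 for r in res)

    @pytest.mark.parametrize("sizes,b,seed", [
        ((4, 4), 3, 0), ((4, 5), 3, 1), ((6, 5), 4, 2), ((3, 4, 5), 3, 3),
        ((8, 8), 5, 4),
    ])
    def test_matches_pingouin(self, sizes, b, seed):
        rng = np.random.default_rng(seed)
        N = sum(sizes)
        Y = rng.normal(size=(N, b)) + rng.normal(size=(N, 1))
        groups = [f"g{k}" for k, n in enumerate(sizes) for _ in range(n)]
        res = mixed_anova_matrix(Y, np.array(groups))
        ref = pg.mixed_anova(data=_mixed_table(Y, groups), dv="peak_dff",
                             within="day", between="group", subject="subject_id")
        for eff, src in [(res[0], "group"), (res[1], "day"), (res[2], "Interaction")]:
            row = ref[ref["Source"] == src].iloc[0]
            assert eff.F == pytest.approx(float(row["F"]), rel=1e-8), src
            assert eff.df_num == int(row["DF1"]) and eff.df_den == int(row["DF2"])

    def test_group_varying_within_subject_rejected(self):
        t = _mixed_table(np.zeros((4, 2)), ["a", "a", "b", "b"])
        t.loc[(t["subject_id"] == "s0") & (t["day"] == 1), "group"] = "b"
        with pytest.raises(ValueError, match="varies within"):
            mixed_anova(t, "peak_dff", "day", "group", "subject_id")

    def test_incomplete_within_layout_rejected(self):
        t = _mixed_table(np.zeros((4, 3)), ["a", "a", "b", "b"])
        t = t[~((t["subject_id"] == "s3") & (t["day"] == 2))]
        with pytest.raises(ValueError, match="missing"):
            mixed_anova(t, "peak_dff", "day", "group", "subject_id")


class TestPosthocs:
    def _table(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, n in [("tfc", 4), ("tone", 5)]:
            for s in range(n):
                for day in (1, 2, 3):
                    rows.append(dict(subject_id=f"{g}{s}", group=g, day=day,
                                     peak_dff=rng.normal(2.0 - 0.5 * day)))
        return pd.DataFrame(rows)

    def test_single_comparison_unadjusted(self):
        fam = [dict(label="d1 vs d2", kind="paired", factor="day", a=1, b=2)]
        out = bonferroni_posthocs(self._table(), fam).table
        assert out["p_adj"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_bonferroni_arithmetic_and_cap(self):
        fam = [dict(label=f"c{i}", kind="paired", factor="day", a=a, b=b)
               for i, (a, b) in enumerate([(1, 2), (1, 3), (2, 3)])]
        out = bonferroni_posthocs(self._table(), fam).table
        assert (out["m"] == 3).all()
        np.testing.assert_allclose(out["p_adj"],
                                   np.minimum(1.0, 3.0 * out["p_raw"]))
        assert (out["p_adj"] >= out["p_raw"]).all()
        assert (out["p_adj"] <= 1.0).all()

    def test_unpaired_between_group_comparison(self):
        fam = [dict(label="tfc vs tone, day 1", kind="unpaired", factor="group",
                    a="tfc", b="tone", where={"day": 1})]
        out = bonferroni_posthocs(self._table(), fam).table
        assert out["df"].iloc[0] == 7  # 4 + 5 - 2

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            bonferroni_posthocs(self._table(), [])


class TestDoseResponse:
    def _responses(self):
        rows = []
        for s, off in [("m1", 0.0), ("m2", 1.0)]:
            for i, amp in [(0.2, 2.0), (0.4, 3.0)]:
                rows.append(dict(subject_id=s, intensity=i, phase="post",
                                 peak_dff=amp + off))
        return pd.DataFrame(rows)

    def test_two_subject_sem_identity(self):
        out = dose_response_summary(self._responses())
        # two subjects differing by 1.0: SEM = |diff| / 2
        np.testing.assert_allclose(out["sem"], 0.5)
        np.testing.assert_allclose(out["mean"], [2.5, 3.5])

    def test_single_subject_sem_missing(self):
        t = self._responses()
        out = dose_response_summary(t[t["subject_id"] == "m1"])
        assert out["sem"].isna().all()
        np.testing.assert_allclose(out["mean"], [2.0, 3.0])

    def test_matches_brute_force_groupby(self):
        rng = np.random.default_rng(7)
        rows = [dict(subject_id=f"m{s}", intensity=i, phase="post",
                     peak_dff=float(rng.normal()))
                for s in range(5) for i in (0.0, 0.2, 0.4) for _ in range(3)]
        t = pd.DataFrame(rows)
        out = dose_response_summary(t).set_index("intensity")
        for i in (0.0, 0.2, 0.4):
            subj = [t[(t["intensity"] == i) & (t["subject_id"] == f"m{s}")]
                    ["peak_dff"].mean() for s in range(5)]
            assert out.loc[i, "mean"] == pytest.approx(np.mean(subj))
            assert out.loc[i, "sem"] == pytest.approx(
                np.std(subj, ddof=1) / np.sqrt(5))
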