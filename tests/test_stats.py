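"""Statistics battery: PSEs, effect sizes, Bayes factors, RM-ANOVA.

Bayes factors are checked against an independent dense-quadrature oracle
written directly from the prior-times-likelihood definition, and against
pingouin's closed-form implementations.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lddnum import (
    bf_pearson,
    bf_ttest_jzs,
    compute_pse,
    correlation_matrix_with_bf,
    effect_size,
    effect_size_table,
    label_evidence,
    paired_t,
    paired_ttest_with_bf,
    pearson_r_with_bf,
    rm_anova,
    summarize_experiment,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def jzs_bf_oracle(t, n, r=0.707, alternative="two-sided", grid=400_000):
    """Brute-force trapezoid quadrature of the JZS integral.

    Substitutes delta = r tan(theta) so the Cauchy prior becomes uniform
    on (-pi/2, pi/2), then integrates the noncentral-t likelihood on a
    dense grid.  Shares no code with the implementation under test.
    """
    if alternative == "two-sided":
        theta = np.linspace(-np.pi / 2, np.pi / 2, grid)[1:-1]
        w = 1.0 / np.pi
    elif alternative == "greater":
        theta = np.linspace(0.0, np.pi / 2, grid)[1:-1]
        w = 2.0 / np.pi
    else:
        theta = np.linspace(-np.pi / 2, 0.0, grid)[1:-1]
        w = 2.0 / np.pi
    delta = r * np.tan(theta)
    like = sps.nct.pdf(t, n - 1, delta * math.sqrt(n))
    num = np.trapezoid(like * w, theta)
    return num / sps.t.pdf(t, n - 1)


# ---------------------------------------------------------------------------
# PSE and effect sizes
# ---------------------------------------------------------------------------


class TestComputePse:
    @staticmethod
    def _log(finals):
        return pd.DataFrame(
            {
                "subject_id": 0,
                "grouping_feature": "color",
                "n_groups": 2,
                "n_test": 20,
                "final_response": finals,
            }
        )

    @pytest.mark.parametrize("finals,expected", [([19, 21], 20.0), ([17], 17.0)])
    def test_cell_mean(self, finals, expected):
        pse = compute_pse(self._log(finals), ["grouping_feature", "n_groups"])
        assert pse["pse"].iloc[0] == expected

    def test_eight_repetitions_average(self, rng):
        finals = list(rng.integers(10, 30, size=8))
        pse = compute_pse(self._log(finals), ["grouping_feature", "n_groups"])
        assert pse["pse"].iloc[0] == pytest.approx(np.mean(finals))

    def test_empty_cells_stay_missing(self):
        pse = compute_pse(self._log([19, 21]), ["grouping_feature", "n_groups"])
        assert len(pse) == 1  # absent cells are not imputed


class TestEffectSize:
    def test_worked_example(self):
        assert effect_size(19, 20) == pytest.approx(-5.0)

    def test_symmetric_and_null_cases(self):
        assert effect_size(21, 20) == pytest.approx(5.0)
        assert effect_size(13.7, 13.7) == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(
        m2=st.floats(0.1, 50),
        m1=st.floats(0.1, 50),
        c=st.floats(0.01, 100),
    )
    def test_scale_invariance(self, m2, m1, c):
        assert effect_size(c * m2, c * m1) == pytest.approx(effect_size(m2, m1))

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            effect_size(19, 0)

    def test_per_set_size_then_averaged(self):
        rows = []
        for n, one, two in ((16, 16.0, 15.0), (20, 20.0, 20.0)):
            rows.append(dict(subject_id=0, grouping_feature="color", n_groups=1,
                             n_test=n, pse=one))
            rows.append(dict(subject_id=0, grouping_feature="color", n_groups=2,
                             n_test=n, pse=two))
        es = effect_size_table(pd.DataFrame(rows))
        # (-6.25% at 16 dots, 0% at 20 dots) -> -3.125%
        assert es["effect_size_pct"].iloc[0] == pytest.approx(-3.125)


# ---------------------------------------------------------------------------
# t-tests and JZS Bayes factors
# ---------------------------------------------------------------------------


class TestPairedT:
    def test_matches_hand_computation_on_four_pairs(self):
        x = np.array([11.0, 14.0, 13.0, 18.0])
        y = np.array([10.0, 12.0, 10.0, 12.0])
        d = x - y
        se = d.std(ddof=1) / 2.0
        res = paired_t(x, y)
        assert res.statistic == pytest.approx(d.mean() / se)
        assert res.delta == pytest.approx(d.mean())
        assert res.df == 3
        assert res.p == pytest.approx(2 * sps.t.sf(abs(res.statistic), 3))

    def test_zero_variance_differences_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t([1.0, 2.0, 3.0, 4.0], [0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="variance"):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestJzsBayesFactor:
    @pytest.mark.parametrize(
        "t,n",
        [(0.0, 10), (1.0, 12), (2.0, 20), (2.5, 55), (-1.7, 30), (4.0, 55)],
    )
    def test_matches_dense_quadrature_oracle(self, t, n):
        for alt in ("two-sided", "greater", "less"):
            mine = bf_ttest_jzs(t, n, alternative=alt)
            oracle = jzs_bf_oracle(t, n, alternative=alt)
            assert mine == pytest.approx(oracle, rel=5e-4)

    @pytest.mark.parametrize("t,n", [(0.5, 10), (2.0, 20), (3.3, 55)])
    def test_prior_halving_identity(self, t, n):
        bf10 = bf_ttest_jzs(t, n)
        bfp = bf_ttest_jzs(t, n, alternative="greater")
        bfm = bf_ttest_jzs(t, n, alternative="less")
        assert (bfp + bfm) / 2 == pytest.approx(bf10, rel=1e-6)

    def test_zero_t_favors_null(self):
        assert bf_ttest_jzs(0.0, 25) < 1.0

    def test_monotone_in_absolute_t(self):
        bfs = [bf_ttest_jzs(t, 20) for t in (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)]
        assert all(b < a for b, a in zip(bfs, bfs[1:]))

    def test_agrees_with_pingouin(self):
        for t, n in [(1.5, 15), (2.5, 40), (-2.0, 55)]:
            assert bf_ttest_jzs(t, n) == pytest.approx(
                float(pg.bayesfactor_ttest(t, n, paired=True)), rel=1e-4
            )

    def test_paired_wrapper_labels_direction(self, rng):
        x = rng.normal(1, 1, 20)
        y = rng.normal(0, 1, 20)
        res = paired_ttest_with_bf(x, y, alternative="greater")
        assert res.bf_direction == "BF+0"
        assert res.bf > 0


class TestPearsonBayesFactor:
    @pytest.mark.parametrize("r,n", [(0.1, 20), (0.378, 55), (-0.3, 30), (0.6, 12)])
    def test_agrees_with_pingouin(self, r, n):
        for alt, pg_alt in [("two-sided", "two-sided"), ("greater", "greater")]:
            assert bf_pearson(r, n, alternative=alt) == pytest.approx(
                float(pg.bayesfactor_pearson(r, n, alternative=pg_alt, method="ly")),
                rel=1e-3,
            )

    def test_directional_halving_identity(self):
        r, n = 0.25, 40
        two = bf_pearson(r, n)
        up = bf_pearson(r, n, alternative="greater")
        dn = bf_pearson(r, n, alternative="less")
        assert (up + dn) / 2 == pytest.approx(two, rel=1e-6)

    def test_perfect_correlation_is_unbounded_evidence(self):
        x = np.arange(10.0)
        res = pearson_r_with_bf(x, 2 * x + 1)
        assert res.delta == pytest.approx(1.0)
        assert math.isinf(res.bf)

    def test_independent_data_gives_small_r(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=2000), rng.normal(size=2000)
        res = pearson_r_with_bf(x, y)
        assert abs(res.delta) < 0.05
        assert res.bf < 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r_with_bf(np.ones(10), np.arange(10.0))

    def test_correlation_matrix_layout(self, rng):
        rows = []
        for s in range(12):
            for f in ("spatial", "size", "color", "motion"):
                rows.append(dict(subject_id=s, grouping_feature=f,
                                 effect_size_pct=rng.normal()))
        mat = correlation_matrix_with_bf(pd.DataFrame(rows))
        assert len(mat) == 6  # unordered pairs of 4 features
        assert (mat["bf_direction"] == "BF+0").all()


class TestEvidenceLabels:
    @pytest.mark.parametrize(
        "bf,label",
        [
            (150, "extreme"),
            (100.0, "very strong"),
            (17.12, "strong"),
            (30.0, "strong"),
            (10.0, "moderate"),
            (3.0, "anecdotal"),
            (1.5, "anecdotal"),
            (1.0, "none"),
            (0.2, "moderate (H0)"),
            (1 / 150, "extreme (H0)"),
        ],
    )
    def test_bins(self, bf, label):
        assert label_evidence(bf) == label

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            label_evidence(0.0)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------


def _within_data(rng, n_subj=12, effects=None):
    """Balanced 2 x 2 x 4 within-subject data with optional injected effects."""
    effects = effects or {}
    rows = []
    for s in range(n_subj):
        base = rng.normal(0, 2)
        for a, b, c in itertools.product(range(2), range(2), range(4)):
            y = base + rng.normal(0, 1)
            y += effects.get("Fa", 0) * a
            y += effects.get("Fb:Fc", 0) * b * c
            rows.append(dict(subj=s, Fa=a, Fb=b, Fc=c, y=y))
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_matches_statsmodels_anovarm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        df = _within_data(rng, effects={"Fa": 0.8, "Fb:Fc": 0.3})
        mine = rm_anova(df, "y", "subj", ["Fa", "Fb", "Fc"], inclusion_bf=False)
        ref = AnovaRM(df, "y", "subj", within=["Fa", "Fb", "Fc"]).fit().anova_table
        for _, row in mine.iterrows():
            key = row["effect"].replace(" * ", ":")
            assert row["F"] == pytest.approx(ref.loc[key, "F Value"], rel=1e-8)
            assert row["p"] == pytest.approx(ref.loc[key, "Pr > F"], abs=1e-10)

    def test_matches_hand_computed_two_factor_table(self):
        # 3 subjects x 2 x 2, computed by textbook marginal-mean formulas
        df = pd.DataFrame(
            [
                dict(subj=s, A=a, B=b, y=y)
                for (s, a, b), y in zip(
                    itertools.product(range(3), range(2), range(2)),
                    [12.0, 14, 15, 19, 11, 12, 14, 16, 13, 16, 17, 21],
                )
            ]
        )
        cube = df.pivot_table(index="subj", columns=["A", "B"], values="y").to_numpy()
        cube = cube.reshape(3, 2, 2)
        grand = cube.mean()
        a_m = cube.mean(axis=(0, 2))
        ss_a = 3 * 2 * np.sum((a_m - grand) ** 2)
        sa_m = cube.mean(axis=2)  # subject x A means
        s_m = cube.mean(axis=(1, 2))
        ss_as = 2 * np.sum(
            (sa_m - s_m[:, None] - a_m[None, :] + grand) ** 2
        )
        f_a = (ss_a / 1) / (ss_as / 2)
        res = rm_anova(df, "y", "subj", ["A", "B"], inclusion_bf=False)
        row = res[res["effect"] == "A"].iloc[0]
        assert row["ss"] == pytest.approx(ss_a)
        assert row["F"] == pytest.approx(f_a)

    def test_matches_pingouin_mixed_anova(self, rng):
        rows = []
        for s in range(20):
            g = "x" if s < 10 else "y"
            base = rng.normal(0, 1.5)
            for w in range(3):
                rows.append(
                    dict(subj=s, G=g, W=w,
                         y=base + 0.4 * w + (0.3 * w if g == "y" else 0)
                         + rng.normal(0, 1))
                )
        df = pd.DataFrame(rows)
        mine = rm_anova(df, "y", "subj", ["W"], between="G", inclusion_bf=False)
        ref = pg.mixed_anova(data=df, dv="y", within="W", subject="subj",
                             between="G")
        pairs = {"G": "G", "W": "W", "G * W": "Interaction"}
        for eff, src in pairs.items():
            m = mine[mine["effect"] == eff].iloc[0]
            r = ref[ref["Source"] == src].iloc[0]
            assert m["F"] == pytest.approx(r["F"], rel=1e-8)
            assert m["partial_eta_sq"] == pytest.approx(r["np2"], rel=1e-6)

    def test_null_data_shows_no_effects(self, rng):
        df = _within_data(rng)
        res = rm_anova(df, "y", "subj", ["Fa", "Fb", "Fc"], inclusion_bf=False)
        # pure additive subject effect + noise: nothing should be extreme
        assert (res["p"] > 1e-3).all()

    def test_injected_main_effect_dominates(self, rng):
        df = _within_data(rng, effects={"Fa": 3.0})
        res = rm_anova(df, "y", "subj", ["Fa", "Fb", "Fc"], inclusion_bf=True)
        top = res.sort_values("F", ascending=False).iloc[0]
        assert top["effect"] == "Fa"
        assert top["bf_inclusion_approx"] > 100
        null_bfs = res[res["effect"] != "Fa"]["bf_inclusion_approx"]
        assert (null_bfs < 3).all()

    def test_gg_correction_matches_pingouin_one_way(self, rng):
        # one within factor with heterogeneous level variances (non-spherical)
        rows = []
        for s in range(15):
            base = rng.normal(0, 1)
            for w, sd in enumerate((0.3, 1.0, 2.0, 4.0)):
                rows.append(dict(subj=s, W=w, y=base + 0.5 * w + rng.normal(0, sd)))
        df = pd.DataFrame(rows)
        mine = rm_anova(df, "y", "subj", ["W"], inclusion_bf=False)
        ref = pg.rm_anova(data=df, dv="y", within="W", subject="subj",
                          correction=True)
        row, r = mine.iloc[0], ref.iloc[0]
        assert row["F"] == pytest.approx(r["F"], rel=1e-8)
        assert row["p_gg"] == pytest.approx(r["p_GG_corr"], rel=1e-6)

    def test_unbalanced_design_names_offending_cell(self, rng):
        df = _within_data(rng)
        df = df[~((df["subj"] == 2) & (df["Fa"] == 1) & (df["Fb"] == 0)
                  & (df["Fc"] == 3))]
        with pytest.raises(ValueError, match="missing cell: subject=2"):
            rm_anova(df, "y", "subj", ["Fa", "Fb", "Fc"])


class TestSummarizeExperiment:
    @staticmethod
    def _pse(values):
        return pd.DataFrame(
            dict(subject_id=range(len(values)), grouping_feature="color",
                 n_groups=1, n_test=16, pse=values)
        )

    def test_ci_half_width_hand_check(self):
        vals = [14.0, 16.0, 15.0, 17.0, 13.0]
        out = summarize_experiment(self._pse(vals), ["grouping_feature", "n_groups"])
        x = np.asarray(vals)
        half = sps.t.ppf(0.975, 4) * x.std(ddof=1) / np.sqrt(5)
        assert out["mean_pse"].iloc[0] == pytest.approx(x.mean())
        assert out["ci_high"].iloc[0] - out["mean_pse"].iloc[0] == pytest.approx(half)
        assert out["ci_low"].iloc[0] <= out["mean_pse"].iloc[0] <= out["ci_high"].iloc[0]

    def test_identical_subjects_give_zero_width(self):
        out = summarize_experiment(self._pse([16.0, 16.0, 16.0]),
                                   ["grouping_feature", "n_groups"])
        assert out["ci_low"].iloc[0] == out["ci_high"].iloc[0] == 16.0
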