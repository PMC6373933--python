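"""Analysis battery for adjustment-task trial logs.

The dependent variable everywhere is the point of subjective equality
(PSE): the final response-array count, averaged over trial repetitions,
per subject and condition.  On top of PSE tables the module provides

* the percentage effect-size statistic for two-group vs. one-group
  arrays, 100 * (M_two / M_one - 1), computed per set size and averaged;
* paired t-tests with default-prior (JZS) Bayes factors, including the
  directional variants obtained by truncating the Cauchy prior to one
  sign;
* Pearson correlations with default Bayes factors under a stretched-beta
  prior on the population correlation;
* balanced repeated-measures / split-plot ANOVA with partial eta^2,
  Greenhouse-Geisser and Huynh-Feldt corrections, and a BIC-based
  approximation to the inclusion Bayes factor (approximate by
  construction: it compares one pair of fixed-effect models rather than
  model-averaging);
* the conventional evidence labels for Bayes factors.

All Bayes factors are computed by one-dimensional numerical integration
over the prior; closed forms are deliberately avoided so the quadrature
can be checked against independent oracles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps

__all__ = [
    "TestResult",
    "compute_pse",
    "effect_size",
    "effect_size_table",
    "paired_t",
    "bf_ttest_jzs",
    "paired_ttest_with_bf",
    "bf_pearson",
    "pearson_r_with_bf",
    "correlation_matrix_with_bf",
    "rm_anova",
    "label_evidence",
    "summarize_experiment",
]

DEFAULT_CAUCHY_SCALE = 0.707  # default effect-size prior width for t-tests
DEFAULT_BETA_KAPPA = 1.0  # stretched-beta prior width for correlations


@dataclass(frozen=True)
class TestResult:
    """One statistical comparison: frequentist and Bayesian summaries."""

    statistic: float
    df: float
    p: float
    delta: Optional[float] = None  # mean difference (dots) or Pearson r
    bf: Optional[float] = None
    bf_direction: str = "BF10"  # {BF10, BF+0, BF-0}
    evidence_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.bf is not None and self.bf <= 0:
            raise ValueError("Bayes factors must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


# ---------------------------------------------------------------------------
# PSE aggregation and effect sizes
# ---------------------------------------------------------------------------


def compute_pse(
    records: pd.DataFrame, condition_cols: Sequence[str]
) -> pd.DataFrame:
    """Per-subject, per-condition, per-numerosity mean final response.

    Returns a tidy frame with columns ``subject_id``, the condition
    columns, ``n_test`` and ``pse``.  Cells with no trials are simply
    absent from the output (missing, never imputed as zero).
    """
    required = {"subject_id", "n_test", "final_response"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"trial log lacks columns {sorted(missing)}")
    keys = ["subject_id", *condition_cols, "n_test"]
    out = (
        records.groupby(keys, dropna=False)["final_response"]
        .mean()
        .rename("pse")
        .reset_index()
    )
    return out


def effect_size(mean_two_group: float, mean_one_group: float) -> float:
    """Percentage over/underestimation of two-group vs one-group arrays.

    ``(mean_two / mean_one - 1) * 100``; e.g. mean reports of 19 dots in
    two-group trials against 20 in one-group trials give -5.0 %.
    """
    if mean_one_group <= 0:
        raise ValueError("one-group mean must be positive")
    return (mean_two_group / mean_one_group - 1.0) * 100.0


def effect_size_table(pse: pd.DataFrame) -> pd.DataFrame:
    """Per-subject grouping effect sizes for an Experiment-1 PSE table.

    For each grouping feature the effect size is computed separately at
    each set size and then averaged across set sizes, yielding one value
    per subject and feature.  Columns: subject_id, grouping_feature,
    effect_size_pct.
    """
    rows = []
    pivot = pse.set_index(["subject_id", "grouping_feature", "n_groups", "n_test"])[
        "pse"
    ]
    subjects = pse["subject_id"].unique()
    features = pse["grouping_feature"].unique()
    set_sizes = sorted(pse["n_test"].unique())
    for s in subjects:
        for f in features:
            vals = []
            for n in set_sizes:
                try:
                    one = pivot.loc[(s, f, 1, n)]
                    two = pivot.loc[(s, f, 2, n)]
                except KeyError:
                    continue
                vals.append(effect_size(two, one))
            if vals:
                rows.append(
                    {
                        "subject_id": s,
                        "grouping_feature": f,
                        "effect_size_pct": float(np.mean(vals)),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# t-tests and JZS Bayes factors
# ---------------------------------------------------------------------------


def paired_t(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Standard paired t-test on x - y; delta is mean(x - y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-d samples with n >= 3")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences")
    res = sps.ttest_rel(x, y, alternative=alternative)
    return TestResult(
        statistic=float(res.statistic),
        df=float(len(x) - 1),
        p=float(res.pvalue),
        delta=float(d.mean()),
    )


def _jzs_half_integral(
    t: float, n: int, prior_scale: float, lo: float, hi: float
) -> tuple[float, float]:
    """Integral of nct-likelihood x Cauchy prior over one sign of delta."""
    nu = n - 1
    sqrt_n = math.sqrt(n)

    def integrand(delta: float) -> float:
        return sps.nct.pdf(t, nu, delta * sqrt_n) * sps.cauchy.pdf(
            delta, 0.0, prior_scale
        )

    return integrate.quad(integrand, lo, hi, limit=200, epsabs=1e-12, epsrel=1e-10)


def bf_ttest_jzs(
    t: float,
    n: int,
    prior_scale: float = DEFAULT_CAUCHY_SCALE,
    alternative: str = "two-sided",
) -> float:
    """Default-prior (JZS) Bayes factor for a one-sample / paired t-test.

    The standardized effect size delta carries a Cauchy(0, prior_scale)
    prior under H1; the marginal likelihood is obtained by numerical
    integration of the noncentral-t likelihood over that prior and
    divided by the central-t likelihood under H0.  ``alternative``
    'greater' / 'less' restricts the prior to a half-Cauchy of the
    corresponding sign (so (BF+0 + BF-0) / 2 = BF10).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    neg, err_n = _jzs_half_integral(t, n, prior_scale, -np.inf, 0.0)
    pos, err_p = _jzs_half_integral(t, n, prior_scale, 0.0, np.inf)
    # the directional numerators reuse the two-sided pieces (half-Cauchy =
    # 2 x Cauchy on one sign), so (BF+0 + BF-0) / 2 == BF10 exactly
    if alternative == "two-sided":
        num = neg + pos
    elif alternative == "greater":
        num = 2.0 * pos
    elif alternative == "less":
        num = 2.0 * neg
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    total, err = neg + pos, err_n + err_p
    if not np.isfinite(total) or total <= 0 or err / total > 1e-6:
        raise RuntimeError(
            f"JZS integration did not converge (value={total}, abserr={err})"
        )
    return num / sps.t.pdf(t, n - 1)


_BF_TAG = {"two-sided": "BF10", "greater": "BF+0", "less": "BF-0"}


def paired_ttest_with_bf(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    prior_scale: float = DEFAULT_CAUCHY_SCALE,
) -> TestResult:
    """Paired t-test plus the matching JZS Bayes factor."""
    freq = paired_t(x, y, alternative=alternative)
    bf = bf_ttest_jzs(
        freq.statistic, len(np.asarray(x)), prior_scale=prior_scale,
        alternative=alternative,
    )
    return TestResult(
        statistic=freq.statistic,
        df=freq.df,
        p=freq.p,
        delta=freq.delta,
        bf=bf,
        bf_direction=_BF_TAG[alternative],
        evidence_label=label_evidence(bf),
    )


# ---------------------------------------------------------------------------
# Pearson correlation Bayes factors
# ---------------------------------------------------------------------------


def _corr_likelihood_ratio(r: float, n: int, rho: float) -> float:
    """p(r | rho, n) / p(r | 0, n) from the exact sampling density of r."""
    if abs(rho) >= 1.0:
        return 0.0
    h = special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)
    h0 = special.hyp2f1(0.5, 0.5, n - 0.5, 0.5)
    return (
        (1.0 - rho * rho) ** ((n - 1) / 2.0)
        * (1.0 - rho * r) ** (1.5 - n)
        * h
        / h0
    )


def bf_pearson(
    r: float,
    n: int,
    alternative: str = "two-sided",
    kappa: float = DEFAULT_BETA_KAPPA,
) -> float:
    """Default Bayes factor for a Pearson correlation.

    The population correlation rho carries a stretched-beta
    (Beta(1/kappa, 1/kappa) on [-1, 1]) prior; kappa = 1 gives the
    uniform default.  One-sided variants truncate (and renormalize) the
    prior to the stated sign.  Computed by numerical integration of the
    exact sampling density of r over the prior.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    a = 1.0 / kappa

    def prior(rho: float) -> float:
        return sps.beta.pdf((rho + 1.0) / 2.0, a, a) / 2.0

    if alternative == "two-sided":
        lo, hi, renorm = -1.0, 1.0, 1.0
    elif alternative == "greater":
        lo, hi, renorm = 0.0, 1.0, 2.0
    elif alternative == "less":
        lo, hi, renorm = -1.0, 0.0, 2.0
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    def integrand(rho: float) -> float:
        return _corr_likelihood_ratio(r, n, rho) * prior(rho) * renorm

    val, err = integrate.quad(integrand, lo, hi, limit=200)
    if not np.isfinite(val) or (val > 0 and err / val > 1e-5):
        raise RuntimeError(
            f"correlation BF integration did not converge "
            f"(value={val}, abserr={err})"
        )
    return val


def pearson_r_with_bf(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    kappa: float = DEFAULT_BETA_KAPPA,
) -> TestResult:
    """Pearson r with frequentist p and a default Bayes factor."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValueError("need two equal-length 1-d samples with n >= 4")
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise ValueError("constant input has no defined correlation")
    res = sps.pearsonr(x, y, alternative=alternative)
    r = float(res.statistic)
    n = len(x)
    if abs(r) >= 1.0 - 1e-12:
        # degenerate perfect correlation: the evidence is unbounded
        bf = math.inf
    else:
        bf = bf_pearson(r, n, alternative=alternative, kappa=kappa)
    tstat = r * math.sqrt((n - 2) / max(1.0 - r * r, 1e-12))
    return TestResult(
        statistic=tstat,
        df=float(n - 2),
        p=float(res.pvalue),
        delta=r,
        bf=bf,
        bf_direction=_BF_TAG[alternative],
        evidence_label=label_evidence(bf),
    )


def correlation_matrix_with_bf(
    table: pd.DataFrame,
    value_col: str = "effect_size_pct",
    key_col: str = "grouping_feature",
    alternative: str = "greater",
) -> pd.DataFrame:
    """Pairwise correlations (r and BF) between per-subject columns.

    ``table`` is tidy (subject_id, key_col, value_col); the output is a
    long frame of all unordered pairs, mirroring a correlation table in
    which the alternative specifies a positive correlation.
    """
    wide = table.pivot(index="subject_id", columns=key_col, values=value_col)
    keys = list(wide.columns)
    rows = []
    for a, b in itertools.combinations(keys, 2):
        res = pearson_r_with_bf(wide[a], wide[b], alternative=alternative)
        rows.append(
            {
                "feature_a": a,
                "feature_b": b,
                "r": res.delta,
                "p": res.p,
                "bf": res.bf,
                "bf_direction": res.bf_direction,
                "evidence": res.evidence_label,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Repeated-measures / split-plot ANOVA
# ---------------------------------------------------------------------------


def _effect_scores(cube: np.ndarray, within_axes: Sequence[int], effect: Sequence[int]) -> np.ndarray:
    """Per-subject effect estimates for a within-effect.

    ``cube`` has shape (n_subjects, p_1, ..., p_k).  Axes in ``effect``
    are mean-centered; the remaining within axes are averaged out.  The
    result has shape (n_subjects, prod_{i in effect} p_i).
    """
    out = cube
    for ax in sorted(within_axes, reverse=True):
        if ax in effect:
            out = out - out.mean(axis=ax, keepdims=True)
        else:
            out = out.mean(axis=ax, keepdims=True)
    n = out.shape[0]
    return out.reshape(n, -1)


def _gg_hf_epsilon(scores: np.ndarray, groups: np.ndarray, d: int) -> tuple[float, float]:
    """Greenhouse-Geisser and Huynh-Feldt epsilon for one within-effect.

    ``scores`` are per-subject effect estimates (already projected onto
    the d-dimensional effect subspace, expressed in cell coordinates);
    the covariance is pooled within between-subject groups.
    """
    n, _ = scores.shape
    levels = np.unique(groups)
    pooled = np.zeros((scores.shape[1], scores.shape[1]))
    for g in levels:
        sub = scores[groups == g]
        sub = sub - sub.mean(axis=0, keepdims=True)
        pooled += sub.T @ sub
    dof = n - len(levels)
    if dof <= 0:
        return 1.0, 1.0
    pooled /= dof
    tr = np.trace(pooled)
    tr2 = np.trace(pooled @ pooled)
    if tr2 <= 0 or tr <= 0:
        return 1.0, 1.0
    gg = (tr * tr) / (d * tr2)
    gg = min(max(gg, 1.0 / d), 1.0)
    denom = d * (dof - d * gg)
    hf = (n * d * gg - 2.0) / denom if denom > 0 else 1.0
    hf = min(max(hf, gg), 1.0)
    return float(gg), float(hf)


def _bic_inclusion_bf(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    all_effects: list[tuple[str, ...]],
    target: tuple[str, ...],
) -> float:
    """BIC-approximate inclusion Bayes factor for one design effect.

    Compares two fixed-effect OLS models on the subject-by-cell means
    (subject as a blocking factor): both contain every design effect that
    does not include the target as a sub-effect, and one additionally
    contains the target.  BF ~= exp((BIC_without - BIC_with) / 2).  This
    is a rough, clearly-labeled stand-in for model-averaged inclusion
    Bayes factors, not equivalent to them.
    """
    import statsmodels.formula.api as smf

    def term(effect: tuple[str, ...]) -> str:
        return ":".join(f"C({f})" for f in effect)

    kept = [e for e in all_effects if not set(target) < set(e) and e != target]
    base = [f"C({subject})"] + [term(e) for e in kept]
    with_f = f"{dv} ~ " + " + ".join(base + [term(target)])
    without_f = f"{dv} ~ " + " + ".join(base)
    bic_with = smf.ols(with_f, data=data).fit().bic
    bic_without = smf.ols(without_f, data=data).fit().bic
    return float(np.exp((bic_without - bic_with) / 2.0))


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: Sequence[str],
    between: Optional[str] = None,
    inclusion_bf: bool = True,
) -> pd.DataFrame:
    """Balanced repeated-measures (optionally split-plot) ANOVA.

    ``data`` is tidy with one or more rows per subject x cell (replicates
    are averaged first).  Every within-subject effect is tested against
    its interaction with subjects (nested in the between group, if any);
    the between factor is tested against subjects-within-groups.  Output
    columns: effect, ss, df1, df2, F, p, p_gg, p_hf, partial_eta_sq,
    bf_inclusion_approx.

    Raises on incomplete designs, naming the first offending cell.
    """
    within = list(within)
    cell_keys = [subject, *within]
    cells = data.groupby(cell_keys + ([between] if between else []), observed=True)[
        dv
    ].mean().reset_index()

    levels = {f: sorted(cells[f].unique().tolist()) for f in within}
    subjects = sorted(cells[subject].unique().tolist())
    n_subj = len(subjects)
    shape = [n_subj] + [len(levels[f]) for f in within]

    if between is not None:
        per_subj = cells.groupby(subject, observed=True)[between].nunique()
        bad = per_subj[per_subj != 1]
        if len(bad):
            raise ValueError(
                f"subject {bad.index[0]!r} has multiple {between!r} levels"
            )
        group_of = cells.groupby(subject, observed=True)[between].first()
        groups = np.asarray([group_of[s] for s in subjects])
    else:
        groups = np.zeros(n_subj, dtype=int)
    n_g = len(np.unique(groups))

    indexed = cells.set_index(cell_keys)[dv]
    cube = np.empty(shape)
    for s_i, s in enumerate(subjects):
        for combo in itertools.product(*[levels[f] for f in within]):
            try:
                val = indexed.loc[(s, *combo)]
            except KeyError:
                raise ValueError(
                    f"missing cell: subject={s!r}, "
                    + ", ".join(f"{f}={v!r}" for f, v in zip(within, combo))
                ) from None
            idx = (s_i,) + tuple(levels[f].index(v) for f, v in zip(within, combo))
            cube[idx] = val

    within_axes = list(range(1, len(within) + 1))
    p_total = int(np.prod(shape[1:]))
    grand = cube.reshape(n_subj, -1).mean(axis=1)  # per-subject mean

    rows = []
    all_effects: list[tuple[str, ...]] = []
    for k in range(1, len(within) + 1):
        for combo in itertools.combinations(range(len(within)), k):
            all_effects.append(tuple(within[i] for i in combo))
    if between is not None:
        between_effects = [(between,)] + [(between, *e) for e in all_effects]
    else:
        between_effects = []

    # between-subjects stratum
    if between is not None:
        gmean = grand.mean()
        ss_b = p_total * sum(
            (grand[groups == g].mean() - gmean) ** 2 * (groups == g).sum()
            for g in np.unique(groups)
        )
        group_means = {g: grand[groups == g].mean() for g in np.unique(groups)}
        ss_sw = p_total * sum(
            (grand[i] - group_means[groups[i]]) ** 2 for i in range(n_subj)
        )
        df_b, df_sw = n_g - 1, n_subj - n_g
        f_b = (ss_b / df_b) / (ss_sw / df_sw)
        p_b = float(sps.f.sf(f_b, df_b, df_sw))
        rows.append(
            {
                "effect": between,
                "ss": ss_b,
                "df1": df_b,
                "df2": df_sw,
                "F": f_b,
                "p": p_b,
                "p_gg": p_b,
                "p_hf": p_b,
                "partial_eta_sq": ss_b / (ss_b + ss_sw),
            }
        )

    # within-subject strata
    for k in range(1, len(within) + 1):
        for combo in itertools.combinations(range(len(within)), k):
            effect_axes = [within_axes[i] for i in combo]
            name = tuple(within[i] for i in combo)
            d = int(np.prod([shape[ax] - 1 for ax in effect_axes]))
            m = p_total / int(np.prod([shape[ax] for ax in effect_axes]))
            scores = _effect_scores(cube, within_axes, effect_axes)

            grand_eff = scores.mean(axis=0)
            ss_e = m * n_subj * float(np.sum(grand_eff**2))
            if between is not None:
                gmeans = {
                    g: scores[groups == g].mean(axis=0) for g in np.unique(groups)
                }
                ss_eb = m * sum(
                    (groups == g).sum() * float(np.sum((gmeans[g] - grand_eff) ** 2))
                    for g in np.unique(groups)
                )
                resid = scores - np.stack([gmeans[g] for g in groups])
            else:
                ss_eb = 0.0
                resid = scores - grand_eff
            ss_err = m * float(np.sum(resid**2))
            df_err = d * (n_subj - n_g)
            gg, hf = _gg_hf_epsilon(scores, groups, d)

            def _row(eff_name, ss, df1):
                f = (ss / df1) / (ss_err / df_err)
                return {
                    "effect": eff_name,
                    "ss": ss,
                    "df1": df1,
                    "df2": df_err,
                    "F": f,
                    "p": float(sps.f.sf(f, df1, df_err)),
                    "p_gg": float(sps.f.sf(f, df1 * gg, df_err * gg)),
                    "p_hf": float(sps.f.sf(f, df1 * hf, df_err * hf)),
                    "partial_eta_sq": ss / (ss + ss_err),
                }

            rows.append(_row(" * ".join(name), ss_e, d))
            if between is not None:
                rows.append(_row(f"{between} * " + " * ".join(name), ss_eb, d * (n_g - 1)))

    out = pd.DataFrame(rows)

    if inclusion_bf:
        design_effects = all_effects + between_effects
        cols = [subject, *within] + ([between] if between else [])
        flat = cells[cols + [dv]].copy()
        name_of = {
            " * ".join(e): e for e in all_effects
        }
        name_of.update({between: (between,)} if between else {})
        name_of.update(
            {f"{between} * " + " * ".join(e): (between, *e) for e in all_effects}
            if between
            else {}
        )
        bfs = []
        for eff in out["effect"]:
            target = name_of[eff]
            try:
                bfs.append(
                    _bic_inclusion_bf(flat, dv, subject, design_effects, target)
                )
            except Exception:
                bfs.append(np.nan)
        out["bf_inclusion_approx"] = bfs
    return out


# ---------------------------------------------------------------------------
# Evidence labels and summaries
# ---------------------------------------------------------------------------

_EVIDENCE_BINS = (
    (100.0, "extreme"),
    (30.0, "very strong"),
    (10.0, "strong"),
    (3.0, "moderate"),
    (1.0, "anecdotal"),
)


def label_evidence(bf: float) -> str:
    """Conventional strength-of-evidence label for a Bayes factor.

    Bins (for the hypothesis the BF favors): anecdotal (1 < BF <= 3),
    moderate (3 < BF <= 10), strong (10 < BF <= 30), very strong
    (30 < BF <= 100), extreme (BF > 100); BF = 1 carries no evidence.
    Bayes factors below 1 are labeled by the reciprocal with an '(H0)'
    suffix.
    """
    if bf <= 0:
        raise ValueError("Bayes factors must be positive")
    if bf == 1.0:
        return "none"
    favored_h0 = bf < 1.0
    mag = 1.0 / bf if favored_h0 else bf
    for cut, lab in _EVIDENCE_BINS:
        if mag > cut:
            return f"{lab} (H0)" if favored_h0 else lab
    return "anecdotal (H0)" if favored_h0 else "anecdotal"


def summarize_experiment(
    pse: pd.DataFrame, condition_cols: Sequence[str]
) -> pd.DataFrame:
    """Subject-averaged condition means with t-based 95% CIs.

    One row per condition cell x n_test: mean PSE across subjects, the
    95% confidence half-width t_{0.975, n-1} * sd / sqrt(n), and n.
    """
    if pse["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    keys = [*condition_cols, "n_test"]
    rows = []
    for vals, sub in pse.groupby(keys, dropna=False):
        vals = vals if isinstance(vals, tuple) else (vals,)
        x = sub["pse"].to_numpy(dtype=float)
        n = len(x)
        mean = float(x.mean())
        if n > 1:
            half = float(sps.t.ppf(0.975, n - 1) * x.std(ddof=1) / math.sqrt(n))
        else:
            half = math.nan
        rows.append(
            dict(
                zip(keys, vals),
                mean_pse=mean,
                ci_low=mean - half,
                ci_high=mean + half,
                n_subjects=n,
            )
        )
    return pd.DataFrame(rows)
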