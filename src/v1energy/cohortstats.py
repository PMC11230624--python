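"""Group-level inference on per-animal endpoints in a 2x2 sex-by-diet design.

The animal is the statistically independent unit.  Endpoints (serum
leptin, AMPK phosphorylation, FRET decay half-time, median OSI, ...) are
compared with a two-factor between-subjects ANOVA whose pooled error
term feeds unadjusted Fisher-LSD pairwise contrasts (t with N - 4
residual df), complemented by JZS Bayes factors: a two-sample default
Bayes test with a Cauchy prior of scale r = 1/sqrt(2) on the
standardized effect size, with BF10 > 3 read as evidence for an effect
and BF10 < 1/3 as moderate evidence for its absence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
import statsmodels.formula.api as smf

SEXES = ("male", "female")
DIETS = ("CTR", "FR")

#: the four sex-matched / diet-matched pairwise contrasts reported for this design
DEFAULT_CONTRASTS = (
    (("male", "CTR"), ("male", "FR")),
    (("female", "CTR"), ("female", "FR")),
    (("male", "CTR"), ("female", "CTR")),
    (("male", "FR"), ("female", "FR")),
)

DEFAULT_PRIOR_SCALE = 1.0 / np.sqrt(2.0)


@dataclass
class ContrastResult:
    """One Fisher-LSD pairwise contrast from the pooled-error ANOVA."""

    label: str
    t: float
    df: int
    p: float
    mean_a: float
    mean_b: float
    mean_diff: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int


@dataclass
class BayesFactorResult:
    """JZS two-sample Bayes factor for one contrast."""

    bf10: float
    effect_size: float
    prior_scale: float
    category: str
    quadrature_error: float = 0.0


def _validate_cells(table: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    sub = table[table["endpoint"] == endpoint] if "endpoint" in table.columns else table
    if len(sub) == 0:
        raise ValueError(f"no rows for endpoint {endpoint!r}")
    for sex in SEXES:
        for diet in DIETS:
            n = ((sub["sex"] == sex) & (sub["diet"] == diet)).sum()
            if n < 2:
                raise ValueError(f"cell ({sex}, {diet}) has {n} animals; need >= 2")
    return sub


def two_way_anova_lsd(
    table: pd.DataFrame,
    endpoint: str,
    contrasts=DEFAULT_CONTRASTS,
) -> list[ContrastResult]:
    """Two-way (sex x diet) ANOVA with Fisher LSD pairwise contrasts.

    The full factorial linear model with interaction is fitted; its
    pooled residual mean square (df = N - 4) is the error term for every
    contrast: ``t = (m1 - m2) / sqrt(MSE * (1/n1 + 1/n2))`` with
    unadjusted two-sided p values (Fisher's LSD, applied after the
    omnibus test to avoid loss of power).

    ``table`` is tidy with columns ``sex`` (male/female), ``diet``
    (CTR/FR), ``endpoint``, ``value``.

    Raises
    ------
    ValueError
        On an empty cell or zero pooled variance.
    """
    sub = _validate_cells(table, endpoint)
    fit = smf.ols("value ~ C(sex) * C(diet)", data=sub).fit()
    mse = float(fit.mse_resid)
    df = int(fit.df_resid)
    scale = max(float(sub["value"].var()), 1.0)
    if not np.isfinite(mse) or mse <= scale * 1e-12:
        raise ValueError("zero pooled variance: contrasts are degenerate")

    cells = sub.groupby(["sex", "diet"])["value"]
    means, ns, sds = cells.mean(), cells.count(), cells.std(ddof=1)

    results = []
    for (sex_a, diet_a), (sex_b, diet_b) in contrasts:
        m_a, m_b = means[(sex_a, diet_a)], means[(sex_b, diet_b)]
        n_a, n_b = int(ns[(sex_a, diet_a)]), int(ns[(sex_b, diet_b)])
        se = np.sqrt(mse * (1.0 / n_a + 1.0 / n_b))
        t = float((m_a - m_b) / se)
        p = float(2.0 * stats.t.sf(abs(t), df))
        results.append(
            ContrastResult(
                label=f"{diet_a} {sex_a} vs {diet_b} {sex_b}",
                t=t, df=df, p=p,
                mean_a=float(m_a), mean_b=float(m_b), mean_diff=float(m_a - m_b),
                sem_a=float(sds[(sex_a, diet_a)] / np.sqrt(n_a)),
                sem_b=float(sds[(sex_b, diet_b)] / np.sqrt(n_b)),
                n_a=n_a, n_b=n_b,
            )
        )
    return results


def _categorize(bf10: float) -> str:
    if bf10 > 3.0:
        return "evidence for effect"
    if bf10 < 1.0 / 3.0:
        return "evidence for absence"
    return "inconclusive"


def jzs_bayes_factor(
    group_a=None,
    group_b=None,
    *,
    t: float | None = None,
    n1: int | None = None,
    n2: int | None = None,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> BayesFactorResult:
    """Two-sample JZS Bayes factor (BF10) by numerical integration.

    The alternative places a Cauchy prior of scale ``prior_scale``
    (default 1/sqrt(2)) on the standardized effect size delta; the
    marginal likelihood of the observed two-sample t statistic is

        p(t | H1) = \\int T_nu(t; delta * sqrt(Neff)) Cauchy(delta; r) d delta

    with nu = n1 + n2 - 2 and Neff = n1 n2 / (n1 + n2), and BF10 is its
    ratio to the central-t density p(t | H0).  Call either with two
    samples or with a precomputed ``t`` and group sizes.

    Raises
    ------
    ValueError
        If both groups have zero variance, groups are too small, or the
        quadrature fails to converge.
    """
    if t is None:
        a = np.asarray(group_a, dtype=float)
        b = np.asarray(group_b, dtype=float)
        n1, n2 = len(a), len(b)
        if n1 < 2 or n2 < 2:
            raise ValueError("each group needs n >= 2")
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        if sp2 <= 0:
            raise ValueError("zero variance in both groups: t undefined")
        t = float((a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
    elif n1 is None or n2 is None:
        raise ValueError("group sizes n1, n2 are required with a precomputed t")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")

    nu = n1 + n2 - 2
    neff = n1 * n2 / (n1 + n2)
    sqrt_neff = np.sqrt(neff)
    r = prior_scale

    def integrand(delta):
        return stats.nct.pdf(t, nu, delta * sqrt_neff) * stats.cauchy.pdf(delta, 0.0, r)

    # piecewise quadrature split at the prior mode and the likelihood peak
    breaks = sorted({0.0, t / sqrt_neff})
    limits = [-np.inf, *breaks, np.inf]
    marg1, err = 0.0, 0.0
    for a_lim, b_lim in zip(limits[:-1], limits[1:]):
        if a_lim == b_lim:
            continue
        part, part_err = integrate.quad(integrand, a_lim, b_lim, limit=200)
        marg1 += part
        err += part_err
    if marg1 <= 0 or not np.isfinite(marg1):
        raise ValueError("quadrature failed for the marginal likelihood")
    if err / marg1 > 1e-6:
        raise ValueError(f"quadrature did not converge (relative error {err / marg1:.2e})")
    marg0 = stats.t.pdf(t, nu)
    bf10 = float(marg1 / marg0)
    effect = float(t * np.sqrt(1.0 / n1 + 1.0 / n2))  # sample Cohen's d from t
    return BayesFactorResult(
        bf10=bf10, effect_size=effect, prior_scale=r,
        category=_categorize(bf10), quadrature_error=float(err / marg1),
    )


def percent_change(ctr_mean: float, fr_mean: float, rounded: bool = False) -> float:
    """Signed percent change of the food-restricted vs control mean.

    ``(fr - ctr) / ctr * 100``; with ``rounded`` the nearest integer is
    returned, the convention used for reporting.

    Raises
    ------
    ValueError
        If the control mean is zero.
    """
    if ctr_mean == 0:
        raise ValueError("control mean is zero: percent change undefined")
    pct = (fr_mean - ctr_mean) / ctr_mean * 100.0
    return float(np.rint(pct)) if rounded else float(pct)


def fold_change(ctr_mean: float, fr_mean: float, rounded: bool = False) -> float:
    """Fold change FR / CTR; with ``rounded`` reported to one decimal.

    Raises
    ------
    ValueError
        If the control mean is not strictly positive.
    """
    if ctr_mean <= 0:
        raise ValueError("control mean must be > 0 for a fold change")
    fold = fr_mean / ctr_mean
    return float(np.round(fold, 1)) if rounded else float(fold)


@dataclass
class CohortReport:
    """Per-endpoint cohort summary: cells, contrasts, Bayes factors, changes."""

    cells: pd.DataFrame
    contrasts: pd.DataFrame
    changes: pd.DataFrame
    text: str


def cohort_report(
    table: pd.DataFrame,
    endpoints=None,
    contrasts=DEFAULT_CONTRASTS,
    bayes: bool = True,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> CohortReport:
    """Figure-legend-style report for every endpoint of a cohort table.

    Per endpoint: cell means +/- SEM and n, all configured Fisher LSD
    contrasts (t, df, p, optional BF10 with its evidence category), and
    the within-sex percent and fold changes of FR vs CTR.
    """
    if endpoints is None:
        endpoints = list(pd.unique(table["endpoint"]))
    cell_rows, contrast_rows, change_rows, lines = [], [], [], []
    for endpoint in endpoints:
        sub = _validate_cells(table, endpoint)
        lines.append(f"Endpoint: {endpoint}")
        g = sub.groupby(["sex", "diet"])["value"]
        for (sex, diet), vals in g:
            sem = vals.std(ddof=1) / np.sqrt(len(vals))
            cell_rows.append(
                dict(endpoint=endpoint, sex=sex, diet=diet, n=len(vals),
                     mean=vals.mean(), sem=sem)
            )
            lines.append(
                f"  {diet} {sex}: {vals.mean():.3g} +/- {sem:.3g} (n = {len(vals)})"
            )
        try:
            lsd = two_way_anova_lsd(sub, endpoint, contrasts=contrasts)
        except ValueError as exc:
            lines.append(f"  contrasts degenerate: {exc}")
            contrast_rows.append(
                dict(endpoint=endpoint, contrast="(degenerate)", t=np.nan,
                     df=len(sub) - 4, p=np.nan, mean_diff=np.nan)
            )
            lsd = []
        for res in lsd:
            row = dict(
                endpoint=endpoint, contrast=res.label, t=res.t, df=res.df, p=res.p,
                mean_diff=res.mean_diff,
            )
            line = f"  {res.label}: t = {res.t:.2f}; df = {res.df}; p = {res.p:.3g}"
            if bayes:
                bf = jzs_bayes_factor(t=res.t, n1=res.n_a, n2=res.n_b,
                                      prior_scale=prior_scale)
                row.update(bf10=bf.bf10, bf_category=bf.category)
                line += f"; BF10 = {bf.bf10:.3g} ({bf.category})"
            contrast_rows.append(row)
            lines.append(line)
        means = g.mean()
        for sex in SEXES:
            ctr, fr = means[(sex, "CTR")], means[(sex, "FR")]
            pct = percent_change(ctr, fr, rounded=True)
            row = dict(endpoint=endpoint, sex=sex, percent_change=pct)
            line = f"  {sex} FR vs CTR: {pct:+.0f}%"
            if ctr > 0:
                fold = fold_change(ctr, fr, rounded=True)
                row["fold_change"] = fold
                line += f" ({fold:.1f}-fold)"
            change_rows.append(row)
            lines.append(line)
    return CohortReport(
        cells=pd.DataFrame(cell_rows),
        contrasts=pd.DataFrame(contrast_rows),
        changes=pd.DataFrame(change_rows),
        text="\n".join(lines),
    )
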