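"""Quartile-based association models: prevalence ratios of CMR by exposure.

Each exposure is cut at its sample 25/50/75 percentiles into quartiles
(ties at a boundary fall to the lower quartile, so quartile sizes can be
unequal in the presence of heavy ties).  Covariate-adjusted logistic
regressions with quartile indicators (first quartile as reference) give
odds ratios with Wald 95% confidence intervals; because the outcome is
common, odds ratios and both CI bounds are converted to prevalence ratios
with

    PR = OR / (1 - P0 + P0 * OR)

where P0 is the observed outcome proportion in the reference quartile.
Linear trend is tested by replacing the quartile indicators with a single
continuous covariate carrying each participant's quartile median.
Stratified fits with a likelihood-ratio interaction test and the two
sensitivity analyses (BMI >= 25 subset with BMI adjustment; glucose-only
outcome) complete the suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DegenerateExposureError, FitError, InputError

Z95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# quartiles
# ---------------------------------------------------------------------------

@dataclass
class QuartileExposure:
    """An exposure cut into sample quartiles with per-quartile summaries."""

    name: str
    cut_points: tuple[float, float, float]
    labels: pd.Series  # participant -> 1..4
    summary: pd.DataFrame  # index 1..4: n, mean, sd, range_low, range_high, median

    @property
    def medians(self) -> pd.Series:
        """Raw-scale median per quartile (the trend-test covariate values)."""
        return self.summary["median"]


def assign_quartiles(values: pd.Series, name: str | None = None) -> QuartileExposure:
    """Cut an exposure at its 25/50/75 sample percentiles.

    Percentiles use linear interpolation; values equal to a cut point go to
    the lower quartile.  Raises for exposures with fewer than 4 distinct
    values.
    """
    v = values.dropna()
    if len(v) < len(values):
        raise InputError(f"exposure {name or values.name!r} has missing values")
    if v.nunique() < 4:
        raise DegenerateExposureError(
            f"exposure {name or values.name!r} has fewer than 4 distinct values"
        )
    cuts = np.percentile(v.to_numpy(), [25, 50, 75], method="linear")
    labels = pd.Series(1, index=v.index, dtype=int)
    for c in cuts:
        labels += (v > c).astype(int)
    rows = []
    for q in (1, 2, 3, 4):
        vq = v[labels == q]
        rows.append(
            {
                "n": int(len(vq)),
                "mean": float(vq.mean()),
                "sd": float(vq.std(ddof=1)) if len(vq) > 1 else 0.0,
                "range_low": float(vq.min()),
                "range_high": float(vq.max()),
                "median": float(vq.median()),
            }
        )
    summary = pd.DataFrame(rows, index=pd.Index([1, 2, 3, 4], name="quartile"))
    return QuartileExposure(
        name=name or str(values.name),
        cut_points=tuple(float(c) for c in cuts),
        labels=labels,
        summary=summary,
    )


# ---------------------------------------------------------------------------
# design matrices and logistic fits
# ---------------------------------------------------------------------------

def _design_matrix(covariates: pd.DataFrame | None, index: pd.Index) -> pd.DataFrame:
    """Numeric covariates pass through; categoricals become drop-first dummies."""
    if covariates is None or covariates.shape[1] == 0:
        return pd.DataFrame(index=index)
    cov = covariates.loc[index]
    if cov.isna().any().any():
        bad = list(cov.columns[cov.isna().any()])
        raise InputError(f"missing covariate values in {bad}")
    parts = []
    for col in cov.columns:
        s = cov[col]
        if s.dtype == bool:
            parts.append(s.astype(float).rename(col))
        elif s.dtype.kind in "ifu":
            parts.append(s.astype(float))
        else:
            d = pd.get_dummies(s.astype(str), prefix=col, drop_first=True, dtype=float)
            parts.append(d)
    return pd.concat(parts, axis=1)


def _logit(y: pd.Series, X: pd.DataFrame):
    yv = pd.Series(y).astype(float)
    if yv.isna().any():
        raise InputError("outcome contains missing values")
    X = X.astype(float)
    # constant columns (e.g. empty dummy levels in small samples) carry no
    # information and make the Hessian singular; drop them
    keep = X.std(axis=0) > 0
    X = X.loc[:, keep]
    Xc = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(yv, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation, singular matrix, ...
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge")
    return res


@dataclass
class QuartileModelFit:
    """Per-quartile odds ratios with Wald CIs from a logistic model."""

    exposure: str
    odds_ratios: pd.DataFrame  # index 2..4: or, ci_low, ci_high, p
    p0: float  # outcome proportion in the reference quartile
    n: int
    n_cases: int
    loglike: float
    result: object = field(repr=False, default=None)


def fit_quartile_model(
    outcome: pd.Series,
    quartiles: QuartileExposure,
    covariates: pd.DataFrame | None = None,
) -> QuartileModelFit:
    """Maximum-likelihood logistic fit of outcome on quartile indicators."""
    idx = quartiles.labels.index
    y = pd.Series(outcome).reindex(idx)
    X = pd.DataFrame(index=idx)
    for q in (2, 3, 4):
        X[f"{quartiles.name}_Q{q}"] = (quartiles.labels == q).astype(float)
    X = pd.concat([X, _design_matrix(covariates, idx)], axis=1)
    res = _logit(y, X)
    ci = res.conf_int()
    rows = {}
    for q in (2, 3, 4):
        term = f"{quartiles.name}_Q{q}"
        rows[q] = {
            "or": float(np.exp(res.params[term])),
            "ci_low": float(np.exp(ci.loc[term, 0])),
            "ci_high": float(np.exp(ci.loc[term, 1])),
            "p": float(res.pvalues[term]),
        }
    y = y.astype(float)
    p0 = float(y[quartiles.labels == 1].mean())
    return QuartileModelFit(
        exposure=quartiles.name,
        odds_ratios=pd.DataFrame(rows).T,
        p0=p0,
        n=int(len(y)),
        n_cases=int(y.sum()),
        loglike=float(res.llf),
        result=res,
    )


def or_to_pr(
    or_value: float, ci_low: float, ci_high: float, p0: float
) -> tuple[float, float, float]:
    """Convert an odds ratio and its CI bounds to prevalence ratios.

    ``PR = OR / (1 - P0 + P0 * OR)``; P0 is the reference-group outcome
    proportion.  The same P0 is applied to the point estimate and both CI
    bounds, so PR CIs are approximate.
    """
    if not 0 <= p0 <= 1:
        raise InputError(f"p0 must lie in [0, 1], got {p0}")
    if or_value <= 0:
        raise InputError(f"odds ratio must be positive, got {or_value}")

    def conv(o: float) -> float:
        return o / (1 - p0 + p0 * o)

    return conv(or_value), conv(ci_low), conv(ci_high)


def trend_test(
    outcome: pd.Series,
    quartiles: QuartileExposure,
    covariates: pd.DataFrame | None = None,
) -> float:
    """Wald p-value for linear trend across quartiles.

    The model carries one continuous covariate equal to each participant's
    quartile median (raw scale) in place of the quartile indicators.
    """
    idx = quartiles.labels.index
    med = quartiles.medians
    X = pd.DataFrame(
        {"trend": quartiles.labels.map(med).astype(float)}, index=idx
    )
    X = pd.concat([X, _design_matrix(covariates, idx)], axis=1)
    res = _logit(pd.Series(outcome).reindex(idx), X)
    return float(res.pvalues["trend"])


# ---------------------------------------------------------------------------
# result rows and tables
# ---------------------------------------------------------------------------

def association_row(
    exposure_name: str,
    model_id: int | str,
    outcome: pd.Series,
    quartiles: QuartileExposure,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """One results-table block: per-quartile cases/N, PRs with CIs, p_trend."""
    fit = fit_quartile_model(outcome, quartiles, covariates)
    y = pd.Series(outcome).reindex(quartiles.labels.index).astype(float)
    row: dict = {"exposure": exposure_name, "model": model_id, "p0": fit.p0}
    for q in (1, 2, 3, 4):
        sel = quartiles.labels == q
        row[f"q{q}_cases"] = int(y[sel].sum())
        row[f"q{q}_n"] = int(sel.sum())
    row["q1_pr"], row["q1_ci_low"], row["q1_ci_high"] = 1.0, 1.0, 1.0
    for q in (2, 3, 4):
        o = fit.odds_ratios.loc[q]
        pr, lo, hi = or_to_pr(o["or"], o["ci_low"], o["ci_high"], fit.p0)
        row[f"q{q}_pr"], row[f"q{q}_ci_low"], row[f"q{q}_ci_high"] = pr, lo, hi
    row["p_trend"] = trend_test(outcome, quartiles, covariates)
    return row


def coadjustment_quartiles(
    raw_exposures: pd.DataFrame,
    representatives: dict[int, str],
    target: str,
) -> pd.DataFrame:
    """Categorical quartile labels of the *other* clusters' representatives.

    The adjustment enters the models as quartile categories, not as
    continuous values.  The target's own cluster is left out.
    """
    cols = {}
    for c, rep in sorted(representatives.items()):
        if rep == target:
            continue
        q = assign_quartiles(raw_exposures[rep], name=rep)
        cols[f"{rep}_q"] = q.labels.astype(str)
    return pd.DataFrame(cols, index=raw_exposures.index)


def stratified_and_interaction(
    outcome: pd.Series,
    quartiles: QuartileExposure,
    covariates: pd.DataFrame | None,
    stratum: pd.Series,
) -> dict:
    """Per-stratum association rows plus a likelihood-ratio interaction p.

    ``stratum`` must be binary (binarize continuous variables by median
    split first).  The interaction test compares the pooled model with and
    without exposure-quartile x stratum product terms (3 df).
    """
    idx = quartiles.labels.index
    strat = pd.Series(stratum).reindex(idx)
    levels = sorted(strat.dropna().unique())
    if len(levels) != 2:
        raise InputError(f"stratum must be binary, found levels {levels}")
    y = pd.Series(outcome).reindex(idx)

    rows = {}
    for lev in levels:
        sel = strat == lev
        if sel.sum() == 0:
            raise FitError(f"stratum {lev!r} is empty")
        if y[sel].astype(float).sum() == 0:
            raise FitError(f"stratum {lev!r} has zero cases")
        sub_q = QuartileExposure(
            name=quartiles.name,
            cut_points=quartiles.cut_points,
            labels=quartiles.labels[sel],
            summary=quartiles.summary,
        )
        sub_cov = None if covariates is None else covariates.loc[sel[sel].index]
        rows[lev] = association_row(quartiles.name, "stratified", y[sel], sub_q, sub_cov)

    # pooled LRT for heterogeneity
    X = pd.DataFrame(index=idx)
    for q in (2, 3, 4):
        X[f"Q{q}"] = (quartiles.labels == q).astype(float)
    X["stratum"] = (strat == levels[1]).astype(float)
    X = pd.concat([X, _design_matrix(covariates, idx)], axis=1)
    res0 = _logit(y, X)
    Xi = X.copy()
    for q in (2, 3, 4):
        Xi[f"Q{q}_x_stratum"] = Xi[f"Q{q}"] * Xi["stratum"]
    res1 = _logit(y, Xi)
    lr = 2.0 * (res1.llf - res0.llf)
    p_int = float(stats.chi2.sf(max(lr, 0.0), df=3))
    return {"strata": rows, "p_interaction": p_int, "levels": levels}


def sensitivity_suite(
    raw_exposures: pd.DataFrame,
    selected: list[str],
    outcome: pd.Series,
    glucose_outcome: pd.Series,
    covariates_builder,
    bmi: pd.Series,
) -> dict[str, pd.DataFrame]:
    """Run the two sensitivity analyses over the selected exposures.

    (a) restrict to BMI >= 25 and add continuous BMI to the covariates;
    (b) refit the main models with the glucose-only outcome.
    ``covariates_builder(target, index)`` returns each model's covariate
    frame for the given target exposure, restricted to ``index``.
    """
    out: dict[str, pd.DataFrame] = {}

    heavy = bmi.index[bmi >= 25]
    if len(heavy) == 0:
        raise InputError("BMI >= 25 subset is empty")
    rows_a, rows_b = [], []
    for name in selected:
        # (a) BMI-restricted, BMI-adjusted
        q_sub = assign_quartiles(raw_exposures.loc[heavy, name], name=name)
        cov = covariates_builder(name, heavy)
        cov = pd.concat([cov, bmi.loc[heavy].rename("bmi").to_frame()], axis=1)
        rows_a.append(association_row(name, "bmi>=25", outcome.loc[heavy], q_sub, cov))
        # (b) glucose-only outcome on the full sample
        q = assign_quartiles(raw_exposures[name], name=name)
        cov_full = covariates_builder(name, raw_exposures.index)
        rows_b.append(
            association_row(name, "glucose_only", glucose_outcome, q, cov_full)
        )
    out["bmi_restricted"] = build_results_table(rows_a)
    out["glucose_only"] = build_results_table(rows_b)
    return out


def build_results_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble association rows into a tidy results table."""
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(rows)


def results_markdown(table: pd.DataFrame, quartile_summaries: dict[str, QuartileExposure] | None = None) -> str:
    """Render a results table as markdown, one block per exposure/model."""
    if table.empty:
        return "(no results)\n"
    lines = []
    for _, row in table.iterrows():
        lines.append(f"### {row['exposure']} (model {row['model']})")
        lines.append("")
        lines.append("| | Q1 | Q2 | Q3 | Q4 |")
        lines.append("|---|---|---|---|---|")
        if quartile_summaries and row["exposure"] in quartile_summaries:
            s = quartile_summaries[row["exposure"]].summary
            lines.append(
                "| Mean (SD) | "
                + " | ".join(
                    f"{s.loc[q, 'mean']:.2f} ({s.loc[q, 'sd']:.2f})" for q in (1, 2, 3, 4)
                )
                + " |"
            )
            lines.append(
                "| Range | "
                + " | ".join(
                    f"{s.loc[q, 'range_low']:.2f}-{s.loc[q, 'range_high']:.2f}"
                    for q in (1, 2, 3, 4)
                )
                + " |"
            )
        lines.append(
            "| Cases/N | "
            + " | ".join(f"{row[f'q{q}_cases']}/{row[f'q{q}_n']}" for q in (1, 2, 3, 4))
            + " |"
        )
        prs = ["1.00 (ref)"] + [
            f"{row[f'q{q}_pr']:.2f} ({row[f'q{q}_ci_low']:.2f}; {row[f'q{q}_ci_high']:.2f})"
            for q in (2, 3, 4)
        ]
        lines.append("| PR (95% CI) | " + " | ".join(prs) + " |")
        lines.append("")
        lines.append(f"p_trend = {row['p_trend']:.3g}")
        lines.append("")
    return "\n".join(lines)
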