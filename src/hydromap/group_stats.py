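"""Group-level statistics: rank tests, mixed models, correlations,
effect sizes, multiplicity correction and summary-statistics tests.

Mirrors the statistical layer of a two-group (patients vs controls),
two-timepoint ROI study: Wilcoxon rank-sum for global group differences,
linear mixed models (group, time, group x time, covariates; subject random
intercept, REML) for regional outcomes, Pearson/Spearman correlations with
clinical covariates, Cohen's d with small/medium/large bands, Bonferroni
correction, and t / Fisher-exact tests recomputable from published summary
tables (means, SDs, proportions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

#: Cohen's d magnitude bands; boundaries are inclusive upward
#: (|d| = 0.5 is "medium", |d| = 0.9 is "large").
D_BANDS = ((0.9, "large"), (0.5, "medium"), (0.3, "small"))

EXACT_WILCOXON_MAX_N = 12


def wilcoxon_ranksum(x, y):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration when n_x + n_y <= 12 with no ties, otherwise the
    tie-corrected normal approximation with continuity correction.
    Returns (U statistic of x, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= EXACT_WILCOXON_MAX_N
                         and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cohens_d(x, y):
    """Pooled-SD standardized mean difference and its magnitude band."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    pooled = np.sqrt(((x.size - 1) * vx + (y.size - 1) * vy)
                     / (x.size + y.size - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    d = (x.mean() - y.mean()) / pooled
    return float(d), d_band(d)


def d_band(d: float) -> str:
    mag = abs(d)
    for cut, name in D_BANDS:
        if mag >= cut:
            return name
    return "negligible"


def correlate(x, y, method: str = "pearson"):
    """Two-sided correlation test; ``method`` is "pearson" or "spearman"."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment: min(1, p * m)."""
    p = np.asarray(p_values, float)
    m = p.size if m is None else int(m)
    if m < p.size:
        raise ValueError("m must be >= the number of p-values")
    return np.minimum(1.0, p * m)


def summary_ttest(mean1, sd1, n1, mean2, sd2, n2):
    """Pooled-variance two-sample t-test from summary statistics.

    Returns (t, df, two-sided p); usable directly on published
    mean (SD) table rows."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both SDs zero: t undefined")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=True)
    return float(res.statistic), float(n1 + n2 - 2), float(res.pvalue)


def fisher_exact(a: int, b: int, c: int, d: int):
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]]
    (exact hypergeometric enumeration, summing tables with probability
    <= the observed one)."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


@dataclass
class MixedModelResult:
    """Fixed-effect rows plus diagnostics for one outcome."""

    effects: pd.DataFrame          # effect, estimate, se, p
    converged: bool
    singular: bool
    resid_shapiro_p: float

    def p_of(self, effect: str) -> float:
        row = self.effects[self.effects["effect"] == effect]
        if row.empty:
            raise KeyError(f"no effect {effect!r} in model")
        return float(row["p"].iloc[0])


def mixed_model(data: pd.DataFrame, outcome: str = "value",
                covariates=(), reml: bool = True) -> MixedModelResult:
    """Linear mixed model: outcome ~ group + time + group:time + covariates,
    with a subject random intercept (REML).

    ``data`` is long format with columns subject, group, time, the outcome,
    and any covariates; missing outcome rows are dropped (unbalanced
    repeated measures are handled by the likelihood).  A residual-normality
    diagnostic (Shapiro-Wilk p) is reported alongside the fit.
    """
    df = data.dropna(subset=[outcome]).copy()
    if df["subject"].nunique() < 3:
        raise ValueError("need at least 3 subjects")
    terms = ["group", "time", "group:time", *covariates]
    formula = f"{outcome} ~ " + " + ".join(terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, df, groups=df["subject"])
        fit = model.fit(reml=reml)
    singular = bool(np.any(np.asarray(fit.cov_re) < 1e-10))
    rows = []
    for name in fit.fe_params.index:
        if name == "Intercept":
            continue
        rows.append({"effect": _simplify_term(name),
                     "estimate": float(fit.fe_params[name]),
                     "se": float(fit.bse_fe[name]),
                     "p": float(fit.pvalues[name])})
    resid = np.asarray(fit.resid)
    sh_p = float(stats.shapiro(resid).pvalue) if 3 <= resid.size <= 5000 \
        else float("nan")
    return MixedModelResult(effects=pd.DataFrame(rows),
                            converged=bool(fit.converged),
                            singular=singular, resid_shapiro_p=sh_p)


def _simplify_term(name: str) -> str:
    """'group[T.hd]:time[T.2]' -> 'group:time', 'group[T.hd]' -> 'group'."""
    parts = [p.split("[")[0] for p in name.split(":")]
    return ":".join(parts)


def effects_table(roi_table: pd.DataFrame, covariates=(), m_comparisons=None,
                  outcome_col: str = "mean_water") -> pd.DataFrame:
    """Mixed-model group/time/interaction tests per (roi, tissue) outcome,
    with Cohen's d at the first timepoint and Bonferroni-adjusted p.

    Input is an ROI statistics table (columns subject, group, timepoint, roi,
    tissue, mean_water, ...) merged with any subject covariates.  Output has
    one row per outcome x effect with estimate, se, p, p_adjusted, d, band,
    and a ``flagged`` column marking singular or non-converged fits.
    """
    rows = []
    outcomes = roi_table[["roi", "tissue"]].drop_duplicates().itertuples(index=False)
    for roi, tissue in outcomes:
        sub = roi_table[(roi_table["roi"] == roi)
                        & (roi_table["tissue"] == tissue)]
        long = sub.rename(columns={outcome_col: "value",
                                   "timepoint": "time"}).copy()
        long["time"] = long["time"].astype(str)
        try:
            res = mixed_model(long, "value", covariates)
        except (ValueError, np.linalg.LinAlgError) as err:
            rows.append({"roi": roi, "tissue": tissue, "effect": "group",
                         "estimate": np.nan, "se": np.nan, "p": np.nan,
                         "d": np.nan, "band": "", "flagged": True,
                         "note": str(err)})
            continue
        t1 = sub[sub["timepoint"] == 1]
        x = t1.loc[t1["group"] == "hd", outcome_col].to_numpy()
        y = t1.loc[t1["group"] == "control", outcome_col].to_numpy()
        try:
            d, band = cohens_d(x, y)
        except ValueError:
            d, band = np.nan, ""
        for _, er in res.effects.iterrows():
            rows.append({"roi": roi, "tissue": tissue, "effect": er["effect"],
                         "estimate": er["estimate"], "se": er["se"],
                         "p": er["p"],
                         "d": d if er["effect"] == "group" else np.nan,
                         "band": band if er["effect"] == "group" else "",
                         "flagged": res.singular or not res.converged,
                         "note": ""})
    out = pd.DataFrame(rows)
    if not out.empty:
        for eff in out["effect"].unique():
            sel = out["effect"] == eff
            ps = out.loc[sel, "p"].to_numpy()
            valid = ~np.isnan(ps)
            m = m_comparisons if m_comparisons is not None else int(valid.sum())
            adj = np.full(ps.shape, np.nan)
            if valid.any():
                adj[valid] = bonferroni(ps[valid], max(m, int(valid.sum())))
            out.loc[sel, "p_adjusted"] = adj
    return out


def correlation_table(subject_table: pd.DataFrame, value_cols, covariate_cols,
                      methods=("pearson", "spearman")) -> pd.DataFrame:
    """All covariate-outcome correlations over subjects (both methods)."""
    rows = []
    for v in value_cols:
        for c in covariate_cols:
            sub = subject_table[[v, c]].dropna()
            for method in methods:
                try:
                    r, p = correlate(sub[v], sub[c], method)
                except ValueError as err:
                    r, p = np.nan, np.nan
                    note = str(err)
                else:
                    note = ""
                rows.append({"outcome": v, "covariate": c, "method": method,
                             "r": r, "p": p, "n": len(sub), "note": note})
    return pd.DataFrame(rows)
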