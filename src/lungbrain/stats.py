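"""Crossover-design statistics on the per-period study table.

The study table has one row per animal x position block x PEEP period with
period means of every trend, index and mechanics variable and
change-from-baseline columns (``d_icp``, ``d_prx_z``, ...).

Implemented strategy:

* crossover assumption tests — linear mixed model of the change-from-baseline
  outcome on PEEP level, sequence (which posture came first) and period of
  intervention (first/second block), with the PEEP x sequence interaction as
  the carry-over term; random intercepts for animal and for position within
  animal.  A paired two-tailed t-test compares the two blocks' baselines.
* baseline comparisons between postures — Shapiro-Wilk decides t-test vs
  Mann-Whitney per variable.
* two-way ANOVA of the change in the outcome across PEEP x position.
* repeated-measures one-way ANOVA of the pooled (position-averaged) change
  across PEEP levels, animal as the repeated factor.
* exploratory screen — for each baseline covariate, a mixed model of the ICP
  change with animal random intercept (slope + Wald p) plus the marginal
  Pearson r on pooled rows; no multiple-comparison correction.

Significance level alpha = 0.05 throughout unless overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.formula.api as smf
from statsmodels.stats.anova import AnovaRM, anova_lm

ALPHA = 0.05

#: Baseline covariates screened against the ICP change, in study-table naming.
DEFAULT_COVARIATES = ("icp", "rap", "pao2", "paco2", "vt_ml", "rr", "paw_ei",
                      "tpp_ei", "tpp_ee", "e_rs", "e_l", "mp_rs", "cvp",
                      "pap", "co")


@dataclass
class StatReport:
    """A named test result: per-term estimates/statistics plus diagnostics."""

    name: str
    model: str
    terms: pd.DataFrame     # columns: term, estimate, stat, df, p
    diagnostics: dict[str, Any] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def p(self, term: str) -> float:
        row = self.terms.loc[self.terms["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r} in report {self.name!r}")
        return float(row["p"].iloc[0])

    def to_dict(self) -> dict[str, Any]:
        return dict(name=self.name, model=self.model,
                    terms=self.terms.to_dict(orient="records"),
                    diagnostics=self.diagnostics, flags=self.flags)


def _terms_frame(rows: list[tuple]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["term", "estimate", "stat", "df", "p"])


def _intervention_rows(tbl: pd.DataFrame, outcome: str) -> pd.DataFrame:
    d = tbl[(tbl["label"] == "intervention") & tbl[outcome].notna()].copy()
    if d.empty:
        raise ValueError("no intervention rows with a finite outcome")
    return d


def _fit_mixed_cascade(formula: str, d: pd.DataFrame):
    """Fit a mixed model, degrading gracefully when variance components hit
    the boundary: animal intercept + position-within-animal component, then
    animal intercept only, then plain OLS."""
    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.mixedlm(formula, data=d, groups=d["animal"],
                              vc_formula={"position": "0 + C(position)"}
                              ).fit(reml=True)
            return fit, formula + " + (1|animal) + (1|animal:position)", flags
        except Exception:
            flags.append("position variance component dropped (singular fit)")
        try:
            fit = smf.mixedlm(formula, data=d, groups=d["animal"]
                              ).fit(reml=True)
            return fit, formula + " + (1|animal)", flags
        except Exception:
            flags.append("random intercept dropped (zero-variance fit); OLS used")
        return smf.ols(formula, data=d).fit(), formula, flags


def _coef_view(fit):
    """Uniform (params, cov, pvalues, tvalues, df_resid) over MixedLM/OLS
    results, restricted to fixed effects."""
    if hasattr(fit, "fe_params"):
        names = list(fit.fe_params.index)
        params = fit.fe_params
        cov = fit.cov_params().loc[names, names]
        # residual df: observations minus fixed effects minus groups
        df_resid = max(float(fit.nobs - len(names) - fit.model.n_groups), 1.0)
    else:
        params = fit.params
        names = list(params.index)
        cov = fit.cov_params()
        df_resid = float(fit.df_resid)
    return params, cov, fit.pvalues[names], fit.tvalues[names], df_resid


# ---------------------------------------------------------------------------
# crossover assumptions


def crossover_assumption_tests(tbl: pd.DataFrame,
                               outcome: str = "d_icp") -> StatReport:
    """Carry-over / sequence / period tests for the crossover design.

    Mixed model: ``outcome ~ C(peep) + sequence + period + C(peep):sequence``
    with a random intercept per animal and a position-within-animal variance
    component.  Carry-over is the joint Wald test of the interaction terms.
    Also runs the paired two-tailed t-test between the two position blocks'
    baseline values of the underlying variable.
    """
    d = _intervention_rows(tbl, outcome)
    flags = []
    sequences = d["sequence"].dropna().unique()
    if len(sequences) < 2:
        flags.append("single sequence: sequence effect not estimable")

    rows = []
    if len(sequences) >= 2:
        d = d.assign(
            peep_f=d["peep"].astype("category"),
            seq=(d["sequence"] == d["sequence"].unique()[0]).astype(int),
            period2=(d["period_order"] == 2).astype(int),
        )
        formula = f"{outcome} ~ C(peep_f) + seq + period2 + C(peep_f):seq"
        fit, model_desc, fit_flags = _fit_mixed_cascade(formula, d)
        flags.extend(fit_flags)
        params, cov, pvalues, tvalues, df_resid = _coef_view(fit)
        rows.append(("sequence", float(params["seq"]),
                     float(tvalues["seq"]), df_resid, float(pvalues["seq"])))
        rows.append(("period", float(params["period2"]),
                     float(tvalues["period2"]), df_resid,
                     float(pvalues["period2"])))
        inter = [name for name in params.index if ":seq" in name]
        if inter:
            # Joint Wald F on the PEEP x sequence interaction block.  The
            # carry-over contrast compares response profiles between the two
            # sequence groups, so the animal is the experimental unit: the
            # denominator df follows the between-within rule (animals minus
            # sequence groups), which keeps the test calibrated at this size.
            beta = params[inter].to_numpy()
            v = cov.loc[inter, inter].to_numpy()
            df_num = len(inter)
            df_den = max(d["animal"].nunique() - len(sequences), 1)
            try:
                stat = float(beta @ np.linalg.solve(v, beta)) / df_num
                p = float(sps.f.sf(stat, df_num, df_den))
            except np.linalg.LinAlgError:
                stat, p = np.nan, np.nan
                flags.append("carryover test degenerate (singular covariance)")
            rows.append(("carryover", np.nan, stat, float(df_num), p))
    else:
        model_desc = "not fitted (single sequence)"

    # paired t-test on the two blocks' baselines of the underlying variable
    base_var = outcome[2:] if outcome.startswith("d_") else outcome
    base = tbl[tbl["label"] == "baseline"].pivot_table(
        index="animal", columns="period_order", values=base_var)
    diag: dict[str, Any] = {}
    if base.shape[1] == 2 and base.dropna().shape[0] >= 2:
        paired = base.dropna()
        diff = paired[1] - paired[2] if 1 in paired.columns else None
        if diff is not None and np.allclose(diff.std(ddof=1), 0.0):
            flags.append("degenerate paired baseline test (zero variance)")
            rows.append(("baseline_paired_t", float(diff.mean()), np.nan,
                         float(len(diff) - 1), np.nan))
        else:
            t, p = sps.ttest_rel(paired.iloc[:, 0], paired.iloc[:, 1])
            rows.append(("baseline_paired_t",
                         float((paired.iloc[:, 0] - paired.iloc[:, 1]).mean()),
                         float(t), float(len(paired) - 1), float(p)))
        diag["n_paired"] = int(base.dropna().shape[0])
    else:
        flags.append("paired baseline test not possible")

    return StatReport(name=f"crossover_assumptions[{outcome}]",
                      model=model_desc, terms=_terms_frame(rows),
                      diagnostics=diag, flags=flags)


# ---------------------------------------------------------------------------
# baseline comparisons


def _describe(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{np.mean(x):.3g} ± {np.std(x, ddof=1):.3g}"
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return f"{q2:.3g} ({q1:.3g}–{q3:.3g})"


def compare_baselines(tbl: pd.DataFrame,
                      variables: tuple[str, ...] | None = None,
                      alpha: float = ALPHA) -> pd.DataFrame:
    """Prone vs supine comparison of first-block baseline values.

    Shapiro-Wilk (per group, needs n >= 3) selects a two-tailed t-test when
    both groups look normal, otherwise Mann-Whitney.  Groups are summarized as
    mean ± SD or median (IQR) accordingly.
    """
    base = tbl[(tbl["label"] == "baseline") & (tbl["period_order"] == 1)]
    if base["position"].nunique() < 2:
        raise ValueError("baseline rows needed for both positions")
    if variables is None:
        skip = {"peep", "start_s", "end_s", "block", "period_order", "n_valid_blocks"}
        variables = tuple(c for c in base.columns
                          if base[c].dtype.kind in "fi" and c not in skip)
    out = []
    for var in variables:
        if var not in base.columns:
            continue
        g1 = base.loc[base["position"] == "prone", var].dropna().to_numpy()
        g2 = base.loc[base["position"] == "supine", var].dropna().to_numpy()
        if len(g1) < 2 or len(g2) < 2:
            continue
        if len(g1) >= 3 and len(g2) >= 3:
            normal = (sps.shapiro(g1).pvalue > alpha
                      and sps.shapiro(g2).pvalue > alpha)
        else:
            normal = False  # too few for a normality test: rank-based branch
        if np.std(g1) == 0 and np.std(g2) == 0 and np.mean(g1) == np.mean(g2):
            test, stat, p = "degenerate", np.nan, 1.0
        elif normal:
            stat, p = sps.ttest_ind(g1, g2)
            test = "t-test"
        else:
            stat, p = sps.mannwhitneyu(g1, g2, alternative="two-sided")
            test = "mann-whitney"
        out.append(dict(variable=var, test=test, stat=float(stat), p=float(p),
                        prone=_describe(g1, normal), supine=_describe(g2, normal),
                        n_prone=len(g1), n_supine=len(g2)))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# ANOVA


def anova_peep_position(tbl: pd.DataFrame, outcome: str = "d_icp") -> StatReport:
    """Two-way ANOVA of the change-from-baseline outcome: PEEP x position."""
    d = _intervention_rows(tbl, outcome)
    counts = d.groupby(["peep", "position"], observed=True)["animal"].nunique()
    levels = d["peep"].unique()
    positions = d["position"].unique()
    expected = {(p, pos) for p in levels for pos in positions}
    missing = expected - set(counts.index)
    if missing:
        raise ValueError(f"missing PEEP x position cells: {sorted(missing)}")

    if np.allclose(d[outcome].std(ddof=0), 0.0):
        rows = [(t, np.nan, 0.0, np.nan, 1.0)
                for t in ("peep", "position", "peep:position")]
        return StatReport(name=f"anova_peep_position[{outcome}]",
                          model=f"{outcome} ~ C(peep)*C(position)",
                          terms=_terms_frame(rows),
                          diagnostics={"note": "constant outcome: F = 0"})

    fit = smf.ols(f"{outcome} ~ C(peep) * C(position)", data=d).fit()
    table = anova_lm(fit, typ=2)
    mapping = {"C(peep)": "peep", "C(position)": "position",
               "C(peep):C(position)": "peep:position"}
    rows = []
    for src, term in mapping.items():
        rows.append((term, np.nan, float(table.loc[src, "F"]),
                     float(table.loc[src, "df"]), float(table.loc[src, "PR(>F)"])))
    resid = fit.resid
    shap_p = float(sps.shapiro(resid).pvalue) if 3 <= len(resid) <= 5000 else np.nan
    return StatReport(
        name=f"anova_peep_position[{outcome}]",
        model=f"{outcome} ~ C(peep)*C(position)",
        terms=_terms_frame(rows),
        diagnostics={"residual_shapiro_p": shap_p,
                     "df_resid": float(fit.df_resid)},
    )


def pooled_change_anova(tbl: pd.DataFrame, outcome: str = "d_icp") -> StatReport:
    """Repeated-measures one-way ANOVA of the pooled change across PEEP levels.

    Positions are pooled by averaging the two blocks' changes per animal and
    PEEP level; animal is the repeated factor.  Classical within-subject F with
    sphericity assumed.
    """
    d = _intervention_rows(tbl, outcome)
    pooled = (d.groupby(["animal", "peep"], as_index=False, observed=True)[outcome]
              .mean())
    if pooled["peep"].nunique() < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 PEEP levels")
    wide = pooled.pivot(index="animal", columns="peep", values=outcome).dropna()
    if np.allclose(wide.sub(wide.mean(axis=1), axis=0).std(ddof=0).sum(), 0.0):
        rows = [("peep", np.nan, 0.0, np.nan, 1.0)]
        return StatReport(name=f"pooled_rm_anova[{outcome}]",
                          model=f"{outcome} ~ peep | animal",
                          terms=_terms_frame(rows),
                          diagnostics={"note": "no within-animal variation: F = 0"})
    long = wide.reset_index().melt(id_vars="animal", var_name="peep",
                                   value_name=outcome)
    res = AnovaRM(long, depvar=outcome, subject="animal", within=["peep"]).fit()
    row = res.anova_table.iloc[0]
    rows = [("peep", np.nan, float(row["F Value"]),
             float(row["Num DF"]), float(row["Pr > F"]))]
    return StatReport(
        name=f"pooled_rm_anova[{outcome}]",
        model=f"{outcome} ~ peep | animal (sphericity assumed)",
        terms=_terms_frame(rows),
        diagnostics={"n_animals": int(wide.shape[0]),
                     "den_df": float(row["Den DF"])},
    )


# ---------------------------------------------------------------------------
# exploratory baseline-covariate screen


def baseline_correlation_screen(tbl: pd.DataFrame,
                                covariates: tuple[str, ...] | None = None,
                                outcome: str = "d_icp") -> pd.DataFrame:
    """Relate intervention-induced changes to baseline covariates.

    For each covariate: mixed model ``d_outcome ~ covariate`` with animal
    random intercept (slope and Wald p), plus marginal Pearson r between the
    pooled per-period changes and the block-baseline covariate value.  Prone
    and supine rows pooled; no multiple-comparison correction.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    d = _intervention_rows(tbl, outcome)
    base = tbl[tbl["label"] == "baseline"].set_index(["animal", "block"])
    rows = []
    for cov in covariates:
        if cov not in tbl.columns:
            continue
        try:
            bvals = base[cov]
        except KeyError:
            continue
        x = np.array([
            bvals.get((a, b), np.nan)
            for a, b in zip(d["animal"], d["block"])
        ], dtype=float)
        y = d[outcome].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            continue
        if np.std(x[ok]) == 0:
            warnings.warn(f"covariate {cov!r} is constant: skipped", stacklevel=2)
            continue
        r, p_r = sps.pearsonr(x[ok], y[ok])
        dd = pd.DataFrame({"y": y[ok], "x": x[ok],
                           "animal": d["animal"].to_numpy()[ok]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = smf.mixedlm("y ~ x", data=dd,
                                  groups=dd["animal"]).fit(reml=True)
                slope = float(fit.params["x"])
                p_mix = float(fit.pvalues["x"])
            except Exception:
                ols = smf.ols("y ~ x", data=dd).fit()
                slope, p_mix = float(ols.params["x"]), float(ols.pvalues["x"])
        rows.append(dict(covariate=cov, slope=slope, p=p_mix,
                         r=float(r), p_pearson=float(p_r), n=int(ok.sum())))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def run_statistics(tbl: pd.DataFrame,
                   outcomes: tuple[str, ...] = ("d_icp", "d_prx_z"),
                   covariates: tuple[str, ...] | None = None,
                   alpha: float = ALPHA) -> dict[str, Any]:
    """The full strategy on one study table; returns reports keyed by stage."""
    reports: dict[str, Any] = {"alpha": alpha}
    for outcome in outcomes:
        key = outcome[2:] if outcome.startswith("d_") else outcome
        reports[f"crossover_{key}"] = crossover_assumption_tests(tbl, outcome)
        reports[f"anova_{key}"] = anova_peep_position(tbl, outcome)
        reports[f"rm_anova_{key}"] = pooled_change_anova(tbl, outcome)
    reports["baselines"] = compare_baselines(tbl)
    reports["screen"] = baseline_correlation_screen(tbl, covariates=covariates)
    return reports
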