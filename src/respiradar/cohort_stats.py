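"""Group comparisons and adjusted association models on the patient table.

Continuous variables are compared between LVEF groups with the Mann-Whitney
U test (exact permutation enumeration for combined n <= 12, normal
approximation with tie correction otherwise); categorical variables with
Fisher's exact test. Associations use ordinary least squares (t-based 95%
CIs) and maximum-likelihood logistic regression (Wald CIs on the log-odds
scale), each adjusted for age, sex and BMI. No multiple-testing correction
is applied: models are reported one exposure at a time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import HIGH_GROUP, LOW_GROUP

DEFAULT_COVARIATES = ("age_years", "sex", "bmi_kg_m2")
EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class EffectEstimate:
    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    covariates: tuple

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.coefficient <= self.ci_high):
            raise ValueError("CI must bracket the coefficient")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class OddsRatioEstimate:
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool
    n: int = 0

    def __post_init__(self) -> None:
        if self.or_value <= 0:
            raise ValueError("odds ratio must be positive")
        if not (self.ci_low <= self.or_value <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")


class SeparationError(RuntimeError):
    """Complete separation: the logistic MLE does not exist."""


# ---------------------------------------------------------------------------
# group comparisons


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    The U statistic of the observed x-assignment is compared against its
    full permutation distribution over C(n1+n2, n1) assignments; the
    two-sided p is the fraction of assignments at least as far from the
    null mean n1*n2/2 as observed. Ties are handled through midranks.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    center = n1 * n2 / 2.0
    dev_obs = abs(u_obs - center)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - center) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return float(u_obs), count / total


def compare_groups(cohort: pd.DataFrame, variable: str) -> dict:
    """Two-group test of one variable across the LVEF groups.

    Numeric variables: Mann-Whitney U (exact enumeration when the combined
    non-missing n <= 12). Categorical: Fisher's exact test on the
    contingency table (2xk collapsed to 2x2 for k == 2; otherwise
    chi-square-free Fisher on the full table is not attempted and a
    freeman-halton style fallback uses scipy only for 2x2).
    """
    g1 = cohort.loc[cohort["group"] == LOW_GROUP, variable].dropna()
    g2 = cohort.loc[cohort["group"] == HIGH_GROUP, variable].dropna()
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError(f"both groups must be non-empty for {variable!r}")

    if pd.api.types.is_numeric_dtype(cohort[variable]):
        x, y = g1.to_numpy(float), g2.to_numpy(float)
        if len(x) + len(y) <= EXACT_MW_MAX_N:
            stat, p = mann_whitney_exact(x, y)
            method = "mann-whitney-exact"
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
            method = "mann-whitney-asymptotic"
        return {"variable": variable, "statistic": stat, "p_value": p,
                "method": method, "n1": len(x), "n2": len(y)}

    levels = sorted(pd.concat([g1, g2]).unique().tolist())
    table = np.array(
        [[int((g == lv).sum()) for lv in levels] for g in (g1, g2)]
    )
    if table.shape[1] == 2:
        _, p = stats.fisher_exact(table)
    else:
        # collapse to most-frequent level vs rest for >2 categories
        top = int(np.argmax(table.sum(axis=0)))
        collapsed = np.stack(
            [table[:, top], table.sum(axis=1) - table[:, top]], axis=1
        )
        _, p = stats.fisher_exact(collapsed)
    return {"variable": variable, "statistic": float("nan"), "p_value": float(p),
            "method": "fisher-exact", "n1": len(g1), "n2": len(g2)}


# ---------------------------------------------------------------------------
# regression models


def _design(cohort: pd.DataFrame, exposure: str, covariates) -> pd.DataFrame:
    X = pd.DataFrame({exposure: cohort[exposure].astype(float)})
    for c in covariates:
        if c == "sex":
            X["sex_male"] = (cohort["sex"] == "male").astype(float)
        else:
            X[c] = cohort[c].astype(float)
    return sm.add_constant(X, has_constant="add")


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if corr.size else ("?", "?")
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"most collinear columns: {worst}"
        )


def fit_linear_association(
    cohort: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates=DEFAULT_COVARIATES,
) -> EffectEstimate:
    """OLS of ``outcome`` on ``exposure`` adjusted for the covariates.

    Returns the per-unit exposure coefficient with its t-based 95% Wald CI.
    Rows with missing outcome or exposure are dropped (the NT-proBNP
    subgroup convention).
    """
    cols = [outcome, exposure] + [c for c in covariates]
    data = cohort.dropna(subset=[c for c in cols if c in cohort.columns])
    X = _design(data, exposure, covariates)
    if len(data) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    _check_rank(X)
    fit = sm.OLS(data[outcome].astype(float), X).fit()
    lo, hi = fit.conf_int().loc[exposure]
    return EffectEstimate(
        coefficient=float(fit.params[exposure]),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(fit.pvalues[exposure]),
        n=int(fit.nobs),
        covariates=tuple(covariates),
    )


def fit_logistic_or(
    cohort: pd.DataFrame,
    exposure: str,
    covariates=DEFAULT_COVARIATES,
    adjusted: bool = True,
) -> OddsRatioEstimate:
    """Logistic model of LVEF<=50 group membership on one exposure.

    OR = exp(beta) per exposure unit, 95% Wald CI on the log scale. The
    crude model (``adjusted=False``) omits the covariates. Complete
    separation raises :class:`SeparationError`.
    """
    data = cohort.dropna(subset=[exposure])
    y = (data["group"] == LOW_GROUP).astype(float)
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    X = _design(data, exposure, covariates if adjusted else ())
    _check_rank(X)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        raise SeparationError(str(exc)) from exc
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError("logistic likelihood maximization did not converge")
    beta = float(fit.params[exposure])
    se = float(fit.bse[exposure])
    if not np.isfinite(se) or se > 50:
        raise SeparationError("quasi-separation: unbounded Wald standard error")
    z = stats.norm.ppf(0.975)
    return OddsRatioEstimate(
        or_value=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=float(fit.pvalues[exposure]),
        adjusted=adjusted,
        n=int(fit.nobs),
    )


# ---------------------------------------------------------------------------
# report


_CONTINUOUS_TABLE1 = ["age_years", "bmi_kg_m2", "cci", "lvef_pct", "lvedd_mm",
                     "lvesd_mm"]
_CATEGORICAL_TABLE1 = ["sex", "smoking"]
_TABLE3 = ["tst_h", "sleep_efficiency_pct", "rdi_events_per_h", "pb_cycle_s"]
_EXPOSURES = ["rdi_events_per_h", "pb_cycle_s"]
_OUTCOMES = ["lvef_pct", "lvedd_mm", "lvesd_mm", "ntprobnp_pg_ml"]


def _mean_sd_row(cohort: pd.DataFrame, var: str) -> dict:
    res = compare_groups(cohort, var)
    out = {"variable": var, "p_value": res["p_value"], "method": res["method"]}
    for label, grp in ((LOW_GROUP, "low"), (HIGH_GROUP, "high")):
        vals = cohort.loc[cohort["group"] == label, var].dropna()
        out[f"{grp}_mean"] = float(vals.mean()) if len(vals) else float("nan")
        out[f"{grp}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        out[f"{grp}_n"] = int(len(vals))
    return out


def build_report(cohort: pd.DataFrame) -> dict:
    """Assemble the descriptive/association report tables.

    Returns a dict of DataFrames: ``characteristics`` (mean±SD group
    comparisons incl. categorical Fisher rows), ``biomarkers`` (NT-proBNP
    subgroup), ``radar`` (sleep/respiratory indices), ``linear``
    (exposure × outcome adjusted coefficient grid) and ``odds``
    (crude + adjusted OR per exposure, 2 exposures × 2 model types).
    """
    if (cohort["group"] == LOW_GROUP).sum() == 0 or (
        cohort["group"] == HIGH_GROUP
    ).sum() == 0:
        raise ValueError("single-group cohort: comparisons undefined")

    char_rows = []
    for var in _CONTINUOUS_TABLE1:
        if var in cohort.columns and cohort[var].notna().any():
            char_rows.append(_mean_sd_row(cohort, var))
    for var in _CATEGORICAL_TABLE1:
        if var in cohort.columns:
            res = compare_groups(cohort, var)
            char_rows.append(
                {"variable": var, "p_value": res["p_value"], "method": res["method"],
                 "low_n": res["n1"], "high_n": res["n2"]}
            )

    bio_rows = []
    sub = cohort.dropna(subset=["ntprobnp_pg_ml"]) if "ntprobnp_pg_ml" in cohort else cohort.iloc[0:0]
    if len(sub) and (sub["group"] == LOW_GROUP).any() and (sub["group"] == HIGH_GROUP).any():
        bio_rows.append(_mean_sd_row(sub, "ntprobnp_pg_ml"))
    else:
        bio_rows.append(
            {"variable": "ntprobnp_pg_ml", "note": f"subgroup n={len(sub)}",
             "p_value": float("nan")}
        )

    radar_rows = [_mean_sd_row(cohort, v) for v in _TABLE3 if v in cohort.columns]

    linear_rows = []
    for exposure in _EXPOSURES:
        for outcome in _OUTCOMES:
            if outcome not in cohort.columns:
                continue
            avail = cohort.dropna(subset=[outcome, exposure])
            if len(avail) < 8:
                linear_rows.append(
                    {"exposure": exposure, "outcome": outcome,
                     "note": f"subgroup n={len(avail)}"}
                )
                continue
            est = fit_linear_association(cohort, outcome, exposure)
            linear_rows.append(
                {"exposure": exposure, "outcome": outcome,
                 "coefficient": est.coefficient, "ci_low": est.ci_low,
                 "ci_high": est.ci_high, "p_value": est.p_value, "n": est.n}
            )

    odds_rows = []
    for exposure in _EXPOSURES:
        for adjusted in (False, True):
            try:
                est = fit_logistic_or(cohort, exposure, adjusted=adjusted)
                odds_rows.append(
                    {"exposure": exposure,
                     "model": "adjusted" if adjusted else "crude",
                     "or_value": est.or_value, "ci_low": est.ci_low,
                     "ci_high": est.ci_high, "p_value": est.p_value, "n": est.n}
                )
            except SeparationError as exc:
                odds_rows.append(
                    {"exposure": exposure,
                     "model": "adjusted" if adjusted else "crude",
                     "note": f"separation: {exc}"}
                )

    return {
        "characteristics": pd.DataFrame(char_rows),
        "biomarkers": pd.DataFrame(bio_rows),
        "radar": pd.DataFrame(radar_rows),
        "linear": pd.DataFrame(linear_rows),
        "odds": pd.DataFrame(odds_rows),
    }


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write each table as TSV plus a plain-text summary; deterministic."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
    lines = ["respiradar cohort report", "=" * 24, ""]
    for name, df in report.items():
        lines.append(f"[{name}]")
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")
    (out / "summary.txt").write_text("\n".join(lines))
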