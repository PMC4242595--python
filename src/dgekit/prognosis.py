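"""IHC staining scores, clinicopathologic association tests, and survival models.

Protein expression on tissue sections is scored by two ordinal
components: the proportion of stained tumor cells (0: none; 1: <=5%;
2: 6-25%; 3: 26-50%; 4: 51-75%; 5: >75%) and the staining intensity
(0-3).  Their product is the staining index (0-15), dichotomized at
>= 5 into high vs low expression groups.  Group prognostic value is
assessed with Kaplan-Meier curves, the log-rank test, and univariate or
multivariate Cox proportional-hazards regression (Efron ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import chi2_contingency, fisher_exact
from statsmodels.duration.hazard_regression import PHReg

from dgekit.config import MARKERS, MARKER_RISK_STATE

__all__ = [
    "StainingScore",
    "CoxFit",
    "staining_index",
    "association_tests",
    "kaplan_meier",
    "logrank_test",
    "cox_fit",
    "marker_combination",
]


@dataclass(frozen=True)
class StainingScore:
    proportion_pct: float
    proportion_score: int
    intensity_grade: int
    staining_index: int
    group: str  # "high" | "low"


def proportion_score(proportion_pct: float) -> int:
    """Ordinal 0-5 bin of the stained-cell percentage.

    Published bins leave (5, 6) uncovered; right-closed bins
    (<=5, <=25, <=50, <=75, >75) are used for exhaustive coverage.
    """
    p = float(proportion_pct)
    if not 0.0 <= p <= 100.0:
        raise ValueError("proportion_pct must lie in [0, 100]")
    if p == 0.0:
        return 0
    for score, upper in ((1, 5.0), (2, 25.0), (3, 50.0), (4, 75.0)):
        if p <= upper:
            return score
    return 5


def staining_index(proportion_pct: float, intensity_grade: int,
                   combine: str = "product", cutoff: int = 5) -> StainingScore:
    """Staining index and high/low dichotomization of one IHC read-out.

    ``combine`` is "product" (default; index range 0-15, the standard
    immunoreactive-score construction) or "sum" (0-8).  Patients with
    index >= ``cutoff`` form the high-expression group.
    """
    if intensity_grade not in (0, 1, 2, 3):
        raise ValueError("intensity_grade must be one of 0, 1, 2, 3")
    ps = proportion_score(proportion_pct)
    if combine == "product":
        idx = ps * int(intensity_grade)
    elif combine == "sum":
        idx = ps + int(intensity_grade)
    else:
        raise ValueError("combine must be 'product' or 'sum'")
    return StainingScore(
        proportion_pct=float(proportion_pct),
        proportion_score=ps,
        intensity_grade=int(intensity_grade),
        staining_index=idx,
        group="high" if idx >= cutoff else "low",
    )


def _crosstab(a: pd.Series, b: pd.Series) -> np.ndarray:
    t = pd.crosstab(a, b)
    return t.to_numpy()


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric enumeration)."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    return float(fisher_exact(table, alternative="two-sided")[1])


def chi_square_test(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction), (r-1)(c-1) df."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square refused: table has an empty row or column")
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)


def association_tests(clinical: pd.DataFrame,
                      markers: tuple[str, ...] = MARKERS,
                      group_suffix: str = "_group") -> pd.DataFrame:
    """Marker/clinicopathologic association p-values (Table-1-style).

    Marker-marker and marker-sex associations (2x2) use Fisher's exact
    test; associations with T stage (2x3 or larger) use the Pearson
    chi-square test without continuity correction.
    """
    cols = [f"{m}{group_suffix}" for m in markers]
    missing = [c for c in cols + ["sex", "t_stage"] if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    rows = []
    variables = list(zip(markers, cols)) + [("sex", "sex")]
    for i, (name_a, col_a) in enumerate(variables):
        for name_b, col_b in variables[i + 1 :]:
            p = fisher_exact_2x2(_crosstab(clinical[col_a], clinical[col_b]))
            rows.append((name_a, name_b, "fisher", p))
        stat, p = chi_square_test(_crosstab(clinical[col_a], clinical["t_stage"]))
        rows.append((name_a, "t_stage", "chi-square", p))
    return pd.DataFrame(rows, columns=["var_a", "var_b", "test", "p"])


def kaplan_meier(records: pd.DataFrame, group: str | pd.Series,
                 duration_col: str = "time",
                 event_col: str = "event") -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns, per group label, a step-function table with columns
    ``time`` and ``survival`` (S(0) = 1 included).
    """
    g = records[group] if isinstance(group, str) else group
    if (records[duration_col] <= 0).any():
        raise ValueError("survival times must be positive")
    curves: dict[str, pd.DataFrame] = {}
    for label in sorted(g.unique()):
        sub = records[g == label]
        if len(sub) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], event_observed=sub[event_col])
        sf = kmf.survival_function_
        curves[str(label)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return curves


def logrank_test(records: pd.DataFrame, group: str | pd.Series,
                 duration_col: str = "time",
                 event_col: str = "event") -> tuple[float, float]:
    """Two-group Mantel-Haenszel log-rank test: (chi-square statistic, p)."""
    g = records[group] if isinstance(group, str) else group
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValueError(f"log-rank test requires exactly 2 groups, got {len(labels)}")
    if records[event_col].sum() < 1:
        raise ValueError("log-rank test requires at least one event")
    mask = g == labels[0]
    res = _ll_logrank(
        records.loc[mask, duration_col], records.loc[~mask, duration_col],
        event_observed_A=records.loc[mask, event_col],
        event_observed_B=records.loc[~mask, event_col],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit: per-covariate summary plus diagnostics."""

    summary: pd.DataFrame  # coef, se, hr, ci_low, ci_high, p per term
    log_likelihood: float
    converged: bool
    ties: str
    n: int
    n_events: int
    message: str = ""


def _design_matrix(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric design matrix; categorical terms are dummy-coded against the
    lexicographically last level (T stage: T1 and T2 each vs T3; sex:
    Female vs Male), matching the published contrast layout."""
    parts = []
    for cov in covariates:
        col = records[cov]
        if col.dtype.kind in "biufc":
            parts.append(col.astype(float).rename(cov))
        else:
            levels = sorted(col.astype(str).unique())
            ref = levels[-1]
            for lev in levels[:-1]:
                parts.append(
                    (col.astype(str) == lev).astype(float).rename(f"{cov}[{lev} vs {ref}]")
                )
    X = pd.concat(parts, axis=1)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"covariates constant across records: {const}")
    return X


def cox_fit(records: pd.DataFrame, covariates: list[str], ties: str = "efron",
            duration_col: str = "time", event_col: str = "event") -> CoxFit:
    """Cox proportional-hazards regression via partial likelihood.

    Pass a single covariate for the univariate column of a results table
    or the full list for the multivariate model.  Wald 95% CIs are
    exp(beta +/- 1.96 se).  Monotone likelihood (complete separation)
    and non-convergence are reported via ``converged``/``message``.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    n_events = int(records[event_col].sum())
    if n_events == 0:
        raise ValueError("Cox regression refused: no events in the data")
    X = _design_matrix(records, covariates)
    if n_events < X.shape[1]:
        raise ValueError(
            f"{n_events} events cannot identify {X.shape[1]} coefficients"
        )
    model = PHReg(
        records[duration_col].to_numpy(dtype=float),
        X.to_numpy(),
        status=records[event_col].to_numpy(dtype=int),
        ties=ties,
    )
    message = ""
    converged = True
    try:
        res = model.fit(disp=False)
        beta = np.asarray(res.params, dtype=float)
        se = np.asarray(res.bse, dtype=float)
        pvals = np.asarray(res.pvalues, dtype=float)
        llf = float(model.loglike(beta))
    except Exception as exc:  # singular information matrix etc.
        converged = False
        message = f"fit failed: {exc}"
        k = X.shape[1]
        beta = np.full(k, np.nan)
        se = np.full(k, np.nan)
        pvals = np.full(k, np.nan)
        llf = float("nan")
    if converged and (not np.all(np.isfinite(se)) or np.any(np.abs(beta) > 20)):
        converged = False
        message = (
            "monotone partial likelihood (complete separation suspected): "
            "coefficient estimates diverge"
        )
    with np.errstate(over="ignore"):
        summary = pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "hr": np.exp(beta),
                "ci_low": np.exp(beta - 1.96 * se),
                "ci_high": np.exp(beta + 1.96 * se),
                "p": pvals,
            },
            index=X.columns,
        )
    return CoxFit(
        summary=summary,
        log_likelihood=llf,
        converged=converged,
        ties=ties,
        n=len(records),
        n_events=n_events,
        message=message,
    )


def marker_combination(records: pd.DataFrame,
                       markers: tuple[str, ...] = MARKERS,
                       group_suffix: str = "_group",
                       duration_col: str = "time",
                       event_col: str = "event") -> dict:
    """Combined-marker risk stratification and survival comparison.

    The high-risk stratum carries the adverse state of every marker
    (ALDH2 low AND CCNE1 high AND SMAD3 high); all other combinations
    form the comparison stratum.  Records missing any marker group are
    excluded and counted.  Returns the stratum labels, per-stratum KM
    curves, and the log-rank comparison.
    """
    cols = [f"{m}{group_suffix}" for m in markers]
    missing_cols = [c for c in cols if c not in records.columns]
    if missing_cols:
        raise ValueError(f"missing marker columns: {missing_cols}")
    complete = records.dropna(subset=cols)
    n_excluded = len(records) - len(complete)
    risk = pd.Series(True, index=complete.index)
    for m in markers:
        risk &= complete[f"{m}{group_suffix}"] == MARKER_RISK_STATE[m]
    strata = risk.map({True: "high-risk", False: "other"})
    if strata.nunique() < 2:
        raise ValueError(
            "comparison refused: all patients fall into a single combined-marker stratum"
        )
    curves = kaplan_meier(complete, strata, duration_col, event_col)
    stat, p = logrank_test(complete, strata, duration_col, event_col)
    return {
        "strata": strata,
        "n_high_risk": int(risk.sum()),
        "n_other": int((~risk).sum()),
        "n_excluded": n_excluded,
        "km_curves": curves,
        "logrank_statistic": stat,
        "logrank_p": p,
    }
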