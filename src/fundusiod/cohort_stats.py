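"""Evaluation statistics: clinical derivations, cohort comparison,
correlation analyses, and multivariate regression reports.

Conventions follow the study design: two-sided p-values throughout, no
multiple-testing correction, chi-square without continuity correction for
2x2 sex tables (configurable), Student's t for continuous train/test
comparisons with a Kolmogorov-Smirnov normality flag per variable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .case_io import SubjectRecord
from .iod_model import IODModel, adjusted_r2

#: axial-length strata (mm): [0, 24), [24, 26), [26, inf); stratum 3 is the
#: high-myopia group
AL_STRATA_BOUNDS = (24.0, 26.0)

ELIGIBILITY_AGE = (16.0, 40.0)
ELIGIBILITY_SER_MAX = 0.5    # diopters, exclusive upper bound
ELIGIBILITY_IOP_MAX = 21.0   # mm Hg, inclusive


def al_stratum(al: float) -> int:
    """1: AL < 24 mm; 2: 24 <= AL < 26 mm; 3: AL >= 26 mm (high myopia)."""
    if al < AL_STRATA_BOUNDS[0]:
        return 1
    if al < AL_STRATA_BOUNDS[1]:
        return 2
    return 3


def derive_clinical(record: SubjectRecord) -> tuple[SubjectRecord, bool, int]:
    """Complete derived fields (MAP, SER) and evaluate eligibility.

    MAP = (SBP + 2 DBP) / 3; SER = sphere + cylinder / 2.  Eligibility: age
    within 16-40 years, SER < 0.5 D and IOP <= 21 mm Hg.  Returns the
    completed record, the eligibility flag and the AL stratum.
    """
    rec = dataclasses.replace(record)
    if np.isfinite(rec.sbp) and np.isfinite(rec.dbp):
        rec.map = (rec.sbp + 2.0 * rec.dbp) / 3.0
    if np.isfinite(rec.sphere) and np.isfinite(rec.cylinder):
        rec.ser = rec.sphere + rec.cylinder / 2.0
    for name in ("age", "ser", "iop", "al"):
        if not np.isfinite(getattr(rec, name)):
            raise ValueError(f"missing required field: {name}")
    eligible = (ELIGIBILITY_AGE[0] <= rec.age <= ELIGIBILITY_AGE[1]
                and rec.ser < ELIGIBILITY_SER_MAX
                and rec.iop <= ELIGIBILITY_IOP_MAX)
    return rec, bool(eligible), al_stratum(rec.al)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("Spearman correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def partial_correlation(x, y, covariates) -> tuple[float, float]:
    """Correlation of x and y after removing linear covariate effects.

    Residualizes both variables on the covariates (with intercept) by OLS and
    correlates the residuals; p is two-sided from a t distribution with
    n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != len(x):
        C = C.T
    k = C.shape[1]
    n = len(x)
    if n <= k + 2:
        raise ValueError("too few observations for partial correlation")
    A = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("collinear covariates")
    rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
    ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    # a variable fully explained by the covariates has nothing left to
    # correlate: report zero association rather than numerical noise
    if np.var(rx) <= 1e-12 * max(np.var(x), 1e-300) \
            or np.var(ry) <= 1e-12 * max(np.var(y), 1e-300):
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1.0 - r * r, 1e-300))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


@dataclass
class RegressionReport:
    """Per-predictor raw (B) and standardized (beta) coefficients with
    two-sided p-values, plus the model's adjusted R2."""

    predictors: list[str]
    b: np.ndarray
    beta: np.ndarray
    p: np.ndarray
    adj_r2: float
    r2: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"B": self.b, "beta": self.beta, "P": self.p},
                            index=self.predictors)


def ols_report(y, X: pd.DataFrame) -> RegressionReport:
    """OLS with intercept; standardized beta = B * sd(x) / sd(y)."""
    y = np.asarray(y, dtype=float)
    model = sm.OLS(y, sm.add_constant(X.astype(float))).fit()
    names = list(X.columns)
    b = model.params[names].to_numpy()
    p = model.pvalues[names].to_numpy()
    sd_y = y.std(ddof=0)
    beta = np.array([b[i] * X[c].std(ddof=0) / sd_y
                     for i, c in enumerate(names)])
    n, k = len(y), len(names)
    report = RegressionReport(
        predictors=names, b=b, beta=beta, p=p,
        adj_r2=adjusted_r2(model.rsquared, n, k),
        r2=float(model.rsquared), n=n)
    assert abs(report.adj_r2 - model.rsquared_adj) < 1e-9
    return report


def compare_train_test(train: pd.DataFrame, test: pd.DataFrame,
                       variables: list[str],
                       categorical: tuple[str, ...] = ("sex",),
                       chi2_correction: bool = False) -> pd.DataFrame:
    """Per-variable comparison of the two sets, mirroring a cohort table.

    Continuous variables: mean +/- sd per set, Student's t-test p-value and a
    Kolmogorov-Smirnov normality p (pooled, against a fitted normal).
    Categorical: counts per set and a chi-square p-value.
    """
    if len(train) == 0 or len(test) == 0:
        raise ValueError("both sets must be non-empty")
    rows = []
    for var in variables:
        a, b = train[var], test[var]
        if var in categorical:
            levels = sorted(set(a) | set(b))
            tab = np.array([[int((a == lv).sum()) for lv in levels],
                            [int((b == lv).sum()) for lv in levels]])
            if (tab.sum(axis=0) == 0).any() or np.array_equal(tab[0], tab[1]):
                p = 1.0
            else:
                _, p, _, _ = stats.chi2_contingency(
                    tab, correction=chi2_correction)
            rows.append({"variable": var, "kind": "categorical",
                         "train": "/".join(str(v) for v in tab[0]),
                         "test": "/".join(str(v) for v in tab[1]),
                         "p": float(p), "ks_normality_p": np.nan})
        else:
            av = np.asarray(a, dtype=float)
            bv = np.asarray(b, dtype=float)
            pooled = np.concatenate([av, bv])
            if pooled.std(ddof=0) == 0:
                raise ValueError(f"zero-variance continuous variable: {var}")
            if np.array_equal(av, bv):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_ind(av, bv, equal_var=True)
            ks_p = stats.kstest(
                (pooled - pooled.mean()) / pooled.std(ddof=1), "norm")[1]
            rows.append({
                "variable": var, "kind": "continuous",
                "train": f"{av.mean():.2f} ± {av.std(ddof=1):.2f}",
                "test": f"{bv.mean():.2f} ± {bv.std(ddof=1):.2f}",
                "p": float(p), "ks_normality_p": float(ks_p)})
    return pd.DataFrame(rows).set_index("variable")


def evaluate_iod(model: IODModel, test: pd.DataFrame,
                 clinical_variables: list[str] | None = None) -> pd.DataFrame:
    """Spearman correlations of the indicator with target and clinical
    variables on the held-out set, plus the linear R2 against its target."""
    if clinical_variables is None:
        clinical_variables = [c for c in
                              ("mChT", "pChT", "al", "ppa_area",
                               "ovality_index", "torsion_angle")
                              if c in test.columns]
    missing = [v for v in clinical_variables if v not in test.columns]
    if missing:
        raise ValueError(f"missing variables: {missing}")
    iod = model.predict(test)
    rows = []
    for var in clinical_variables:
        vals = np.asarray(test[var], dtype=float)
        if np.ptp(vals) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = spearman(iod, vals)
        rows.append({"variable": var, "r": r, "p": p})
    out = pd.DataFrame(rows).set_index("variable")
    target_vals = np.asarray(test[model.target], dtype=float)
    pearson_r = float(np.corrcoef(iod, target_vals)[0, 1])
    out.attrs["target_linear_r2"] = pearson_r ** 2
    return out


def stratified_reports(y, X: pd.DataFrame, al: np.ndarray
                       ) -> dict[str, RegressionReport]:
    """The overall regression report plus one per axial-length stratum."""
    al = np.asarray(al, dtype=float)
    y = np.asarray(y, dtype=float)
    strata = np.array([al_stratum(v) for v in al])
    out = {"all": ols_report(y, X)}
    for s, label in ((1, "al_lt_24"), (2, "al_24_to_26"), (3, "al_ge_26")):
        m = strata == s
        if m.sum() > X.shape[1] + 2:
            out[label] = ols_report(y[m], X.loc[m])
    assert sum((strata == s).sum() for s in (1, 2, 3)) == len(al)
    return out
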