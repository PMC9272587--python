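"""Group-level inference on the subject feature table.

The feature table carries one row per analysed subject with the six
modelling variables: ΔΔ ALPHA_AMP (uV), ΔΔ CONNECTIVITY (Fisher-z units),
ΔΔ SLEEPINESS (VAS change difference, dimensionless), MISMATCH (Hz),
EFIELD_alphaBOLD and EFIELD_strong (V/m). On it run the 2x2
repeated-measures ANOVA, the session ANCOVA with a sleepiness covariate,
the four multiple-regression variants

    ΔΔ ALPHA_AMP | ΔΔ CONNECTIVITY  ~  ΔΔ SLEEPINESS + MISMATCH + EFIELD_*

plus the reduced model without MISMATCH, leave-one-out cross-validation,
Bonferroni correction over the model family, and the residualize-then-
correlate check that isolates the field-dose contribution from sleepiness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sp_stats

from .errors import AnalysisError, InputError

FEATURE_COLUMNS = (
    "dd_alpha_amp",
    "dd_connectivity",
    "dd_sleepiness",
    "mismatch",
    "efield_alphabold",
    "efield_strong",
)

#: the four published model variants plus the reduced final model
MODEL_VARIANTS = {
    "alpha_alphabold": ("dd_alpha_amp", ["dd_sleepiness", "mismatch", "efield_alphabold"]),
    "alpha_strong": ("dd_alpha_amp", ["dd_sleepiness", "mismatch", "efield_strong"]),
    "conn_alphabold": ("dd_connectivity", ["dd_sleepiness", "mismatch", "efield_alphabold"]),
    "conn_strong": ("dd_connectivity", ["dd_sleepiness", "mismatch", "efield_strong"]),
    "eq3": ("dd_alpha_amp", ["dd_sleepiness", "efield_alphabold"]),
}


@dataclass
class SubjectFeatures:
    """One row of the modelling table."""

    subject_id: str
    dd_alpha_amp: float
    dd_connectivity: float
    dd_sleepiness: float
    mismatch: float
    efield_alphabold: float
    efield_strong: float

    def __post_init__(self):
        for name in FEATURE_COLUMNS:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InputError(f"{name} must be finite, got {v}")
        if self.mismatch < 0:
            raise InputError("mismatch must be nonnegative")
        if self.efield_alphabold < 0 or self.efield_strong < 0:
            raise InputError("field strengths must be nonnegative")


@dataclass
class ModelFit:
    """Summary of one OLS model fit (one row of the published model table)."""

    response: str
    predictors: list[str]
    params: dict[str, float]
    bse: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    fvalue: float
    f_pvalue: float
    r2: float
    r2_adj: float
    rmse: float
    loocv_rmse: float
    n: int

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "coefficients": self.params,
            "standard_errors": self.bse,
            "t_values": self.tvalues,
            "p_values": self.pvalues,
            "model_F": self.fvalue,
            "model_p": self.f_pvalue,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "rmse": self.rmse,
            "loocv_rmse": self.loocv_rmse,
            "n": self.n,
        }


@dataclass
class AnovaResult:
    """2x2 within-subject ANOVA: F and p per effect, common dof (1, n-1)."""

    f: dict[str, float]
    p: dict[str, float]
    dof: tuple[int, int]
    ss: dict[str, float] = field(default_factory=dict)


def assemble_features(
    features: list[SubjectFeatures | dict],
    excluded: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble per-subject pipeline outputs into the modelling table.

    Returns ``(table, exclusions)``: the table has one row per included
    subject (index ``subject_id``); exclusions lists dropped subjects with
    the recorded reason (e.g. a non-identifiable alpha peak).
    """
    rows = []
    for f in features:
        if isinstance(f, dict):
            f = SubjectFeatures(**f)
        rows.append({"subject_id": f.subject_id,
                     **{c: getattr(f, c) for c in FEATURE_COLUMNS}})
    table = pd.DataFrame(rows, columns=["subject_id", *FEATURE_COLUMNS])
    if table["subject_id"].duplicated().any():
        dups = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise InputError(f"duplicate subject ids: {dups}")
    table = table.set_index("subject_id")
    excl = pd.DataFrame(
        [{"subject_id": k, "reason": v} for k, v in (excluded or {}).items()],
        columns=["subject_id", "reason"],
    )
    return table, excl


def _design(table: pd.DataFrame, response: str, predictors: list[str]):
    y = np.asarray(table[response], dtype=float)
    X = np.column_stack([np.ones(len(y))] + [np.asarray(table[p], float) for p in predictors])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise AnalysisError(
            f"rank-deficient design: predictors {predictors} are collinear "
            "(with the intercept)"
        )
    return y, X


def fit_linear_model(
    table: pd.DataFrame,
    response: str,
    predictors: list[str],
    rmse_ddof: int = 0,
) -> ModelFit:
    """OLS fit with intercept, coefficient t-tests, fit quality, and LOOCV.

    RMSE is the root mean squared residual with divisor ``n - rmse_ddof``
    (default ``n``, which makes it directly comparable to the LOOCV RMSE);
    LOOCV RMSE is computed exactly through the hat-matrix identity
    ``e_loo = e / (1 - h)``.
    """
    n = len(table)
    if n <= len(predictors) + 1:
        raise AnalysisError(f"n = {n} rows cannot identify {len(predictors)} predictors")
    y, X = _design(table, response, predictors)
    res = sm.OLS(y, X).fit()
    names = ["const", *predictors]
    resid = res.resid
    rmse = float(np.sqrt((resid**2).sum() / (n - rmse_ddof)))
    h = (X * (X @ np.linalg.inv(X.T @ X))).sum(axis=1)
    if np.any(1 - h < 1e-10):
        raise AnalysisError("a leave-one-out refit is rank deficient (leverage 1)")
    loocv = float(np.sqrt(np.mean((resid / (1 - h)) ** 2)))
    return ModelFit(
        response=response,
        predictors=list(predictors),
        params=dict(zip(names, map(float, res.params))),
        bse=dict(zip(names, map(float, res.bse))),
        tvalues=dict(zip(names, map(float, res.tvalues))),
        pvalues=dict(zip(names, map(float, res.pvalues))),
        fvalue=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        rmse=rmse,
        loocv_rmse=loocv,
        n=n,
    )


def loocv_rmse(table: pd.DataFrame, response: str, predictors: list[str]) -> float:
    """Root mean squared error of the n held-out single-subject predictions."""
    n = len(table)
    if n <= len(predictors) + 2:
        raise AnalysisError(f"n = {n} is too small for leave-one-out validation")
    y, X = _design(table, response, predictors)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    h = (X * (X @ np.linalg.inv(X.T @ X))).sum(axis=1)
    if np.any(1 - h < 1e-10):
        raise AnalysisError("a leave-one-out refit is rank deficient (leverage 1)")
    return float(np.sqrt(np.mean((resid / (1 - h)) ** 2)))


def rm_anova_2x2(values: np.ndarray) -> AnovaResult:
    """Two-way within-subject ANOVA for a complete 2x2 design.

    ``values`` has shape ``(n_subjects, 2, 2)`` with axis 1 = run
    (pre, post) and axis 2 = session (tACS, sham). Each effect is tested
    against its own subject-interaction error term with dof (1, n-1).
    Degenerate zero-variance effects are reported as F = 0 with a warning.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 3 or Y.shape[1:] != (2, 2):
        raise InputError(f"expected shape (n, 2, 2), got {Y.shape}")
    if not np.all(np.isfinite(Y)):
        raise InputError("missing or non-finite cells in the 2x2 design")
    n = Y.shape[0]
    if n < 2:
        raise InputError("need at least 2 subjects")

    grand = Y.mean()
    subj = Y.mean(axis=(1, 2))
    run_m = Y.mean(axis=(0, 2))
    sess_m = Y.mean(axis=(0, 1))
    cell = Y.mean(axis=0)
    run_subj = Y.mean(axis=2)
    sess_subj = Y.mean(axis=1)

    ss = {
        "run": 2 * n * ((run_m - grand) ** 2).sum(),
        "session": 2 * n * ((sess_m - grand) ** 2).sum(),
        "run x session": n * ((cell - run_m[:, None] - sess_m[None, :] + grand) ** 2).sum(),
        "run_error": 2 * ((run_subj - subj[:, None] - run_m[None, :] + grand) ** 2).sum(),
        "session_error": 2 * ((sess_subj - subj[:, None] - sess_m[None, :] + grand) ** 2).sum(),
    }
    # three-way residual: Y minus all main effects and two-way interactions
    pred = (subj[:, None, None] + run_m[None, :, None] + sess_m[None, None, :]
            - 2 * grand
            + (run_subj - subj[:, None] - run_m[None, :] + grand)[:, :, None]
            + (sess_subj - subj[:, None] - sess_m[None, :] + grand)[:, None, :]
            + (cell - run_m[:, None] - sess_m[None, :] + grand)[None, :, :])
    ss["interaction_error"] = ((Y - pred) ** 2).sum()

    dof = (1, n - 1)
    f, p = {}, {}
    for effect, err in (("run", "run_error"), ("session", "session_error"),
                        ("run x session", "interaction_error")):
        num = ss[effect] / dof[0]
        den = ss[err] / dof[1]
        if den == 0:
            if num == 0:
                warnings.warn(f"no variation for effect {effect!r}; F set to 0")
                f[effect], p[effect] = 0.0, 1.0
            else:
                warnings.warn(f"zero error variance for effect {effect!r}")
                f[effect], p[effect] = float("inf"), 0.0
        else:
            f[effect] = float(num / den)
            p[effect] = float(sp_stats.f.sf(f[effect], *dof))
    return AnovaResult(f=f, p=p, dof=dof, ss={k: float(v) for k, v in ss.items()})


def ancova_group(
    delta_values: np.ndarray, covariate: np.ndarray
) -> tuple[float, float, tuple[int, int]]:
    """ANCOVA on post-pre changes: F-test of the session term.

    ``delta_values`` and ``covariate`` have shape ``(n, 2)`` with columns
    (tACS, sham). The test is the condition term of the stacked linear model
    ``delta ~ condition + covariate`` with dof (1, 2n - 3).
    """
    d = np.asarray(delta_values, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if d.shape != c.shape or d.ndim != 2 or d.shape[1] != 2:
        raise InputError("delta_values and covariate must both be (n, 2)")
    if np.ptp(c) == 0:
        raise AnalysisError("constant covariate carries no information")
    n = d.shape[0]
    y = d.T.ravel()  # tACS block then sham block
    cond = np.r_[np.ones(n), np.zeros(n)]
    cov = c.T.ravel()
    X = np.column_stack([np.ones(2 * n), cond, cov])
    res = sm.OLS(y, X).fit()
    tval = res.tvalues[1]
    F = 0.0 if (not np.isfinite(tval) and abs(res.params[1]) < 1e-12) else float(tval**2)
    dof = (1, 2 * n - 3)
    p = float(sp_stats.f.sf(F, *dof)) if np.isfinite(F) else 0.0
    return F, p, dof


def residualize_then_correlate(
    y: np.ndarray, x: np.ndarray, covariate: np.ndarray, residualize_x: bool = False
) -> float:
    """Pearson correlation of x with y after regressing the covariate out of y.

    Used to quantify the field-dose / alpha-change relation once sleepiness
    is partialled out of the response. With ``residualize_x=True`` the
    covariate is removed from both variables (classical partial correlation).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if not (y.shape == x.shape == c.shape) or y.ndim != 1:
        raise InputError("y, x and covariate must be 1-D of equal length")
    if y.size < 4:
        raise InputError("need at least 4 observations")
    if np.ptp(y) == 0 or np.ptp(x) == 0 or np.ptp(c) == 0:
        raise AnalysisError("constant input has no correlation")
    Xc = np.column_stack([np.ones(y.size), c])
    ry = y - Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
    rx = x - Xc @ np.linalg.lstsq(Xc, x, rcond=None)[0] if residualize_x else x
    return float(sp_stats.pearsonr(ry, rx).statistic)


def bonferroni(p_values, m: int = 4, alpha: float = 0.05):
    """Bonferroni significance calls: significant iff p < alpha / m.

    The default family size m = 4 covers the four model variants and gives
    the 0.0125 threshold.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    if m < 1:
        raise InputError("m must be a positive count")
    threshold = alpha / m
    return p < threshold, threshold


def fit_model_variants(table: pd.DataFrame, rmse_ddof: int = 0) -> dict[str, ModelFit]:
    """Fit the four published model variants plus the reduced final model."""
    return {
        name: fit_linear_model(table, resp, preds, rmse_ddof=rmse_ddof)
        for name, (resp, preds) in MODEL_VARIANTS.items()
    }
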