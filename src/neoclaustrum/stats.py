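"""Group statistics: GLMs with partial eta-squared, scan-age matching,
paired longitudinal tests, and random-intercept mixed models.

Model conventions
-----------------
* OLS with the preterm group coded 1 (term 0) and sex coded male = 1.
* Partial eta-squared for a 1-df term is t^2 / (t^2 + df_resid), which for
  such terms equals SS_term / (SS_term + SS_resid).
* Mixed models: single random intercept per subject, REML, Wald p-values
  (no small-sample df correction).
* Rows with missing values in any used column are dropped per analysis and
  the count is logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

log = logging.getLogger(__name__)

GROUP_CODES = {"term": 0.0, "preterm": 1.0}
SEX_CODES = {"female": 0.0, "male": 1.0}


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermResult:
    coef: float
    se: float
    t: float
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class GLMResult:
    outcome: str
    terms: dict  # name -> TermResult
    df_resid: int
    n: int
    n_dropped: int

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n": self.n,
            "n_dropped": self.n_dropped,
            "df_resid": self.df_resid,
            "terms": {
                k: {"coef": v.coef, "se": v.se, "t": v.t, "p": v.p,
                    "partial_eta_sq": v.partial_eta_sq}
                for k, v in self.terms.items()
            },
        }


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_difference: float
    n_pairs: int

    def to_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p,
                "mean_difference": self.mean_difference, "n_pairs": self.n_pairs}


@dataclass(frozen=True)
class MixedModelResult:
    outcome: str
    fixed_effects: dict  # name -> {"coef", "se", "p"}
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_subjects: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "fixed_effects": self.fixed_effects,
            "random_intercept_var": self.random_intercept_var,
            "residual_var": self.residual_var,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
        }


@dataclass(frozen=True)
class MatchResult:
    pairs: tuple  # ((preterm_id, term_id), ...)
    gaps: tuple   # per-pair |scan-age difference|
    unmatched_terms: tuple

    @property
    def mean_gap(self) -> float:
        return float(np.mean(self.gaps)) if self.gaps else float("nan")


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLMSpec:
    """Outcome, optional categorical group term, and continuous/binary
    covariates (any cohort-table column)."""

    outcome: str
    group: str | None = "group"
    covariates: tuple = ("scan_age", "sex")

    def __post_init__(self) -> None:
        preds = ([self.group] if self.group else []) + list(self.covariates)
        if self.outcome in preds:
            raise ValueError(f"outcome {self.outcome!r} cannot also be a predictor")


def partial_eta_squared(t: float, df: int) -> float:
    """Effect-size share of variance for a 1-df model term:
    t^2 / (t^2 + df_resid)."""
    if df <= 0:
        raise ValueError(f"residual df must be positive, got {df}")
    return t**2 / (t**2 + df)


def _encode(table: pd.DataFrame, col: str) -> np.ndarray:
    x = table[col]
    if col == "group" or set(x.dropna().unique()) <= set(GROUP_CODES):
        return x.map(GROUP_CODES).to_numpy(dtype=float)
    if col == "sex" or set(x.dropna().unique()) <= set(SEX_CODES):
        return x.map(SEX_CODES).to_numpy(dtype=float)
    return pd.to_numeric(x).to_numpy(dtype=float)


def _design(table: pd.DataFrame, spec: GLMSpec):
    cols = {"intercept": np.ones(len(table))}
    if spec.group:
        cols[spec.group] = _encode(table, spec.group)
    for c in spec.covariates:
        cols[c] = _encode(table, c)
    X = pd.DataFrame(cols, index=table.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns by incremental rank checks
        bad, kept = [], []
        for c in X.columns:
            trial = X[kept + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(c)
            else:
                bad.append(c)
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    return X


def fit_glm(table: pd.DataFrame, spec: GLMSpec) -> GLMResult:
    """Ordinary least squares for one outcome, with per-term partial
    eta-squared.  Rows with missing values in the used columns are dropped
    (count recorded)."""
    used = [spec.outcome] + ([spec.group] if spec.group else []) + list(spec.covariates)
    sub = table[used].copy()
    n_before = len(sub)
    sub = sub.dropna()
    n_dropped = n_before - len(sub)
    if n_dropped:
        log.info("fit_glm(%s): dropped %d rows with missing values", spec.outcome, n_dropped)
    X = _design(sub, spec)
    if len(sub) <= X.shape[1] + 1:
        raise ValueError(
            f"too few complete rows ({len(sub)}) for {X.shape[1]} parameters"
        )
    y = pd.to_numeric(sub[spec.outcome]).to_numpy(dtype=float)
    fit = sm.OLS(y, X.to_numpy()).fit()
    df_resid = int(fit.df_resid)
    terms = {}
    for j, name in enumerate(X.columns):
        t = float(fit.tvalues[j])
        terms[name] = TermResult(
            coef=float(fit.params[j]),
            se=float(fit.bse[j]),
            t=t,
            p=float(fit.pvalues[j]),
            partial_eta_sq=partial_eta_squared(t, df_resid),
        )
    return GLMResult(
        outcome=spec.outcome, terms=terms, df_resid=df_resid,
        n=len(sub), n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Paired test
# ---------------------------------------------------------------------------

def paired_t(first, second) -> PairedTestResult:
    """Two-sided paired t-test on second - first (pairing by position,
    which callers establish by subject id)."""
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    if first.shape != second.shape:
        raise ValueError("paired samples must have equal length")
    if len(first) < 2:
        raise ValueError("need at least two pairs")
    diffs = second - first
    if np.allclose(diffs.std(ddof=1), 0):
        raise ValueError("zero-variance differences: paired t undefined")
    res = sps.ttest_rel(second, first)
    return PairedTestResult(
        t=float(res.statistic),
        df=len(first) - 1,
        p=float(res.pvalue),
        mean_difference=float(diffs.mean()),
        n_pairs=len(first),
    )


# ---------------------------------------------------------------------------
# Mixed model
# ---------------------------------------------------------------------------

def fit_random_intercept_model(
    table: pd.DataFrame,
    outcome: str,
    fixed_terms=("scan_age", "birth_age", "sex"),
    subject_col: str = "subject_id",
) -> MixedModelResult:
    """Linear mixed model with a single random intercept per subject,
    fitted by REML; fixed-effect p-values are Wald tests."""
    used = [outcome, subject_col] + list(fixed_terms)
    sub = table[used].dropna()
    n_dropped = len(table) - len(sub)
    if n_dropped:
        log.info("mixed model (%s): dropped %d incomplete rows", outcome, n_dropped)
    y = pd.to_numeric(sub[outcome]).to_numpy(dtype=float)
    X = pd.DataFrame({"intercept": np.ones(len(sub))}, index=sub.index)
    for c in fixed_terms:
        X[c] = _encode(sub, c)
    groups = sub[subject_col].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance estimates warn
        model = sm.MixedLM(y, X.to_numpy(), groups=groups)
        try:
            fit = model.fit(reml=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError(f"mixed model failed to converge: {exc}") from exc
    if not fit.converged:
        raise RuntimeError(
            f"mixed model for {outcome!r} did not converge (method {fit.method})"
        )
    fixed = {}
    for j, name in enumerate(X.columns):
        fixed[name] = {
            "coef": float(fit.params[j]),
            "se": float(fit.bse[j]),
            "p": float(fit.pvalues[j]),
        }
    return MixedModelResult(
        outcome=outcome,
        fixed_effects=fixed,
        random_intercept_var=float(np.asarray(fit.cov_re)[0, 0]),
        residual_var=float(fit.scale),
        n_obs=len(sub),
        n_subjects=int(pd.unique(groups).size),
        converged=bool(fit.converged),
    )


# ---------------------------------------------------------------------------
# Scan-age matching
# ---------------------------------------------------------------------------

def match_controls(preterm_rows: pd.DataFrame, term_rows: pd.DataFrame) -> MatchResult:
    """Greedy one-to-one case-control matching on scan age.

    Preterm subjects are processed in ascending scan age (ties by id); each
    receives the still-unused term subject with the smallest absolute
    scan-age gap (ties broken by smaller term scan age, then smaller id).
    Deterministic and independent of input row order.
    """
    need = ["subject_id", "scan_age"]
    pt = preterm_rows[need].sort_values(["scan_age", "subject_id"]).reset_index(drop=True)
    ft = term_rows[need].copy()
    if len(ft) < len(pt):
        raise ValueError(
            f"term pool ({len(ft)}) smaller than preterm group ({len(pt)})"
        )
    lo, hi = ft["scan_age"].min(), ft["scan_age"].max()
    outside = ((pt["scan_age"] < lo) | (pt["scan_age"] > hi)).sum()
    if outside:
        log.warning("%d preterm scan ages fall outside the term scan-age range", outside)
    available = ft.sort_values(["scan_age", "subject_id"]).reset_index(drop=True)
    used = np.zeros(len(available), dtype=bool)
    ages = available["scan_age"].to_numpy()
    ids = available["subject_id"].to_numpy()
    pairs, gaps = [], []
    for _, row in pt.iterrows():
        gap = np.abs(ages - row["scan_age"])
        gap[used] = np.inf
        # ties: smaller gap, then smaller term scan age, then smaller id —
        # `available` is pre-sorted by (age, id), so argmin's first-hit rule
        # implements exactly that order.
        j = int(np.argmin(gap))
        if not np.isfinite(gap[j]):
            raise RuntimeError("term pool exhausted during matching")
        used[j] = True
        pairs.append((row["subject_id"], ids[j]))
        gaps.append(float(gap[j]))
    unmatched = tuple(ids[~used])
    return MatchResult(pairs=tuple(pairs), gaps=tuple(gaps), unmatched_terms=unmatched)
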