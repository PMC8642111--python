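"""Mixed-effects model ladder with AIC selection, type-III Wald tests and
corrected post-hoc contrasts.

Models are written in lme4-style formulas, e.g. ::

    hu_asin ~ condition*age + condition*emotion + emotion*age + (condition|participant)
    duration ~ condition + age + (condition|participant) + (1|movie)

Estimation is delegated to ``statsmodels`` ``MixedLM`` with maximum
likelihood (not REML), so AIC values are comparable across fixed-effect
structures. A candidate higher on the ladder is accepted only if its AIC is
at least two lower than the incumbent's, it converged, and the fit is not
singular (no random-effect variance collapsed to zero, no correlation pinned
at +/-1).
"""

from __future__ import annotations

import re as _re
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sstats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelSpec",
    "FitResult",
    "fit_mixed_model",
    "aic_ladder",
    "wald_anova",
    "posthoc_contrasts",
]

AIC_IMPROVEMENT = 2.0
SINGULAR_SD_FRACTION = 1e-4
SINGULAR_CORR = 0.999


# --------------------------------------------------------------------------
# Formula handling
# --------------------------------------------------------------------------

def _split_top_level(expr: str, sep: str = "+") -> list:
    """Split on ``sep`` outside parentheses."""
    parts, depth, cur = [], 0, []
    for ch in expr:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == sep and depth == 0:
            parts.append("".join(cur).strip())
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur).strip())
    return [p for p in parts if p]


@dataclass(frozen=True)
class ModelSpec:
    """A mixed-model specification parsed from an lme4-style formula."""

    formula: str
    outcome: str = field(init=False)
    fixed_terms: tuple = field(init=False)
    random_terms: tuple = field(init=False)  # (re_expr, group) pairs

    def __post_init__(self) -> None:
        if "~" not in self.formula:
            raise ValueError("formula must contain '~'")
        lhs, rhs = self.formula.split("~", 1)
        fixed, random = [], []
        for term in _split_top_level(rhs):
            if term.startswith("(") and "|" in term:
                inner = term[1:-1]
                re_expr, group = (s.strip() for s in inner.split("|", 1))
                random.append((re_expr, group))
            else:
                fixed.append(term)
        if not random:
            raise ValueError("random structure must be non-empty")
        object.__setattr__(self, "outcome", lhs.strip())
        object.__setattr__(self, "fixed_terms", tuple(fixed))
        object.__setattr__(self, "random_terms", tuple(random))

    def referenced_columns(self) -> set:
        cols = {self.outcome}
        for term in self.fixed_terms:
            cols |= set(_re.findall(r"[A-Za-z_]\w*", term))
        for re_expr, group in self.random_terms:
            cols |= set(_re.findall(r"[A-Za-z_]\w*", re_expr))
            cols.add(group)
        return cols - {"1", "0", "C", "Sum"}


def _sum_code(expr: str, data: pd.DataFrame) -> str:
    """Wrap categorical column references in sum-to-zero coding."""
    cats = [
        c
        for c in data.columns
        if data[c].dtype == object
        or isinstance(data[c].dtype, pd.CategoricalDtype)
        or data[c].dtype == bool
    ]
    for c in cats:
        expr = _re.sub(rf"(?<![\w(]){c}(?![\w)])", f"C({c}, Sum)", expr)
    return expr


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    """A fitted mixed model plus the bookkeeping the ladder needs."""

    spec: ModelSpec
    converged: bool
    singular: bool
    aic: float
    llf: float
    k_params: int
    fe_params: pd.Series | None = None
    fe_cov: pd.DataFrame | None = None
    design_info: object = None
    result: object = None
    data: pd.DataFrame | None = None
    message: str = ""

    @property
    def usable(self) -> bool:
        return self.converged and not self.singular


def _is_singular(result, outcome_sd: float) -> bool:
    sd_floor = SINGULAR_SD_FRACTION * outcome_sd
    cov_re = np.atleast_2d(np.asarray(result.cov_re))
    if cov_re.size:
        sds = np.sqrt(np.clip(np.diag(cov_re), 0, None))
        if np.any(sds < sd_floor):
            return True
        if cov_re.shape[0] > 1:
            denom = np.outer(sds, sds)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = cov_re / denom
            off = corr[~np.eye(len(sds), dtype=bool)]
            if np.any(np.abs(off[np.isfinite(off)]) > SINGULAR_CORR):
                return True
    vcomp = np.asarray(result.vcomp)
    if vcomp.size and np.any(np.sqrt(np.clip(vcomp, 0, None)) < sd_floor):
        return True
    return False


def _check_full_rank(rhs: str, data: pd.DataFrame) -> None:
    """Raise if the fixed-effect design is rank deficient, naming the
    aliased term when one can be identified."""
    X = patsy.dmatrix(rhs, data, return_type="matrix")
    arr = np.asarray(X)
    full_rank = np.linalg.matrix_rank(arr)
    if full_rank == arr.shape[1]:
        return
    for name, sl in X.design_info.term_name_slices.items():
        others = np.ones(arr.shape[1], dtype=bool)
        others[sl] = False
        if np.linalg.matrix_rank(arr[:, others]) == full_rank:
            raise ValueError(f"term {name!r} is aliased (design is rank deficient)")
    raise ValueError("fixed-effect design matrix is rank deficient")


def fit_mixed_model(spec: ModelSpec | str, data: pd.DataFrame) -> FitResult:
    """Fit a linear mixed model by maximum likelihood.

    The first random term supplies the grouping factor (and, if present,
    random slopes with a full covariance); any further random terms must be
    intercept-only and are added as variance components within the grouping
    factor. Non-convergence is reported in the result, not raised.
    """
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    missing = spec.referenced_columns() - set(data.columns)
    if missing:
        raise ValueError(f"data lacks columns referenced by the model: {sorted(missing)}")
    for _, group in spec.random_terms:
        if data[group].nunique() < 2:
            raise ValueError(f"grouping factor {group!r} needs at least 2 levels")
    if data[list(spec.referenced_columns())].isna().any().any():
        raise ValueError("data contain missing values in referenced columns")

    fixed_rhs = " + ".join(spec.fixed_terms) if spec.fixed_terms else "1"
    fixed_formula = f"{spec.outcome} ~ {_sum_code(fixed_rhs, data)}"
    _check_full_rank(fixed_formula.split("~", 1)[1], data)

    re_expr, group = spec.random_terms[0]
    re_formula = None if re_expr == "1" else f"1 + {_sum_code(re_expr, data)}"
    vc_formula = {}
    for extra_expr, extra_group in spec.random_terms[1:]:
        if extra_expr != "1":
            raise ValueError(
                "only the first random term may carry slopes; "
                f"({extra_expr}|{extra_group}) is not intercept-only"
            )
        vc_formula[extra_group] = f"0 + C({extra_group})"

    outcome_sd = float(np.std(data[spec.outcome]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM.from_formula(
                fixed_formula,
                data,
                groups=data[group],
                re_formula=re_formula,
                vc_formula=vc_formula or None,
            )
            result = model.fit(reml=False, method=["bfgs", "powell"], maxiter=500)
    except Exception as exc:  # pragma: no cover - estimator pathologies
        return FitResult(
            spec, False, False, np.nan, np.nan, 0, message=f"fit failed: {exc}"
        )

    converged = bool(result.converged)
    singular = _is_singular(result, outcome_sd)
    k = int(result.df_modelwc)
    aic = float(2 * k - 2 * result.llf)
    k_fe = len(result.fe_params)
    fe_cov = pd.DataFrame(
        np.asarray(result.cov_params())[:k_fe, :k_fe],
        index=result.fe_params.index,
        columns=result.fe_params.index,
    )
    return FitResult(
        spec,
        converged,
        singular,
        aic,
        float(result.llf),
        k,
        fe_params=result.fe_params,
        fe_cov=fe_cov,
        design_info=model.data.design_info,
        result=result,
        data=data,
    )


def aic_ladder(candidates, data: pd.DataFrame):
    """Walk a simple-to-complex model ladder.

    A more complex candidate replaces the incumbent only if it converged,
    is not singular, and lowers the AIC by at least two. Returns
    ``(selected FitResult, trace)`` where the trace records each
    candidate's AIC and the decision taken.
    """
    specs = [ModelSpec(c) if isinstance(c, str) else c for c in candidates]
    if not specs:
        raise ValueError("no candidate models")
    best = fit_mixed_model(specs[0], data)
    if not best.usable:
        raise RuntimeError(
            f"first candidate failed ({best.message or 'singular or non-converged'})"
        )
    trace = [
        {"formula": specs[0].formula, "aic": best.aic, "decision": "baseline"}
    ]
    for spec in specs[1:]:
        fit = fit_mixed_model(spec, data)
        if not fit.converged:
            decision = "rejected: did not converge"
        elif fit.singular:
            decision = "rejected: singular fit"
        elif fit.aic <= best.aic - AIC_IMPROVEMENT:
            decision = "accepted"
            best = fit
        else:
            decision = "rejected: AIC improvement < 2"
        trace.append({"formula": spec.formula, "aic": fit.aic, "decision": decision})
    return best, trace


# --------------------------------------------------------------------------
# Inference on fitted models
# --------------------------------------------------------------------------

def wald_anova(fit: FitResult) -> pd.DataFrame:
    """Type-III analysis-of-deviance table (Wald chi-square per term).

    Fixed effects use sum-to-zero contrasts, so each term's chi-square
    tests its coefficients against zero in the presence of all others.
    """
    if not fit.converged:
        raise ValueError("cannot compute Wald table for a non-converged fit")
    beta = fit.fe_params.to_numpy()
    cov = fit.fe_cov.to_numpy()
    X = np.asarray(
        patsy.build_design_matrices([fit.design_info], fit.data)[0]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for name, sl in fit.design_info.term_name_slices.items():
            others = np.ones(X.shape[1], dtype=bool)
            others[sl] = False
            if np.linalg.matrix_rank(X[:, others]) == np.linalg.matrix_rank(X):
                raise ValueError(f"term {name!r} is aliased (design is rank deficient)")
        raise ValueError("design matrix is rank deficient")

    rows = []
    for name, sl in fit.design_info.term_name_slices.items():
        if name == "Intercept":
            continue
        idx = np.arange(*sl.indices(len(beta)))
        b = beta[idx]
        V = cov[np.ix_(idx, idx)]
        chi2 = float(b @ np.linalg.solve(V, b))
        df = len(idx)
        rows.append(
            {
                "term": name,
                "chi2": chi2,
                "df": df,
                "p": float(sstats.chi2.sf(chi2, df)),
            }
        )
    return pd.DataFrame(rows).set_index("term")


def _reference_grid(fit: FitResult) -> pd.DataFrame:
    cols = {}
    used = set()
    for term in fit.spec.fixed_terms:
        used |= set(_re.findall(r"[A-Za-z_]\w*", term))
    for c in fit.data.columns:
        if c not in used or c == fit.spec.outcome:
            continue
        col = fit.data[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            cols[c] = sorted(col.unique())
        else:
            cols[c] = [float(col.mean())]
    names = list(cols)
    grid = pd.DataFrame(list(product(*[cols[n] for n in names])), columns=names)
    return grid


def posthoc_contrasts(
    fit: FitResult,
    factor: str,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Pairwise estimated-marginal-mean differences over a factor's levels.

    Marginal means average model predictions over a balanced reference grid
    of the other fixed factors (numeric covariates at their means).
    ``correction`` is ``"bonferroni"`` or ``"fdr"`` (Benjamini-Hochberg
    step-up). p-values come from asymptotic z tests.
    """
    if correction not in ("bonferroni", "fdr"):
        raise ValueError("correction must be 'bonferroni' or 'fdr'")
    grid = _reference_grid(fit)
    if factor not in grid.columns:
        raise KeyError(f"factor {factor!r} is not in the model")
    beta = fit.fe_params.to_numpy()
    cov = fit.fe_cov.to_numpy()

    emm_rows = {}
    for level in sorted(fit.data[factor].unique()):
        sub = grid[grid[factor] == level]
        X = np.asarray(patsy.build_design_matrices([fit.design_info], sub)[0])
        emm_rows[level] = X.mean(axis=0)

    rows = []
    for a, b in combinations(sorted(emm_rows), 2):
        c = emm_rows[a] - emm_rows[b]
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        z = est / se if se > 0 else np.inf
        p = 2 * sstats.norm.sf(abs(z))
        rows.append({"contrast": f"{a} - {b}", "estimate": est, "se": se, "z": z, "p": p})
    table = pd.DataFrame(rows)
    method = "bonferroni" if correction == "bonferroni" else "fdr_bh"
    table["p_corrected"] = multipletests(table["p"], method=method)[1]
    return table
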