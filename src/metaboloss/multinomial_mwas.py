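"""Multinomial logistic metabolome-wide association screening.

The outcome is a four-level weight-change group (reference: weight stable)
and each metabolite is screened in its own model, adjusted for a declared
covariate set.  The fitter maximises the multinomial log-likelihood by
Newton-Raphson with step-halving; standard errors come from the inverse
observed information.  Multiplicity is controlled per contrast with the
Benjamini-Hochberg step-up rule.

Model
-----
For participant i with covariate row x_i and outcome category k among
{stable, gain, intentional_loss, unintentional_loss},

    log P(y_i = k) / P(y_i = stable) = x_i' b_k,    k != stable,

so each non-reference category carries its own coefficient vector.  A
metabolite enters as a standardized log peak area, and its coefficient is
the log-odds per 1 SD for that contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignSpec",
    "MultinomialFit",
    "SeparationError",
    "SingularDesignError",
    "COVARIATE_SETS",
    "CONTRASTS",
    "REFERENCE_GROUP",
    "Z_95",
    "build_design",
    "encode_outcome",
    "fit_multinomial",
    "wald_test",
    "bh_fdr",
    "screen_metabolites",
    "screen_stratified",
    "augmented_term_test",
]

REFERENCE_GROUP = "stable"
CONTRASTS = ("gain", "intentional_loss", "unintentional_loss")

#: normal quantile used for 95% confidence intervals
Z_95 = 1.959964

#: reference levels for categorical covariates (configurable per call)
DEFAULT_CATEGORICAL_REFS = {
    "race": "White",
    "sex": "men",
    "bmi_cat": "<25",
    "appetite": "very good",
    "walk_pace": "strolling",
}

#: named adjustment sets used by the screening stage
COVARIATE_SETS = {
    "M_min": ["age", "race", "sex"],
    "M_bmi": ["age", "race", "sex", "bmi_cat"],
}

_SEPARATION_BOUND = 15.0


class SingularDesignError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


class SeparationError(RuntimeError):
    """Quasi-complete separation detected (runaway coefficients)."""


@dataclass
class DesignSpec:
    """Declares the covariate design for one model.

    terms are column names of the cohort table; categorical columns are
    expanded to indicator columns against their reference level.  The
    metabolite term, when present, is appended last (optionally with a
    square term or an interaction with a modifier).
    """

    terms: list[str]
    categorical_refs: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORICAL_REFS)
    )
    outcome: str = "four_group"
    reference: str = REFERENCE_GROUP


@dataclass
class MultinomialFit:
    """A fitted multinomial logit: (K-1) x p coefficients vs the reference."""

    categories: list[str]  # reference first
    colnames: list[str]
    coef: np.ndarray  # (K-1, p)
    cov: np.ndarray  # ((K-1)p, (K-1)p), row-major by category then column
    loglik: float
    n_iter: int
    converged: bool
    ridge_used: bool
    n_obs: int
    grad_norm: float
    ll_trace: list[float] = field(default_factory=list)

    @property
    def contrasts(self) -> list[str]:
        return self.categories[1:]

    def _index(self, contrast: str, term: str) -> tuple[int, int]:
        k = self.contrasts.index(contrast)
        j = self.colnames.index(term)
        return k, j

    def coef_for(self, contrast: str, term: str) -> float:
        k, j = self._index(contrast, term)
        return float(self.coef[k, j])

    def se_for(self, contrast: str, term: str) -> float:
        k, j = self._index(contrast, term)
        p = len(self.colnames)
        return float(np.sqrt(self.cov[k * p + j, k * p + j]))


def _expand_categorical(series: pd.Series, ref: str) -> pd.DataFrame:
    levels = [lv for lv in pd.unique(series.dropna()) if lv != ref]
    levels.sort(key=str)
    out = {}
    for lv in levels:
        out[f"{series.name}[{lv}]"] = (series == lv).astype(float)
    df = pd.DataFrame(out, index=series.index)
    # preserve missingness: NA in the source -> NA in every indicator
    df[series.isna()] = np.nan
    return df


def build_design(
    df: pd.DataFrame,
    terms: list[str],
    categorical_refs: dict[str, str] | None = None,
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Expand covariate terms into a numeric design frame (no row dropping).

    Continuous columns pass through; object/categorical columns become
    indicator columns against the declared reference level.  Missing values
    propagate so callers can take complete cases per model.
    """
    refs = dict(DEFAULT_CATEGORICAL_REFS)
    if categorical_refs:
        refs.update(categorical_refs)
    parts = []
    if add_intercept:
        parts.append(pd.DataFrame({"(intercept)": 1.0}, index=df.index))
    for t in terms:
        if t not in df.columns:
            raise KeyError(f"covariate column {t!r} not in table")
        col = df[t]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            if t not in refs:
                raise KeyError(f"no reference level declared for categorical {t!r}")
            parts.append(_expand_categorical(col, refs[t]))
        elif col.dtype == bool:
            parts.append(col.astype(float).to_frame(t))
        else:
            parts.append(col.astype(float).to_frame(t))
    return pd.concat(parts, axis=1)


def encode_outcome(
    series: pd.Series, reference: str = REFERENCE_GROUP
) -> tuple[np.ndarray, list[str]]:
    """Integer-code an outcome with the reference category first."""
    present = list(pd.unique(series.dropna()))
    if reference not in present:
        raise ValueError(f"reference category {reference!r} absent from outcome")
    others = sorted((c for c in present if c != reference), key=str)
    categories = [reference] + others
    codes = series.map({c: i for i, c in enumerate(categories)}).to_numpy(float)
    return codes, categories


def _check_rank(X: np.ndarray, colnames: list[str]) -> None:
    if X.shape[0] < X.shape[1]:
        raise SingularDesignError(
            f"n={X.shape[0]} rows < p={X.shape[1]} columns"
        )
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [colnames[j] for j in np.where(diag <= tol)[0]]
    if bad:
        raise SingularDesignError(f"collinear design columns: {bad}")


def _softmax_probs(eta: np.ndarray) -> np.ndarray:
    """Category probabilities with an implicit zero column for the reference."""
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    np.exp(full, out=full)
    full /= full.sum(axis=1, keepdims=True)
    return full


def _penalized_loglik(
    P: np.ndarray, y: np.ndarray, B: np.ndarray, ridge: float, pen: np.ndarray
) -> float:
    ll = float(np.log(np.clip(P[np.arange(len(y)), y], 1e-300, None)).sum())
    if ridge > 0:
        ll -= 0.5 * ridge * float((B[:, pen] ** 2).sum())
    return ll


def fit_multinomial(
    y: np.ndarray,
    X: np.ndarray,
    categories: list[str] | None = None,
    colnames: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    ridge: float = 0.0,
    check_separation: bool = True,
) -> MultinomialFit:
    """Maximum-likelihood fit of a multinomial logit by Newton-Raphson.

    Parameters
    ----------
    y
        Integer outcome codes 0..K-1; 0 is the reference category.
    X
        n x p design matrix (include the intercept column explicitly).
    ridge
        Quadratic penalty on non-intercept coefficients; 0 for plain ML.
        A small ridge (1e-8) is the recommended fallback under separation.

    Newton steps are halved (up to 30 times) until the penalized
    log-likelihood does not decrease; convergence requires both a
    log-likelihood change below ``tol`` and a gradient sup-norm below 1e-6.
    """
    y = np.asarray(y, dtype=int)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    K = int(y.max()) + 1
    if categories is None:
        categories = [str(k) for k in range(K)]
    if colnames is None:
        colnames = [f"x{j}" for j in range(p)]
    if K < 2:
        raise ValueError("outcome has a single category")
    if (y == 0).sum() == 0:
        raise ValueError("reference category is empty")
    if n <= (K - 1) * p and ridge == 0:
        raise ValueError(
            f"n={n} does not exceed the {(K - 1) * p} free parameters"
        )
    _check_rank(X, colnames)

    pen = np.array(
        [not name.lower().startswith("(intercept") for name in colnames]
    )
    Y = np.zeros((n, K))
    Y[np.arange(n), y] = 1.0

    B = np.zeros((K - 1, p))
    P = _softmax_probs(X @ B.T)
    ll = _penalized_loglik(P, y, B, ridge, pen)
    ll_trace = [ll]
    converged = False
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # gradient: per category k>=1, X'(y_k - p_k), minus ridge term
        resid = Y[:, 1:] - P[:, 1:]  # n x (K-1)
        G = resid.T @ X  # (K-1) x p
        if ridge > 0:
            G[:, pen] -= ridge * B[:, pen]
        grad_norm = float(np.abs(G).max())
        # observed information, ((K-1)p)^2 in category-major blocks
        info = np.empty(((K - 1) * p, (K - 1) * p))
        for k in range(1, K):
            for l in range(k, K):
                w = P[:, k] * ((k == l) - P[:, l])
                blk = X.T @ (w[:, None] * X)
                info[(k - 1) * p:k * p, (l - 1) * p:l * p] = blk
                if l != k:
                    info[(l - 1) * p:l * p, (k - 1) * p:k * p] = blk
        if ridge > 0:
            ridx = np.concatenate(
                [np.where(pen)[0] + (k - 1) * p for k in range(1, K)]
            )
            info[ridx, ridx] += ridge
        try:
            step = np.linalg.solve(info, G.ravel()).reshape(K - 1, p)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, G.ravel(), rcond=None)[0].reshape(
                K - 1, p
            )
        # step-halving: shrink until the objective does not decrease
        scale = 1.0
        for _ in range(31):
            B_new = B + scale * step
            eta = X @ B_new.T
            if not np.all(np.isfinite(eta)):
                scale *= 0.5
                continue
            P_new = _softmax_probs(eta)
            ll_new = _penalized_loglik(P_new, y, B_new, ridge, pen)
            if ll_new >= ll - 1e-12 * max(1.0, abs(ll)):
                break
            scale *= 0.5
        else:
            B_new, P_new, ll_new = B, P, ll  # no improving step found
        delta = abs(ll_new - ll)
        B, P, ll = B_new, P_new, ll_new
        ll_trace.append(ll)
        resid = Y[:, 1:] - P[:, 1:]
        G = resid.T @ X
        if ridge > 0:
            G[:, pen] -= ridge * B[:, pen]
        grad_norm = float(np.abs(G).max())
        if delta < tol and grad_norm < 1e-6:
            converged = True
            break

    if check_separation and ridge == 0 and np.abs(B).max() > _SEPARATION_BOUND:
        raise SeparationError(
            "coefficients diverging (|b| > 15): likely quasi-complete "
            "separation; re-fit with a small ridge penalty (e.g. ridge=1e-8)"
        )

    # covariance from the (penalized) observed information at the optimum
    info = np.empty(((K - 1) * p, (K - 1) * p))
    for k in range(1, K):
        for l in range(k, K):
            w = P[:, k] * ((k == l) - P[:, l])
            blk = X.T @ (w[:, None] * X)
            info[(k - 1) * p:k * p, (l - 1) * p:l * p] = blk
            if l != k:
                info[(l - 1) * p:l * p, (k - 1) * p:k * p] = blk
    if ridge > 0:
        ridx = np.concatenate(
            [np.where(pen)[0] + (k - 1) * p for k in range(1, K)]
        )
        info[ridx, ridx] += ridge
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    cov = 0.5 * (cov + cov.T)

    return MultinomialFit(
        categories=list(categories),
        colnames=list(colnames),
        coef=B,
        cov=cov,
        loglik=float(ll),
        n_iter=it,
        converged=converged,
        ridge_used=ridge > 0,
        n_obs=n,
        grad_norm=grad_norm,
        ll_trace=ll_trace,
    )


def wald_test(fit: MultinomialFit, term: str, contrast: str) -> tuple[float, float]:
    """Wald z statistic and two-sided normal p for one coefficient."""
    if not fit.converged:
        raise RuntimeError("Wald test on a non-converged fit")
    if term not in fit.colnames:
        raise KeyError(f"term {term!r} not in design")
    b = fit.coef_for(contrast, term)
    se = fit.se_for(contrast, term)
    z = b / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted values and rejection flags.

    Rejects hypotheses 1..i* where i* is the largest i with
    p_(i) <= i*q/m; the adjusted value ("q-value") for p_(i) is
    min_{j>=i} m*p_(j)/j, capped at 1.  Output order matches input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="mergesort")  # stable: ties keep input order
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    thresh = np.arange(1, m + 1) * q / m
    passing = np.where(p[order] <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if len(passing):
        reject[order[: passing.max() + 1]] = True
    return adj, reject


def _complete_case_mask(frames: list[pd.DataFrame | pd.Series]) -> pd.Series:
    mask = None
    for f in frames:
        ok = f.notna() if isinstance(f, pd.Series) else f.notna().all(axis=1)
        mask = ok if mask is None else (mask & ok)
    return mask


def _fit_one(
    y: np.ndarray,
    X: np.ndarray,
    categories: list[str],
    colnames: list[str],
    ridge_fallback: float,
) -> MultinomialFit:
    try:
        return fit_multinomial(y, X, categories, colnames)
    except SeparationError:
        return fit_multinomial(
            y, X, categories, colnames, ridge=ridge_fallback
        )


def screen_metabolites(
    processed: pd.DataFrame,
    cohort: pd.DataFrame,
    covariate_set: str | list[str] = "M_bmi",
    subset: pd.Series | None = None,
    q: float = 0.05,
    fdr_family: str = "per_contrast",
    ridge_fallback: float = 1e-8,
    extra_terms: list[str] | None = None,
    outcome: str = "four_group",
    categorical_refs: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One multinomial model per metabolite; all contrasts vs weight stable.

    Parameters
    ----------
    processed
        Participants x metabolites matrix of standardized log peak areas
        (index aligned with ``cohort``).
    covariate_set
        A named set in :data:`COVARIATE_SETS` or an explicit list of
        covariate columns; ``extra_terms`` appends further columns (used by
        the attenuation stage for confounder blocks).
    subset
        Optional boolean mask restricting the analysis stratum.

    Returns a long table with one row per metabolite x contrast: n, beta
    (log-odds per SD), se, OR with 95% CI, Wald p, BH q and significance
    flags.  Estimation is complete-case for the model's variables.
    """
    if isinstance(covariate_set, str):
        terms = list(COVARIATE_SETS[covariate_set])
    else:
        terms = list(covariate_set)
    if extra_terms:
        terms = terms + [t for t in extra_terms if t not in terms]
    cohort = cohort.loc[cohort.index.intersection(processed.index)]
    design = build_design(cohort, terms, categorical_refs)
    frames = [design, cohort[outcome]]
    if subset is not None:
        frames.append(subset.map(lambda v: True if v else np.nan))
    mask = _complete_case_mask(frames)
    base = design.loc[mask]
    out = cohort.loc[mask, outcome]
    met = processed.loc[mask]

    rows = []
    for name in met.columns:
        zcol = met[name]
        ok = zcol.notna()
        ycodes, categories = encode_outcome(out[ok])
        keep = ~np.isnan(ycodes)
        X = np.column_stack([base[ok].to_numpy()[keep], zcol[ok].to_numpy()[keep]])
        colnames = list(base.columns) + ["metabolite"]
        fit = _fit_one(ycodes[keep].astype(int), X, categories, colnames,
                       ridge_fallback)
        for contrast in fit.contrasts:
            b = fit.coef_for(contrast, "metabolite")
            se = fit.se_for(contrast, "metabolite")
            z, p = wald_test(fit, "metabolite", contrast)
            rows.append(
                {
                    "metabolite": name,
                    "contrast": contrast,
                    "n": fit.n_obs,
                    "beta": b,
                    "se": se,
                    "or": np.exp(b),
                    "ci_low": np.exp(b - Z_95 * se),
                    "ci_high": np.exp(b + Z_95 * se),
                    "z": z,
                    "p": p,
                    "converged": fit.converged,
                    "ridge_used": fit.ridge_used,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = np.nan
    if fdr_family == "per_contrast":
        for contrast, idx in table.groupby("contrast").groups.items():
            adj, _ = bh_fdr(table.loc[idx, "p"].to_numpy(), q)
            table.loc[idx, "q"] = adj
    elif fdr_family == "pooled":
        adj, _ = bh_fdr(table["p"].to_numpy(), q)
        table["q"] = adj
    else:
        raise ValueError("fdr_family must be 'per_contrast' or 'pooled'")
    table["sig_p05"] = table["p"] < 0.05
    table["sig_fdr05"] = table["q"] <= q
    return table


def screen_stratified(
    processed: pd.DataFrame,
    cohort: pd.DataFrame,
    by: str,
    covariate_set: str | list[str] = "M_bmi",
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Run the screen within strata of ``by`` ('race_sex' or 'bmi').

    The stratifying variable (and its components) is removed from the
    adjustment set; strata missing an outcome category are skipped with a
    warning.
    """
    if isinstance(covariate_set, str):
        terms = list(COVARIATE_SETS[covariate_set])
    else:
        terms = list(covariate_set)
    if by == "race_sex":
        strata = cohort["race"].astype(str) + "/" + cohort["sex"].astype(str)
        drop = {"race", "sex"}
    elif by == "bmi":
        strata = cohort["bmi_cat"].astype(str)
        drop = {"bmi_cat"}
    else:
        raise ValueError("by must be 'race_sex' or 'bmi'")
    terms = [t for t in terms if t not in drop]
    out = {}
    for label in sorted(strata.dropna().unique()):
        mask = strata == label
        groups = cohort.loc[mask, kwargs.get("outcome", "four_group")]
        if groups.dropna().nunique() < len(CONTRASTS) + 1:
            warnings.warn(
                f"stratum {label!r} lacks an outcome category; skipped"
            )
            continue
        out[label] = screen_metabolites(
            processed, cohort, covariate_set=terms, subset=mask, **kwargs
        )
    return out


def augmented_term_test(
    processed: pd.DataFrame,
    cohort: pd.DataFrame,
    metabolite: str,
    kind: str,
    modifier: str | None = None,
    contrast: str = "unintentional_loss",
    covariate_set: str | list[str] = "M_bmi",
    ridge_fallback: float = 1e-8,
    categorical_refs: dict[str, str] | None = None,
) -> float:
    """Wald p for a square or interaction term added to the screening model.

    kind='square' adds metabolite^2; kind='interaction' adds
    metabolite x indicator(s) of the modifier (race, sex or bmi_cat) and
    tests the added coefficients jointly (chi-square with df = number of
    indicator columns) in the requested contrast equation.
    """
    if kind not in {"square", "interaction"}:
        raise ValueError("kind must be 'square' or 'interaction'")
    if isinstance(covariate_set, str):
        terms = list(COVARIATE_SETS[covariate_set])
    else:
        terms = list(covariate_set)
    cohort = cohort.loc[cohort.index.intersection(processed.index)]
    design = build_design(cohort, terms, categorical_refs)
    zcol = processed[metabolite]
    mask = _complete_case_mask([design, cohort["four_group"], zcol])
    base = design.loc[mask]
    z = zcol.loc[mask]
    extra = {}
    if kind == "square":
        extra["metabolite^2"] = z**2
    else:
        if modifier not in {"race", "sex", "bmi_cat"}:
            raise ValueError("modifier must be race, sex or bmi_cat")
        mod = cohort.loc[mask, modifier]
        if mod.nunique() < 2:
            raise ValueError(f"modifier {modifier!r} is constant: no contrast")
        refs = dict(DEFAULT_CATEGORICAL_REFS)
        if categorical_refs:
            refs.update(categorical_refs)
        ind = _expand_categorical(mod, refs[modifier])
        for c in ind.columns:
            extra[f"metabolite:{c}"] = z * ind[c]
    ycodes, categories = encode_outcome(cohort.loc[mask, "four_group"])
    keep = ~np.isnan(ycodes)
    cols = pd.concat(
        [base, z.rename("metabolite"), pd.DataFrame(extra, index=base.index)],
        axis=1,
    )
    X = cols.to_numpy()[keep]
    fit = _fit_one(
        ycodes[keep].astype(int), X, categories, list(cols.columns),
        ridge_fallback,
    )
    p_ = len(fit.colnames)
    k = fit.contrasts.index(contrast)
    idx = [k * p_ + fit.colnames.index(t) for t in extra]
    c = fit.coef.ravel()[idx]
    V = fit.cov[np.ix_(idx, idx)]
    stat = float(c @ np.linalg.solve(V, c))
    return float(stats.chi2.sf(stat, df=len(idx)))
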