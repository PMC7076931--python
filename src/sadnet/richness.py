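"""Explain richness from environmental covariates.

Covariate pruning by pairwise Pearson correlation, Gaussian or
negative-binomial regression (optionally with unpenalized natural cubic
spline terms of fixed df), stepwise model selection by AIC with forced
terms, and a best-model summary table.

The negative-binomial family uses a log link; its dispersion is estimated by
profile maximum likelihood (an outer 1-D optimization around IRLS fits with
fixed dispersion) and counts as a parameter in the AIC.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .io_tables import EnvTable

logger = logging.getLogger(__name__)

FAMILIES = ("gaussian", "negative_binomial")


# ---------------------------------------------------------------------------
# covariate pruning
# ---------------------------------------------------------------------------

def prune_covariates(env: EnvTable, r_threshold: float = 0.6
                     ) -> tuple[EnvTable, list[str]]:
    """Drop the later member of every covariate pair with |Pearson R| above
    ``r_threshold`` (strict), iterating columns in sorted order.  Constant
    columns are excluded (with a warning) before correlations are computed."""
    cols = sorted(env.data.columns)
    if len(cols) < 2:
        raise ValueError("pruning requires at least 2 numeric columns")
    removed: list[str] = []
    constant = [c for c in cols if env.data[c].nunique(dropna=True) <= 1]
    if constant:
        logger.warning("prune_covariates: excluding constant columns %s", constant)
        removed.extend(constant)
    keep: list[str] = []
    for col in cols:
        if col in removed:
            continue
        correlated = False
        for prior in keep:
            r = env.data[prior].corr(env.data[col])
            if np.isfinite(r) and abs(r) > r_threshold:
                correlated = True
                break
        if correlated:
            removed.append(col)
        else:
            keep.append(col)
    return EnvTable(env.data[keep].copy(), env.units), removed


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """One model term: a linear covariate, a fixed-df natural cubic spline of
    a covariate, or a categorical factor (dummy-coded)."""

    name: str
    kind: str = "linear"        # linear | spline | categorical
    df: int = 3

    def label(self) -> str:
        if self.kind == "spline":
            return f"s({self.name},df={self.df})"
        return self.name


def natural_cubic_basis(x: np.ndarray, df: int = 3,
                        knots: np.ndarray | None = None) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Boundary and interior knots sit at quantiles of ``x``; the basis is the
    standard truncated-power construction made linear beyond the boundaries.
    """
    x = np.asarray(x, dtype=np.float64)
    if df < 2:
        raise ValueError("spline df must be >= 2")
    if knots is None:
        probs = np.linspace(0, 1, df + 1)
        knots = np.quantile(x, probs)
        knots = np.unique(knots)
    if knots.size < 3:
        raise ValueError("not enough distinct knot positions for a spline")
    k = knots
    km = k[-1]

    def d(j):
        num = (np.maximum(x - k[j], 0.0) ** 3
               - np.maximum(x - km, 0.0) ** 3)
        return num / (km - k[j])

    cols = [x]
    for j in range(k.size - 2):
        cols.append(d(j) - d(k.size - 2))
    basis = np.column_stack(cols[:df])
    # standardize columns for numeric stability
    basis = (basis - basis.mean(axis=0)) / np.where(basis.std(axis=0) > 0,
                                                    basis.std(axis=0), 1.0)
    return basis


def build_design(env_data: pd.DataFrame, terms: list[Term]
                 ) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(env_data))]
    names = ["(Intercept)"]
    for term in terms:
        if term.kind == "linear":
            cols.append(env_data[term.name].to_numpy(dtype=np.float64))
            names.append(term.name)
        elif term.kind == "spline":
            basis = natural_cubic_basis(
                env_data[term.name].to_numpy(dtype=np.float64), term.df)
            for j in range(basis.shape[1]):
                cols.append(basis[:, j])
                names.append(f"s({term.name}).{j + 1}")
        elif term.kind == "categorical":
            levels = sorted(env_data[term.name].astype(str).unique())
            for lev in levels[1:]:
                cols.append((env_data[term.name].astype(str) == lev)
                            .to_numpy(dtype=np.float64))
                names.append(f"{term.name}[{lev}]")
        else:
            raise ValueError(f"unknown term kind {term.kind!r}")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    family: str
    terms: list[Term]
    coefficients: pd.Series
    log_lik: float
    aic: float
    null_deviance: float
    deviance: float
    deviance_explained: float
    pseudo_r2: float
    fitted: np.ndarray
    dispersion: float | None = None
    converged: bool = True

    @property
    def n_params(self) -> int:
        extra = 1  # gaussian sigma^2 or NB dispersion
        return len(self.coefficients) + extra


def fit_model(response, env: EnvTable, terms: list[Term],
              family: str = "gaussian") -> ModelFit:
    """Fit a Gaussian-identity or negative-binomial (log link) model.

    Gaussian deviance is the residual sum of squares; NB deviance is the GLM
    deviance at the profiled dispersion.  ``deviance_explained`` is
    1 - residual/null deviance, and ``pseudo_r2`` the squared Pearson
    correlation between response and fitted values.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    y = np.asarray(response, dtype=np.float64)
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains missing values")
    data = env.data
    if data.isna().to_numpy().any():
        raise ValueError("environment table contains missing values; filter rows first")
    design, names = build_design(data, terms)
    n, p = design.shape
    if n <= p:
        raise ValueError(f"n = {n} observations cannot support {p} coefficients")
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank} < {p}); collinear terms among "
            f"{[t.label() for t in terms]}")

    if family == "gaussian":
        model = sm.GLM(y, design, family=sm.families.Gaussian())
        res = model.fit()
        ll = float(res.llf)
        k = p + 1  # + sigma^2
        dispersion = float(res.scale)
        null_dev = float(np.sum((y - y.mean()) ** 2))
        dev = float(res.deviance)
    else:
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("negative-binomial family requires non-negative "
                             "integer response (round Chao1 first)")

        def negll(log_alpha: float) -> float:
            fam = sm.families.NegativeBinomial(alpha=math.exp(log_alpha))
            try:
                r = sm.GLM(y, design, family=fam).fit(maxiter=200)
            except Exception:
                return 1e12
            return -float(r.llf) if np.isfinite(r.llf) else 1e12

        opt = optimize.minimize_scalar(negll, bounds=(-10.0, 6.0),
                                       method="bounded",
                                       options={"xatol": 1e-6})
        alpha = math.exp(opt.x)
        fam = sm.families.NegativeBinomial(alpha=alpha)
        res = sm.GLM(y, design, family=fam).fit(maxiter=200)
        ll = float(res.llf)
        k = p + 1  # + dispersion
        dispersion = alpha
        null_res = sm.GLM(y, np.ones((n, 1)), family=fam).fit()
        null_dev = float(null_res.deviance)
        dev = float(res.deviance)

    fitted = np.asarray(res.fittedvalues, dtype=np.float64)
    dev_expl = 1.0 - dev / null_dev if null_dev > 0 else 0.0
    if np.std(fitted) > 0 and np.std(y) > 0:
        pseudo = float(np.corrcoef(y, fitted)[0, 1] ** 2)
    else:
        pseudo = 0.0
    return ModelFit(
        family=family, terms=list(terms),
        coefficients=pd.Series(res.params, index=names),
        log_lik=ll, aic=float(2 * k - 2 * ll),
        null_deviance=null_dev, deviance=dev,
        deviance_explained=float(np.clip(dev_expl, 0.0, 1.0)),
        pseudo_r2=pseudo, fitted=fitted, dispersion=dispersion,
        converged=bool(getattr(res, "converged", True)))


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    selected: ModelFit
    path: list[dict] = field(default_factory=list)
    forced_terms: list[Term] = field(default_factory=list)


def _candidate_moves(current: list[Term], pool: list[Term],
                     forced: set[str], direction: str,
                     allow_splines: bool, spline_df: int):
    labels = {t.label() for t in current}
    if direction in ("both", "backward"):
        for t in current:
            if t.name not in forced:
                yield ("drop", t, [u for u in current if u != t])
    if direction in ("both", "forward"):
        present = {t.name for t in current}
        for t in pool:
            if t.name not in present:
                yield ("add", t, current + [t])
    if allow_splines:
        for t in current:
            if t.kind == "linear" and t.name not in forced:
                swap = Term(t.name, "spline", spline_df)
                if swap.label() not in labels:
                    yield ("swap", swap,
                           [swap if u == t else u for u in current])
            elif t.kind == "spline":
                swap = Term(t.name, "linear")
                if swap.label() not in labels:
                    yield ("swap", swap,
                           [swap if u == t else u for u in current])


def stepwise_aic(response, env: EnvTable, family: str = "gaussian",
                 forced_terms: list[Term] | None = None,
                 direction: str = "both", allow_splines: bool = False,
                 spline_df: int = 3) -> StepwiseResult:
    """Stepwise AIC selection starting from the saturated model.

    Every round evaluates all single-term drops and adds (and, when
    ``allow_splines``, linear<->spline(df) swaps); the move with the lowest
    AIC is accepted if it improves the current AIC by more than 1e-10, with
    ties broken toward fewer terms then lexicographically.  Forced terms are
    never dropped.
    """
    if direction not in ("both", "forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    forced_terms = list(forced_terms or [])
    forced_names = {t.name for t in forced_terms}
    pool = [Term(c) for c in sorted(env.data.columns)
            if c not in forced_names]
    current = forced_terms + pool
    fit = fit_model(response, env, current, family)
    path = [{"action": "start", "term": None,
             "model": [t.label() for t in current], "aic": fit.aic}]
    while True:
        best_move = None
        for action, term, terms in _candidate_moves(
                current, pool, forced_names, direction, allow_splines, spline_df):
            try:
                cand = fit_model(response, env, terms, family)
            except (ValueError, np.linalg.LinAlgError):
                continue
            key = (cand.aic, len(terms), tuple(sorted(t.label() for t in terms)))
            if best_move is None or key < best_move[0]:
                best_move = (key, action, term, terms, cand)
        if best_move is None:
            break
        _, action, term, terms, cand = best_move
        if cand.aic < fit.aic - 1e-10:
            current, fit = terms, cand
            path.append({"action": action, "term": term.label(),
                         "model": [t.label() for t in current], "aic": fit.aic})
        else:
            break
    return StepwiseResult(selected=fit, path=path, forced_terms=forced_terms)


def add_factor(env: EnvTable, name: str, values) -> tuple[EnvTable, Term]:
    """Attach a categorical column (e.g. region) and return its forced Term.

    The column is stored label-encoded so the EnvTable stays numeric; the
    Term carries the categorical kind so the design matrix dummy-codes it.
    """
    series = pd.Series(values, index=env.data.index).astype(str)
    codes = pd.Categorical(series).codes.astype(np.float64)
    data = env.data.copy()
    data[name] = codes
    return EnvTable(data, env.units), Term(name, "categorical")


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def summarize_best_models(results: dict[str, StepwiseResult]) -> pd.DataFrame:
    """Per-domain best-model summary: ordered predictors, family, R^2 and
    percent deviance explained."""
    rows = []
    max_terms = max((len(r.selected.terms) for r in results.values()), default=0)
    for domain in sorted(results):
        sel = results[domain].selected
        row = {"response": f"{domain} Chao1"}
        labels = [t.label() for t in sel.terms]
        for i in range(max_terms):
            row[f"predictor_{i + 1}"] = labels[i] if i < len(labels) else ""
        row["distribution"] = ("Negative binomial"
                               if sel.family == "negative_binomial" else "Gaussian")
        row["r_squared"] = round(sel.pseudo_r2, 3)
        row["deviance_explained_pct"] = round(100.0 * sel.deviance_explained, 2)
        rows.append(row)
    return pd.DataFrame(rows)
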