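"""Decomposition of the Erreygers-corrected index into covariate contributions.

A binary utilisation outcome ``y`` is modelled with a weighted probit,
``E(y | x) = Phi(b0 + sum_j b_j x_j)``.  The nonlinear model is linearised by
replacing each latent coefficient with a partial effect ``beta_j^m``:

* continuous covariates — the average over the sample of the per-observation
  derivative ``b_j * phi(eta_i)``;
* binary covariates — the per-observation discrete change of the fitted
  probability when ``x_j`` flips 0 -> 1 holding everything else at observed
  values, averaged over the subgroup that actually has ``x_j = 1`` (so the
  effect of, say, female sex is the mean effect among women).  The
  conventional average over everyone is computed alongside for comparison.

With the linearised model ``y = beta0 + sum_j beta_j^m x_j + e``, the
Erreygers index splits into covariate contributions

    E(h) = 4 [ sum_j beta_j^m GC(x_j) + GC(e) ],

where ``GC(x) = x_bar C(x) = 2 cov_w(x, R)`` is the generalized concentration
index of the covariate.  Each contribution ``4 beta_j^m GC(x_j)`` is the
product of how strongly the covariate moves the outcome and how unequally the
covariate itself is distributed over income.  The residual term is defined by
closure (``E(h)`` minus the explained sum), so additivity holds exactly; the
separately computed ``4 GC(e)`` is kept as a diagnostic.

Covariates carry Andersen-framework role tags — predisposing (age, sex,
race, employment), enabling (income, education, insurance, region) and need
(health status, chronic disease) — and contributions can be aggregated by
role.  Shares (contribution / E(h)) may legitimately exceed 100% or be
negative; they are suppressed, with contributions still reported, when |E(h)|
falls below a configurable floor to guard against division blow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    AlignmentError,
    ConvergenceError,
    SeparationError,
)
from .concentration import OutcomeBounds, erreygers_index
from .ranking import RankedSample

__all__ = [
    "CovariateDesign",
    "ProbitFit",
    "PartialEffects",
    "DecompositionTable",
    "fit_probit",
    "partial_effects",
    "generalized_concentration",
    "decompose",
    "contribution_shares",
]

ROLES = ("predisposing", "enabling", "need")


@dataclass
class CovariateDesign:
    """Design matrix with Andersen role tags.

    ``matrix`` holds the non-constant columns; an intercept is appended at fit
    time when ``intercept`` is True.  Categorical covariates must already be
    expanded to indicator columns (see :meth:`from_frame`), with the reference
    level excluded.
    """

    matrix: np.ndarray
    names: list
    roles: dict
    kinds: dict  # name -> "binary" | "continuous"
    intercept: bool = True

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim == 1:
            self.matrix = self.matrix[:, None]
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("design matrix width does not match the name list")
        if len(set(self.names)) != len(self.names):
            raise ValueError("covariate names must be unique")
        for name in self.names:
            if self.roles.get(name) not in ROLES:
                raise ValueError(
                    f"covariate {name!r} must carry an Andersen role in {ROLES}"
                )
        for j, name in enumerate(self.names):
            col = self.matrix[:, j]
            if self.matrix.shape[0] > 1 and np.all(col == col[0]):
                raise ValueError(
                    f"covariate {name!r} is constant; constants belong to the intercept"
                )
            if name not in self.kinds:
                vals = np.unique(col)
                self.kinds[name] = (
                    "binary" if np.isin(vals, (0.0, 1.0)).all() else "continuous"
                )

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        columns,
        roles: dict,
        categorical: Optional[dict] = None,
        intercept: bool = True,
    ) -> "CovariateDesign":
        """Build a design from DataFrame columns.

        ``categorical`` maps a column name to its reference level; the column
        is expanded to one indicator per remaining level, named
        ``column[level]``, each inheriting the column's role.
        """
        categorical = categorical or {}
        mats, names, out_roles, kinds = [], [], {}, {}
        for col in columns:
            if col not in df.columns:
                raise KeyError(f"covariate column {col!r} not found in data")
            if col in categorical:
                ref = categorical[col]
                levels = [lv for lv in pd.unique(df[col]) if lv != ref]
                if ref not in set(pd.unique(df[col])):
                    raise ValueError(
                        f"reference level {ref!r} absent from column {col!r}"
                    )
                for lv in sorted(map(str, levels)):
                    name = f"{col}[{lv}]"
                    mats.append((df[col].astype(str) == lv).to_numpy(float))
                    names.append(name)
                    out_roles[name] = roles[col]
                    kinds[name] = "binary"
            else:
                mats.append(df[col].to_numpy(float))
                names.append(col)
                out_roles[col] = roles[col]
        return cls(
            matrix=np.column_stack(mats) if mats else np.empty((len(df), 0)),
            names=names,
            roles=out_roles,
            kinds=kinds,
            intercept=intercept,
        )

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def full_matrix(self) -> np.ndarray:
        if self.intercept:
            return np.column_stack([np.ones(self.n), self.matrix])
        return self.matrix


@dataclass
class ProbitFit:
    """A converged weighted probit fit on the latent scale."""

    coefficients: pd.Series  # includes "intercept" when present
    converged: bool
    log_likelihood: float
    fitted_probabilities: np.ndarray
    design: CovariateDesign
    weights: np.ndarray


@dataclass
class PartialEffects:
    """Per-observation and averaged partial effects of every covariate."""

    per_observation: dict
    effects: dict  # beta_j^m under the chosen (paper-style) averaging rule
    overall_effects: dict  # conventional average marginal effects
    averaging_rule: dict  # name -> "subgroup_mean" | "overall_mean"


@dataclass
class DecompositionTable:
    """Covariate contributions to the Erreygers index, closing to E(h)."""

    table: pd.DataFrame  # rows per covariate: beta_m, gc, contribution, share, role
    residual_contribution: float
    residual_gc_diagnostic: float
    total_index: float
    role_subtotals: pd.DataFrame
    shares_suppressed: bool = False
    share_floor: float = 0.01


def fit_probit(y, design: CovariateDesign, weights) -> ProbitFit:
    """Weighted maximum-likelihood probit of a binary outcome on the design.

    Raises :class:`SeparationError` naming the offending covariate when the
    likelihood is degenerate, and :class:`ConvergenceError` with the iteration
    trace when IRLS fails to converge.  Rank-deficient designs are rejected.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.shape[0] != design.n or w.shape[0] != design.n:
        raise AlignmentError("outcome, weights and design must be aligned")
    if not np.isin(np.unique(y), (0.0, 1.0)).all():
        raise ValueError("probit outcome must be binary 0/1")
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")

    X = design.full_matrix()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "design is rank-deficient (collinear columns) — "
            f"rank {rank} < {X.shape[1]} columns"
        )

    model = sm.GLM(
        y,
        X,
        family=sm.families.Binomial(link=sm.families.links.Probit()),
        var_weights=w,
    )
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    separated = False
    with np.errstate(all="ignore"), _warnings.catch_warnings(record=True) as rec:
        _warnings.simplefilter("always")
        try:
            res = model.fit(maxiter=200)
        except Exception as exc:  # statsmodels raises on hard separation
            raise SeparationError(f"probit fit failed: {exc}") from exc
        separated = any(
            issubclass(w.category, PerfectSeparationWarning) for w in rec
        )

    params = np.asarray(res.params, dtype=float)
    names = (["intercept"] if design.intercept else []) + list(design.names)
    slope_params = params[1:] if design.intercept else params
    # separation: flagged by the optimiser, or runaway latent coefficients
    if slope_params.size and (separated or np.max(np.abs(slope_params)) > 50.0):
        worst = design.names[int(np.argmax(np.abs(slope_params)))]
        raise SeparationError(
            f"covariate {worst!r} appears to perfectly separate the outcome "
            f"(latent coefficient {np.max(np.abs(slope_params)):.1f})"
        )
    if not res.converged:
        raise ConvergenceError(
            f"probit IRLS did not converge in {res.fit_history['iteration']} "
            f"iterations; deviance trace: {res.fit_history.get('deviance')}"
        )

    fitted = np.asarray(res.predict(X), dtype=float)
    fitted = np.clip(fitted, np.finfo(float).tiny, 1.0 - 1e-16)
    return ProbitFit(
        coefficients=pd.Series(params, index=names),
        converged=bool(res.converged),
        log_likelihood=float(res.llf),
        fitted_probabilities=fitted,
        design=design,
        weights=w,
    )


def partial_effects(fit: ProbitFit, design: Optional[CovariateDesign] = None) -> PartialEffects:
    """Per-observation partial effects and their averages ``beta_j^m``.

    Continuous covariates use the derivative ``b_j phi(eta_i)`` averaged over
    all observations.  Binary covariates use the discrete 0 -> 1 change in the
    fitted probability averaged over the subgroup holding the attribute
    (``subgroup_mean``); the overall average is stored alongside.  All
    averages are survey-weighted.
    """
    design = design or fit.design
    if design.names != fit.design.names:
        missing = set(design.names) - set(fit.design.names)
        raise KeyError(f"covariates absent from the fit: {sorted(missing)}")
    X = design.matrix
    w = fit.weights
    wn = w / w.sum()
    b = fit.coefficients
    eta = design.full_matrix() @ b.to_numpy()

    per_obs, eff, overall, rule = {}, {}, {}, {}
    for j, name in enumerate(design.names):
        bj = float(b[name])
        if design.kinds[name] == "continuous":
            pe = bj * stats.norm.pdf(eta)
            per_obs[name] = pe
            eff[name] = float(np.sum(wn * pe))
            overall[name] = eff[name]
            rule[name] = "overall_mean"
        else:
            x = X[:, j]
            pe = stats.norm.cdf(eta + bj * (1.0 - x)) - stats.norm.cdf(eta - bj * x)
            per_obs[name] = pe
            overall[name] = float(np.sum(wn * pe))
            mask = x == 1.0
            if mask.any():
                eff[name] = float(np.sum(w[mask] * pe[mask]) / np.sum(w[mask]))
                rule[name] = "subgroup_mean"
            else:
                eff[name] = overall[name]
                rule[name] = "overall_mean"
    return PartialEffects(
        per_observation=per_obs,
        effects=eff,
        overall_effects=overall,
        averaging_rule=rule,
    )


def generalized_concentration(x_j, ranked: RankedSample, weights) -> float:
    """Generalized concentration index ``GC(x) = x_bar C(x) = 2 cov_w(x, R)``.

    The covariance form is valid for covariates of any sign (including
    centred or negative-valued ones, where ``C(x)`` itself is undefined).
    """
    x = np.asarray(x_j, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape[0] != ranked.n or w.shape[0] != ranked.n:
        raise AlignmentError("covariate, weights and ranks must be aligned")
    wn = w / w.sum()
    xbar = np.sum(wn * x)
    return 2.0 * float(np.sum(wn * (x - xbar) * (ranked.ranks - 0.5)))


def decompose(
    h,
    design: CovariateDesign,
    ranked: RankedSample,
    weights,
    averaging: str = "subgroup",
    share_floor: float = 0.01,
    bounds: OutcomeBounds = OutcomeBounds(),
) -> DecompositionTable:
    """Decompose the Erreygers index of a binary outcome over the design.

    ``averaging`` selects the partial-effect rule for binary covariates:
    ``"subgroup"`` (mean effect within the attribute-holding subgroup, the
    default) or ``"overall"`` (conventional average marginal effect).

    The residual is defined by closure, ``E(h) - sum_j contribution_j``, so
    the additivity identity holds to machine precision on every input; the
    independently computed ``4 GC(e)`` of the linear-approximation error is
    reported as a diagnostic.
    """
    if averaging not in ("subgroup", "overall"):
        raise ValueError("averaging must be 'subgroup' or 'overall'")
    h = np.asarray(h, dtype=float)
    w = np.asarray(weights, dtype=float)
    total = erreygers_index(h, ranked, w, bounds).value

    fit = fit_probit(h, design, w)
    pe = partial_effects(fit)
    beta_m = pe.effects if averaging == "subgroup" else pe.overall_effects

    rows = []
    wn = w / w.sum()
    for j, name in enumerate(design.names):
        x = design.matrix[:, j]
        gc = generalized_concentration(x, ranked, w)
        contribution = 4.0 * beta_m[name] * gc
        rows.append(
            {
                "covariate": name,
                "role": design.roles[name],
                "beta_m": beta_m[name],
                "averaging_rule": pe.averaging_rule[name]
                if averaging == "subgroup"
                else "overall_mean",
                "gc": gc,
                "contribution": contribution,
            }
        )
    table = pd.DataFrame(rows).set_index("covariate") if rows else pd.DataFrame(
        columns=["role", "beta_m", "averaging_rule", "gc", "contribution"]
    )
    explained = float(table["contribution"].sum()) if len(table) else 0.0
    residual = total - explained

    # diagnostic: GC of the linear-approximation error, computed directly
    beta_vec = np.array([beta_m[n] for n in design.names])
    linear_pred = design.matrix @ beta_vec if design.k else np.zeros_like(h)
    beta0 = float(np.sum(wn * h) - np.sum(wn * linear_pred))
    e = h - (beta0 + linear_pred)
    residual_gc = 4.0 * generalized_concentration(e, ranked, w)

    suppressed = abs(total) < share_floor
    if len(table):
        table["share"] = np.nan if suppressed else table["contribution"] / total

    if len(table):
        sub = table.groupby("role", sort=True)["contribution"].sum().to_frame()
        if not suppressed:
            sub["share"] = sub["contribution"] / total
    else:
        sub = pd.DataFrame(columns=["contribution", "share"])

    return DecompositionTable(
        table=table,
        residual_contribution=residual,
        residual_gc_diagnostic=residual_gc,
        total_index=total,
        role_subtotals=sub,
        shares_suppressed=suppressed,
        share_floor=share_floor,
    )


def contribution_shares(
    table: DecompositionTable, grouping: str = "covariate"
) -> pd.DataFrame:
    """Contribution shares relative to E(h), by covariate or Andersen role.

    Shares are fractions of the total index; they may exceed 1 or be negative
    when contributions of opposite sign offset.  A residual row closes the
    sum to 1.
    """
    if table.shares_suppressed:
        raise ValueError(
            f"shares suppressed: |E(h)| = {abs(table.total_index):.4g} is below "
            f"the floor {table.share_floor}; use the raw contributions instead"
        )
    if grouping == "covariate":
        out = table.table[["role", "contribution", "share"]].copy()
        out.loc["residual"] = {
            "role": "residual",
            "contribution": table.residual_contribution,
            "share": table.residual_contribution / table.total_index,
        }
        return out
    if grouping == "role":
        out = table.role_subtotals.copy()
        out.loc["residual"] = {
            "contribution": table.residual_contribution,
            "share": table.residual_contribution / table.total_index,
        }
        return out
    raise ValueError("grouping must be 'covariate' or 'role'")
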