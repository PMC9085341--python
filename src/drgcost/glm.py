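"""Multivariable gamma regression of hospitalisation cost with a log link.

The model is E[cost | x] = exp(x'beta) with gamma-distributed errors and a
constant shape, the standard choice for strictly positive, right-skewed
cost data.  Exponentiated coefficients are *cost ratios* (CR): the
multiplicative effect of a factor level on expected cost relative to that
factor's reference level.  Dispersion is estimated by Pearson chi-square
over residual degrees of freedom; confidence intervals are Wald intervals
on the log scale, exponentiated.

Marginal means are response-scale predictions averaged over a balanced grid
of all other factors (equal weight per level combination).  Under the log
link this makes the ratio of a level's marginal mean to its reference's
marginal mean equal that level's CR exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ConfigurationError, ConvergenceError, InputError, SingularityError

__all__ = ["ModelSpec", "GammaFit", "GammaCostModel", "fit_gamma", "marginal_means"]

#: factor -> reference level of the default cost model.
DEFAULT_FACTORS: dict[str, str] = {
    "sex": "female",
    "age_band": "0-17",
    "social_insurance": "yes",
    "admission_route": "outpatient_other",
    "cc_level": "NonCC",
    "long_stay": "no",
    "discharge_mode": "home",
}

_LEVEL_ORDERS = {
    "sex": ("female", "male"),
    "age_band": ("0-17", "18-65", ">65"),
    "social_insurance": ("yes", "no"),
    "admission_route": ("outpatient_other", "emergency"),
    "cc_level": ("NonCC", "CC", "MCC"),
    "long_stay": ("no", "yes"),
    "discharge_mode": ("home", "transfer", "death", "other"),
}

@dataclass(frozen=True)
class ModelSpec:
    """Factors and reference levels of the cost model."""

    factors: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_FACTORS))
    response: str = "total_cost"

    def validate(self, frame: pd.DataFrame) -> None:
        for factor, ref in self.factors.items():
            if factor not in frame.columns:
                raise ConfigurationError(f"factor {factor!r} not in cohort")
            observed = set(_categorical(frame[factor]).unique())
            if ref not in observed:
                raise ConfigurationError(
                    f"reference level {ref!r} of {factor!r} not observed"
                )


def _categorical(col: pd.Series) -> pd.Series:
    """Booleans become no/yes strings; everything else is stringified."""
    if col.dtype == bool:
        return col.map({False: "no", True: "yes"})
    return col.astype(str)


def _level_order(factor: str, observed: Sequence[str], ref: str) -> list[str]:
    order = _LEVEL_ORDERS.get(factor, tuple(sorted(observed)))
    levels = [lv for lv in order if lv in observed]
    levels += [lv for lv in observed if lv not in levels]
    if ref in levels:
        levels.remove(ref)
    return [ref] + levels


def _build_design(
    frame: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Treatment-coded design matrix with an intercept; returns the matrix
    and the per-factor observed level order (reference first)."""
    n = len(frame)
    cols: dict[str, np.ndarray] = {"const": np.ones(n)}
    level_orders: dict[str, list[str]] = {}
    for factor, ref in spec.factors.items():
        series = _categorical(frame[factor])
        observed = list(pd.unique(series))
        levels = _level_order(factor, observed, ref)
        level_orders[factor] = levels
        for lv in levels[1:]:
            cols[f"{factor}[{lv}]"] = (series == lv).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=frame.index)
    for name in X.columns[1:]:
        if X[name].std() == 0:
            raise SingularityError(f"degenerate (constant) column {name!r}", name)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularityError("collinear design matrix")
    return X, level_orders


@dataclass
class GammaFit:
    """Fitted log-link gamma regression, report-ready.

    ``table`` has one row per factor level (reference rows included with
    CR = 1): marginal mean, difference to the reference's marginal mean,
    cost ratio with 95% Wald CI, and p-value.
    """

    params: pd.Series
    bse: pd.Series
    dispersion: float
    table: pd.DataFrame
    converged: bool
    n_iter: int
    model: "GammaCostModel"

    def cost_ratio(self, factor: str, level: str) -> float:
        return float(self.table.loc[(factor, level), "cost_ratio"])

    def cost_ratio_ci(self, factor: str, level: str) -> tuple[float, float]:
        row = self.table.loc[(factor, level)]
        return float(row["ci_low"]), float(row["ci_high"])

    def marginal_mean(self, factor: str, level: str) -> float:
        return float(self.table.loc[(factor, level), "marginal_mean"])


class GammaCostModel(BaseEstimator, RegressorMixin):
    """Log-link gamma GLM of cost on categorical factors (sklearn estimator).

    Parameters
    ----------
    spec : ModelSpec or None
        Factors with reference levels; defaults to the standard cost model.
    tol, max_iter : IRLS convergence control.
    """

    def __init__(self, spec: ModelSpec | None = None, tol: float = 1e-8,
                 max_iter: int = 100):
        self.spec = spec
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y: Sequence[float] | None = None):
        spec = self.spec if self.spec is not None else ModelSpec()
        if y is None:
            if spec.response not in X.columns:
                raise ConfigurationError(f"response {spec.response!r} not in data")
            y = X[spec.response]
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            raise InputError("costs must be strictly positive for a gamma model")
        spec.validate(X)
        design, level_orders = _build_design(X, spec)
        glm = sm.GLM(y, design, family=sm.families.Gamma(sm.families.links.Log()))
        res = glm.fit(maxiter=self.max_iter, tol=self.tol, scale="X2")
        if not getattr(res, "converged", True):
            raise ConvergenceError(
                f"IRLS did not converge in {self.max_iter} iterations",
                trace=res.fit_history.get("deviance"),
            )
        self.spec_ = spec
        self.level_orders_ = level_orders
        self.result_ = res
        self.params_ = res.params
        self.bse_ = res.bse
        self.dispersion_ = float(res.scale)
        self.n_iter_ = len(res.fit_history.get("deviance", [])) or self.max_iter
        self.n_obs_ = len(y)
        self.feature_names_in_ = list(design.columns)
        return self

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise InputError("model is not fitted")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Expected cost on the response scale."""
        self._check_fitted()
        n = len(X)
        cols = {"const": np.ones(n)}
        for factor, levels in self.level_orders_.items():
            series = _categorical(X[factor])
            for lv in levels[1:]:
                cols[f"{factor}[{lv}]"] = (series == lv).to_numpy(dtype=float)
        design = pd.DataFrame(cols, index=X.index)[self.feature_names_in_]
        return np.asarray(self.result_.predict(design))

    # -- reporting ---------------------------------------------------------
    def _balanced_grid(self) -> pd.DataFrame:
        factors = list(self.level_orders_)
        combos = itertools.product(*(self.level_orders_[f] for f in factors))
        return pd.DataFrame(list(combos), columns=factors)

    def marginal_means(self) -> pd.Series:
        """Balanced-grid (equal weight per combination) marginal means."""
        self._check_fitted()
        grid = self._balanced_grid()
        pred = self.predict(grid)
        out = {}
        for factor, levels in self.level_orders_.items():
            for lv in levels:
                out[(factor, lv)] = float(pred[(grid[factor] == lv).to_numpy()].mean())
        return pd.Series(out)

    def summary_table(self) -> pd.DataFrame:
        """Report table: marginal mean, difference, CR, 95% CI, p per level."""
        self._check_fitted()
        mm = self.marginal_means()
        conf = self.result_.conf_int(alpha=0.05)
        rows = []
        for factor, levels in self.level_orders_.items():
            ref = levels[0]
            for lv in levels:
                if lv == ref:
                    rows.append({
                        "factor": factor, "level": lv, "is_ref": True,
                        "marginal_mean": mm[(factor, lv)],
                        "difference": 0.0, "cost_ratio": 1.0,
                        "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                    })
                else:
                    name = f"{factor}[{lv}]"
                    beta = float(self.params_[name])
                    lo, hi = conf.loc[name]
                    rows.append({
                        "factor": factor, "level": lv, "is_ref": False,
                        "marginal_mean": mm[(factor, lv)],
                        "difference": mm[(factor, lv)] - mm[(factor, ref)],
                        "cost_ratio": float(np.exp(beta)),
                        "ci_low": float(np.exp(lo)), "ci_high": float(np.exp(hi)),
                        "p_value": float(self.result_.pvalues[name]),
                    })
        columns = ["factor", "level", "is_ref", "marginal_mean", "difference",
                   "cost_ratio", "ci_low", "ci_high", "p_value"]
        return pd.DataFrame(rows, columns=columns).set_index(["factor", "level"])


def fit_gamma(
    cohort: pd.DataFrame,
    spec: ModelSpec | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GammaFit:
    """Fit the cost model and return the report-ready :class:`GammaFit`."""
    model = GammaCostModel(spec=spec, tol=tol, max_iter=max_iter).fit(cohort)
    return GammaFit(
        params=model.params_,
        bse=model.bse_,
        dispersion=model.dispersion_,
        table=model.summary_table(),
        converged=True,
        n_iter=model.n_iter_,
        model=model,
    )


def marginal_means(fit: GammaFit) -> pd.Series:
    """Per-level balanced-grid marginal means of a converged fit."""
    return fit.model.marginal_means()
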