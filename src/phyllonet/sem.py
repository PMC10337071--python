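"""Observed-variable path analysis (covariance-based SEM).

Fits recursive path models among observed variables by maximum-likelihood
covariance fitting: minimize

    F(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

where S is the sample covariance and Sigma(theta) the model-implied
covariance of a linear system  eta = B eta + Gamma xi + zeta  with free
exogenous covariances Phi and diagonal residual covariances Psi.  Fit is
judged by chi^2 = (n-1) F_min, CFI against the independence baseline, and
RMSEA.  Inputs are z-scored by default so path estimates are standardized
effects.

The prior model for the saponin analysis is
``Saponins ~ Env + Modules; Modules ~ Env`` — environment acts on the
module eigengenes and on total saponin, and the modules act on saponin
directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["PathModel", "PathResults", "fit_path_model"]

_BIG = 1e12


def _parse_formulas(formulas) -> list[tuple[str, list[str]]]:
    if isinstance(formulas, str):
        formulas = [f for f in formulas.split(";") if f.strip()]
    parsed = []
    for f in formulas:
        lhs, rhs = f.split("~")
        terms = [t.strip() for t in rhs.split("+") if t.strip()]
        parsed.append((lhs.strip(), terms))
    return parsed


class PathModel:
    """Recursive path model over observed variables.

    Parameters
    ----------
    formulas : str or list of str
        Regression equations, e.g. ``"Sap ~ pH + M2; M2 ~ pH"``.
    data : DataFrame
        Per-sample observations of every named variable.
    standardize : bool
        z-score columns before fitting (default), making estimates
        standardized path coefficients.
    """

    def __init__(self, formulas, data: pd.DataFrame, standardize: bool = True):
        self.equations = _parse_formulas(formulas)
        endo = [lhs for lhs, _ in self.equations]
        if len(set(endo)) != len(endo):
            raise ValueError("duplicate endogenous variable")
        rhs_vars = [v for _, terms in self.equations for v in terms]
        exo = sorted(set(rhs_vars) - set(endo))
        self.endo = endo
        self.exo = exo
        self.variables = endo + exo
        missing = [v for v in self.variables if v not in data.columns]
        if missing:
            raise ValueError(f"variables absent from data: {missing}")
        x = data[self.variables].to_numpy(dtype=float)
        if standardize:
            sd = x.std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise ValueError("constant variable cannot be standardized")
            x = (x - x.mean(axis=0)) / sd
        self.n = x.shape[0]
        self.S = np.cov(x, rowvar=False, ddof=1)
        sign, _ = np.linalg.slogdet(self.S)
        if sign <= 0:
            raise ValueError(
                "sample covariance is not positive definite "
                f"(condition number {np.linalg.cond(self.S):.3g})"
            )
        self._data = x
        self._index_params()

    @classmethod
    def from_formula(cls, formulas, data: pd.DataFrame, **kw) -> "PathModel":
        return cls(formulas, data, **kw)

    # -- parameter bookkeeping ------------------------------------------------
    def _index_params(self) -> None:
        self.param_names: list[str] = []
        self._beta_idx: list[tuple[int, int, int]] = []  # (param, row, col) in B
        self._gamma_idx: list[tuple[int, int, int]] = []
        ne, nx_ = len(self.endo), len(self.exo)
        k = 0
        for i, (lhs, terms) in enumerate(self.equations):
            for t in terms:
                if t in self.endo:
                    self._beta_idx.append((k, i, self.endo.index(t)))
                else:
                    self._gamma_idx.append((k, i, self.exo.index(t)))
                self.param_names.append(f"{lhs} ~ {t}")
                k += 1
        self._psi_start = k
        for lhs in self.endo:
            self.param_names.append(f"{lhs} ~~ {lhs}")
            k += 1
        self._phi_start = k
        self._phi_pairs = [(a, b) for a in range(nx_) for b in range(a + 1)]
        for a, b in self._phi_pairs:
            self.param_names.append(f"{self.exo[a]} ~~ {self.exo[b]}")
            k += 1
        self.n_free = k
        self.df = len(self.variables) * (len(self.variables) + 1) // 2 - self.n_free
        if self.df < 0:
            raise ValueError("model has more free parameters than moments")
        if self.n <= self.n_free:
            raise ValueError("need more samples than free parameters")

    def implied_cov(self, theta: np.ndarray) -> np.ndarray:
        ne, nx_ = len(self.endo), len(self.exo)
        b = np.zeros((ne, ne))
        g = np.zeros((ne, nx_))
        for k, i, j in self._beta_idx:
            b[i, j] = theta[k]
        for k, i, j in self._gamma_idx:
            g[i, j] = theta[k]
        psi = np.diag(theta[self._psi_start : self._phi_start])
        phi = np.zeros((nx_, nx_))
        for (a, bb), v in zip(self._phi_pairs, theta[self._phi_start :]):
            phi[a, bb] = phi[bb, a] = v
        ia = np.linalg.inv(np.eye(ne) - b)
        cov_ee = ia @ (g @ phi @ g.T + psi) @ ia.T
        cov_ex = ia @ g @ phi
        top = np.hstack([cov_ee, cov_ex])
        bottom = np.hstack([cov_ex.T, phi])
        return np.vstack([top, bottom])

    def discrepancy(self, theta: np.ndarray) -> float:
        sigma = self.implied_cov(theta)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0 or not np.isfinite(logdet):
            return _BIG
        try:
            sinv = np.linalg.solve(sigma, self.S)
        except np.linalg.LinAlgError:
            return _BIG
        p = len(self.variables)
        _, logdet_s = np.linalg.slogdet(self.S)
        f = logdet + np.trace(sinv) - logdet_s - p
        return float(f) if np.isfinite(f) else _BIG

    def _start_values(self) -> np.ndarray:
        """OLS per equation; sample moments for Phi."""
        theta = np.zeros(self.n_free)
        x = self._data
        var_idx = {v: i for i, v in enumerate(self.variables)}
        for i, (lhs, terms) in enumerate(self.equations):
            yv = x[:, var_idx[lhs]]
            xm = np.column_stack([x[:, var_idx[t]] for t in terms])
            coef, *_ = np.linalg.lstsq(xm, yv - yv.mean(), rcond=None)
            resid = yv - yv.mean() - xm @ coef
            for k, ii, j in self._beta_idx:
                if ii == i:
                    coef_pos = terms.index(self.endo[j])
                    theta[k] = coef[coef_pos]
            for k, ii, j in self._gamma_idx:
                if ii == i:
                    coef_pos = terms.index(self.exo[j])
                    theta[k] = coef[coef_pos]
            theta[self._psi_start + i] = max(resid.var(ddof=1), 1e-3)
        for off, (a, b) in enumerate(self._phi_pairs):
            ia, ib = var_idx[self.exo[a]], var_idx[self.exo[b]]
            theta[self._phi_start + off] = self.S[ia, ib]
        return theta

    def fit(self, start: np.ndarray | None = None, method: str = "BFGS") -> "PathResults":
        theta0 = self._start_values() if start is None else np.asarray(start, float)
        res = optimize.minimize(
            self.discrepancy, theta0, method=method,
            options={"maxiter": 5000, "gtol": 1e-10}
            if method == "BFGS"
            else {"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
        )
        theta = res.x
        f_min = max(self.discrepancy(theta), 0.0)
        return PathResults(self, theta, f_min)


def _num_hessian(fun, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    h = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            h[i, j] = h[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * eps**2)
    return h


class PathResults:
    """Estimates, standard errors, and fit indices of a fitted path model."""

    def __init__(self, model: PathModel, theta: np.ndarray, f_min: float):
        self.model = model
        self.theta = theta
        self.f_min = f_min
        n, df = model.n, model.df
        self.chi2 = max((n - 1) * f_min, 0.0)
        self.df = df
        self.chi2_p = float(stats.chi2.sf(self.chi2, df)) if df > 0 else 1.0

        # independence baseline: Sigma = diag(S)
        s = model.S
        p = s.shape[0]
        f_base = float(np.sum(np.log(np.diag(s))) - np.linalg.slogdet(s)[1])
        chi2_b = max((n - 1) * f_base, 0.0)
        df_b = p * (p + 1) // 2 - p
        num = max(self.chi2 - df, 0.0)
        den = max(chi2_b - df_b, num, np.finfo(float).tiny)
        self.cfi = 1.0 - num / den
        self.rmsea = (
            float(np.sqrt(num / (df * (n - 1)))) if df > 0 else 0.0
        )

        h = _num_hessian(model.discrepancy, theta)
        try:
            acov = (2.0 / (n - 1)) * np.linalg.pinv(h)
            se = np.sqrt(np.clip(np.diag(acov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full_like(theta, np.nan)
        self.se = se
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, theta / se, np.nan)
        self.zvalues = z
        self.pvalues = 2 * stats.norm.sf(np.abs(z))

    @property
    def params(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.theta,
                "se": self.se,
                "z": self.zvalues,
                "p": self.pvalues,
            },
            index=self.model.param_names,
        )

    def path_estimate(self, lhs: str, rhs: str) -> float:
        return float(self.params.loc[f"{lhs} ~ {rhs}", "estimate"])

    def summary(self) -> str:
        lines = [
            "Path model (ML covariance fitting)",
            f"  n = {self.model.n}, free parameters = {self.model.n_free}",
            f"  chi2 = {self.chi2:.4f}  df = {self.df}  p = {self.chi2_p:.4f}",
            f"  CFI = {self.cfi:.4f}  RMSEA = {self.rmsea:.4f}",
            "",
            self.params.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "chi2_p": self.chi2_p,
            "cfi": self.cfi,
            "rmsea": self.rmsea,
            "estimates": {
                name: {"estimate": float(e), "se": float(s), "p": float(p)}
                for name, e, s, p in zip(
                    self.model.param_names, self.theta, self.se, self.pvalues
                )
            },
        }


def fit_path_model(data: pd.DataFrame, formulas, standardize: bool = True) -> PathResults:
    """Convenience wrapper: build and fit a :class:`PathModel`."""
    return PathModel(formulas, data, standardize=standardize).fit()
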