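"""Gamma GLM with log link, fitted by iteratively reweighted least squares.

For the gamma family with a log link the IRLS working weights
``(dmu/deta)^2 / V(mu)`` are identically 1, so each iteration is an
ordinary least-squares regression of the working response
``z = eta + (y - mu)/mu`` on the design.  Convergence is declared on
the relative change in deviance; a deviance increase triggers
step-halving.  Dispersion is estimated by the Pearson method,
``phi = sum r_P^2 / (n - p)``, and the gamma shape used for the
log-likelihood is ``1/phi``.  Inference is Wald with normal
approximation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from .aggregate import RankDeficiencyError


@dataclass
class ModelSpec:
    """Covariate specification for one payer equation.

    ``terms`` are column names in the observation table; categorical
    (object/category dtype) columns are dummy-encoded dropping the first
    level.  ``state_mode`` records whether state variation enters as the
    eight state covariates or as state fixed effects (a ``state_id``
    term).  An intercept is always included, exactly once.
    """

    payer: str
    terms: list[str] = field(default_factory=list)
    response: str = "pcr"
    state_mode: str = "covariates"

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            dupes = sorted({t for t in self.terms if self.terms.count(t) > 1})
            raise ValueError(f"duplicate terms in spec: {dupes}")
        if "intercept" in self.terms:
            raise ValueError("the intercept is implicit; do not list it as a term")


def build_design(
    spec: ModelSpec, observations: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str], dict]:
    """Design matrix + response for one payer equation.

    Rows with any missing covariate or response are dropped (and
    counted in the returned info dict).  Raises
    :class:`~paycharge.aggregate.RankDeficiencyError` naming the
    offending columns if the matrix is not full column rank.
    """
    df = observations
    if "payer" in df.columns:
        df = df[df["payer"] == spec.payer]
        if df.empty:
            raise ValueError(f"no observations for payer {spec.payer!r}")
    missing = [t for t in spec.terms if t not in df.columns]
    if missing:
        raise KeyError(f"spec terms not in observations: {missing}")
    if spec.response not in df.columns:
        raise KeyError(f"response {spec.response!r} not in observations")

    blocks = [pd.Series(1.0, index=df.index, name="intercept")]
    for term in spec.terms:
        col = df[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=term, drop_first=True, dtype=float)
            blocks.extend(dummies[c] for c in dummies.columns)
        else:
            blocks.append(col.astype(float))
    X_df = pd.concat(blocks, axis=1)
    y = df[spec.response].astype(float)

    ok = X_df.notna().all(axis=1) & y.notna()
    n_dropped = int((~ok).sum())
    X_df, y = X_df[ok], y[ok]
    if len(X_df) == 0:
        raise ValueError("empty estimation sample after dropping missing rows")

    X = X_df.to_numpy(dtype=float)
    names = list(X_df.columns)
    # QR with pivoting identifies linearly dependent columns by name
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise RankDeficiencyError(bad)
    info = {"n_dropped": n_dropped, "n": len(y), "index": X_df.index.to_numpy()}
    return X, y.to_numpy(), names, info


class GammaGLM:
    """Gamma-family, log-link generalized linear model.

    Parameters
    ----------
    endog : array-like, strictly positive response (the PCR).
    exog : (n, p) design matrix including an intercept column.
    exog_names : column names (defaults to x0..x_{p-1}).

    Use :meth:`from_spec` to build the design from an observation table
    and a :class:`ModelSpec`.
    """

    def __init__(self, endog, exog, exog_names=None, spec: ModelSpec | None = None,
                 row_index=None):
        y = np.asarray(endog, dtype=float)
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("endog/exog dimension mismatch")
        if np.any(y <= 0):
            raise ValueError("gamma response must be strictly positive")
        if len(y) <= X.shape[1]:
            raise ValueError("need n > p observations")
        self.endog = y
        self.exog = X
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(X.shape[1])]
        self.spec = spec
        self.row_index = row_index

    @classmethod
    def from_spec(cls, spec: ModelSpec, observations: pd.DataFrame) -> "GammaGLM":
        X, y, names, info = build_design(spec, observations)
        model = cls(y, X, exog_names=names, spec=spec, row_index=info["index"])
        model.n_dropped = info["n_dropped"]
        return model

    # -- fitting -----------------------------------------------------------
    def fit(self, max_iter: int = 100, tol: float = 1e-8) -> "GammaGLMResults":
        X, y = self.exog, self.endog
        n, p = X.shape
        beta = linalg.lstsq(X, np.log(y))[0]
        dev = self._deviance(y, np.exp(np.clip(X @ beta, -30, 30)))
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            eta = np.clip(X @ beta, -30, 30)
            mu = np.exp(eta)
            z = eta + (y - mu) / mu
            beta_new = linalg.lstsq(X, z)[0]
            dev_new = self._deviance(y, np.exp(np.clip(X @ beta_new, -30, 30)))
            # step-halve if the deviance went up
            halvings = 0
            while dev_new > dev + 1e-12 and halvings < 30:
                beta_new = (beta_new + beta) / 2.0
                dev_new = self._deviance(y, np.exp(np.clip(X @ beta_new, -30, 30)))
                halvings += 1
            rel = abs(dev - dev_new) / (0.1 + abs(dev_new))
            beta, dev = beta_new, dev_new
            if rel < tol:
                converged = True
                break
        if not converged:
            warnings.warn(f"IRLS did not converge in {max_iter} iterations", RuntimeWarning)

        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        pearson = (y - mu) / mu
        dispersion = float(np.sum(pearson**2) / (n - p))
        xtx_inv = linalg.inv(X.T @ X)
        cov = dispersion * xtx_inv
        shape = 1.0 / dispersion
        loglik = float(np.sum(shape * np.log(shape * y / mu) - shape * y / mu
                              - np.log(y) - special.gammaln(shape)))
        return GammaGLMResults(
            model=self, params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(cov, index=self.exog_names, columns=self.exog_names),
            dispersion=dispersion, deviance=float(dev), loglik=loglik,
            nobs=n, df_model=p, converged=converged, n_iter=n_iter,
            fittedvalues=mu,
        )

    @staticmethod
    def _deviance(y, mu):
        return float(2.0 * np.sum((y - mu) / mu - np.log(y / mu)))


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_marker(p: float) -> str:
    """Significance stars at the conventional printed thresholds
    (strict inequality: p exactly at a threshold gets the weaker mark)."""
    for thresh, mark in _STAR_LEVELS:
        if p < thresh:
            return mark
    return ""


@dataclass
class GammaGLMResults:
    """Fitted gamma log-link equation: estimates, Wald inference,
    residuals, prediction, and corrected AIC."""

    model: GammaGLM
    params: pd.Series
    cov_params: pd.DataFrame
    dispersion: float
    deviance: float
    loglik: float
    nobs: int
    df_model: int
    converged: bool
    n_iter: int
    fittedvalues: np.ndarray

    # -- inference ---------------------------------------------------------
    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.params.index)

    def wald_table(self) -> pd.DataFrame:
        """Per-coefficient SE, z, two-sided normal p-value and stars."""
        if np.any(~np.isfinite(self.bse)) or (self.bse <= 0).any():
            raise np.linalg.LinAlgError("singular coefficient covariance")
        p = self.pvalues
        return pd.DataFrame({
            "coef": self.params, "se": self.bse, "z": self.zvalues,
            "p": p, "stars": [star_marker(v) for v in p],
            "exp_coef_minus_1": np.expm1(self.params),
        })

    # -- residuals & prediction --------------------------------------------
    def resid(self, kind: str = "response") -> np.ndarray:
        """Residuals: ``response`` (y - mu), ``pearson`` ((y - mu)/mu) or
        signed ``deviance`` contributions."""
        y, mu = self.model.endog, self.fittedvalues
        if kind == "response":
            return y - mu
        if kind == "pearson":
            return (y - mu) / mu
        if kind == "deviance":
            d2 = 2.0 * ((y - mu) / mu - np.log(y / mu))
            return np.sign(y - mu) * np.sqrt(np.maximum(d2, 0.0))
        raise ValueError(f"unknown residual kind {kind!r}")

    def predict(self, exog=None) -> np.ndarray:
        """Mean response exp(X beta); ``exog`` may be an ndarray aligned
        with the fit's columns or a DataFrame containing them (the
        intercept is supplied automatically for DataFrames)."""
        if exog is None:
            return self.fittedvalues.copy()
        if isinstance(exog, pd.DataFrame):
            cols = [c for c in self.params.index if c != "intercept"]
            missing = [c for c in cols if c not in exog.columns]
            if missing:
                raise KeyError(f"prediction frame lacks columns: {missing}")
            X = np.column_stack([np.ones(len(exog))]
                                + [exog[c].to_numpy(dtype=float) for c in cols])
            names = ["intercept"] + cols
            beta = self.params.reindex(names).to_numpy()
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.params):
                raise ValueError("column mismatch with the fitted design")
            beta = self.params.to_numpy()
        return np.exp(np.clip(X @ beta, -30, 30))

    # -- model comparison ---------------------------------------------------
    @property
    def aicc(self) -> float:
        """Corrected AIC, counting the dispersion as a parameter:
        ``-2*loglik + 2k + 2k(k+1)/(n-k-1)`` with ``k = p + 1``."""
        return aicc(self.loglik, self.nobs, self.df_model + 1)

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        payer = self.model.spec.payer if self.model.spec else "?"
        lines = [
            f"Gamma GLM (log link) — payer: {payer}",
            f"N = {self.nobs}   p = {self.df_model}   converged = {self.converged}"
            f" ({self.n_iter} iterations)",
            f"deviance = {self.deviance:.4f}   dispersion (Pearson) = {self.dispersion:.4f}",
            f"log-likelihood = {self.loglik:.2f}   AICc = {self.aicc:.2f}",
            "-" * 72,
            f"{'term':<28}{'coef':>10}{'se':>10}{'z':>8}{'p':>9}  stars",
        ]
        tab = self.wald_table()
        for name, row in tab.iterrows():
            lines.append(f"{name:<28}{row['coef']:>10.4f}{row['se']:>10.4f}"
                         f"{row['z']:>8.2f}{row['p']:>9.4f}  {row['stars']}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        tab = self.wald_table()
        return {
            "payer": self.model.spec.payer if self.model.spec else None,
            "n": int(self.nobs), "converged": bool(self.converged),
            "dispersion": self.dispersion, "loglik": self.loglik,
            "aicc": self.aicc,
            "coefficients": {
                name: {"coef": float(r["coef"]), "se": float(r["se"]),
                       "p": float(r["p"]), "stars": r["stars"]}
                for name, r in tab.iterrows()},
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def aicc(loglik: float, n: int, k: int) -> float:
    """Corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: need n - k - 1 > 0 (n={n}, k={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
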