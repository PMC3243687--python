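"""Resource-selection model estimation from use-availability data.

Two model forms are supported:

* the **exponential resource selection function** (RSF),
  ``w(x) = exp(x'beta)`` — a relative selection weight whose intercept is not
  identifiable from use-availability data and is therefore fixed at zero;
* the **logistic resource selection probability function** (RSPF),
  ``pi(x) = expit(beta0 + x'beta)`` — a true selection probability in (0, 1).

Both are estimated by maximizing the weighted-distribution log-likelihood

    l(beta) = sum_{i in used} log pi(x_i; beta)
              - n_used * log( (1/n_avail) * sum_{j in avail} pi(x_j; beta) )

in which the availability sample acts as a Monte-Carlo integration set for
the normalizing constant of the use distribution. Covariates are internally
centered and scaled for optimization and coefficients are reported back on
the input scale.

The public surface follows the statsmodels convention: build a
:class:`ResourceSelectionModel` from a dataset and a :class:`ModelSpec`,
call :meth:`~ResourceSelectionModel.fit`, and read estimates, standard
errors, the BIC and predictions off the returned :class:`RSPFResults`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp

__all__ = [
    "Term",
    "parse_term",
    "ModelSpec",
    "linear_predictor",
    "selection_prob",
    "use_available_loglik",
    "ResourceSelectionModel",
    "RSPFResults",
    "fit_rspf",
    "fd_hessian",
    "standard_errors_from_hessian",
]


# ---------------------------------------------------------------------------
# model terms

_POWER_RE = re.compile(r"^\(?\s*([^()^]+?)\s*\)?\s*\^\s*(\d+)$")


@dataclass(frozen=True)
class Term:
    """One term of the linear predictor.

    kind: ``main`` (a covariate), ``product`` (the product of two covariates,
    written ``a*b``) or ``power`` (an integer power, written ``(a)^2``).
    """

    kind: str
    names: tuple[str, ...]
    exponent: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("main", "product", "power"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        n = {"main": 1, "product": 2, "power": 1}[self.kind]
        if len(self.names) != n:
            raise ValueError(f"{self.kind} term needs {n} covariate name(s)")

    @property
    def label(self) -> str:
        if self.kind == "main":
            return self.names[0]
        if self.kind == "product":
            return f"{self.names[0]}*{self.names[1]}"
        return f"({self.names[0]})^{self.exponent}"

    def value(self, table: pd.DataFrame) -> np.ndarray:
        for name in self.names:
            if name not in table.columns:
                raise KeyError(f"covariate {name!r} missing from the table")
        if self.kind == "main":
            return table[self.names[0]].to_numpy(dtype=float)
        if self.kind == "product":
            return (table[self.names[0]].to_numpy(dtype=float)
                    * table[self.names[1]].to_numpy(dtype=float))
        return table[self.names[0]].to_numpy(dtype=float) ** self.exponent


def parse_term(s: str | Term) -> Term:
    """Parse ``"closed"``, ``"natural*MainroadDist"`` or ``"(agDist)^2"``.

    A ``*`` (or ``:``) denotes a single product term, not a main-effects
    expansion; ``^k`` denotes an integer power of one covariate.
    """
    if isinstance(s, Term):
        return s
    s = s.strip()
    m = _POWER_RE.match(s)
    if m:
        return Term("power", (m.group(1).strip(),), int(m.group(2)))
    for sep in ("*", ":"):
        if sep in s:
            a, b = (p.strip() for p in s.split(sep, 1))
            return Term("product", (a, b))
    return Term("main", (s,))


@dataclass(frozen=True)
class ModelSpec:
    """Model form plus an ordered term list.

    The logistic form carries an intercept; the exponential form does not
    (it is not identifiable under the use-availability likelihood: adding a
    constant to the linear predictor leaves the likelihood unchanged).
    """

    form: str
    terms: tuple[Term, ...]

    def __init__(self, form: str, terms) -> None:
        if form not in ("exponential", "logistic"):
            raise ValueError("form must be 'exponential' or 'logistic'")
        parsed = tuple(parse_term(t) for t in terms)
        labels = [t.label for t in parsed]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate terms in model spec")
        object.__setattr__(self, "form", form)
        object.__setattr__(self, "terms", parsed)

    @property
    def has_intercept(self) -> bool:
        return self.form == "logistic"

    @property
    def k(self) -> int:
        """Number of estimated coefficients (intercept included)."""
        return len(self.terms) + (1 if self.has_intercept else 0)

    @property
    def param_names(self) -> list[str]:
        names = ["intercept"] if self.has_intercept else []
        return names + [t.label for t in self.terms]

    def covariate_names(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms:
            out.update(t.names)
        return out

    def design_matrix(self, table: pd.DataFrame) -> np.ndarray:
        cols = []
        if self.has_intercept:
            cols.append(np.ones(len(table)))
        cols.extend(t.value(table) for t in self.terms)
        return np.column_stack(cols) if cols else np.empty((len(table), 0))


# ---------------------------------------------------------------------------
# likelihood pieces


def linear_predictor(spec: ModelSpec, beta: np.ndarray, table: pd.DataFrame) -> np.ndarray:
    """eta = beta0*[intercept] + sum_k beta_k * term_k(row), per row."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != spec.k:
        raise ValueError(f"beta has {beta.shape[0]} entries; spec needs {spec.k}")
    return spec.design_matrix(table) @ beta


def selection_prob(form: str, eta: np.ndarray | float) -> np.ndarray | float:
    """pi (logistic, a probability) or w (exponential, a relative weight)."""
    eta = np.asarray(eta, dtype=float)
    if form == "logistic":
        out = expit(eta)
    elif form == "exponential":
        out = np.exp(eta)
    else:
        raise ValueError(f"unknown form {form!r}")
    return out if out.ndim else float(out)


def _log_pi(form: str, eta: np.ndarray) -> np.ndarray:
    if form == "logistic":
        return -np.logaddexp(0.0, -eta)  # log expit(eta), overflow-safe
    return eta


def _loglik_from_eta(form: str, eta_used: np.ndarray, eta_avail: np.ndarray) -> float:
    n_used, n_avail = len(eta_used), len(eta_avail)
    lp_used = _log_pi(form, eta_used)
    # a used site whose selection probability underflows to exactly zero
    if np.any(np.exp(lp_used) == 0.0):
        return -np.inf
    log_mean_avail = logsumexp(_log_pi(form, eta_avail)) - np.log(n_avail)
    return float(lp_used.sum() - n_used * log_mean_avail)


def use_available_loglik(beta, data, spec: ModelSpec) -> float:
    """Weighted-distribution log-likelihood at ``beta``.

    ``data`` is a :class:`~rspfit.design.UseAvailableDataset` (or any object
    with ``used_table()``/``available_table()`` returning covariate frames).
    A used site with selection probability exactly zero yields ``-inf``.
    """
    beta = np.asarray(beta, dtype=float)
    eta_u = linear_predictor(spec, beta, data.used_table())
    eta_a = linear_predictor(spec, beta, data.available_table())
    return _loglik_from_eta(spec.form, eta_u, eta_a)


def _loglik_and_grad(form: str, beta: np.ndarray, Xu: np.ndarray, Xa: np.ndarray) -> tuple[float, np.ndarray]:
    eta_u = Xu @ beta
    eta_a = Xa @ beta
    n_used = Xu.shape[0]
    lp_a = _log_pi(form, eta_a)
    lse = logsumexp(lp_a)
    ll = _loglik_from_eta(form, eta_u, eta_a)
    w_a = np.exp(lp_a - lse)  # availability weights, sum to 1
    if form == "logistic":
        pi_u = expit(eta_u)
        pi_a = expit(eta_a)
        grad = (Xu.T @ (1.0 - pi_u)) - n_used * (Xa.T @ (w_a * (1.0 - pi_a)))
    else:
        grad = Xu.sum(axis=0) - n_used * (Xa.T @ w_a)
    return ll, grad


# ---------------------------------------------------------------------------
# numerical standard errors


def fd_hessian(f, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian of scalar ``f`` at ``x``.

    Step per coordinate: ``rel_step * max(1, |x_k|)``.
    """
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f(x) + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def standard_errors_from_hessian(neg_hessian: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """SEs from the observed information (the Hessian of the negative
    log-likelihood at the maximum).

    Returns (se, cov, is_positive_definite); coordinates whose variance is
    not positive get ``nan`` SEs.
    """
    k = neg_hessian.shape[0]
    try:
        np.linalg.cholesky(neg_hessian)
        pd_flag = True
        cov = np.linalg.inv(neg_hessian)
    except np.linalg.LinAlgError:
        pd_flag = False
        cov = np.linalg.pinv(neg_hessian)
    diag = np.diag(cov).copy()
    se = np.full(k, np.nan)
    ok = diag > 0
    se[ok] = np.sqrt(diag[ok])
    if not pd_flag:
        se[~ok] = np.nan
    return se, cov, pd_flag


# ---------------------------------------------------------------------------
# Model / Results


class ResourceSelectionModel:
    """Use-availability resource selection model (exponential RSF or
    logistic RSPF).

    Parameters
    ----------
    data
        A :class:`~rspfit.design.UseAvailableDataset`, or a DataFrame with a
        0/1 ``used`` column plus one column per covariate.
    spec
        The model form and term list.
    """

    def __init__(self, data, spec: ModelSpec, used_col: str = "used") -> None:
        self.spec = spec
        if isinstance(data, pd.DataFrame):
            used_mask = data[used_col].to_numpy().astype(bool)
            table = data.drop(columns=[used_col])
        else:
            table = data.table()
            used_mask = data.used_mask()
        self.table = table.reset_index(drop=True)
        self.used_mask = np.asarray(used_mask, dtype=bool)
        self.n_used = int(self.used_mask.sum())
        self.n_available = int((~self.used_mask).sum())
        if self.n_used < 1 or self.n_available < 1:
            raise ValueError("need at least one used and one available site")
        missing = spec.covariate_names() - set(self.table.columns)
        if missing:
            raise KeyError(f"covariates missing from data: {sorted(missing)}")
        X = spec.design_matrix(self.table)
        if not np.all(np.isfinite(X)):
            raise ValueError("design matrix contains non-finite values")
        self._X = X
        self._Xu = X[self.used_mask]
        self._Xa = X[~self.used_mask]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, form: str, terms, used_col: str = "used"):
        return cls(df, ModelSpec(form, terms), used_col=used_col)

    # -- likelihood on the raw scale -------------------------------------
    def loglik(self, beta) -> float:
        beta = np.asarray(beta, dtype=float)
        return _loglik_from_eta(self.spec.form, self._Xu @ beta, self._Xa @ beta)

    def score(self, beta) -> np.ndarray:
        _, g = _loglik_and_grad(self.spec.form, np.asarray(beta, float), self._Xu, self._Xa)
        return g

    # -- fitting ----------------------------------------------------------
    def _standardize(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Center/scale non-intercept columns; constant columns are flagged
        (scale forced to 1 so they stay inert) and their coefficients pinned
        at zero during optimization."""
        X = self._X
        k = X.shape[1]
        mu = np.zeros(k)
        sd = np.ones(k)
        start = 1 if self.spec.has_intercept else 0
        const = np.zeros(k, dtype=bool)
        for j in range(start, k):
            col = X[:, j]
            s = col.std()
            if s <= 0:
                const[j] = True
                mu[j] = col.mean()  # term contributes nothing after centering
            else:
                mu[j] = col.mean()
                sd[j] = s
        Z = (X - mu) / sd
        if self.spec.has_intercept:
            Z[:, 0] = 1.0
            mu[0], sd[0] = 0.0, 1.0
        return Z, mu, sd, const

    def fit(self, n_restarts: int = 5, seed: int = 0, gtol: float = 1e-6,
            maxiter: int = 500, restart_scale: float = 0.5,
            separation_bound: float = 50.0, start=None) -> "RSPFResults":
        """Maximize the use-availability likelihood.

        Quasi-Newton (BFGS, analytic gradient) from ``beta = 0`` plus
        ``n_restarts`` random restarts drawn N(0, ``restart_scale``^2) on the
        standardized scale; the best optimum is kept. Non-convergence is
        reported on the results object, never raised.
        """
        Z, mu, sd, const = self._standardize()
        free = ~const
        Zu, Za = Z[self.used_mask][:, free], Z[~self.used_mask][:, free]
        k_free = int(free.sum())
        form = self.spec.form

        def neg(beta):
            ll, g = _loglik_and_grad(form, beta, Zu, Za)
            return -ll, -g

        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E1EC7]))
        starts = [np.zeros(k_free)]
        if start is not None:
            starts.insert(0, np.asarray(start, float)[free])
        starts += [rng.normal(0.0, restart_scale, k_free) for _ in range(n_restarts)]

        best = None
        for s0 in starts:
            res = optimize.minimize(neg, s0, jac=True, method="BFGS",
                                    options={"gtol": gtol, "maxiter": maxiter})
            if best is None or -res.fun > -best.fun + 1e-12:
                best = res
        gnorm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.inf
        converged = bool(best.success or gnorm < 1e-4)

        flags: list[str] = []
        if const.any():
            flags.append("inestimable: " + ", ".join(
                np.array(self.spec.param_names)[const]))
        if np.any(np.abs(best.x) > separation_bound):
            flags.append("separation")
            converged = False

        beta_std = np.zeros(Z.shape[1])
        beta_std[free] = best.x
        beta_raw = self._destandardize(beta_std, mu, sd, const)
        llf = self.loglik(beta_raw)

        se = np.full(Z.shape[1], np.nan)
        cov = np.full((Z.shape[1], Z.shape[1]), np.nan)
        hess_pd = False
        if converged:
            se, cov, hess_pd = self._standard_errors(beta_raw, free)
        if converged and not hess_pd:
            flags.append("hessian_not_pd")

        return RSPFResults(
            model=self, spec=self.spec,
            params=pd.Series(beta_raw, index=self.spec.param_names),
            bse=pd.Series(se, index=self.spec.param_names),
            cov_params=cov, llf=llf, converged=converged,
            n_used=self.n_used, n_available=self.n_available,
            flags=flags, gradient_norm=gnorm, n_iter=int(best.nit),
        )

    def _destandardize(self, beta_std: np.ndarray, mu: np.ndarray, sd: np.ndarray,
                       const: np.ndarray) -> np.ndarray:
        beta = beta_std / sd
        beta[const] = 0.0
        if self.spec.has_intercept:
            shift = float(np.sum((beta_std[1:] * mu[1:] / sd[1:])[~const[1:]]))
            beta[0] = beta_std[0] - shift
        return beta

    def _standard_errors(self, beta_raw: np.ndarray, free: np.ndarray):
        """Inverse observed information at the raw-scale maximum."""
        idx = np.nonzero(free)[0]

        def negll(b_free):
            b = beta_raw.copy()
            b[idx] = b_free
            return -self.loglik(b)

        H = fd_hessian(negll, beta_raw[idx])
        se_f, cov_f, pd_flag = standard_errors_from_hessian(H)
        k = beta_raw.size
        se = np.full(k, np.nan)
        cov = np.full((k, k), np.nan)
        se[idx] = se_f
        cov[np.ix_(idx, idx)] = cov_f
        return se, cov, pd_flag


@dataclass
class RSPFResults:
    """Fit results: estimates, uncertainties, diagnostics, predictions."""

    model: ResourceSelectionModel
    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    cov_params: np.ndarray
    llf: float
    converged: bool
    n_used: int
    n_available: int
    flags: list[str] = field(default_factory=list)
    gradient_norm: float = np.nan
    n_iter: int = 0

    @property
    def k(self) -> int:
        return self.spec.k

    def bic(self, n: str = "used") -> float:
        """BIC = -2 l + k log(n); ``n`` counts used sites by default (the
        availability sample is an integration device, not data)."""
        n_eff = self.n_used if n == "used" else self.n_used + self.n_available
        return -2.0 * self.llf + self.k * np.log(n_eff)

    def predict(self, table: pd.DataFrame | None = None) -> np.ndarray:
        """pi(x; beta_hat) per row of ``table`` (default: the fitted data)."""
        if table is None:
            table = self.model.table
        eta = linear_predictor(self.spec, self.params.to_numpy(), table)
        return np.asarray(selection_prob(self.spec.form, eta))

    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def summary(self) -> str:
        lines = [
            "Resource selection model " + "=" * 40,
            f"  form:        {self.spec.form}"
            + ("  (RSPF, probabilities)" if self.spec.form == "logistic"
               else "  (RSF, relative weights; intercept fixed at 0)"),
            f"  n_used:      {self.n_used}",
            f"  n_available: {self.n_available}",
            f"  log-lik:     {self.llf:.3f}",
            f"  BIC:         {self.bic():.3f}",
            f"  converged:   {self.converged}" + (f"  flags: {self.flags}" if self.flags else ""),
            "",
            f"  {'term':<24}{'coef':>10}{'std err':>10}{'z':>8}",
        ]
        for name in self.params.index:
            b, s = self.params[name], self.bse[name]
            z = b / s if s and np.isfinite(s) and s > 0 else np.nan
            lines.append(f"  {name:<24}{b:>10.3f}{s:>10.3f}{z:>8.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "form": self.spec.form,
            "terms": [t.label for t in self.spec.terms],
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: (float(v) if np.isfinite(v) else None) for k, v in self.bse.items()},
            "loglik": float(self.llf),
            "bic": float(self.bic()),
            "converged": bool(self.converged),
            "flags": list(self.flags),
            "n_used": self.n_used,
            "n_available": self.n_available,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fit_rspf(spec: ModelSpec, data, **fit_options) -> RSPFResults:
    """Functional wrapper: build the model and fit in one call."""
    return ResourceSelectionModel(data, spec).fit(**fit_options)
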