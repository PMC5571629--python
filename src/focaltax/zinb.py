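"""Zero-inflated count models for focal-taxon abundance.

The model is a two-component mixture: a logistic regression for structural
(excess) zeros and a negative-binomial (or Poisson) regression for counts,
with the log of the per-sample total read count entering BOTH linear
predictors as an offset with coefficient 1, so the model describes
proportions rather than raw counts:

    logit(pi_i) = x_i' gamma + log T_i
    log(mu_i)   = x_i' beta  + log T_i
    P(y_i = 0)      = pi_i + (1 - pi_i) f(0; mu_i, k)
    P(y_i = y), y>0 = (1 - pi_i) f(y; mu_i, k)

where f is the NB2 pmf with dispersion k (Var = mu + mu^2/k); the
zero-inflated Poisson (ZIP) is the k -> infinity member of the family.
Fitting is direct joint maximum likelihood with analytic gradients and
multiple starts; the dispersion is parameterized as log(k).

Also provided: dummy-coded design construction with a hidden "missing"
category per categorical covariate, a univariate p<0.1 screen (logistic
and plain NB, each with the offset), AIC/BIC/LRT model comparison, and
average-predicted-value (APV) fitted mean proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

__all__ = [
    "DesignMatrix",
    "ZINBFit",
    "APVResult",
    "build_design",
    "univariate_screen",
    "fit_mixture",
    "compare_models",
    "apv_proportions",
]

MISSING_LEVEL = "missing"


# ---------------------------------------------------------------------------
# design construction


@dataclass
class DesignMatrix:
    """Dummy-coded design with offset = log total reads.

    ``columns_by_covariate`` maps each covariate to its design columns so
    that APV can toggle whole covariates at once; categorical covariates
    with missingness carry an extra hidden "missing" level.
    """

    X: pd.DataFrame
    offset: np.ndarray
    columns_by_covariate: dict
    reference_levels: dict
    kinds: dict  # covariate -> "continuous" | "categorical"

    @property
    def n(self) -> int:
        return len(self.X)

    def matrix(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)


def build_design(
    meta: pd.DataFrame,
    depths: pd.Series,
    covariates: Sequence[str],
    reference_levels: Mapping[str, str] | None = None,
) -> DesignMatrix:
    """Intercept + dummy-coded covariates with stated reference levels.

    Missing values in a categorical covariate become a hidden "missing"
    level; rows missing a continuous covariate are excluded (the hidden
    category device only applies to categorical variables).
    """
    reference_levels = dict(reference_levels or {})
    meta = meta.copy()
    keep = np.ones(len(meta), dtype=bool)
    kinds = {}
    for cov in covariates:
        if cov not in meta.columns:
            raise KeyError(f"covariate {cov!r} not in metadata")
        kinds[cov] = "continuous" if pd.api.types.is_numeric_dtype(meta[cov]) else "categorical"
        if kinds[cov] == "continuous":
            keep &= meta[cov].notna().to_numpy()
    meta = meta.loc[keep]

    cols = {"intercept": np.ones(len(meta))}
    columns_by_covariate: dict = {}
    refs = {}
    for cov in covariates:
        if kinds[cov] == "continuous":
            cols[cov] = meta[cov].to_numpy(dtype=float)
            columns_by_covariate[cov] = [cov]
            continue
        vals = meta[cov].astype(object).where(meta[cov].notna(), MISSING_LEVEL)
        levels = [lv for lv in pd.unique(vals) if lv != MISSING_LEVEL]
        ref = reference_levels.get(cov, levels[0] if levels else None)
        if ref not in levels:
            warnings.warn(
                f"reference level {ref!r} absent from {cov}; using {levels[0]!r}"
            )
            ref = levels[0]
        refs[cov] = ref
        cov_cols = []
        ordered = [lv for lv in levels if lv != ref]
        if (vals == MISSING_LEVEL).any():
            ordered.append(MISSING_LEVEL)
        for lv in ordered:
            name = f"{cov}[{lv}]"
            col = (vals == lv).to_numpy(dtype=float)
            if col.sum() == 0:
                warnings.warn(f"level {lv!r} of {cov} unobserved; dropped")
                continue
            cols[name] = col
            cov_cols.append(name)
        columns_by_covariate[cov] = cov_cols

    X = pd.DataFrame(cols, index=meta.index)
    empty = [c for c in X.columns if (X[c] == 0).all()]
    if empty:
        raise ValueError(f"all-zero design columns: {empty}")
    offset = np.log(depths.loc[meta.index].to_numpy(dtype=float))
    if not np.isfinite(offset).all():
        raise ValueError("offset (log depth) must be finite; check depths > 0")
    return DesignMatrix(X, offset, columns_by_covariate, refs, kinds)


# ---------------------------------------------------------------------------
# univariate screen


def univariate_screen(
    y: np.ndarray,
    meta: pd.DataFrame,
    depths: pd.Series,
    candidates: Sequence[str],
    baseline: Sequence[str] = ("age", "sex", "race"),
    alpha: float = 0.1,
    positives_only_nb: bool = False,
) -> dict:
    """Screen candidate covariates one at a time.

    Each candidate is fitted alone in (a) a logistic regression of
    presence with the log-depth offset in the linear predictor, and (b)
    a plain NB regression of counts (all samples by default; positives
    only behind the flag) with the same offset.  A candidate is selected
    when any non-reference level has p < ``alpha`` in either model; the
    baseline covariates are always retained.
    """
    y = np.asarray(y)
    rows = {}
    selected = []
    for cov in candidates:
        vals = meta[cov]
        nlev = vals.dropna().nunique()
        if pd.api.types.is_numeric_dtype(vals):
            if vals.dropna().nunique() < 2:
                warnings.warn(f"candidate {cov} has a single value; excluded")
                continue
        elif nlev < 2:
            warnings.warn(f"candidate {cov} has a single level; excluded")
            continue
        design = build_design(meta, depths, [cov])
        idx = design.X.index
        yy = pd.Series(y, index=meta.index).loc[idx].to_numpy()
        X = design.matrix()
        off = design.offset
        p_logit = p_nb = float("nan")
        try:
            glm = sm.GLM((yy > 0).astype(float), X, family=sm.families.Binomial(),
                         offset=off)
            res = glm.fit()
            p_logit = float(np.nanmin(res.pvalues[1:])) if X.shape[1] > 1 else float("nan")
        except Exception:
            pass
        try:
            if positives_only_nb:
                mask = yy > 0
                nb = sm.NegativeBinomial(yy[mask], X[mask], offset=off[mask])
            else:
                nb = sm.NegativeBinomial(yy, X, offset=off)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nbres = nb.fit(disp=0, maxiter=200)
            p_nb = float(np.nanmin(nbres.pvalues[1:-1])) if X.shape[1] > 1 else float("nan")
        except Exception:
            pass
        hit = (np.nan_to_num(p_logit, nan=1.0) < alpha) or (
            np.nan_to_num(p_nb, nan=1.0) < alpha
        )
        rows[cov] = {"p_logistic": p_logit, "p_negbin": p_nb, "selected": bool(hit)}
        if hit:
            selected.append(cov)
    table = pd.DataFrame.from_dict(rows, orient="index")
    final = list(dict.fromkeys(list(baseline) + selected))
    return {"selected": final, "table": table}


# ---------------------------------------------------------------------------
# joint MLE


@dataclass
class ZINBFit:
    """Fitted zero-inflated (or plain) count model."""

    family: str                      # zinb | zip | nb | poisson
    gamma: np.ndarray                # logistic component (empty if no inflation)
    beta: np.ndarray                 # count component
    k: float | None                  # NB dispersion (None for Poisson family)
    loglik: float
    df: int
    n: int
    aic: float
    bic: float
    se: np.ndarray                   # in packed order (gamma, beta[, log k])
    z: np.ndarray
    p: np.ndarray
    param_names: list[str]
    converged: bool
    grad_norm: float
    design: "DesignMatrix | None" = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)

    @property
    def inflated(self) -> bool:
        return self.family in ("zinb", "zip")

    def coef_table(self) -> pd.DataFrame:
        est = np.concatenate([
            self.gamma, self.beta,
            [np.log(self.k)] if self.family in ("zinb", "nb") else [],
        ])
        return pd.DataFrame({
            "estimate": est, "se": self.se, "z": self.z, "p": self.p,
        }, index=self.param_names)

    def predict_mean(self, X: np.ndarray | None = None, offset: np.ndarray | None = None) -> np.ndarray:
        """Unconditional fitted mean E[y] = (1 - pi) * mu."""
        if X is None:
            X = self.design.matrix()
        if offset is None:
            offset = self.design.offset
        mu = np.exp(X @ self.beta + offset)
        if self.inflated:
            pi = special.expit(X @ self.gamma + offset)
            return (1.0 - pi) * mu
        return mu


def _sigmoid(x):
    return special.expit(x)


def _nll_and_grad(params, y, X, offset, family):
    """Negative log-likelihood and gradient, vectorized.

    Packed parameter order: gamma (q, only for inflated families), beta
    (p), log k (only for nb-dispersed families).
    """
    n, p = X.shape
    inflated = family in ("zinb", "zip")
    dispersed = family in ("zinb", "nb")
    q = p if inflated else 0
    gamma = params[:q]
    beta = params[q:q + p]
    grad = np.zeros_like(params)

    eta1 = X @ beta + offset
    eta1 = np.clip(eta1, -700, 35)
    mu = np.exp(eta1)
    z = y == 0
    pos = ~z

    if dispersed:
        t = params[-1]
        t = min(max(t, -20.0), 30.0)
        k = np.exp(t)
        log_ratio = np.log(k) - np.log(k + mu)       # log(k/(k+mu))
        log_p0 = k * log_ratio                       # log f(0)
        mu_frac = mu / (k + mu)
    else:
        k = None
        log_p0 = -mu
        mu_frac = None

    if inflated:
        eta0 = X @ gamma + offset
        log_pi = -np.logaddexp(0.0, -eta0)           # log sigmoid
        log_1mpi = -np.logaddexp(0.0, eta0)
        pi = _sigmoid(eta0)
    else:
        log_pi = None
        log_1mpi = np.zeros(n)
        pi = np.zeros(n)

    ll = 0.0
    # zero observations
    if z.any():
        if inflated:
            ll0 = np.logaddexp(log_pi[z], log_1mpi[z] + log_p0[z])
        else:
            ll0 = log_p0[z]
        ll += ll0.sum()
    # positive observations
    if pos.any():
        yp, mup = y[pos], mu[pos]
        if dispersed:
            llp = (special.gammaln(yp + k) - special.gammaln(k)
                   - special.gammaln(yp + 1)
                   + k * log_ratio[pos] + yp * (eta1[pos] - np.log(k + mup)))
        else:
            llp = yp * eta1[pos] - mup - special.gammaln(yp + 1)
        ll += llp.sum() + log_1mpi[pos].sum()

    # gradients ------------------------------------------------------------
    g_eta0 = np.zeros(n)
    g_eta1 = np.zeros(n)
    g_t = 0.0
    if z.any():
        if inflated:
            # A = pi + (1 - pi) p0, in log space for stability
            logA = np.logaddexp(log_pi[z], log_1mpi[z] + log_p0[z])
            w = np.exp(log_1mpi[z] + log_p0[z] - logA)   # (1-pi) p0 / A
            v = np.exp(log_pi[z] - logA)                 # pi / A
            # d/d eta0 log A = v (1 - pi) - w pi
            g_eta0[z] = v * (1 - pi[z]) - w * pi[z]
        else:
            w = np.ones(z.sum())
        if dispersed:
            g_eta1[z] = -w * k * mu_frac[z]
            g_t += (w * k * (log_ratio[z] + mu_frac[z])).sum()
        else:
            g_eta1[z] = -w * mu[z]
    if pos.any():
        if inflated:
            g_eta0[pos] = -pi[pos]
        yp, mup = y[pos], mu[pos]
        if dispersed:
            g_eta1[pos] = yp - (yp + k) * mu_frac[pos]
            g_t += (k * (special.digamma(yp + k) - special.digamma(k)
                         + log_ratio[pos] + 1.0
                         - (yp + k) / (k + mup))).sum()
        else:
            g_eta1[pos] = yp - mup
    if inflated:
        grad[:q] = X.T @ g_eta0
    grad[q:q + p] = X.T @ g_eta1
    if dispersed:
        grad[-1] = g_t
    return -ll, -grad


def _starts(y, X, offset, family):
    n, p = X.shape
    inflated = family in ("zinb", "zip")
    dispersed = family in ("zinb", "nb")
    zfrac = float(np.mean(y == 0))
    rate = max(np.sum(y) / np.sum(np.exp(offset)), 1e-12)
    starts = []

    # null start
    s = []
    if inflated:
        g0 = np.zeros(p)
        g0[0] = special.logit(min(max(zfrac, 1e-4), 1 - 1e-4)) - np.mean(offset)
        s.append(g0)
    b0 = np.zeros(p)
    b0[0] = np.log(rate)
    s.append(b0)
    if dispersed:
        s.append(np.zeros(1))
    starts.append(np.concatenate(s))

    # two-stage start: logistic on the zero indicator, Poisson on positives
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            parts = []
            if inflated:
                glm0 = sm.GLM((y == 0).astype(float), X,
                              family=sm.families.Binomial(), offset=offset)
                parts.append(np.clip(glm0.fit().params, -20, 20))
            mask = y > 0
            if mask.sum() > p:
                glm1 = sm.GLM(y[mask], X[mask], family=sm.families.Poisson(),
                              offset=offset[mask])
                parts.append(np.clip(glm1.fit().params, -30, 30))
            else:
                parts.append(b0)
            if dispersed:
                parts.append(np.zeros(1))
            starts.append(np.concatenate(parts))
    except Exception:
        pass
    return starts


def fit_mixture(y, design: DesignMatrix, family: str = "zinb") -> ZINBFit:
    """Joint maximum-likelihood fit of a (zero-inflated) count model.

    ``family`` is one of ``zinb``, ``zip`` (inflated), ``nb``, ``poisson``
    (no inflation component).  Standard errors are Wald, from the inverse
    numerical Hessian at the optimum.
    """
    family = family.lower()
    if family not in ("zinb", "zip", "nb", "poisson"):
        raise ValueError(f"unknown family {family!r}")
    y = np.asarray(y, dtype=float)
    X = design.matrix()
    offset = np.asarray(design.offset, dtype=float)
    if len(y) != len(X):
        raise ValueError("design rows must match y")
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("y must be non-negative integers")
    n, p = X.shape
    inflated = family in ("zinb", "zip")
    dispersed = family in ("zinb", "nb")
    npar = (p if inflated else 0) + p + (1 if dispersed else 0)
    if n <= npar:
        raise ValueError("more parameters than observations")
    if inflated and not (y == 0).any():
        warnings.warn("no zeros observed; inflation component is weakly identified")

    best = None
    for x0 in _starts(y, X, offset, family):
        res = optimize.minimize(
            _nll_and_grad, x0, args=(y, X, offset, family), jac=True,
            method="L-BFGS-B",
            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = best.x
    nll, grad = _nll_and_grad(params, y, X, offset, family)
    grad_norm = float(np.max(np.abs(grad)))
    if not best.success and grad_norm / max(1.0, n) > 1e-3:
        warnings.warn("optimizer did not fully converge; returning best fit found")

    # Wald standard errors via central-difference Hessian of the nll
    from statsmodels.tools.numdiff import approx_hess2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        H = approx_hess2(params, lambda th: _nll_and_grad(th, y, X, offset, family)[0])
    se = np.full(npar, np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
    except np.linalg.LinAlgError:
        pass
    zstat = params / se
    pvals = 2 * stats.norm.sf(np.abs(zstat))

    q = p if inflated else 0
    gamma = params[:q]
    beta = params[q:q + p]
    k = float(np.exp(params[-1])) if dispersed else None
    loglik = -float(nll)
    aic = 2 * npar - 2 * loglik
    bic = npar * np.log(n) - 2 * loglik
    names = ([f"logit:{c}" for c in design.X.columns] if inflated else []) + \
        [f"count:{c}" for c in design.X.columns] + \
        (["log_dispersion"] if dispersed else [])
    if inflated:
        pi = _sigmoid(X @ gamma + offset)
        if pi.max() > 1 - 1e-10 or pi.min() < 1e-10:
            warnings.warn("possible separation in the logistic component")
    return ZINBFit(
        family=family, gamma=gamma, beta=beta, k=k, loglik=loglik, df=npar,
        n=n, aic=float(aic), bic=float(bic), se=se, z=zstat, p=pvals,
        param_names=names, converged=bool(best.success), grad_norm=grad_norm,
        design=design, y=y.astype(int),
    )


def compare_models(fit_a: ZINBFit, fit_b: ZINBFit) -> dict:
    """AIC/BIC deltas and likelihood-ratio test between nested fits.

    The LRT chi-square reference is approximate when the restriction lies
    on the boundary of the parameter space (k -> infinity for ZINB vs
    ZIP), making the reported p conservative.
    """
    if fit_a.n != fit_b.n:
        raise ValueError("fits must be on identical data (n differs)")
    full, restricted = (fit_a, fit_b) if fit_a.df >= fit_b.df else (fit_b, fit_a)
    df_diff = full.df - restricted.df
    lrt = 2.0 * (full.loglik - restricted.loglik)
    lrt = max(lrt, 0.0)
    p = float(stats.chi2.sf(lrt, df_diff)) if df_diff > 0 else 1.0
    return {
        "delta_aic": fit_a.aic - fit_b.aic,
        "delta_bic": fit_a.bic - fit_b.bic,
        "lrt_stat": lrt,
        "lrt_df": df_diff,
        "lrt_p": p,
    }


@dataclass
class APVResult:
    covariate: str | None
    proportions_pct: pd.Series      # level -> overall fitted mean proportion, %
    significant_logistic: pd.Series | None = None
    significant_count: pd.Series | None = None


def apv_proportions(fit: ZINBFit, design: DesignMatrix, covariate: str | None = None,
                    alpha: float = 0.05) -> APVResult:
    """Average-predicted-value fitted mean proportions.

    For each level L of ``covariate``, every sample's covariate is set to
    L, the unconditional mean E[y] = (1 - pi) mu is predicted and averaged
    over samples, and divided by the mean total read count; reported as a
    percentage.  With ``covariate=None`` the overall fitted mean
    proportion is returned.
    """
    X0 = design.X.copy()
    T = np.exp(design.offset)
    mean_T = float(np.mean(T))

    def _apv(Xmod: pd.DataFrame) -> float:
        mean_pred = float(np.mean(fit.predict_mean(Xmod.to_numpy(dtype=float),
                                                   design.offset)))
        return 100.0 * mean_pred / mean_T

    if covariate is None:
        return APVResult(None, pd.Series({"overall": _apv(X0)}))

    if covariate not in design.columns_by_covariate:
        raise KeyError(f"covariate {covariate!r} not in design")
    if design.kinds.get(covariate) == "continuous":
        raise ValueError("APV levels are defined for categorical covariates")
    cov_cols = design.columns_by_covariate[covariate]
    ref = design.reference_levels[covariate]
    levels = [ref] + [c[c.index("[") + 1:-1] for c in cov_cols]
    out = {}
    sig_l, sig_c = {}, {}
    coef = fit.coef_table()
    for lv in levels:
        Xmod = X0.copy()
        for c in cov_cols:
            Xmod[c] = 1.0 if c == f"{covariate}[{lv}]" else 0.0
        out[lv] = _apv(Xmod)
        if lv == ref:
            sig_l[lv] = sig_c[lv] = False
        else:
            col = f"{covariate}[{lv}]"
            sig_l[lv] = bool(fit.inflated and coef.loc[f"logit:{col}", "p"] < alpha)
            sig_c[lv] = bool(coef.loc[f"count:{col}", "p"] < alpha)
    return APVResult(covariate, pd.Series(out),
                     pd.Series(sig_l), pd.Series(sig_c))
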