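"""Day-wise linear mixed-effects inference on component measures.

Each component measure (amplitude or latency, per deviant type) is modelled
as ``response ~ day`` with day categorical (day 1 the reference) as the fixed
effect and by-participant random intercepts and day slopes, estimated by
maximum likelihood.  Fixed-effect p-values use Satterthwaite-approximated
degrees of freedom.

The estimation engine is statsmodels' MixedLM; this module owns the model
specification, the Satterthwaite approximation (delta method on the GLS
fixed-effect variance with a finite-difference Hessian of the profiled ML
log-likelihood), and a documented fallback chain for the convergence
failures that small samples with full random-slope covariances invite:
full covariance -> diagonal -> random intercept only -> pooled OLS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .erp import ComponentMeasure

logger = logging.getLogger(__name__)

RESPONSES = {"amplitude": "amplitude_uv", "latency": "latency_ms"}


@dataclass(frozen=True)
class EffectEstimate:
    name: str
    estimate: float
    se: float
    t: float
    df: float
    p: float

    def __post_init__(self) -> None:
        if self.se <= 0 or self.df <= 0:
            raise ValueError("SE and df must be positive")


@dataclass(frozen=True)
class LmmFit:
    """Fixed-effect table of one fitted mixed model."""

    response: str
    component: str
    deviant_type: str
    effects: tuple[EffectEstimate, ...]
    converged: bool
    structure: str            # "full" | "diagonal" | "intercept" | "ols"
    loglike: float = np.nan

    def effect(self, name: str) -> EffectEstimate:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self, latency_in_seconds: bool = False) -> pd.DataFrame:
        rows = []
        for e in self.effects:
            scale = 0.001 if (latency_in_seconds and self.response == "latency") else 1.0
            rows.append({"effect": e.name, "Estimate": e.estimate * scale,
                         "SE": e.se * scale, "t": e.t, "df": e.df, "P": e.p})
        return pd.DataFrame(rows)


def build_measure_table(measures: list[ComponentMeasure]) -> pd.DataFrame:
    """Pivot component measures into the modelling layout.

    One row per participant x day x deviant type x component; duplicates are
    a validation error.  Days are integers with day 1 as the reference level.
    """
    if not measures:
        return pd.DataFrame(columns=["participant", "day", "deviant_type",
                                     "component", "amplitude_uv", "latency_ms"])
    df = pd.DataFrame([{
        "participant": m.participant, "day": int(m.day),
        "deviant_type": m.deviant_type, "component": m.component,
        "amplitude_uv": m.amplitude_uv, "latency_ms": m.latency_ms,
    } for m in measures])
    keys = ["participant", "day", "deviant_type", "component"]
    dup = df.duplicated(subset=keys)
    if dup.any():
        bad = df.loc[dup, keys].to_records(index=False)
        raise ValueError(f"duplicate measurement cells: {list(bad)[:5]}")
    return df.sort_values(keys).reset_index(drop=True)


def _design(sub: pd.DataFrame):
    days = np.sort(sub["day"].unique())
    ref = days[0]
    X = np.column_stack([np.ones(len(sub))] +
                        [(sub["day"] == d).to_numpy(float) for d in days[1:]])
    names = ["Intercept"] + [f"Day {d}" for d in days[1:]]
    return X, names, ref


def fit_lmm(table: pd.DataFrame, response: str, component: str,
            deviant_type: str) -> LmmFit:
    """Fit ``response ~ day + (day | participant)`` by ML for one cell.

    Requires >= 2 participants, each day observed for >= 2 participants.
    Satterthwaite df and two-sided p are attached per fixed effect.  When the
    full random-effects covariance fails to converge the structure is
    simplified (diagonal, then intercept-only, then pooled OLS), each step
    logged as a warning.
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {sorted(RESPONSES)}")
    sub = table[(table["component"] == component) &
                (table["deviant_type"] == deviant_type)].copy()
    if sub.empty:
        raise ValueError(f"no rows for component={component!r}, "
                         f"deviant_type={deviant_type!r}")
    if sub["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    day_counts = sub.groupby("day")["participant"].nunique()
    thin = day_counts[day_counts < 2]
    if not thin.empty:
        raise ValueError(
            f"rank-deficient design: days {list(thin.index)} observed for "
            f"fewer than 2 participants")
    sub = sub.sort_values(["participant", "day"])
    y = sub[RESPONSES[response]].to_numpy(float)
    X, names, _ = _design(sub)
    groups = sub["participant"].to_numpy()

    for structure in ("full", "diagonal", "intercept"):
        fit = _try_mixedlm(y, X, groups, structure)
        if fit is not None:
            effects = _satterthwaite_effects(y, X, groups, names, fit)
            if effects is not None:
                if structure != "full":
                    logger.warning("LMM %s/%s %s: simplified to %s structure",
                                   component, deviant_type, response, structure)
                return LmmFit(response=response, component=component,
                              deviant_type=deviant_type, effects=effects,
                              converged=True, structure=structure,
                              loglike=float(fit["llf"]))
    logger.warning("LMM %s/%s %s: mixed fit failed; pooled OLS fallback",
                   component, deviant_type, response)
    return _ols_fallback(y, X, names, response, component, deviant_type)


def _try_mixedlm(y, X, groups, structure: str):
    """One statsmodels MixedLM fit; returns parameter dict or None."""
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLMParams

    exog_re = np.ones((len(y), 1)) if structure == "intercept" else X
    k_re = exog_re.shape[1]
    free = None
    if structure == "diagonal":
        free = MixedLMParams.from_components(
            fe_params=np.ones(X.shape[1]), cov_re=np.eye(k_re))
    model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=False, free=free, method=["lbfgs", "bfgs"],
                            maxiter=200)
    except Exception:
        return None
    if not res.converged:
        return None
    beta = np.asarray(res.fe_params)
    cov_re = np.atleast_2d(np.asarray(res.cov_re)) * 1.0
    sigma2 = float(res.scale)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(cov_re))
            and np.isfinite(sigma2) and sigma2 > 0):
        return None
    return {"beta": beta, "cov_re": cov_re, "sigma2": sigma2,
            "exog_re": exog_re, "llf": res.llf, "structure": structure}


# ---------------------------------------------------------------------------
# Satterthwaite machinery
# ---------------------------------------------------------------------------

def _pack_theta(cov_re: np.ndarray, sigma2: float, structure: str) -> np.ndarray:
    if structure == "diagonal" or structure == "intercept":
        return np.concatenate([np.diag(cov_re), [sigma2]])
    q = cov_re.shape[0]
    tril = cov_re[np.tril_indices(q)]
    return np.concatenate([tril, [sigma2]])


def _unpack_theta(theta: np.ndarray, q: int, structure: str):
    if structure == "diagonal" or structure == "intercept":
        G = np.diag(theta[:q])
        return G, float(theta[q])
    G = np.zeros((q, q))
    G[np.tril_indices(q)] = theta[:-1]
    G = G + np.tril(G, -1).T
    return G, float(theta[-1])


def _group_blocks(y, X, Z, groups):
    blocks = []
    for g in pd.unique(groups):
        m = groups == g
        blocks.append((y[m], X[m], Z[m]))
    return blocks


def _beta_cov_and_loglike(blocks, G, sigma2):
    """GLS fixed-effect covariance and profiled ML log-likelihood at theta."""
    k = blocks[0][1].shape[1]
    XtVX = np.zeros((k, k))
    XtVy = np.zeros(k)
    logdet = 0.0
    n_total = 0
    for yi, Xi, Zi in blocks:
        Vi = Zi @ G @ Zi.T + sigma2 * np.eye(len(yi))
        sign, ld = np.linalg.slogdet(Vi)
        if sign <= 0:
            return None, None, None
        Vinv = np.linalg.inv(Vi)
        XtVX += Xi.T @ Vinv @ Xi
        XtVy += Xi.T @ Vinv @ yi
        logdet += ld
        n_total += len(yi)
    C = np.linalg.inv(XtVX)
    beta = C @ XtVy
    quad = 0.0
    for yi, Xi, Zi in blocks:
        Vi = Zi @ G @ Zi.T + sigma2 * np.eye(len(yi))
        ri = yi - Xi @ beta
        quad += ri @ np.linalg.solve(Vi, ri)
    llf = -0.5 * (n_total * np.log(2 * np.pi) + logdet + quad)
    return C, beta, llf


def _satterthwaite_effects(y, X, groups, names, fit,
                           rel_step: float = 1e-4):
    """Delta-method Satterthwaite df for every fixed effect.

    For effect j, f(theta) = [ (sum_i X_i' V_i^-1 X_i)^-1 ]_jj and
    df_j = 2 f^2 / (g' A g) with g the gradient of f and A the inverse
    observed information of the profiled ML log-likelihood.  df is clamped
    to [1, n - k].  Returns None if the likelihood surface is numerically
    unusable (caller then simplifies the structure).
    """
    structure = fit["structure"]
    Z = fit["exog_re"]
    q = Z.shape[1]
    blocks = _group_blocks(y, X, Z, np.asarray(groups))
    theta_hat = _pack_theta(fit["cov_re"], fit["sigma2"], structure)
    scale = np.maximum(np.abs(theta_hat), fit["sigma2"] * 1e-3)
    h = rel_step * scale

    def f_and_ll(theta):
        G, s2 = _unpack_theta(theta, q, structure)
        if s2 <= 0:
            return None, None
        # project G to PSD (finite differences can step past the boundary)
        w, V = np.linalg.eigh((G + G.T) / 2)
        G = (V * np.maximum(w, 0.0)) @ V.T
        C, _, llf = _beta_cov_and_loglike(blocks, G, s2)
        if C is None:
            return None, None
        return np.diag(C), llf

    p = len(theta_hat)
    f0, ll0 = f_and_ll(theta_hat)
    if f0 is None:
        return None
    k = X.shape[1]
    n = len(y)

    # gradient of f (per effect) and Hessian of loglike, central differences
    grads = np.zeros((k, p))
    H = np.zeros((p, p))
    ll_cache = {}

    def ll_at(offsets: tuple) -> float | None:
        if offsets not in ll_cache:
            theta = theta_hat + np.array(offsets) * h
            ll_cache[offsets] = f_and_ll(theta)
        return ll_cache[offsets]

    for a in range(p):
        e = tuple(1 if i == a else 0 for i in range(p))
        me = tuple(-1 if i == a else 0 for i in range(p))
        fp, lp = ll_at(e)
        fm, lm = ll_at(me)
        if fp is None or fm is None:
            return None
        grads[:, a] = (fp - fm) / (2 * h[a])
        H[a, a] = (lp - 2 * ll0 + lm) / h[a] ** 2
    for a in range(p):
        for b in range(a + 1, p):
            pp = ll_at(tuple(1 if i in (a, b) else 0 for i in range(p)))[1]
            pm = ll_at(tuple(1 if i == a else (-1 if i == b else 0)
                             for i in range(p)))[1]
            mp = ll_at(tuple(-1 if i == a else (1 if i == b else 0)
                             for i in range(p)))[1]
            mm = ll_at(tuple(-1 if i in (a, b) else 0 for i in range(p)))[1]
            if None in (pp, pm, mp, mm):
                return None
            H[a, b] = H[b, a] = (pp - pm - mp + mm) / (4 * h[a] * h[b])

    info = -H
    A = np.linalg.pinv((info + info.T) / 2)

    C_hat, beta, _ = _beta_cov_and_loglike(
        blocks, *_unpack_theta(theta_hat, q, structure))
    effects = []
    for j, name in enumerate(names):
        var_j = float(C_hat[j, j])
        if var_j <= 0 or not np.isfinite(var_j):
            return None
        g = grads[j]
        denom = float(g @ A @ g)
        df = 2 * var_j**2 / denom if denom > 1e-300 else float(n - k)
        df = float(np.clip(df, 1.0, n - k))
        se = np.sqrt(var_j)
        t = float(beta[j] / se)
        p_val = float(2 * stats.t.sf(abs(t), df))
        effects.append(EffectEstimate(name, float(beta[j]), se, t, df,
                                      max(p_val, np.finfo(float).tiny)))
    return tuple(effects)


def _ols_fallback(y, X, names, response, component, deviant_type) -> LmmFit:
    """Pooled OLS when every mixed structure fails (degenerate variance)."""
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(n - k, 1)
    s2 = float(resid @ resid) / dof
    C = np.linalg.inv(X.T @ X)
    effects = []
    for j, name in enumerate(names):
        se = float(np.sqrt(max(s2 * C[j, j], np.finfo(float).tiny)))
        t = float(beta[j] / se)
        p_val = float(2 * stats.t.sf(abs(t), dof))
        effects.append(EffectEstimate(name, float(beta[j]), se, t, float(dof),
                                      max(p_val, np.finfo(float).tiny)))
    return LmmFit(response=response, component=component,
                  deviant_type=deviant_type, effects=tuple(effects),
                  converged=False, structure="ols")


def fit_all(table: pd.DataFrame, latency_in_seconds: bool = False) -> pd.DataFrame:
    """Fit every component x deviant type x response; tidy results table."""
    rows = []
    for response in RESPONSES:
        for comp in sorted(table["component"].unique()):
            for dtype in sorted(table["deviant_type"].unique()):
                fit = fit_lmm(table, response, comp, dtype)
                frame = fit.to_frame(latency_in_seconds=latency_in_seconds)
                frame.insert(0, "response", response)
                frame.insert(1, "component", comp)
                frame.insert(2, "deviant_type", dtype)
                frame["structure"] = fit.structure
                rows.append(frame)
    return pd.concat(rows, ignore_index=True)
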