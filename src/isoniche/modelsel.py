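"""Information-theoretic model comparison for Gaussian (mixed) models.

Fits the candidate set for delta15N ~ length x protection status (and any
other Gaussian response) as ordinary least squares or as a linear mixed
model with a site random intercept, then compares models with AICc:

    AICc = -2 logL + 2K + 2K(K+1)/(n - K - 1)
    Delta_i = AICc_i - min AICc
    W_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)

Models with Delta <= 2 are flagged well-supported; models with Delta < 4
form the averaging set.  Averaged coefficients use the natural-average
(conditional) convention with Buckland unconditional variance; relative
variable importance (RVI) of a predictor is the sum of the Akaike weights
of all candidate models containing it.

K counts every estimated parameter: fixed effects plus the residual
variance, plus the between-group variance for random-intercept models.
Some published tables instead count the intercept separately (K one
larger); :func:`selection_table` accepts externally supplied
(logLik, K, n) triples, so either convention can be reproduced.

The random-intercept fitter profiles the likelihood down to the single
variance ratio lambda = sigma_site^2 / sigma_resid^2 and maximises it by
1-D numerical optimisation — exact for this model family, with the
boundary lambda = 0 (no site variance) checked explicitly.  Model
selection compares ML fits; REML is available for reporting variance
components but REML likelihoods are never compared across different
fixed-effect structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .records import ConfigurationError, DataError, logger


# ---------------------------------------------------------------------------
# predictor standardisation
# ---------------------------------------------------------------------------

def standardize_2sd(x) -> np.ndarray:
    """(x - mean) / (2 sd), sd with n-1 denominator.

    Puts continuous predictors on a scale comparable with binary ones, so
    averaged coefficients can be compared directly across predictors.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("standardize_2sd expects a 1-D column with >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DataError("cannot standardize a constant column")
    return (x - x.mean()) / (2.0 * sd)


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class ModelFit:
    """A fitted Gaussian model reduced to what model selection needs."""

    name: str
    response: str
    terms: tuple[str, ...]
    has_random_intercept: bool
    loglik: float
    k: int
    n: int
    coefficients: dict[str, tuple[float, float]]  # name -> (estimate, SE)
    r2_marginal: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("K must be >= 2 (intercept + residual variance)")
        if self.n <= self.k + 1:
            raise ValueError(f"AICc needs n > K + 1 (n={self.n}, K={self.k})")


def _design(df: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; 'a:b' terms are elementwise products."""
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(df[a].to_numpy(float) * df[b].to_numpy(float))
        else:
            cols.append(df[t].to_numpy(float))
        names.append(t)
    return np.column_stack(cols), names


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.argsort(diag)[: x.shape[1] - rank]]
        raise DataError(f"rank-deficient design; aliased terms: {bad}")


def fit_linear(df: pd.DataFrame, response: str, terms: Sequence[str],
               name: str | None = None) -> ModelFit:
    """Exact least-squares Gaussian fit; logLik at the ML residual variance.

    K = number of coefficients + 1 (residual variance).  A perfect fit
    (residual variance numerically zero) is flagged in ``extra`` and given
    a clipped variance so the log-likelihood stays finite.
    """
    y = df[response].to_numpy(float)
    x, names = _design(df, terms)
    n, p = x.shape
    if n <= p + 1:
        raise DataError(f"n={n} too small for {p} coefficients")
    _check_rank(x, names)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    perfect = sigma2_ml < 1e-12 * max(float(y.var()), 1.0)
    if perfect:
        logger.warning("model %s: residual variance ~ 0 (perfect fit)", name or terms)
        sigma2_ml = max(sigma2_ml, 1e-12)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
    xtx_inv = np.linalg.inv(x.T @ x)
    sigma2_unbiased = rss / (n - p) if n > p else np.nan
    se = np.sqrt(np.diag(xtx_inv) * sigma2_unbiased)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return ModelFit(
        name=name or ("~" + "+".join(terms) if terms else "~1"),
        response=response, terms=tuple(terms), has_random_intercept=False,
        loglik=float(loglik), k=p + 1, n=n,
        coefficients={nm: (float(b), float(s)) for nm, b, s in zip(names, beta, se)},
        r2_marginal=r2,
        extra={"sigma2_ml": sigma2_ml, "perfect_fit": perfect},
    )


def _profiled_loglik(lam: float, y: np.ndarray, x: np.ndarray,
                     group_idx: list[np.ndarray], reml: bool) -> tuple[float, dict]:
    """Profiled (restricted) log-likelihood at variance ratio lambda >= 0.

    V = sigma^2 (I + lambda Z Z'); the block structure of the random
    intercept gives W_j^{-1} = I - lambda/(1 + n_j lambda) 11' per group,
    so everything is O(n).
    """
    n, p = x.shape
    xtwx = np.zeros((p, p))
    xtwy = np.zeros(p)
    logdet_w = 0.0
    for idx in group_idx:
        nj = len(idx)
        xj, yj = x[idx], y[idx]
        c = lam / (1.0 + nj * lam)
        sx = xj.sum(axis=0)
        sy = yj.sum()
        xtwx += xj.T @ xj - c * np.outer(sx, sx)
        xtwy += xj.T @ yj - c * sx * sy
        logdet_w += np.log1p(nj * lam)
    beta = np.linalg.solve(xtwx, xtwy)
    q = 0.0
    for idx in group_idx:
        rj = y[idx] - x[idx] @ beta
        c = lam / (1.0 + len(idx) * lam)
        q += rj @ rj - c * rj.sum() ** 2
    if reml:
        sigma2 = q / (n - p)
        sign, logdet_xtwx = np.linalg.slogdet(xtwx)
        ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
                     + logdet_w + logdet_xtwx)
    else:
        sigma2 = q / n
        ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_w)
    return float(ll), {"beta": beta, "sigma2": sigma2, "xtwx": xtwx}


def fit_random_intercept(df: pd.DataFrame, response: str, terms: Sequence[str],
                         group: str, method: str = "ML",
                         name: str | None = None) -> ModelFit:
    """Gaussian linear model with one random intercept per group level.

    Maximises the (restricted) likelihood profiled down to
    lambda = sigma_group^2 / sigma_resid^2 by bounded 1-D optimisation on
    log(lambda), with the boundary lambda = 0 checked explicitly (flagged
    when selected).  K counts fixed effects + 2 variance components.
    """
    if method not in ("ML", "REML"):
        raise ConfigurationError("method must be 'ML' or 'REML'")
    y = df[response].to_numpy(float)
    x, names = _design(df, terms)
    n, p = x.shape
    labels = df[group].to_numpy()
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise DataError("random intercept requires >= 2 group levels")
    if n <= p + 2:
        raise DataError(f"n={n} too small for {p} coefficients + 2 variance components")
    _check_rank(x, names)
    group_idx = [np.flatnonzero(labels == g) for g in levels]
    reml = method == "REML"

    def neg(t):  # t = log(lambda)
        return -_profiled_loglik(np.exp(t), y, x, group_idx, reml)[0]

    res = minimize_scalar(neg, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        raise DataError(f"random-intercept fit did not converge: {res.message}; "
                        f"bracket log-lambda in [-12, 8]")
    ll_opt = -res.fun
    lam = float(np.exp(res.x))
    ll0, _ = _profiled_loglik(0.0, y, x, group_idx, reml)
    boundary = ll0 >= ll_opt - 1e-10
    if boundary:
        lam, ll_opt = 0.0, ll0
        logger.info("model %s: between-group variance estimated at boundary 0",
                    name or terms)
    ll, parts = _profiled_loglik(lam, y, x, group_idx, reml)
    sigma2 = parts["sigma2"]
    se = np.sqrt(np.diag(np.linalg.inv(parts["xtwx"])) * sigma2)
    beta = parts["beta"]
    # marginal R2: fixed-effects variance share of the total modelled variance
    fitted = x @ beta
    var_f = float(fitted.var(ddof=0))
    r2_marg = var_f / (var_f + lam * sigma2 + sigma2)
    return ModelFit(
        name=name or ("~" + "+".join(terms) + f" + (1|{group})"),
        response=response, terms=tuple(terms), has_random_intercept=True,
        loglik=float(ll), k=p + 2, n=n,
        coefficients={nm: (float(b), float(s)) for nm, b, s in zip(names, beta, se)},
        r2_marginal=r2_marg,
        extra={"method": method, "lambda": lam, "sigma2_resid": float(sigma2),
               "sigma2_group": float(lam * sigma2), "boundary": bool(boundary)},
    )


# ---------------------------------------------------------------------------
# AICc, selection table, averaging
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n <= K + 1 (n={n}, K={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _as_triple(fit) -> tuple[str, float, int, int]:
    if isinstance(fit, ModelFit):
        return fit.name, fit.loglik, fit.k, fit.n
    name, loglik, k, n = fit
    return str(name), float(loglik), int(k), int(n)


def selection_table(fits: Sequence,
                    delta_support: float = 2.0,
                    delta_average: float = 4.0) -> pd.DataFrame:
    """AICc / Delta / Akaike-weight table over a candidate model set.

    Accepts :class:`ModelFit` objects or plain (name, logLik, K, n)
    tuples, so externally fitted models (e.g. Poisson GLMMs of transect
    counts) can enter the same table.  All models must share n (and
    response, when known): AICc values are otherwise not comparable.
    """
    if not fits:
        raise ConfigurationError("empty candidate set")
    triples = [_as_triple(f) for f in fits]
    ns = {t[3] for t in triples}
    if len(ns) != 1:
        raise ConfigurationError(f"models fitted to different n: {sorted(ns)}")
    responses = {f.response for f in fits if isinstance(f, ModelFit)}
    if len(responses) > 1:
        raise ConfigurationError(f"models fit different responses: {sorted(responses)}")
    rows = [{"model": name, "loglik": ll, "k": k, "n": n,
             "aicc": aicc(ll, k, n)} for name, ll, k, n in triples]
    df = pd.DataFrame(rows)
    df["delta_aicc"] = df["aicc"] - df["aicc"].min()
    rel = np.exp(-df["delta_aicc"] / 2.0)
    df["weight"] = rel / rel.sum()
    df["well_supported"] = df["delta_aicc"] <= delta_support
    df["averaging_set"] = df["delta_aicc"] < delta_average
    return df.sort_values("delta_aicc", ignore_index=True)


def selection_report(table: pd.DataFrame, response: str = "") -> str:
    """Plain-text report (Model, K, Log(L), AICc, Delta AICc, W_i)."""
    lines = [f"{'Model':<40}{'K':>4}{'Log(L)':>10}{'AICc':>9}{'dAICc':>8}{'Wi':>7}"]
    for _, r in table.iterrows():
        lines.append(f"{r['model']:<40}{r['k']:>4d}{r['loglik']:>10.2f}"
                     f"{r['aicc']:>9.1f}{r['delta_aicc']:>8.2f}{r['weight']:>7.2f}")
    header = f"Response: {response}\n" if response else ""
    return header + "\n".join(lines) + "\n"


def model_average(fits: Sequence[ModelFit],
                  table: pd.DataFrame | None = None,
                  delta_average: float = 4.0,
                  convention: str = "natural") -> pd.DataFrame:
    """Averaged coefficients, unconditional variance, and RVI per predictor.

    Averaging runs over the models with Delta AICc < ``delta_average``.
    ``natural`` (conditional) averaging renormalises weights over the
    models that contain each predictor; ``full`` substitutes zero where a
    predictor is absent.  Unconditional variance follows the Buckland
    form: sum of weights * (SE^2 + (beta_i - beta_bar)^2).  RVI is the
    sum of the weights of all candidate models containing the predictor,
    over the full candidate set.
    """
    if convention not in ("natural", "full"):
        raise ConfigurationError("convention must be 'natural' or 'full'")
    if table is None:
        table = selection_table(fits, delta_average=delta_average)
    weight = dict(zip(table["model"], table["weight"]))
    in_set = dict(zip(table["model"], table["averaging_set"]))
    avg_fits = [f for f in fits if in_set.get(f.name, False)]
    if not avg_fits:
        raise ConfigurationError("empty averaging set")

    predictors: list[str] = []
    for f in fits:
        for c in f.coefficients:
            if c not in predictors:
                predictors.append(c)
    rows = []
    for pred in predictors:
        having = [f for f in avg_fits if pred in f.coefficients]
        if not having:
            continue
        w = np.array([weight[f.name] for f in having])
        b = np.array([f.coefficients[pred][0] for f in having])
        s = np.array([f.coefficients[pred][1] for f in having])
        if convention == "natural":
            wn = w / w.sum()
        else:
            absent = [f for f in avg_fits if pred not in f.coefficients]
            w = np.concatenate([w, [weight[f.name] for f in absent]])
            b = np.concatenate([b, np.zeros(len(absent))])
            s = np.concatenate([s, np.zeros(len(absent))])
            wn = w / w.sum()
        bbar = float(wn @ b)
        var_u = float(wn @ (s ** 2 + (b - bbar) ** 2))
        rvi = float(sum(weight[f.name] for f in fits if pred in f.coefficients))
        rows.append({"predictor": pred, "estimate": bbar,
                     "unconditional_se": np.sqrt(var_u), "rvi": rvi,
                     "n_models": len(having)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the delta15N candidate set
# ---------------------------------------------------------------------------

#: candidate fixed-effect structures for delta15N ~ length x status,
#: respecting marginality (interactions carry their main effects)
D15N_CANDIDATES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("Length + Status + Length*Status",
     ("length_std", "protected", "length_std:protected")),
    ("Length + Status", ("length_std", "protected")),
    ("Status", ("protected",)),
    ("Length", ("length_std",)),
    ("Intercept", ()),
)


def fit_d15n_candidates(df: pd.DataFrame, group: str = "site",
                        method: str = "ML") -> list[ModelFit]:
    """Fit the delta15N candidate set with a site random intercept.

    Expects columns ``d15n``, ``length_cm``, ``protected`` (0/1) and the
    grouping column.  Length is 2-SD standardized before fitting.
    """
    df = df.copy()
    df["length_std"] = standardize_2sd(df["length_cm"].to_numpy())
    return [fit_random_intercept(df, "d15n", terms, group, method=method, name=name)
            for name, terms in D15N_CANDIDATES]
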