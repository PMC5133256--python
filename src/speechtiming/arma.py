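"""ARMA(p, d, q) model grid with Akaike-weight multimodel inference.

The observed series is the log of the interval durations, NaN-masked
across phrase breaks; the exogenous regressor is the *preceding*
intensity difference.  Differencing order d chooses between modeling
absolute log-durations (d = 0) and relative durations, i.e. log-ratios
of adjacent intervals (d = 1).  With p, q ∈ 0..5 and d ∈ {0, 1} the
grid has 72 variants; models are compared through the small-sample
corrected information criterion AICc and the derived Akaike weights.

Likelihoods are exact Gaussian likelihoods computed by a state-space
(Kalman filter) recursion that skips missing observations
(statsmodels' SARIMAX backend); stationarity and invertibility are
enforced by parameter transformation, and optimization is
deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.statespace.sarimax import SARIMAX

__all__ = [
    "ArmaSpec",
    "ArmaFit",
    "ModelTable",
    "ArmaError",
    "MAX_ORDER",
    "enumerate_grid",
    "fit_arma",
    "aicc",
    "akaike_weights",
    "akaike_set",
    "grid_search",
    "d1_weight_share",
    "marginal_weights_by_p",
]

logger = logging.getLogger(__name__)

#: Default maximum AR/MA order of the search grid.
MAX_ORDER = 5

#: Default minimum number of present observations required for a fit.
MIN_OBSERVATIONS = 20


class ArmaError(ValueError):
    """Raised for invalid specifications or unusable input series."""


@dataclass(frozen=True, order=True)
class ArmaSpec:
    """One grid point: AR order p, differencing order d, MA order q."""

    p: int
    d: int
    q: int
    with_exog: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.p and 0 <= self.q and 0 <= self.d <= 1):
            raise ArmaError(f"invalid ARMA spec ({self.p},{self.d},{self.q})")

    @property
    def order(self) -> int:
        return self.p + self.d + self.q


@dataclass
class ArmaFit:
    """A maximum-likelihood fit of one specification."""

    spec: ArmaSpec
    loglik: float
    k: int
    n_eff: int
    aicc: float
    coefficients: dict[str, float]
    innovation_var: float
    converged: bool


@dataclass
class ModelTable:
    """All grid fits for one language plus the weight-based summaries."""

    fits: list[ArmaFit]
    weights: np.ndarray
    akaike_set: list[int] = field(default_factory=list)
    best: ArmaFit | None = None

    def to_dataframe(self) -> pd.DataFrame:
        in_set = set(self.akaike_set)
        rows = []
        for idx, (f, w) in enumerate(zip(self.fits, self.weights)):
            rows.append(
                {
                    "p": f.spec.p,
                    "d": f.spec.d,
                    "q": f.spec.q,
                    "with_exog": f.spec.with_exog,
                    "loglik": f.loglik,
                    "k": f.k,
                    "n_eff": f.n_eff,
                    "aicc": f.aicc,
                    "weight": w,
                    "in_akaike_set": idx in in_set,
                    "converged": f.converged,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def enumerate_grid(
    max_p: int = MAX_ORDER, max_q: int = MAX_ORDER, max_d: int = 1, with_exog: bool = True
) -> list[ArmaSpec]:
    """All specifications with p ≤ max_p, q ≤ max_q, d ≤ max_d
    (72 variants at the defaults)."""
    return [
        ArmaSpec(p=p, d=d, q=q, with_exog=with_exog)
        for p in range(max_p + 1)
        for d in range(max_d + 1)
        for q in range(max_q + 1)
    ]


def _prepare(
    y: np.ndarray, x: np.ndarray | None, spec: ArmaSpec
) -> tuple[np.ndarray, np.ndarray | None]:
    """Difference and lag-align the series and regressor.

    d = 1 differences the log-durations (NaN propagates), turning the
    series into log-ratios; the exogenous intensity difference is NOT
    differenced (it is already a first difference), and is aligned so
    that observation t is regressed on the intensity difference that
    precedes it.  For d = 0 the first observation is dropped to obtain
    the same lag-1 alignment.
    """
    y = np.asarray(y, dtype=float)
    if spec.with_exog:
        if x is None:
            raise ArmaError("spec requires an exogenous regressor but x is None")
        x = np.asarray(x, dtype=float)
        if x.shape != y.shape:
            raise ArmaError("y and x must have equal length")
    if spec.d == 1:
        endog = np.diff(y)  # r_s = y_{s+1} − y_s; NaN propagates
        exog = x[:-1].copy() if spec.with_exog else None
    else:
        endog = y[1:].copy()
        exog = x[:-1].copy() if spec.with_exog else None
    if exog is not None:
        # Where the regressor is missing the observation cannot enter the
        # likelihood; mask it and zero the regressor (ignored by the
        # filter once the observation is NaN).
        bad = ~np.isfinite(exog)
        endog = endog.copy()
        endog[bad] = np.nan
        exog[bad] = 0.0
        exog = exog.reshape(-1, 1)
    return endog, exog


def fit_arma(
    y: np.ndarray,
    x: np.ndarray | None,
    spec: ArmaSpec,
    min_obs: int = MIN_OBSERVATIONS,
    drift: bool = False,
    maxiter: int = 200,
) -> ArmaFit:
    """Fit one specification by exact maximum likelihood.

    Parameters
    ----------
    y : array
        Log interval durations with NaN for masked intervals.
    x : array or None
        Intensity differences aligned with ``y`` (NaN-masked); required
        when ``spec.with_exog``.
    spec : ArmaSpec
        Orders to fit.
    min_obs : int
        Minimum number of present observations after differencing.
    drift : bool
        Include a constant under d = 1 (off by default: relative
        durations are treated as mean-zero).
    """
    endog, exog = _prepare(y, x, spec)
    n_eff = int(np.isfinite(endog).sum())
    if n_eff < min_obs:
        raise ArmaError(
            f"too few observations for ({spec.p},{spec.d},{spec.q}): "
            f"{n_eff} < {min_obs}"
        )
    trend = "c" if (spec.d == 0 or drift) else "n"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SARIMAX(
            endog,
            exog=exog,
            order=(spec.p, 0, spec.q),
            trend=trend,
            enforce_stationarity=True,
            enforce_invertibility=True,
        )
        res = model.fit(method="lbfgs", maxiter=maxiter, disp=False)
    converged = bool(res.mle_retvals.get("converged", True))
    k = len(res.params)  # AR + MA + trend + exog + innovation variance
    coefficients = {name: float(v) for name, v in zip(res.model.param_names, res.params)}
    fit = ArmaFit(
        spec=spec,
        loglik=float(res.llf),
        k=k,
        n_eff=n_eff,
        aicc=np.nan,
        coefficients=coefficients,
        innovation_var=float(coefficients.get("sigma2", np.nan)),
        converged=converged,
    )
    fit.aicc = aicc(fit)
    return fit


def aicc(fit: ArmaFit) -> float:
    """Small-sample corrected AIC:
    AICc = −2·loglik + 2k + 2k(k+1)/(n_eff − k − 1),
    infinite (model excluded) when n_eff ≤ k + 1."""
    aic = -2.0 * fit.loglik + 2.0 * fit.k
    denom = fit.n_eff - fit.k - 1
    if denom <= 0:
        return float("inf")
    return float(aic + 2.0 * fit.k * (fit.k + 1) / denom)


def akaike_weights(aiccs: np.ndarray) -> np.ndarray:
    """Akaike weights w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2) with
    Δ_i = AICc_i − min_j AICc_j; infinite AICc gets weight 0."""
    a = np.asarray(aiccs, dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ArmaError("no finite AICc value to weight")
    delta = a - a[finite].min()
    raw = np.where(finite, np.exp(-0.5 * np.where(finite, delta, 0.0)), 0.0)
    return raw / raw.sum()


def akaike_set(
    weights: np.ndarray,
    threshold: float = 0.95,
    tiebreak: list | None = None,
) -> list[int]:
    """Indices of the minimal weight-sorted prefix with cumulative
    weight ≥ threshold.

    ``tiebreak`` optionally supplies a sortable key per model (e.g.
    (k, p+d+q, (p, d, q))) used to order equal weights deterministically.
    """
    w = np.asarray(weights, dtype=float)
    keys = tiebreak if tiebreak is not None else list(range(len(w)))
    order = sorted(range(len(w)), key=lambda i: (-w[i], keys[i]))
    out: list[int] = []
    cum = 0.0
    for i in order:
        out.append(i)
        cum += w[i]
        if cum >= threshold - 1e-12:
            break
    return out


def grid_search(
    y: np.ndarray,
    x: np.ndarray | None,
    max_p: int = MAX_ORDER,
    max_q: int = MAX_ORDER,
    max_d: int = 1,
    with_exog: bool = True,
    threshold: float = 0.95,
    min_obs: int = MIN_OBSERVATIONS,
    drift: bool = False,
) -> ModelTable:
    """Fit the full grid and run the Akaike-weight comparison.

    Non-converged fits (and fits with infinite AICc) are excluded from
    the weight normalization and logged; their weight is 0.
    """
    specs = enumerate_grid(max_p=max_p, max_q=max_q, max_d=max_d, with_exog=with_exog)
    fits: list[ArmaFit] = []
    for spec in specs:
        try:
            fit = fit_arma(y, x, spec, min_obs=min_obs, drift=drift)
        except ArmaError:
            raise
        except Exception as exc:  # numerical failure inside the optimizer
            logger.warning(
                "spec (%d,%d,%d) failed to fit: %s", spec.p, spec.d, spec.q, exc
            )
            fit = ArmaFit(
                spec=spec,
                loglik=float("-inf"),
                k=0,
                n_eff=0,
                aicc=float("inf"),
                coefficients={},
                innovation_var=float("nan"),
                converged=False,
            )
        if not fit.converged:
            logger.warning(
                "spec (%d,%d,%d) did not converge; excluded from weights",
                spec.p,
                spec.d,
                spec.q,
            )
        fits.append(fit)
    usable = np.array(
        [f.converged and np.isfinite(f.aicc) for f in fits], dtype=bool
    )
    if not usable.any():
        raise ArmaError("no model in the grid converged")
    aiccs = np.array([f.aicc if u else float("inf") for f, u in zip(fits, usable)])
    weights = akaike_weights(aiccs)
    tiebreak = [
        (f.k, f.spec.order, (f.spec.p, f.spec.d, f.spec.q)) for f in fits
    ]
    members = akaike_set(weights, threshold=threshold, tiebreak=tiebreak)
    best_idx = min(
        (i for i in range(len(fits)) if usable[i]),
        key=lambda i: (aiccs[i], tiebreak[i]),
    )
    return ModelTable(
        fits=fits, weights=weights, akaike_set=members, best=fits[best_idx]
    )


def d1_weight_share(table: ModelTable) -> float:
    """Percentage of total Akaike weight on d = 1 models."""
    mask = np.array([f.spec.d == 1 for f in table.fits])
    return float(100.0 * table.weights[mask].sum())


def marginal_weights_by_p(table: ModelTable, max_p: int = MAX_ORDER) -> np.ndarray:
    """Akaike weights summed over d and q for each AR order p."""
    out = np.zeros(max_p + 1)
    for f, w in zip(table.fits, table.weights):
        out[f.spec.p] += w
    return out
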