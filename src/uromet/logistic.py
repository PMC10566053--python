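"""Binary logistic regression engine and endpoint definitions.

Every modelling stage of the pipeline — univariate screening, AIC
backward elimination, panel sizing, and the final risk models — calls
:func:`fit_logistic`.  The fit is maximum likelihood via iteratively
reweighted least squares (IRLS); when the likelihood is unbounded
(quasi-complete separation) or IRLS fails to converge, the model is
refit with a small ridge penalty on the slopes (never the intercept) and
flagged, so that screening loops never abort on a degenerate candidate.

The four dichotomous endpoints map NCCN risk strata (and Gleason sum)
onto binary outcomes:

* ``I``   — benign vs any prostate cancer;
* ``II``  — insignificant (benign, VLR, LR) vs significant (FIR and up),
  the framing for men with long life expectancy;
* ``III`` — insignificant (benign through FIR) vs significant (UIR and
  up), for shorter life expectancy;
* ``GS``  — benign or Gleason sum < 7 vs Gleason sum >= 7 (high grade).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "LogisticFit",
    "fit_logistic",
    "predict_probability",
    "EndpointSpec",
    "ENDPOINTS",
    "build_endpoint_labels",
]

_MAX_ITER = 100
_GTOL = 1e-8
_RIDGE_FALLBACK = 1e-4
_ETA_CLIP = 30.0


@dataclass
class LogisticFit:
    """A fitted binary logistic model.

    ``params[0]`` is the intercept; ``params[1:]`` align with
    ``predictor_ids``.  ``converged`` is True only when the plain
    (unpenalised) maximum-likelihood fit converged; a ridge-rescued fit
    reports ``converged=False`` with ``penalty`` > 0.
    """

    params: np.ndarray
    predictor_ids: tuple
    llf: float
    aic: float
    bse: np.ndarray
    pvalues: np.ndarray
    converged: bool
    penalty: float
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "predictor_ids": list(self.predictor_ids),
            "intercept": float(self.params[0]),
            "coef": [float(b) for b in self.params[1:]],
            "llf": float(self.llf),
            "aic": float(self.aic),
            "converged": bool(self.converged),
            "penalty": float(self.penalty),
            "n_obs": int(self.n_obs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticFit":
        params = np.asarray([d["intercept"]] + list(d["coef"]), dtype=float)
        k = params.size
        return cls(
            params=params,
            predictor_ids=tuple(d["predictor_ids"]),
            llf=float(d["llf"]),
            aic=float(d["aic"]),
            bse=np.full(k, np.nan),
            pvalues=np.full(k, np.nan),
            converged=bool(d["converged"]),
            penalty=float(d["penalty"]),
            n_obs=int(d["n_obs"]),
        )


def _as_design(X) -> tuple[np.ndarray, tuple]:
    if isinstance(X, pd.DataFrame):
        return np.asarray(X.to_numpy(dtype=float)), tuple(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, tuple(range(X.shape[1]))


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + e^eta), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


try:  # the JIT-compiled inner loop is a pure speed optimisation
    from numba import njit as _njit

    @_njit(cache=False, fastmath=False)
    def _irls_core(Xd, y, pen, beta, max_iter, gtol, eta_clip, plain):
        n, p = Xd.shape
        eta = Xd @ beta
        for i in range(n):
            if eta[i] > eta_clip:
                eta[i] = eta_clip
            elif eta[i] < -eta_clip:
                eta[i] = -eta_clip
        llf = 0.0
        for i in range(n):
            sp = np.log1p(np.exp(-abs(eta[i]))) + max(eta[i], 0.0)
            llf += y[i] * eta[i] - sp
        obj = llf - 0.5 * np.sum(pen * beta * beta)
        H = np.eye(p)
        for _ in range(max_iter):
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            for i in range(n):
                if w[i] < 1e-10:
                    w[i] = 1e-10
            grad = Xd.T @ (y - mu) - pen * beta
            H = (Xd * w.reshape(-1, 1)).T @ Xd
            for j in range(p):
                H[j, j] += pen[j]
            gmax = 0.0
            for j in range(p):
                if abs(grad[j]) > gmax:
                    gmax = abs(grad[j])
            if gmax < gtol:
                return beta, H, 1
            step = np.linalg.solve(H, grad)
            accepted = False
            cand = beta
            eta_c = eta
            obj_c = obj
            for _ in range(25):
                cand = beta + step
                eta_c = Xd @ cand
                for i in range(n):
                    if eta_c[i] > eta_clip:
                        eta_c[i] = eta_clip
                    elif eta_c[i] < -eta_clip:
                        eta_c[i] = -eta_clip
                llf_c = 0.0
                for i in range(n):
                    sp = np.log1p(np.exp(-abs(eta_c[i]))) + max(eta_c[i], 0.0)
                    llf_c += y[i] * eta_c[i] - sp
                obj_c = llf_c - 0.5 * np.sum(pen * cand * cand)
                finite = True
                for j in range(p):
                    if not np.isfinite(cand[j]):
                        finite = False
                        break
                if finite and obj_c >= obj - 1e-12:
                    accepted = True
                    break
                step = step * 0.5
            if not accepted:
                return beta, H, 0
            beta, eta, obj = cand, eta_c, obj_c
            if plain == 1:
                bmax = 0.0
                for j in range(p):
                    if abs(beta[j]) > bmax:
                        bmax = abs(beta[j])
                if bmax > 30.0:
                    return beta, H, 0
        return beta, H, 0

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba always present in practice
    _HAVE_NUMBA = False


def _irls(Xd: np.ndarray, y: np.ndarray, ridge: float, start=None):
    """One IRLS run.  Returns (beta, hessian, converged)."""
    n, p = Xd.shape
    if _HAVE_NUMBA:
        pen = np.zeros(p)
        pen[1:] = ridge
        beta = np.zeros(p) if start is None else start.copy()
        if start is None:
            pbar = min(max(y.mean(), 1e-6), 1 - 1e-6)
            beta[0] = np.log(pbar / (1 - pbar))
        try:
            beta, H, ok = _irls_core(
                np.ascontiguousarray(Xd), np.ascontiguousarray(y), pen, beta,
                _MAX_ITER, _GTOL, _ETA_CLIP, 1 if ridge == 0.0 else 0,
            )
        except Exception:  # singular information matrix
            return beta, np.eye(p), False
        return beta, H, bool(ok)
    return _irls_numpy(Xd, y, ridge, start)


def _irls_numpy(Xd: np.ndarray, y: np.ndarray, ridge: float, start=None):
    """Pure-numpy IRLS (fallback when no JIT is available)."""
    n, p = Xd.shape
    pen = np.zeros(p)
    pen[1:] = ridge  # never penalise the intercept
    beta = np.zeros(p) if start is None else start.copy()
    if start is None:
        # initialise intercept at the empirical log-odds
        pbar = min(max(y.mean(), 1e-6), 1 - 1e-6)
        beta[0] = np.log(pbar / (1 - pbar))
    XdT = np.ascontiguousarray(Xd.T)
    diag = np.arange(p)
    eta = np.clip(Xd @ beta, -_ETA_CLIP, _ETA_CLIP)
    obj = _loglik(eta, y) - 0.5 * float(pen @ (beta * beta))
    H = None
    for _ in range(_MAX_ITER):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        np.maximum(w, 1e-10, out=w)
        grad = XdT @ (y - mu) - pen * beta
        H = (XdT * w) @ Xd
        H[diag, diag] += pen
        if np.abs(grad).max() < _GTOL:
            return beta, H, True
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, H, False
        # step halving keeps the penalised likelihood monotone
        for _ in range(25):
            cand = beta + step
            eta_c = np.clip(Xd @ cand, -_ETA_CLIP, _ETA_CLIP)
            obj_c = _loglik(eta_c, y) - 0.5 * float(pen @ (cand * cand))
            if obj_c >= obj - 1e-12 and np.all(np.isfinite(cand)):
                break
            step *= 0.5
        else:
            return beta, H, False
        beta, eta, obj = cand, eta_c, obj_c
        if ridge == 0.0 and np.abs(beta).max() > 30.0:
            # coefficients diverging: quasi-complete separation; stop
            # crawling toward infinity and let the ridge rescue take over
            return beta, H, False
    return beta, H, False


def fit_logistic(X, y, predictor_ids=None, start=None, compute_se: bool = True) -> LogisticFit:
    """Fit a binary logistic regression by maximum likelihood.

    Parameters
    ----------
    X : array-like or DataFrame, shape (n, k)
        Predictor matrix (no intercept column; one is added).
    y : array-like of {0, 1}
    predictor_ids : optional sequence naming the columns of ``X``.
    start : optional warm-start coefficient vector (intercept first).

    Raises
    ------
    ValueError
        If only one outcome class is present ("degenerate outcome") or
        n < k + 2.
    """
    Xmat, ids = _as_design(X)
    if predictor_ids is not None:
        ids = tuple(predictor_ids)
    if not np.all(np.isfinite(Xmat)):
        raise ValueError("non-finite values in predictor matrix")
    y = np.asarray(y, dtype=float).ravel()
    n, k = Xmat.shape
    if y.size != n:
        raise ValueError(f"X has {n} rows but y has {y.size}")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("y must be binary 0/1")
    if uniq.size < 2:
        raise ValueError("degenerate outcome: only one class present")
    if n < k + 2:
        raise ValueError(f"too few observations ({n}) for {k} predictors")

    Xd = np.column_stack([np.ones(n), Xmat])
    beta, H, ok = _irls(Xd, y, ridge=0.0, start=start)
    penalty = 0.0
    # saturated log-odds (|beta| ~ 30 drives probabilities to 0/1)
    # signal quasi-complete separation even when the gradient vanished
    if not (ok and np.all(np.isfinite(beta)) and np.abs(beta).max() < 30.0):
        beta, H, _ = _irls(Xd, y, ridge=_RIDGE_FALLBACK, start=None)
        penalty = _RIDGE_FALLBACK
        ok = False

    eta = np.clip(Xd @ beta, -_ETA_CLIP, _ETA_CLIP)
    llf = _loglik(eta, y)
    aic = 2.0 * (k + 1) - 2.0 * llf
    if compute_se:
        try:
            cov = np.linalg.inv(H)
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            bse = np.full(k + 1, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / bse
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    else:  # AIC-only scoring fits skip Wald inference
        bse = np.full(k + 1, np.nan)
        pvals = np.full(k + 1, np.nan)

    return LogisticFit(
        params=beta,
        predictor_ids=ids,
        llf=llf,
        aic=aic,
        bse=bse,
        pvalues=pvals,
        converged=ok,
        penalty=penalty,
        n_obs=n,
    )


def predict_probability(fit: LogisticFit, X):
    """Return (probabilities, logits) for new data under a fitted model.

    When ``X`` is a DataFrame its columns are aligned to the fit's
    predictor ids; missing or extra predictors raise a ``ValueError``
    naming them.
    """
    if isinstance(X, pd.DataFrame):
        missing = [c for c in fit.predictor_ids if c not in X.columns]
        if missing:
            raise ValueError(f"missing predictors: {missing}")
        Xmat = X.loc[:, list(fit.predictor_ids)].to_numpy(dtype=float)
    else:
        Xmat = np.asarray(X, dtype=float)
        if Xmat.ndim == 1:
            Xmat = Xmat[:, None]
        if Xmat.shape[1] != len(fit.predictor_ids):
            raise ValueError(
                f"expected {len(fit.predictor_ids)} predictors "
                f"({list(fit.predictor_ids)}), got {Xmat.shape[1]}"
            )
    logit = fit.params[0] + Xmat @ fit.params[1:]
    prob = 1.0 / (1.0 + np.exp(-np.clip(logit, -_ETA_CLIP, _ETA_CLIP)))
    return prob, logit


# ---------------------------------------------------------------------------
# Endpoints
# ---------------------------------------------------------------------------

_POSITIVE_GROUPS = {
    "I": {"VLR", "LR", "FIR", "UIR", "HR", "VHR", "mPC"},
    "II": {"FIR", "UIR", "HR", "VHR", "mPC"},
    "III": {"UIR", "HR", "VHR", "mPC"},
}


@dataclass(frozen=True)
class EndpointSpec:
    """One dichotomous endpoint: a total mapping from (risk group,
    Gleason sum) to a binary label."""

    model_id: str
    description: str = field(default="", compare=False)

    def label(self, risk_group: str, gleason_sum=None) -> int:
        if risk_group not in ("benign",) and risk_group not in _POSITIVE_GROUPS["I"]:
            raise ValueError(f"unmapped risk group: {risk_group!r}")
        if self.model_id == "GS":
            if risk_group == "benign":
                return 0
            if gleason_sum is None or (
                isinstance(gleason_sum, float) and np.isnan(gleason_sum)
            ):
                raise ValueError(
                    f"Gleason sum required for cancer subject ({risk_group})"
                )
            return int(float(gleason_sum) >= 7)
        return int(risk_group in _POSITIVE_GROUPS[self.model_id])


ENDPOINTS: dict[str, EndpointSpec] = {
    "I": EndpointSpec("I", "benign vs any prostate cancer"),
    "II": EndpointSpec("II", "benign+VLR/LR vs FIR and higher (long life expectancy)"),
    "III": EndpointSpec("III", "benign+VLR/LR+FIR vs UIR and higher (shorter life expectancy)"),
    "GS": EndpointSpec("GS", "benign or Gleason<7 vs Gleason>=7 (high grade)"),
}


def build_endpoint_labels(subjects: pd.DataFrame, spec: EndpointSpec | str) -> np.ndarray:
    """Binary outcome vector for one endpoint, aligned to ``subjects``."""
    if isinstance(spec, str):
        spec = ENDPOINTS[spec]
    gs = subjects.get("gleason_sum")
    labels = np.empty(len(subjects), dtype=int)
    for i, (rg, g) in enumerate(
        zip(subjects["risk_group"], gs if gs is not None else [None] * len(subjects))
    ):
        labels[i] = spec.label(rg, g)
    return labels
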