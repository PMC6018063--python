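"""Univariate Gaussian finite mixtures fitted by EM, scored by BIC.

The mixture density is f(x) = sum_j pi_j * phi(x; m_j, sd_j^2). Component
standard deviations are either free per component ("V" configuration) or
constrained equal across components ("E" configuration). Model quality is
scored as BIC = 2*lnL - p*ln(n) (larger is better), with p = 3k-1 free
parameters under "V" and p = 2k under "E".

EM starts from a deterministic quantile partition of the sorted data into k
contiguous equal-count blocks and iterates until the relative change of the
log-likelihood drops below ``FitConfig.tol``. Component variances are floored
at ``variance_floor`` times the total data variance so that no component can
collapse onto a single observation and send the likelihood to infinity.
Components are always stored sorted by ascending mean, so the first component
is the lowest-concentration (background) regime.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .data import DailySeries, FitConfig, InfeasibleModelError

_LOG_2PI = math.log(2.0 * math.pi)
_TINY_VAR = np.finfo(float).tiny


@dataclass
class MixtureFit:
    """A fitted k-component univariate Gaussian mixture.

    ``technique`` records which clustering route produced the fit
    ("fmm", "hc" or "km"); ``loglik_history`` the per-iteration EM
    log-likelihood trace (a single entry for the one-E-step km bridge).
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    config: str
    loglik: float
    n_params: int
    bic: float
    assignments: np.ndarray
    responsibilities: np.ndarray
    converged: bool
    technique: str = "fmm"
    n: int = 0
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "technique": self.technique,
            "k": self.k,
            "config": self.config,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "converged": bool(self.converged),
            "n": self.n,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _as_values(ds) -> np.ndarray:
    values = ds.values if isinstance(ds, DailySeries) else np.asarray(ds, float)
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0 or not np.all(np.isfinite(values)):
        raise ValueError("series values must be non-empty and finite")
    return values


def _validate_params(weights, means, sds):
    weights = np.asarray(weights, float).ravel()
    means = np.asarray(means, float).ravel()
    sds = np.asarray(sds, float).ravel()
    if not (weights.shape == means.shape == sds.shape):
        raise ValueError("weights, means and sds must have equal length")
    if np.any(sds <= 0):
        raise ValueError("all component sds must be > 0")
    if np.any(weights <= 0) or abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be positive and sum to 1")
    return weights, means, sds


def gaussian_logpdf(x, mean, sd):
    z = (x - mean) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def _weighted_logdens(values, weights, means, sds):
    """(n, k) matrix of ln(pi_j) + ln phi(x_i; m_j, sd_j^2)."""
    x = values[:, None]
    return np.log(weights)[None, :] + gaussian_logpdf(x, means[None, :], sds[None, :])


def mixture_loglik(values, weights, means, sds) -> float:
    """Observed-data log-likelihood sum_i ln sum_j pi_j phi(x_i), in log space."""
    weights, means, sds = _validate_params(weights, means, sds)
    values = _as_values(values)
    return float(np.sum(logsumexp(_weighted_logdens(values, weights, means, sds), axis=1)))


def estep_responsibilities(values, weights, means, sds) -> np.ndarray:
    """Posterior component probabilities r_ij, rows normalized to 1."""
    weights, means, sds = _validate_params(weights, means, sds)
    values = _as_values(values)
    logdens = _weighted_logdens(values, weights, means, sds)
    return np.exp(logdens - logsumexp(logdens, axis=1, keepdims=True))


def bic_score(loglik: float, n_params: int, n: int) -> float:
    """BIC = 2*lnL - p*ln(n); larger values indicate better models."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_params < 0:
        raise ValueError("n_params must be >= 0")
    return 2.0 * loglik - n_params * math.log(n)


def mixture_n_params(k: int, config: str) -> int:
    """Free parameters: (k-1) weights + k means + (k variances | 1 variance)."""
    if config == "V":
        return 3 * k - 1
    if config == "E":
        return 2 * k
    raise ValueError(f"unknown configuration {config!r}")


def _init_from_labels(values: np.ndarray, labels: np.ndarray, config: str, floor: float):
    """M-step on a hard partition: weights, means and (pooled) variances."""
    n = values.size
    uniq = np.unique(labels)
    weights = np.array([(labels == u).mean() for u in uniq])
    means = np.array([values[labels == u].mean() for u in uniq])
    if config == "E":
        pooled = sum((labels == u).sum() * values[labels == u].var() for u in uniq) / n
        variances = np.full(uniq.size, max(pooled, floor))
    else:
        variances = np.maximum([values[labels == u].var() for u in uniq], floor)
    return weights, means, variances


def _quantile_init(values: np.ndarray, k: int, config: str, floor: float):
    """Deterministic init: M-step on k contiguous equal-count blocks of sorted data."""
    order = np.argsort(values, kind="stable")
    labels = np.empty(values.size, dtype=int)
    for j, block in enumerate(np.array_split(order, k)):
        labels[block] = j
    return _init_from_labels(values, labels, config, floor)


def _kmeans_init(values: np.ndarray, k: int, config: str, floor: float, cfg: FitConfig):
    """Second deterministic start: M-step on a seeded k-means partition.

    Starting EM from the k-means parameterization guarantees (by EM
    monotonicity) that the converged mixture never scores below the
    hard-clustering parameterization of the same data, keeping the BIC
    comparison across techniques coherent.
    """
    from sklearn.cluster import KMeans  # local import avoids module cycle

    km = KMeans(n_clusters=k, n_init=cfg.n_starts,
                random_state=cfg.seed % (2**32), algorithm="lloyd")
    labels = km.fit(values[:, None]).labels_
    return _init_from_labels(values, labels, config, floor)


def run_em(
    values: np.ndarray,
    weights: np.ndarray,
    means: np.ndarray,
    variances: np.ndarray,
    config: str,
    cfg: FitConfig,
    floor: float,
    technique: str = "fmm",
) -> MixtureFit:
    """Run EM to convergence from an explicit parameter point.

    Shared by the quantile-initialized mixture fit and the hierarchical-
    clustering bridge (which initializes from a tree cut). Convergence is
    declared when |lnL_t - lnL_{t-1}| <= tol * |lnL_t|.
    """
    values = np.asarray(values, float)
    n = values.size
    k = weights.size
    x = values[:, None]
    history = []
    prev = -np.inf
    converged = False
    degenerate = False
    for _ in range(cfg.max_iter):
        logdens = np.log(weights)[None, :] + gaussian_logpdf(
            x, means[None, :], np.sqrt(variances)[None, :]
        )
        row_ll = logsumexp(logdens, axis=1)
        loglik = float(row_ll.sum())
        history.append(loglik)
        if np.isfinite(prev) and abs(loglik - prev) <= cfg.tol * max(abs(loglik), 1e-12):
            converged = True
            break
        prev = loglik
        resp = np.exp(logdens - row_ll[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            degenerate = True
            break
        weights = nk / n
        means = (resp * x).sum(axis=0) / nk
        sq = resp * (x - means[None, :]) ** 2
        if config == "E":
            variances = np.full(k, max(sq.sum() / n, floor))
        else:
            variances = np.maximum(sq.sum(axis=0) / nk, floor)
    # refresh responsibilities at the final parameter point
    sds = np.sqrt(variances)
    logdens = np.log(weights)[None, :] + gaussian_logpdf(x, means[None, :], sds[None, :])
    row_ll = logsumexp(logdens, axis=1)
    loglik = float(row_ll.sum())
    resp = np.exp(logdens - row_ll[:, None])

    order = np.argsort(means, kind="stable")
    weights, means, sds = weights[order], means[order], sds[order]
    resp = resp[:, order]
    p = mixture_n_params(k, config)
    return MixtureFit(
        k=k,
        weights=weights,
        means=means,
        sds=sds,
        config=config,
        loglik=loglik,
        n_params=p,
        bic=bic_score(loglik, p, n),
        assignments=np.argmax(resp, axis=1),
        responsibilities=resp,
        converged=converged and not degenerate,
        technique=technique,
        n=n,
        loglik_history=np.asarray(history),
    )


def fit_gmm(ds, k: int, config: str = "V", cfg: FitConfig | None = None) -> MixtureFit:
    """Fit a k-component Gaussian mixture by EM ("E" or "V" configuration).

    EM is run from two deterministic starts — a quantile partition of the
    sorted data into k contiguous equal-count blocks, and a seeded k-means
    partition — and the fit with the higher converged log-likelihood is
    returned (both starts are reproducible given ``cfg.seed``). Requires
    n >= 2k observations.
    """
    cfg = cfg or FitConfig()
    values = _as_values(ds)
    if k < 1:
        raise ValueError("k must be >= 1")
    if config not in ("E", "V"):
        raise ValueError(f"unknown configuration {config!r}")
    n = values.size
    if n < 2 * k:
        raise InfeasibleModelError(f"need n >= 2k observations (n={n}, k={k})")
    floor = cfg.variance_floor * max(float(values.var()), _TINY_VAR)
    inits = [_quantile_init(values, k, config, floor)]
    if k > 1:
        inits.append(_kmeans_init(values, k, config, floor, cfg))
    best = None
    for weights, means, variances in inits:
        fit = run_em(values, weights.copy(), means.copy(), variances.copy(),
                     config, cfg, floor, technique="fmm")
        if best is None or (fit.converged, fit.loglik) > (best.converged, best.loglik):
            best = fit
    return best
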