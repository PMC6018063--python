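"""k-state univariate Gaussian hidden Markov models for daily series.

An HMM extends the finite mixture to serially dependent data: a hidden
Markov chain with initial distribution delta and transition matrix Gamma
selects, each day, which Gaussian emission distribution generates the
observed concentration. Fitting is by Baum-Welch (EM with scaled
forward-backward recursions), decoding by Viterbi, and model quality by the
same BIC = 2*lnL - p*ln(n) used for the other techniques, with

    p = (k - 1) initial + k(k - 1) transition + k means + k variances
      = k^2 + 2k - 1

free parameters. State variances are free per state ("V" configuration).
Missing days are bridged as if consecutive: the transition matrix is applied
once per adjacent pair of observed days.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._kernels import forward_backward, forward_loglik_kernel, viterbi_kernel
from .data import FitConfig, InfeasibleModelError
from .mixture import _as_values, _TINY_VAR, bic_score, gaussian_logpdf


@dataclass
class HMMFit:
    """A fitted k-state Gaussian HMM, states sorted by ascending mean."""

    k: int
    initial: np.ndarray
    transition: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n_params: int
    bic: float
    path: np.ndarray
    converged: bool
    technique: str = "hmm"
    config: str = "V"
    n: int = 0
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def assignments(self) -> np.ndarray:
        """Hard state labels (Viterbi decoding), mirroring MixtureFit."""
        return self.path

    def posterior_path(self, values) -> np.ndarray:
        """Per-day smoothed-posterior (local) decoding, as an alternative
        to the global Viterbi path."""
        post = state_posteriors(values, self.initial, self.transition,
                                self.means, self.sds)
        return np.argmax(post, axis=1)

    def to_dict(self) -> dict:
        runs = _run_length_encode(self.path)
        return {
            "technique": self.technique,
            "k": self.k,
            "config": self.config,
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "converged": bool(self.converged),
            "n": self.n,
            "path_rle": runs,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _run_length_encode(path: np.ndarray) -> list[list[int]]:
    runs = []
    for s in path:
        if runs and runs[-1][0] == int(s):
            runs[-1][1] += 1
        else:
            runs.append([int(s), 1])
    return runs


def hmm_n_params(k: int) -> int:
    """Free parameters of a k-state Gaussian HMM: k^2 + 2k - 1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return k * k + 2 * k - 1


def _validate_hmm_params(delta, gamma_mat, means, sds):
    delta = np.asarray(delta, float).ravel()
    gamma_mat = np.atleast_2d(np.asarray(gamma_mat, float))
    means = np.asarray(means, float).ravel()
    sds = np.asarray(sds, float).ravel()
    k = delta.size
    if gamma_mat.shape != (k, k) or means.size != k or sds.size != k:
        raise ValueError("inconsistent HMM parameter dimensions")
    if np.any(sds <= 0):
        raise ValueError("all state sds must be > 0")
    if np.any(delta < 0) or abs(delta.sum() - 1.0) > 1e-8:
        raise ValueError("initial distribution must be a probability vector")
    if np.any(gamma_mat < 0) or np.any(np.abs(gamma_mat.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("transition matrix rows must each sum to 1")
    return delta, gamma_mat, means, sds


def _shifted_emissions(values, means, sds):
    logb = gaussian_logpdf(values[:, None], means[None, :], sds[None, :])
    rowmax = logb.max(axis=1)
    return np.exp(logb - rowmax[:, None]), rowmax, logb


def forward_loglik(values, delta, gamma_mat, means, sds) -> float:
    """Observed-data log-likelihood via the scaled forward algorithm."""
    delta, gamma_mat, means, sds = _validate_hmm_params(delta, gamma_mat, means, sds)
    values = _as_values(values)
    b, rowmax, _ = _shifted_emissions(values, means, sds)
    return float(forward_loglik_kernel(b, rowmax, delta, gamma_mat))


def state_posteriors(values, delta, gamma_mat, means, sds) -> np.ndarray:
    """Smoothed posteriors P(state_t = j | all data), one row per day."""
    delta, gamma_mat, means, sds = _validate_hmm_params(delta, gamma_mat, means, sds)
    values = _as_values(values)
    b, rowmax, _ = _shifted_emissions(values, means, sds)
    _, post, _ = forward_backward(b, rowmax, delta, gamma_mat)
    return post


def viterbi_path(values, delta, gamma_mat, means, sds) -> np.ndarray:
    """Jointly most probable state sequence (ties toward lower state index)."""
    delta, gamma_mat, means, sds = _validate_hmm_params(delta, gamma_mat, means, sds)
    values = _as_values(values)
    _, _, logb = _shifted_emissions(values, means, sds)
    with np.errstate(divide="ignore"):
        log_delta = np.log(delta)
        log_gamma = np.log(gamma_mat)
    return viterbi_kernel(log_delta, log_gamma, logb)


def _baum_welch(values, delta, gamma_mat, means, variances, cfg, floor):
    """EM iterations from one start; returns params, trace and success flag."""
    n = values.size
    k = delta.size
    history = []
    prev = -np.inf
    converged = False
    for _ in range(cfg.max_iter):
        b, rowmax, _ = _shifted_emissions(values, means, np.sqrt(variances))
        loglik, post, xi_sum = forward_backward(b, rowmax, delta, gamma_mat)
        history.append(loglik)
        if np.isfinite(prev) and abs(loglik - prev) <= cfg.tol * max(abs(loglik), 1e-12):
            converged = True
            break
        prev = loglik
        occup = post.sum(axis=0)
        if np.any(occup < 1e-10):
            break  # a state lost all occupancy: degenerate start
        delta = post[0] / post[0].sum()
        rows = xi_sum.sum(axis=1)
        gamma_mat = xi_sum / np.maximum(rows, 1e-300)[:, None]
        for i in range(k):
            if rows[i] <= 0:  # state never occupied before the last day
                gamma_mat[i] = 0.0
                gamma_mat[i, i] = 1.0
        means = post.T @ values / occup
        variances = np.maximum(
            (post * (values[:, None] - means[None, :]) ** 2).sum(axis=0) / occup, floor
        )
    return delta, gamma_mat, means, variances, history, converged


def fit_hmm(ds, k: int, cfg: FitConfig | None = None) -> HMMFit:
    """Fit a k-state Gaussian HMM by Baum-Welch with multi-start.

    The deterministic start places state means at the k mid-quantiles of the
    data, all state variances at the total variance, self-transitions at 0.8
    (rest uniform) and a uniform initial distribution; ``cfg.hmm_starts``
    additional starts perturb the means with seeded Gaussian noise. The best
    converged final log-likelihood is kept; if no start converges the best
    fit is returned flagged ``converged=False``.
    """
    cfg = cfg or FitConfig()
    values = _as_values(ds)
    n = values.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 2 * k:
        raise InfeasibleModelError(f"need n >= 2k observations (n={n}, k={k})")
    var_total = max(float(values.var()), _TINY_VAR)
    sd_total = np.sqrt(var_total)
    floor = cfg.variance_floor * var_total

    base_means = np.quantile(values, (2 * np.arange(k) + 1) / (2 * k))
    if k == 1:
        base_gamma = np.ones((1, 1))
    else:
        base_gamma = np.full((k, k), 0.2 / (k - 1))
        np.fill_diagonal(base_gamma, 0.8)
    base_delta = np.full(k, 1.0 / k)

    rng = np.random.default_rng(cfg.seed)
    starts = [base_means.copy()]
    if k > 1:
        for _ in range(cfg.hmm_starts):
            starts.append(np.sort(base_means + rng.normal(0.0, 0.25 * sd_total, k)))

    best = None
    for init_means in starts:
        delta, gm, means, variances, history, ok = _baum_welch(
            values,
            base_delta.copy(),
            base_gamma.copy(),
            init_means.astype(float),
            np.full(k, var_total),
            cfg,
            floor,
        )
        final_ll = history[-1]
        key = (ok, final_ll)
        if best is None or key > best[0]:
            best = (key, delta, gm, means, variances, history, ok)

    _, delta, gm, means, variances, history, ok = best
    sds = np.sqrt(variances)
    order = np.argsort(means, kind="stable")
    means, sds = means[order], sds[order]
    delta = delta[order]
    gm = gm[np.ix_(order, order)]
    loglik = forward_loglik(values, delta, gm, means, sds)
    path = viterbi_path(values, delta, gm, means, sds)
    p = hmm_n_params(k)
    return HMMFit(
        k=k,
        initial=delta,
        transition=gm,
        means=means,
        sds=sds,
        loglik=loglik,
        n_params=p,
        bic=bic_score(loglik, p, n),
        path=path,
        converged=ok,
        n=n,
        loglik_history=np.asarray(history),
    )
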