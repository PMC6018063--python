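"""k-means and Ward hierarchical clustering bridged to Gaussian mixtures.

Both hard-partition techniques are re-expressed as equal-variance ("E")
Gaussian mixtures so that their solutions can be scored with the same
BIC = 2*lnL - p*ln(n) used for the model-based techniques:

* k-means: cluster representations become mixing weights, cluster means the
  component means, and the common variance is the size-weighted average of
  the within-cluster (maximum-likelihood) variances. The likelihood is then
  evaluated in a single E-step at that parameter point — no EM refinement.
* Ward: the agglomerative merge tree is cut at each candidate k and the
  resulting partition seeds a full "E"-configuration EM run to convergence.

k-means itself is delegated to scikit-learn (Lloyd iterations, seeded
restarts) and the Ward merge tree to scipy's hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .data import FitConfig, InfeasibleModelError
from .mixture import (
    MixtureFit,
    _as_values,
    _TINY_VAR,
    bic_score,
    estep_responsibilities,
    mixture_loglik,
    mixture_n_params,
    run_em,
)


@dataclass
class Partition:
    """A hard partition of a univariate sample, clusters sorted by mean.

    ``within_var`` holds per-cluster maximum-likelihood variances (divide by
    the cluster size), consistent with the MLE framework behind the BIC.
    """

    labels: np.ndarray
    sizes: np.ndarray
    cluster_means: np.ndarray
    within_var: np.ndarray

    @property
    def k(self) -> int:
        return len(self.sizes)

    @property
    def n(self) -> int:
        return int(self.sizes.sum())


def partition_from_labels(values: np.ndarray, labels: np.ndarray) -> Partition:
    """Build a Partition, relabelling clusters by ascending cluster mean."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    means = np.array([values[labels == u].mean() for u in uniq])
    order = np.argsort(means, kind="stable")
    remap = {uniq[o]: rank for rank, o in enumerate(order)}
    new_labels = np.array([remap[l] for l in labels])
    sizes = np.bincount(new_labels, minlength=len(uniq))
    cluster_means = np.array([values[new_labels == j].mean() for j in range(len(uniq))])
    within = np.array([values[new_labels == j].var() for j in range(len(uniq))])
    return Partition(new_labels, sizes, cluster_means, within)


def fit_kmeans(ds, k: int, cfg: FitConfig | None = None) -> Partition:
    """k-means (Lloyd) with seeded restarts; best within-cluster SS kept."""
    cfg = cfg or FitConfig()
    values = _as_values(ds)
    n = values.size
    if not 1 <= k <= n:
        raise InfeasibleModelError(f"need 1 <= k <= n (n={n}, k={k})")
    if k == 1:
        return partition_from_labels(values, np.zeros(n, dtype=int))
    km = KMeans(
        n_clusters=k,
        n_init=cfg.n_starts,
        random_state=cfg.seed % (2**32),
        algorithm="lloyd",
    ).fit(values[:, None])
    return partition_from_labels(values, km.labels_)


def pooled_variance(p: Partition, floor: float = 0.0) -> float:
    """Common variance: size-weighted average of within-cluster ML variances."""
    pooled = float(np.sum(p.sizes / p.n * p.within_var))
    return max(pooled, floor)


def kmeans_as_mixture(ds, p: Partition, cfg: FitConfig | None = None) -> MixtureFit:
    """Score a k-means partition as an "E"-configuration mixture.

    The partition's weights, means and pooled common variance parameterize
    the mixture; the log-likelihood is a single E-step evaluation at that
    point (no EM refinement), with p = 2k free parameters. Hard assignments
    keep the nearest-centre k-means labels.
    """
    cfg = cfg or FitConfig()
    values = _as_values(ds)
    n = values.size
    floor = cfg.variance_floor * max(float(values.var()), _TINY_VAR)
    weights = p.sizes / n
    sd = np.sqrt(pooled_variance(p, floor))
    sds = np.full(p.k, sd)
    loglik = mixture_loglik(values, weights, p.cluster_means, sds)
    resp = estep_responsibilities(values, weights, p.cluster_means, sds)
    n_params = mixture_n_params(p.k, "E")
    return MixtureFit(
        k=p.k,
        weights=weights,
        means=p.cluster_means.copy(),
        sds=sds,
        config="E",
        loglik=loglik,
        n_params=n_params,
        bic=bic_score(loglik, n_params, n),
        assignments=p.labels.copy(),
        responsibilities=resp,
        converged=True,
        technique="km",
        n=n,
        loglik_history=np.array([loglik]),
    )


@dataclass
class WardTree:
    """Full Ward agglomerative merge sequence over a univariate sample."""

    linkage_matrix: np.ndarray
    n: int

    def cut(self, k: int) -> np.ndarray:
        """Labels (0-based, arbitrary order) for a k-cluster cut of the tree."""
        if not 1 <= k <= self.n:
            raise ValueError(f"need 1 <= k <= n (n={self.n}, k={k})")
        if k == self.n:
            return np.arange(self.n)
        return fcluster(self.linkage_matrix, t=k, criterion="maxclust") - 1

    @property
    def merge_costs(self) -> np.ndarray:
        """Ward merge costs n1*n2/(n1+n2)*(m1-m2)^2, in merge order."""
        return self.linkage_matrix[:, 2] ** 2 / 2.0


def fit_ward(ds) -> WardTree:
    """Agglomerative merge tree under the Ward minimum-variance criterion."""
    values = _as_values(ds)
    if values.size < 2:
        raise InfeasibleModelError("Ward clustering needs n >= 2")
    Z = linkage(values[:, None], method="ward")
    return WardTree(Z, values.size)


def hc_as_mixture(ds, tree: WardTree, k: int, cfg: FitConfig | None = None) -> MixtureFit:
    """Refine a k-cluster Ward cut into an "E"-configuration mixture by EM.

    The cut partition supplies the initial weights, means and pooled common
    variance; EM then runs to convergence (unlike the one-shot k-means
    bridge), and the fit is tagged "hc".
    """
    cfg = cfg or FitConfig()
    values = _as_values(ds)
    part = partition_from_labels(values, tree.cut(k))
    floor = cfg.variance_floor * max(float(values.var()), _TINY_VAR)
    weights = part.sizes / part.n
    variances = np.full(part.k, pooled_variance(part, floor))
    fit = run_em(values, weights, part.cluster_means.copy(), variances,
                 "E", cfg, floor, technique="hc")
    return fit
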