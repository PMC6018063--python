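"""Model selection over k and extraction of the background regime.

For one site-year series and one clustering technique, every candidate
cluster count k is fitted and scored with BIC = 2*lnL - p*ln(n); the k with
the maximum BIC among converged fits wins (ties, within 1e-9, go to the
smaller k — parsimony). Sorting the selected solution's clusters by
ascending mean makes the first cluster the lowest-concentration regime: the
background pollution. Its mixing proportion (representation, % of valid
days), mean m and standard deviation sd are the exposure estimates of
interest, reported next to the annual mean M.

Hard day-to-cluster assignment follows each technique's native rule:
maximum-posterior for the mixture and hierarchical routes, nearest centre
for k-means, and the Viterbi path for the HMM.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import DailySeries, FitConfig, InfeasibleModelError
from .hardcluster import fit_kmeans, fit_ward, hc_as_mixture, kmeans_as_mixture
from .hmm import HMMFit, fit_hmm
from .mixture import MixtureFit, fit_gmm

logger = logging.getLogger(__name__)

TECHNIQUES = ("fmm", "hc", "hmm", "km")
_BIC_TIE_TOL = 1e-9


@dataclass
class KSweepResult:
    """BIC-over-k sweep for one technique on one series."""

    technique: str
    per_k: dict[int, tuple[float, bool]]
    best_k: int
    best_fit: MixtureFit | HMMFit
    site: str = ""
    pollutant: str = ""
    year: int | None = None

    def to_dict(self) -> dict:
        return {
            "technique": self.technique,
            "site": self.site,
            "pollutant": self.pollutant,
            "year": self.year,
            "per_k": {str(k): {"bic": bic, "converged": conv}
                      for k, (bic, conv) in sorted(self.per_k.items())},
            "best_k": self.best_k,
            "best_fit": self.best_fit.to_dict(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class BackgroundRegime:
    """Exposure estimates for the background (first, lowest-mean) cluster."""

    representation: float
    m: float
    sd: float
    conc_min: float
    conc_max: float
    n_days: int
    M: float
    k: int
    technique: str
    site: str = ""
    pollutant: str = ""
    year: int | None = None


def _fit_one(ds: DailySeries, technique: str, k: int, cfg: FitConfig, context):
    if technique == "fmm":
        return fit_gmm(ds, k, "V", cfg)
    if technique == "hmm":
        return fit_hmm(ds, k, cfg)
    if technique == "km":
        return kmeans_as_mixture(ds, fit_kmeans(ds, k, cfg), cfg)
    if technique == "hc":
        return hc_as_mixture(ds, context["tree"], k, cfg)
    raise ValueError(f"unknown technique {technique!r}; expected one of {TECHNIQUES}")


def sweep_k(ds: DailySeries, technique: str, cfg: FitConfig | None = None) -> KSweepResult:
    """Fit every k in ``cfg.k_range`` and select the max-BIC converged fit.

    Infeasible cluster counts (k > n/2) are skipped with a warning;
    non-converged fits are recorded but excluded from the argmax.
    """
    cfg = cfg or FitConfig()
    if technique not in TECHNIQUES:
        raise ValueError(f"unknown technique {technique!r}; expected one of {TECHNIQUES}")
    context = {"tree": fit_ward(ds)} if technique == "hc" else {}
    per_k: dict[int, tuple[float, bool]] = {}
    best_k, best_bic, best_fit = None, -np.inf, None
    for k in sorted(cfg.k_range):
        if ds.n_days < 2 * k:
            logger.warning("skipping infeasible k=%d for series of %d days", k, ds.n_days)
            continue
        try:
            fit = _fit_one(ds, technique, k, cfg, context)
        except InfeasibleModelError as exc:
            logger.warning("skipping k=%d (%s)", k, exc)
            continue
        per_k[k] = (fit.bic, fit.converged)
        logger.debug("%s %s/%s/%s k=%d bic=%.4f converged=%s",
                     technique, ds.site, ds.pollutant, ds.year, k, fit.bic, fit.converged)
        if fit.converged and fit.bic > best_bic + _BIC_TIE_TOL:
            best_k, best_bic, best_fit = k, fit.bic, fit
    if best_fit is None:
        raise RuntimeError(
            f"no converged {technique} fit for series "
            f"{ds.site}/{ds.pollutant}/{ds.year} over k_range={cfg.k_range}"
        )
    return KSweepResult(technique, per_k, best_k, best_fit,
                        site=ds.site, pollutant=ds.pollutant, year=ds.year)


def hard_assignments(fit: MixtureFit | HMMFit) -> np.ndarray:
    """Per-day hard cluster labels under the technique's native rule."""
    if isinstance(fit, HMMFit):
        return fit.path
    return fit.assignments


def extract_background(ds: DailySeries, sweep: KSweepResult) -> BackgroundRegime:
    """Exposure estimates from the first (lowest-mean) cluster of the best fit.

    representation = 100 * (days assigned to cluster 1) / n_days; m and sd
    are the model parameters of cluster 1 (not the empirical moments of the
    assigned days); conc_min/conc_max the empirical range of the assigned
    observations; M the annual mean.
    """
    fit = sweep.best_fit
    if not fit.converged:
        raise RuntimeError("best fit is not converged")
    labels = hard_assignments(fit)
    mask = labels == 0
    n_bg = int(mask.sum())
    if n_bg == 0:
        raise RuntimeError("first cluster is empty after hard assignment (degenerate fit)")
    assigned = ds.values[mask]
    return BackgroundRegime(
        representation=100.0 * n_bg / ds.n_days,
        m=float(fit.means[0]),
        sd=float(fit.sds[0]),
        conc_min=float(assigned.min()),
        conc_max=float(assigned.max()),
        n_days=n_bg,
        M=ds.annual_mean,
        k=fit.k,
        technique=sweep.technique,
        site=ds.site,
        pollutant=ds.pollutant,
        year=ds.year,
    )


SUMMARY_COLUMNS = ["site", "pollutant", "year", "technique", "k",
                   "conc_min", "conc_max", "n_days", "representation", "m", "sd", "M"]


def summarize_series(ds: DailySeries, regimes: Sequence[BackgroundRegime]) -> pd.DataFrame:
    """One row per technique for a single site-year (per-site-year table)."""
    for r in regimes:
        if (r.site, r.pollutant, r.year) != (ds.site, ds.pollutant, ds.year):
            raise ValueError(
                f"regime metadata {(r.site, r.pollutant, r.year)} does not match "
                f"series {(ds.site, ds.pollutant, ds.year)}"
            )
    rows = [
        {
            "site": r.site, "pollutant": r.pollutant, "year": r.year,
            "technique": r.technique, "k": r.k,
            "conc_min": r.conc_min, "conc_max": r.conc_max,
            "n_days": r.n_days, "representation": r.representation,
            "m": r.m, "sd": r.sd, "M": r.M,
        }
        for r in regimes
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def tabulate_detection(results: Iterable[KSweepResult]) -> pd.DataFrame:
    """Cluster-detection counts: series with k=1 vs k>1 per technique/pollutant.

    Returns a long-format table with one row per (detection, technique,
    pollutant) plus per-technique totals over all pollutants, each row
    carrying the count, the number of available series and the percentage.
    """
    results = list(results)
    if not results:
        raise ValueError("no sweep results to tabulate")
    records = [(r.technique, r.pollutant or "all", r.best_k) for r in results]
    df = pd.DataFrame(records, columns=["technique", "pollutant", "best_k"])
    totals = df.groupby("pollutant").size() / df["technique"].nunique()
    rows = []
    for detection, pred in (("k=1", lambda k: k == 1), ("k>1", lambda k: k > 1)):
        for technique, sub in df.groupby("technique"):
            for pollutant, psub in sub.groupby("pollutant"):
                n_avail = int(totals[pollutant])
                count = int(psub["best_k"].map(pred).sum())
                rows.append({"detection": detection, "technique": technique,
                             "pollutant": pollutant, "count": count,
                             "available": n_avail,
                             "percent": 100.0 * count / n_avail})
            n_total = len(sub)
            count = int(sub["best_k"].map(pred).sum())
            rows.append({"detection": detection, "technique": technique,
                         "pollutant": "total", "count": count,
                         "available": n_total,
                         "percent": 100.0 * count / n_total})
    return pd.DataFrame(rows)
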