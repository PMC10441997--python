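"""Sloan neutral community model: occurrence-frequency fitting.

The model predicts the probability of detecting an ASV in a local community
of N individuals, given its mean relative abundance p in the metacommunity,
as the upper tail of a beta distribution:

    freq(p) = 1 - BetaCDF(d; Nm*p, Nm*(1-p))

where d is the detection limit (1/N by default) and Nm the product of
community size and migration rate m.  Nm is fitted by least squares of
observed against predicted detection frequencies; R^2 = 1 - SSE/SST.
Confidence intervals and 95% prediction bands come from a nonparametric
bootstrap over ASVs, and each ASV is partitioned as occurring above, within
or below the neutral prediction band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = ["occurrence_stats", "predict_frequency", "fit_ncm", "NcmFit"]

_LOG_NM_BOUNDS = (-3.0, 7.0)  # log10 of Nm search interval


def occurrence_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Per-ASV mean relative abundance (p) and detection frequency.

    p is the mean over samples of the ASV's within-sample proportion; freq
    is the fraction of samples where it is detected (count > 0).  ASVs
    absent from every sample are retained here with p = freq = 0 and are
    excluded (logged) by :func:`fit_ncm`.
    """
    if table.shape[1] < 5:
        logger.warning("only %d samples; occupancy estimates are coarse", table.shape[1])
    rel = table / table.sum(axis=0)
    return pd.DataFrame(
        {"p": rel.mean(axis=1), "freq": (table > 0).mean(axis=1)}, index=table.index
    )


def predict_frequency(p, nm: float, d: float):
    """Neutral prediction of detection frequency at mean abundance ``p``."""
    if nm <= 0:
        raise ValueError("Nm must be positive")
    if not 0 < d < 1:
        raise ValueError("detection limit d must be in (0, 1)")
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("p must lie strictly in (0, 1)")
    return stats.beta.sf(d, nm * p, nm * (1.0 - p))


@dataclass
class NcmFit:
    m: float
    nm: float
    r2: float
    n_reads: float
    detection_limit: float
    ci95_m: tuple[float, float]
    ci95_r2: tuple[float, float]
    n_bootstrap: int
    seed: int
    per_asv: pd.DataFrame = field(repr=False)  # p, freq, predicted, partition

    @property
    def partition_counts(self) -> pd.Series:
        return self.per_asv["partition"].value_counts()


def _fit_nm(p: np.ndarray, freq: np.ndarray, d: float) -> float:
    def sse(log_nm: float) -> float:
        pred = stats.beta.sf(d, 10.0**log_nm * p, 10.0**log_nm * (1.0 - p))
        return float(((freq - pred) ** 2).sum())

    res = optimize.minimize_scalar(sse, bounds=_LOG_NM_BOUNDS, method="bounded")
    log_nm = float(res.x)
    if min(abs(log_nm - b) for b in _LOG_NM_BOUNDS) < 1e-3:
        logger.warning("NCM optimizer at parameter bound (log10 Nm = %.3f)", log_nm)
    return 10.0**log_nm


def fit_ncm(
    occ: pd.DataFrame,
    n_reads: float,
    bootstrap: int = 1000,
    seed: int = 0,
    detection_limit: float | None = None,
) -> NcmFit:
    """Fit the neutral model to per-ASV occurrence statistics.

    ``occ`` comes from :func:`occurrence_stats`; ``n_reads`` is the number
    of individuals (reads) per sample, assumed uniform (e.g. the
    rarefaction depth).  The detection limit defaults to the continuity-
    corrected 1/(2 * n_reads): an ASV is detected when at least one read is
    observed, which in the continuous abundance approximation corresponds
    to crossing the half-read midpoint rather than a full read.
    """
    d = 0.5 / n_reads if detection_limit is None else detection_limit
    keep = (occ["p"] > 0) & (occ["p"] < 1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("NCM: excluding %d ASV(s) with p outside (0,1)", dropped)
    occ = occ.loc[keep]
    if len(occ) < 10:
        raise ValueError(f"need >= 10 ASVs with 0 < p < 1, got {len(occ)}")
    p = occ["p"].to_numpy()
    freq = occ["freq"].to_numpy()
    if np.allclose(freq, 1.0):
        raise ValueError("every ASV is detected everywhere; the fit is degenerate")

    nm = _fit_nm(p, freq, d)
    pred = predict_frequency(p, nm, d)
    sst = float(((freq - freq.mean()) ** 2).sum())
    r2 = 1.0 - float(((freq - pred) ** 2).sum()) / sst

    rng = np.random.default_rng(seed)
    n = len(p)
    boot_nm = np.empty(bootstrap)
    boot_r2 = np.empty(bootstrap)
    boot_pred = np.empty((bootstrap, n))
    for b in range(bootstrap):
        idx = rng.integers(0, n, size=n)
        nm_b = _fit_nm(p[idx], freq[idx], d)
        boot_nm[b] = nm_b
        pred_b = predict_frequency(p[idx], nm_b, d)
        sst_b = float(((freq[idx] - freq[idx].mean()) ** 2).sum())
        boot_r2[b] = 1.0 - float(((freq[idx] - pred_b) ** 2).sum()) / max(sst_b, 1e-300)
        boot_pred[b] = predict_frequency(p, nm_b, d)
    lo, hi = np.percentile(boot_pred, [2.5, 97.5], axis=0)
    partition = np.where(freq > hi, "above", np.where(freq < lo, "below", "within"))

    per_asv = pd.DataFrame(
        {
            "p": p,
            "freq": freq,
            "predicted": pred,
            "band_lo": lo,
            "band_hi": hi,
            "partition": partition,
        },
        index=occ.index,
    )
    ci_m = tuple(np.percentile(boot_nm, [2.5, 97.5]) / n_reads)
    ci_r2 = tuple(np.percentile(boot_r2, [2.5, 97.5]))
    return NcmFit(
        m=nm / n_reads,
        nm=nm,
        r2=r2,
        n_reads=n_reads,
        detection_limit=d,
        ci95_m=(float(ci_m[0]), float(ci_m[1])),
        ci95_r2=(float(ci_r2[0]), float(ci_r2[1])),
        n_bootstrap=bootstrap,
        seed=seed,
        per_asv=per_asv,
    )
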