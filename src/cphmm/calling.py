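"""Per-site methylation calling from bisulfite read counts.

CpG sites are called by a threshold on the non-conversion-corrected
methylation level Me = m/n - R (clamped to [0, 1]); CpH sites, whose levels
are far lower, are called by an exact upper-tail binomial test against the
non-conversion rate R, with the p-value cutoff calibrated by an empirical
false-discovery-rate procedure on simulated null counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import CPG, CPH, GenomicInterval, MethylomeTable, SampleMeta

logger = logging.getLogger(__name__)

DEFAULT_PVALUE_GRID = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6)


@dataclass
class CallThresholds:
    """Cutoffs for methylation calls.

    ``mcpg_me_min``: a CpG is methylated if Me strictly exceeds this.
    ``mcpg_me_min_lowmeth``: looser CpG cutoff for globally hypomethylated
    samples (e.g. DNMT-rescued ES cells).
    ``cph_pvalue_max``: a CpH is methylated if its binomial upper-tail
    p-value is strictly below this.
    """

    mcpg_me_min: float = 0.8
    mcpg_me_min_lowmeth: float = 0.5
    cph_pvalue_max: float = 1.0e-5

    def __post_init__(self) -> None:
        for name in ("mcpg_me_min", "mcpg_me_min_lowmeth", "cph_pvalue_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class FdrCalibration:
    """Empirical FDR (null calls / real calls) over a p-value grid."""

    thresholds: tuple[float, ...]
    real_counts: np.ndarray
    null_counts: np.ndarray
    fdr: np.ndarray
    seed: int
    recommended_cutoff: float | None = None


@dataclass
class RegionMethylation:
    interval: GenomicInterval
    mcpg_level: float | None
    mcph_level: float | None
    n_cpg: int
    n_cph: int
    n_mcph: int


def methylation_level(
    m: np.ndarray | int, n: np.ndarray | int, nonconversion_rate: float
) -> np.ndarray | float:
    """Me = pooled m / pooled n - R, clamped to [0, 1].  n must be > 0."""
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("methylation level undefined where total reads n == 0")
    me = np.clip(m / n - nonconversion_rate, 0.0, 1.0)
    return float(me) if me.ndim == 0 else me


def cph_pvalue(
    m: np.ndarray | int, n: np.ndarray | int, nonconversion_rate: float
) -> np.ndarray | float:
    """Upper-tail binomial p-value P(X >= m), X ~ Binomial(n, R).

    This is the probability of seeing at least the observed number of
    unconverted reads if the site were truly unmethylated and every
    methylated read were a conversion failure.  The tail is exact (regularized
    incomplete beta), not a normal approximation.
    """
    m = np.asarray(m)
    n = np.asarray(n)
    if np.any(m < 0) or np.any(m > n) or np.any(n <= 0):
        raise ValueError("require 0 <= m <= n and n > 0")
    R = nonconversion_rate
    if R == 0.0:
        logger.warning("cph_pvalue: R=0; any m>0 yields p=0 by convention")
        p = np.where(m > 0, 0.0, 1.0)
    elif not 0.0 < R < 1.0:
        raise ValueError(f"nonconversion rate must be in [0, 1), got {R}")
    else:
        # sf(m-1) = P(X >= m); continuous in the beta-function sense, exact tail
        p = stats.binom.sf(m - 1, n, R)
        p = np.minimum(p, 1.0)
    return float(p) if p.ndim == 0 else p


def call_sites(
    table: MethylomeTable,
    thresholds: CallThresholds | None = None,
    low_meth: bool = False,
) -> pd.DataFrame:
    """Call every site in the table.

    Returns a DataFrame aligned with ``table.df`` with columns
    ``chrom, pos, strand, context, motif, me, pvalue, methylated``.
    CpG calls carry no p-value (NaN); CpH calls carry no Me-based cutoff.
    """
    thresholds = thresholds or CallThresholds()
    df = table.df
    R = table.meta.nonconversion_rate
    me = methylation_level(df["m"].to_numpy(), df["n"].to_numpy(), R)
    is_cpg = (df["context"] == CPG).to_numpy()
    pvalue = np.full(len(df), np.nan)
    if (~is_cpg).any():
        pvalue[~is_cpg] = cph_pvalue(
            df["m"].to_numpy()[~is_cpg], df["n"].to_numpy()[~is_cpg], R
        )
    cut = thresholds.mcpg_me_min_lowmeth if low_meth else thresholds.mcpg_me_min
    methylated = np.where(
        is_cpg, me > cut, pvalue < thresholds.cph_pvalue_max
    )
    out = df[["chrom", "pos", "strand", "context", "motif"]].copy()
    out["me"] = me
    out["pvalue"] = pvalue
    out["methylated"] = methylated
    return out


def call_mcpg(
    table: MethylomeTable,
    thresholds: CallThresholds | None = None,
    low_meth: bool = False,
) -> pd.DataFrame:
    """Threshold-based CpG calls only (Me strictly above the cutoff)."""
    calls = call_sites(table, thresholds, low_meth)
    return calls[calls["context"] == CPG].reset_index(drop=True)


def call_mcph(
    table: MethylomeTable, thresholds: CallThresholds | None = None
) -> pd.DataFrame:
    """Binomial-test CpH calls only (p-value strictly below the cutoff)."""
    calls = call_sites(table, thresholds)
    return calls[calls["context"] == CPH].reset_index(drop=True)


def calibrate_fdr(
    table: MethylomeTable,
    grid: tuple[float, ...] = DEFAULT_PVALUE_GRID,
    seed: int = 0,
    fdr_target: float = 0.01,
    n_replicates: int = 1,
) -> FdrCalibration:
    """Empirical FDR of CpH calls over a descending p-value grid.

    Null methylated-read counts are drawn as Binomial(n_i, R) per CpH site
    with the given seed; at each cutoff the FDR is (calls on null data) /
    (calls on real data), with 0/0 defined as 0.  With ``n_replicates > 1``
    null counts are averaged over replicates.
    """
    grid = tuple(sorted(grid, reverse=True))
    cph = table.df[table.df["context"] == CPH]
    if cph.empty:
        raise ValueError("no CpH sites to calibrate on")
    R = table.meta.nonconversion_rate
    n = cph["n"].to_numpy()
    real_p = cph_pvalue(cph["m"].to_numpy(), n, R)
    rng = np.random.default_rng(seed)
    null_counts = np.zeros(len(grid))
    for _ in range(n_replicates):
        null_m = rng.binomial(n, R)
        null_p = cph_pvalue(null_m, n, R)
        null_counts += np.array([(null_p < a).sum() for a in grid], dtype=float)
    null_counts /= n_replicates
    real_counts = np.array([(real_p < a).sum() for a in grid], dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(real_counts > 0, null_counts / real_counts, 0.0)
    ok = [a for a, f in zip(grid, fdr) if f < fdr_target]
    recommended = max(ok) if ok else None
    if real_counts[-1] == 0 and real_counts[0] == 0:
        logger.warning("calibrate_fdr: no real calls at any cutoff")
        recommended = None
    return FdrCalibration(
        thresholds=grid,
        real_counts=real_counts,
        null_counts=null_counts,
        fdr=fdr,
        seed=seed,
        recommended_cutoff=recommended,
    )


def region_methylation(
    table: MethylomeTable,
    calls: pd.DataFrame,
    interval: GenomicInterval,
) -> RegionMethylation:
    """Region-level methylation summaries.

    mCpG level is the mean Me over CpG sites (both strands) in the interval;
    mCpH level is the number of methylated CpHs divided by the number of CpH
    sites.  Zero-denominator levels are reported as None, not 0.
    """
    in_region = (
        (calls["chrom"] == interval.chrom)
        & (calls["pos"] >= interval.start)
        & (calls["pos"] < interval.end)
    )
    sub = calls[in_region]
    cpg = sub[sub["context"] == CPG]
    cph = sub[sub["context"] == CPH]
    n_cpg, n_cph = len(cpg), len(cph)
    n_mcph = int(cph["methylated"].sum())
    mcpg_level = float(cpg["me"].mean()) if n_cpg else None
    mcph_level = n_mcph / n_cph if n_cph else None
    return RegionMethylation(interval, mcpg_level, mcph_level, n_cpg, n_cph, n_mcph)


def genome_mcph_level(calls: pd.DataFrame) -> float:
    """Genome-wide mCpH level: methylated CpHs / all CpH sites."""
    cph = calls[calls["context"] == CPH]
    if cph.empty:
        raise ValueError("no CpH sites")
    return float(cph["methylated"].mean())


class MethylationCaller(BaseEstimator):
    """Estimator-style front end for methylation calling.

    ``fit`` optionally runs the empirical-FDR calibration on the training
    table and stores the chosen CpH p-value cutoff; ``predict`` produces the
    per-site call table.  Usable unfitted with the default thresholds via
    :func:`call_sites`.
    """

    def __init__(
        self,
        mcpg_me_min: float = 0.8,
        mcpg_me_min_lowmeth: float = 0.5,
        cph_pvalue_max: float = 1.0e-5,
        low_meth: bool = False,
        calibrate: bool = False,
        fdr_target: float = 0.01,
        seed: int = 0,
    ):
        self.mcpg_me_min = mcpg_me_min
        self.mcpg_me_min_lowmeth = mcpg_me_min_lowmeth
        self.cph_pvalue_max = cph_pvalue_max
        self.low_meth = low_meth
        self.calibrate = calibrate
        self.fdr_target = fdr_target
        self.seed = seed

    def _thresholds(self, cph_pvalue_max: float | None = None) -> CallThresholds:
        return CallThresholds(
            mcpg_me_min=self.mcpg_me_min,
            mcpg_me_min_lowmeth=self.mcpg_me_min_lowmeth,
            cph_pvalue_max=cph_pvalue_max or self.cph_pvalue_max,
        )

    def fit(self, X: MethylomeTable, y=None) -> "MethylationCaller":
        cutoff = self.cph_pvalue_max
        self.calibration_ = None
        if self.calibrate:
            self.calibration_ = calibrate_fdr(
                X, seed=self.seed, fdr_target=self.fdr_target
            )
            if self.calibration_.recommended_cutoff is not None:
                cutoff = self.calibration_.recommended_cutoff
        self.thresholds_ = self._thresholds(cutoff)
        return self

    def predict(self, X: MethylomeTable) -> pd.DataFrame:
        thresholds = getattr(self, "thresholds_", None) or self._thresholds()
        return call_sites(X, thresholds, low_meth=self.low_meth)
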