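"""Three-state HMM segmentation of a methylome into P/N/U correlation states.

The genome is tiled into 180-bp bins (the periodicity of de-novo DNA
methylation along nucleosomes).  Each bin emits its pooled CpH
methylated-read count under a binomial whose success probability is
state-specific:

* U (uncorrelated): the genome-wide CpH methylated-read ratio.
* P (positive correlation with CpG methylation): a beta-posterior mean whose
  prior is shifted *up* from the genome-wide ratio in proportion to the
  bin's CpG-methylation z-score.
* N (negative correlation, i.e. a CpG-CpH DMR): the same shift, downward.

The prior strength is the bin's CpG read total (used as pseudo-counts), so
bins with deep CpG coverage pull the P/N emission probabilities further
apart.  Transition probabilities (and the initial distribution) are the only
free parameters and are fitted by Baum-Welch; decoding is Viterbi.  Runs of
N-state bins are the CpG-CpH DMRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from ._kernels import expected_counts, forward_log, viterbi_log
from .io import CPG, CPH, GenomicInterval, MethylomeTable

logger = logging.getLogger(__name__)

STATES = ("P", "N", "U")
P, N, U = 0, 1, 2
UNASSIGNED = -1

#: numerical clamp keeping prior means and thetas inside (0, 1)
THETA_EPS = 1e-6

#: default self-transition mass at EM initialization; methylation states are
#: long-ranged (DMRs span many bins), and a uniform start is an unstable
#: fixed point of the transition-only EM from which it cannot escape
DEFAULT_SELF_TRANSITION = 0.9


def sticky_transition_init(self_p: float = DEFAULT_SELF_TRANSITION) -> np.ndarray:
    a = np.full((3, 3), (1.0 - self_p) / 2.0)
    np.fill_diagonal(a, self_p)
    return a

BIN_COLUMNS = ["chrom", "index", "start", "end",
               "cpg_m", "cpg_n", "cph_m", "cph_n", "detected"]


@dataclass
class GenomeMethylationStats:
    """Genome-wide summaries over detected bins.

    theta_u: CpH methylated-read ratio pooled over the genome (the U-state
    emission probability).  med_mg / sd_mg: median and sample SD of the
    per-bin CpG methylated-read ratio mG.  sd_mh: sample SD of the per-bin
    CpH methylated-read ratio.
    """

    theta_u: float
    med_mg: float
    sd_mg: float
    sd_mh: float
    n_detected: int


@dataclass
class EmissionParameters:
    """Per-bin binomial emission parameters for the three states."""

    m_prior: np.ndarray      # (n_bins, 2) prior means for P, N
    alpha: np.ndarray        # (n_bins, 2) beta pseudo-counts
    beta: np.ndarray         # (n_bins, 2)
    theta: np.ndarray        # (n_bins, 3) posterior-mean success probabilities
    log_e: np.ndarray        # (n_bins, 3) log emission probabilities
    detected: np.ndarray     # (n_bins,) bool


@dataclass
class HmmModel:
    states: tuple[str, ...]
    transition: np.ndarray
    initial: np.ndarray
    em_history: list[dict] = field(default_factory=list)
    converged: bool = True


@dataclass
class StateSegment:
    chrom: str
    start: int
    end: int
    state: str
    n_bins: int
    n_gap_bins_absorbed: int = 0


def make_bins(
    table: MethylomeTable,
    bin_size: int = 180,
    min_bin_reads: int = 10,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Tile each chromosome into fixed bins and pool read counts per bin.

    A bin is *detected* when both its CpG and its CpH read totals strictly
    exceed ``min_bin_reads``.  Bins are half-open [start, start+bin_size);
    only the chromosome tail bin may be shorter (when ``chrom_sizes`` gives
    the true length).
    """
    if len(table) == 0:
        raise ValueError("empty methylome table")
    df = table.df
    frames = []
    for chrom, sub in df.groupby("chrom", sort=True, observed=True):
        pos = sub["pos"].to_numpy()
        size = (chrom_sizes or {}).get(chrom, int(pos.max()) + 1)
        n_bins = int(np.ceil(size / bin_size))
        idx = pos // bin_size
        is_cpg = (sub["context"] == CPG).to_numpy()
        m = sub["m"].to_numpy(dtype=float)
        n = sub["n"].to_numpy(dtype=float)
        cpg_m = np.bincount(idx[is_cpg], weights=m[is_cpg], minlength=n_bins)
        cpg_n = np.bincount(idx[is_cpg], weights=n[is_cpg], minlength=n_bins)
        cph_m = np.bincount(idx[~is_cpg], weights=m[~is_cpg], minlength=n_bins)
        cph_n = np.bincount(idx[~is_cpg], weights=n[~is_cpg], minlength=n_bins)
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, size)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "index": np.arange(n_bins, dtype=np.int64),
            "start": starts,
            "end": ends,
            "cpg_m": cpg_m.astype(np.int64),
            "cpg_n": cpg_n.astype(np.int64),
            "cph_m": cph_m.astype(np.int64),
            "cph_n": cph_n.astype(np.int64),
        }))
    bins = pd.concat(frames, ignore_index=True)
    bins["detected"] = (bins["cpg_n"] > min_bin_reads) & (bins["cph_n"] > min_bin_reads)
    return bins


def genome_stats(bins: pd.DataFrame) -> GenomeMethylationStats:
    """Genome-wide methylation statistics over detected bins."""
    det = bins[bins["detected"]]
    if len(det) < 2:
        raise ValueError("need at least 2 detected bins")
    theta_u = float(det["cph_m"].sum() / det["cph_n"].sum())
    mg = (det["cpg_m"] / det["cpg_n"]).to_numpy()
    mh = (det["cph_m"] / det["cph_n"]).to_numpy()
    sd_mg = float(np.std(mg, ddof=1))
    sd_mh = float(np.std(mh, ddof=1))
    if sd_mg == 0.0 or sd_mh == 0.0:
        raise ValueError(
            "degenerate genome: per-bin methylation has zero variance; "
            "regenerate the input with variable methylation levels"
        )
    return GenomeMethylationStats(
        theta_u=theta_u,
        med_mg=float(np.median(mg)),
        sd_mg=sd_mg,
        sd_mh=sd_mh,
        n_detected=len(det),
    )


def prior_mean(
    mg: np.ndarray | float, stats: GenomeMethylationStats, state: str
) -> np.ndarray | float:
    """Prior mean of the CpH rate for state P or N at CpG ratio ``mg``.

    M_P = theta_u + sd_mh * z and M_N = theta_u - sd_mh * z with
    z = (mG - med_mg)/sd_mg, clamped into (0, 1).
    """
    if state not in ("P", "N"):
        raise ValueError("prior_mean is defined for states P and N only")
    z = (np.asarray(mg, dtype=float) - stats.med_mg) / stats.sd_mg
    sign = 1.0 if state == "P" else -1.0
    m = stats.theta_u + sign * stats.sd_mh * z
    m = np.clip(m, THETA_EPS, 1.0 - THETA_EPS)
    return float(m) if m.ndim == 0 else m


def posterior_theta(
    cph_m: np.ndarray | float,
    cph_n: np.ndarray | float,
    cpg_n: np.ndarray | float,
    m_prior: np.ndarray | float,
) -> np.ndarray | float:
    """Beta-posterior mean CpH rate with CpG reads as pseudo-counts.

    alpha = cpg_n * M and beta = cpg_n - alpha, so
    theta_hat = (cph_m + alpha) / (cph_n + cpg_n).
    """
    alpha = np.asarray(cpg_n, dtype=float) * np.asarray(m_prior, dtype=float)
    th = (np.asarray(cph_m, dtype=float) + alpha) / (
        np.asarray(cph_n, dtype=float) + np.asarray(cpg_n, dtype=float)
    )
    th = np.clip(th, THETA_EPS, 1.0 - THETA_EPS)
    return float(th) if th.ndim == 0 else th


def emission_matrix(
    bins: pd.DataFrame, stats: GenomeMethylationStats
) -> EmissionParameters:
    """Per-bin log emission probabilities for states (P, N, U).

    Detected bins emit their CpH methylated-read count under
    Binomial(cph_n, theta_state); undetected bins are uninformative
    (log e = 0 for every state) so that they carry genomic distance without
    influencing the decoded path.
    """
    n_bins = len(bins)
    cpg_m = bins["cpg_m"].to_numpy(dtype=float)
    cpg_n = bins["cpg_n"].to_numpy(dtype=float)
    cph_m = bins["cph_m"].to_numpy(dtype=float)
    cph_n = bins["cph_n"].to_numpy(dtype=float)
    detected = bins["detected"].to_numpy(dtype=bool)

    m_prior = np.full((n_bins, 2), np.nan)
    alpha = np.full((n_bins, 2), np.nan)
    beta_pc = np.full((n_bins, 2), np.nan)
    theta = np.full((n_bins, 3), np.nan)
    log_e = np.zeros((n_bins, 3))

    d = detected
    with np.errstate(invalid="ignore", divide="ignore"):
        mg = np.where(cpg_n > 0, cpg_m / np.where(cpg_n > 0, cpg_n, 1.0), np.nan)
    for si, state in ((P, "P"), (N, "N")):
        m_prior[d, si] = prior_mean(mg[d], stats, state)
        alpha[d, si] = cpg_n[d] * m_prior[d, si]
        beta_pc[d, si] = cpg_n[d] - alpha[d, si]
        theta[d, si] = posterior_theta(cph_m[d], cph_n[d], cpg_n[d], m_prior[d, si])
    theta[d, U] = np.clip(stats.theta_u, THETA_EPS, 1.0 - THETA_EPS)
    for si in (P, N, U):
        log_e[d, si] = sps.binom.logpmf(cph_m[d], cph_n[d], theta[d, si])
    return EmissionParameters(m_prior, alpha, beta_pc, theta, log_e, detected)


def split_chains(
    bins: pd.DataFrame, max_gap_bp: int = 100_000, bin_size: int = 180
) -> list[tuple[int, int]]:
    """Split bins into HMM chains at long undetected stretches.

    A new chain starts after any run of consecutive undetected bins spanning
    strictly more than ``max_gap_bp``; chains never cross chromosome
    boundaries, and leading/trailing undetected runs are trimmed.  Returns
    half-open (start, stop) positional index ranges into ``bins``.
    """
    chains: list[tuple[int, int]] = []
    detected = bins["detected"].to_numpy(dtype=bool)
    offset = 0
    for chrom, sub in bins.groupby("chrom", sort=True, observed=True):
        d = detected[offset : offset + len(sub)]
        det_idx = np.flatnonzero(d)
        if det_idx.size:
            # break where the undetected run between consecutive detected
            # bins spans more than max_gap_bp
            gaps = np.diff(det_idx) - 1
            breaks = np.flatnonzero(gaps * bin_size > max_gap_bp)
            chain_start = det_idx[0]
            for b in breaks:
                chains.append((offset + chain_start, offset + det_idx[b] + 1))
                chain_start = det_idx[b + 1]
            chains.append((offset + chain_start, offset + det_idx[-1] + 1))
        offset += len(sub)
    return chains


def fit_transitions(
    chain_log_e: list[np.ndarray],
    tol: float = 5e-4,
    max_iter: int = 500,
    transition_init: np.ndarray | None = None,
    initial_init: np.ndarray | None = None,
) -> HmmModel:
    """Baum-Welch restricted to the transition matrix and initial law.

    Emissions are fixed bin-specific binomials and are not re-estimated.
    Iterates until the largest absolute change of any transition probability
    falls below ``tol``.  The per-iteration data log-likelihood is recorded
    and is non-decreasing.  Initialization defaults to a sticky diagonal
    (self-transition ``DEFAULT_SELF_TRANSITION``), uniform initial law.
    """
    if not chain_log_e:
        raise ValueError("no chains to train on")
    S = 3
    a = (sticky_transition_init() if transition_init is None
         else np.array(transition_init, dtype=float))
    pi = (np.full(S, 1.0 / S) if initial_init is None
          else np.array(initial_init, dtype=float))
    history: list[dict] = []
    converged = False
    if all(le.shape[0] < 2 for le in chain_log_e):
        logger.warning("fit_transitions: no chain has >=2 bins; "
                       "transition matrix left at initialization")
        return HmmModel(STATES, a, pi, history, converged=True)
    for it in range(max_iter):
        log_a = np.log(np.maximum(a, 1e-300))
        log_pi = np.log(np.maximum(pi, 1e-300))
        xi_sum = np.zeros((S, S))
        gamma0_sum = np.zeros(S)
        loglik = 0.0
        for le in chain_log_e:
            xi, gamma0, ll = expected_counts(log_a, log_pi, le)
            xi_sum += xi
            gamma0_sum += gamma0
            loglik += ll
        row = xi_sum.sum(axis=1, keepdims=True)
        a_new = np.where(row > 0, xi_sum / np.where(row > 0, row, 1.0), a)
        pi_new = gamma0_sum / gamma0_sum.sum()
        delta = float(np.abs(a_new - a).max())
        history.append({"iteration": it, "delta": delta, "loglik": float(loglik)})
        a, pi = a_new, pi_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("fit_transitions: max_iter=%d reached without convergence",
                       max_iter)
    return HmmModel(STATES, a, pi, history, converged=converged)


def viterbi_decode(
    chains: list[tuple[int, int]],
    emissions: EmissionParameters,
    model: HmmModel,
) -> np.ndarray:
    """Most probable state per bin; bins outside every chain stay unassigned."""
    a = model.transition
    if not np.allclose(a.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must sum to 1")
    states = np.full(emissions.log_e.shape[0], UNASSIGNED, dtype=np.int64)
    log_a = np.log(np.maximum(a, 1e-300))
    log_pi = np.log(np.maximum(model.initial, 1e-300))
    for i0, i1 in chains:
        path, _ = viterbi_log(log_a, log_pi, emissions.log_e[i0:i1])
        states[i0:i1] = path
    return states


def emission_argmax_states(emissions: EmissionParameters) -> np.ndarray:
    """State of highest emission probability per detected bin.

    Exact ties go to the earlier state in (P, N, U) order; undetected bins
    remain unassigned.
    """
    log_e = emissions.log_e
    states = np.full(log_e.shape[0], UNASSIGNED, dtype=np.int64)
    d = emissions.detected
    states[d] = np.argmax(log_e[d], axis=1)  # argmax takes the first maximum
    n_ties = int((np.sum(log_e[d] == log_e[d].max(axis=1, keepdims=True), axis=1) > 1).sum())
    if n_ties:
        logger.info("emission_argmax_states: %d bins with tied emissions "
                    "resolved in (P, N, U) order", n_ties)
    return states


def link_and_extract_dmrs(
    bins: pd.DataFrame,
    states: np.ndarray,
    max_gap_bins: int = 3,
) -> tuple[list[StateSegment], list[GenomicInterval]]:
    """Link same-state runs across short gaps and return N segments as DMRs.

    Two runs of the same state are merged when the gap between them is
    shorter than ``max_gap_bins`` bins (i.e. at most ``max_gap_bins - 1``
    bins of other or unassigned state, 540 bp at the defaults).  Merging is
    greedy left-to-right, so absorbed gap bins belong to the earlier
    segment; their per-bin states are not relabeled.
    """
    segments: list[StateSegment] = []
    offset = 0
    for chrom, sub in bins.groupby("chrom", sort=True, observed=True):
        st = states[offset : offset + len(sub)]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # run-length encode
        runs: list[tuple[int, int, int]] = []  # (state, first_bin, last_bin+1)
        i = 0
        while i < len(st):
            j = i
            while j < len(st) and st[j] == st[i]:
                j += 1
            runs.append((int(st[i]), i, j))
            i = j
        r = 0
        while r < len(runs):
            s, b0, b1 = runs[r]
            if s == UNASSIGNED:
                r += 1
                continue
            gaps = 0
            nxt = r + 1
            while True:
                g = 0
                k = nxt
                while (k < len(runs) and runs[k][0] != s
                       and g + (runs[k][2] - runs[k][1]) <= max_gap_bins - 1):
                    g += runs[k][2] - runs[k][1]
                    k += 1
                if k < len(runs) and runs[k][0] == s:
                    gaps += g
                    b1 = runs[k][2]
                    nxt = k + 1
                else:
                    break
            segments.append(StateSegment(
                chrom=chrom,
                start=int(starts[b0]),
                end=int(ends[b1 - 1]),
                state=STATES[s],
                n_bins=b1 - b0,
                n_gap_bins_absorbed=gaps,
            ))
            r = nxt
        offset += len(sub)
    dmrs = [GenomicInterval(seg.chrom, seg.start, seg.end, name="N")
            for seg in segments if seg.state == "N"]
    return segments, dmrs


class HmmSegmenter(BaseEstimator):
    """Three-state (P/N/U) HMM genome segmenter.

    fit(bins) computes genome statistics and per-bin emissions, splits the
    genome into chains at long undetected stretches, and trains the
    transition matrix by Baum-Welch.  predict(bins) Viterbi-decodes a
    per-bin state array (UNASSIGNED outside chains).  ``bins`` is the
    DataFrame produced by :func:`make_bins`.

    Fitted attributes: ``stats_``, ``emissions_``, ``chains_``, ``model_``,
    ``transition_``, ``initial_``, ``em_history_``, ``n_iter_``.
    """

    def __init__(
        self,
        bin_size: int = 180,
        max_gap_bp: int = 100_000,
        link_gap_bins: int = 3,
        tol: float = 5e-4,
        max_iter: int = 500,
    ):
        self.bin_size = bin_size
        self.max_gap_bp = max_gap_bp
        self.link_gap_bins = link_gap_bins
        self.tol = tol
        self.max_iter = max_iter

    def _prepare(self, bins: pd.DataFrame):
        stats = genome_stats(bins)
        emissions = emission_matrix(bins, stats)
        chains = split_chains(bins, self.max_gap_bp, self.bin_size)
        return stats, emissions, chains

    def fit(self, X: pd.DataFrame, y=None) -> "HmmSegmenter":
        self.stats_, self.emissions_, self.chains_ = self._prepare(X)
        chain_log_e = [self.emissions_.log_e[i0:i1] for i0, i1 in self.chains_]
        self.model_ = fit_transitions(chain_log_e, tol=self.tol,
                                      max_iter=self.max_iter)
        self.transition_ = self.model_.transition
        self.initial_ = self.model_.initial
        self.em_history_ = self.model_.em_history
        self.n_iter_ = len(self.em_history_)
        self._fit_bins_id = id(X)
        return self

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("HmmSegmenter is not fitted")
        if X is None or id(X) == self._fit_bins_id:
            emissions, chains = self.emissions_, self.chains_
        else:
            _, emissions, chains = self._prepare(X)
        return viterbi_decode(chains, emissions, self.model_)

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).predict(X)

    def extract_dmrs(
        self, bins: pd.DataFrame, states: np.ndarray
    ) -> tuple[list[StateSegment], list[GenomicInterval]]:
        return link_and_extract_dmrs(bins, states, self.link_gap_bins)
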