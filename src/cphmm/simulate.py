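"""Synthetic methylomes with planted P/N-state structure.

The generator builds an artificial chromosome in 180-bp bins.  Every bin
carries a CpG methylation level drawn uniformly on (0, 1); planted N-state
regions invert the CpG-CpH coupling: the CpH level is 0.1 x Me_CpG inside
P-state bins and 0.1 x (1 - Me_CpG) inside N-state bins, reflecting the
roughly tenfold lower methylation of CpH sites.  Read counts are drawn per
site with Poisson depth and binomial methylated-read counts, optionally
adding bisulfite non-conversion noise.  A bin-level generator for HMM
parameter-recovery experiments and a CpH-only generator for the
false-discovery-rate calibration are included, together with bin-level
precision/recall scoring of DMR callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CPG, CPH, GenomicInterval, MethylomeTable, SampleMeta, table_from_arrays
from .segmentation import (
    N, P, STATES, UNASSIGNED, HmmSegmenter, emission_argmax_states, emission_matrix,
    genome_stats, make_bins, split_chains,
)

logger = logging.getLogger(__name__)

SIM_CHROM = "chrSim"


@dataclass
class SimulationConfig:
    """Study conditions for one artificial chromosome.

    Defaults follow the validation design: mean read depth 10, 180-bp bins,
    CpH levels at one tenth of the CpG scale, and planted N regions of
    1-100 bins.  Site densities default to 2 CpG and 21 CpH sites per bin,
    matching genome-average dinucleotide frequencies.
    """

    genome_length: int = 9_000_000
    bin_size: int = 180
    mean_depth: float = 10.0
    n_regions: int = 50
    region_len_range: tuple[int, int] = (1, 100)
    cpg_per_bin_mean: float = 2.0
    cph_per_bin_mean: float = 21.0
    nonconversion_rate: float = 0.005
    mcph_scale: float = 0.1
    seed: int = 0
    fixed_depth: bool = False
    add_noise: bool = True
    sample_id: str = "sim"

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.bin_size <= 0 or self.mean_depth <= 0:
            raise ValueError("genome_length, bin_size and mean_depth must be positive")
        lo, hi = self.region_len_range
        if not 1 <= lo <= hi <= self.n_bins:
            raise ValueError("region_len_range must lie within [1, n_bins]")

    @property
    def n_bins(self) -> int:
        return int(np.ceil(self.genome_length / self.bin_size))


@dataclass
class PlantedTruth:
    """Ground truth of one simulated chromosome (bin-level)."""

    states: np.ndarray                 # (n_bins,) with P=0, N=1
    me_cpg: np.ndarray                 # (n_bins,) CpG methylation level per bin
    regions: list[GenomicInterval]     # planted N regions, bp coordinates
    bin_size: int
    chrom: str = SIM_CHROM


@dataclass
class EvaluationResult:
    """Bin-level N-state detection counts and rates; 0/0 rates are None."""

    tp: int
    fp: int
    fn: int
    precision: float | None = field(init=False)
    recall: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.precision = self.tp / (self.tp + self.fp) if self.tp + self.fp else None
        self.recall = self.tp / (self.tp + self.fn) if self.tp + self.fn else None


def plant_truth(config: SimulationConfig) -> PlantedTruth:
    """Place non-overlapping N-state regions at random; all other bins are P.

    Region lengths are uniform over ``region_len_range`` (in bins); starts
    are uniform over the chromosome.  Overlapping draws are rejected and
    redrawn.  Per-bin CpG methylation levels are Uniform(0, 1).
    """
    rng = np.random.default_rng(config.seed)
    n_bins = config.n_bins
    lo, hi = config.region_len_range
    lengths = rng.integers(lo, hi + 1, size=config.n_regions)
    if lengths.sum() > 0.8 * n_bins:
        raise ValueError(
            f"cannot pack {config.n_regions} regions totalling {lengths.sum()} bins "
            f"into {n_bins} bins (over 80% occupancy)"
        )
    occupied = np.zeros(n_bins, dtype=bool)
    regions: list[GenomicInterval] = []
    for length in lengths:
        for _ in range(10_000):
            start = int(rng.integers(0, n_bins - length + 1))
            if not occupied[start : start + length].any():
                occupied[start : start + length] = True
                regions.append(GenomicInterval(
                    SIM_CHROM,
                    start * config.bin_size,
                    (start + length) * config.bin_size,
                    name="N",
                ))
                break
        else:
            raise ValueError("failed to place a planted region without overlap")
    states = np.where(occupied, N, P).astype(np.int64)
    me_cpg = rng.uniform(0.0, 1.0, size=n_bins)
    regions.sort(key=lambda iv: iv.start)
    return PlantedTruth(states, me_cpg, regions, config.bin_size)


def simulate_methylome(truth: PlantedTruth, config: SimulationConfig) -> MethylomeTable:
    """Draw per-site read counts for a planted truth.

    Site counts per bin are Poisson; positions are uniform without
    replacement within the bin; per-site depth is Poisson(mean_depth) (or
    exactly mean_depth in fixed-depth mode); methylated reads are
    Binomial(depth, Me_site).  Sites with zero depth are absent from the
    output, as in real count reports.  With ``add_noise`` a
    Binomial(n - m, R) count of falsely methylated reads is added.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_bins = len(truth.states)
    bin_size = config.bin_size
    k_cpg = rng.poisson(config.cpg_per_bin_mean, size=n_bins)
    k_cph = rng.poisson(config.cph_per_bin_mean, size=n_bins)
    k_tot = np.minimum(k_cpg + k_cph, bin_size)
    k_cpg = np.minimum(k_cpg, k_tot)
    k_cph = k_tot - k_cpg

    # distinct within-bin offsets: one random permutation of [0, bin_size)
    # per bin, first k_cpg columns are CpG sites, next k_cph are CpH
    perm = rng.permuted(
        np.broadcast_to(np.arange(bin_size), (n_bins, bin_size)).copy(), axis=1
    )
    cols = np.broadcast_to(np.arange(bin_size), (n_bins, bin_size))
    mask_cpg = cols < k_cpg[:, None]
    mask_cph = (cols >= k_cpg[:, None]) & (cols < k_tot[:, None])

    rows_cpg, _ = np.nonzero(mask_cpg)
    rows_cph, _ = np.nonzero(mask_cph)
    pos = np.concatenate([
        rows_cpg * bin_size + perm[mask_cpg],
        rows_cph * bin_size + perm[mask_cph],
    ])
    bin_of = np.concatenate([rows_cpg, rows_cph])
    is_cpg = np.zeros(len(pos), dtype=bool)
    is_cpg[: len(rows_cpg)] = True

    me_cpg = truth.me_cpg[bin_of]
    in_n = truth.states[bin_of] == N
    me_cph = np.where(in_n, 1.0 - me_cpg, me_cpg) * config.mcph_scale
    me_site = np.where(is_cpg, me_cpg, me_cph)

    if config.fixed_depth:
        n = np.full(len(pos), int(round(config.mean_depth)), dtype=np.int64)
    else:
        n = rng.poisson(config.mean_depth, size=len(pos))
    m = rng.binomial(n, me_site)
    if config.add_noise and config.nonconversion_rate > 0:
        m = m + rng.binomial(n - m, config.nonconversion_rate)
    covered = n > 0
    order = np.argsort(pos[covered], kind="mergesort")

    meta = SampleMeta(config.sample_id, config.nonconversion_rate, ["sim"])
    motif = np.where(is_cpg[covered][order], "CGG", "CAC")
    return table_from_arrays(
        chrom=np.full(int(covered.sum()), truth.chrom, dtype=object),
        pos=pos[covered][order],
        strand=np.full(int(covered.sum()), "+", dtype=object),
        context=np.where(is_cpg[covered][order], CPG, CPH),
        m=m[covered][order],
        n=n[covered][order],
        meta=meta,
        motif=motif,
    )


def make_null_calibration_input(
    n_sites: int = 200_000,
    mean_depth: float = 10.0,
    nonconversion_rate: float = 0.005,
    frac_methylated: float = 0.05,
    true_level: float = 0.3,
    seed: int = 0,
) -> MethylomeTable:
    """CpH-only table for empirical-FDR calibration.

    A ``frac_methylated`` fraction of sites is truly methylated at
    ``true_level``; the rest carry only non-conversion noise,
    m ~ Binomial(n, R).  Zero-depth sites are redrawn to depth 1 so every
    site is covered.
    """
    if not 0.0 <= frac_methylated < 1.0:
        raise ValueError("frac_methylated must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = rng.poisson(mean_depth, size=n_sites)
    n = np.maximum(n, 1)
    methylated = rng.random(n_sites) < frac_methylated
    level = np.where(methylated, true_level, nonconversion_rate)
    m = rng.binomial(n, level)
    meta = SampleMeta("null_calibration", nonconversion_rate, ["sim"])
    return table_from_arrays(
        chrom=np.full(n_sites, SIM_CHROM, dtype=object),
        pos=np.arange(n_sites, dtype=np.int64) * 2,
        strand=np.full(n_sites, "+", dtype=object),
        context=np.full(n_sites, CPH, dtype=object),
        m=m,
        n=n,
        meta=meta,
        motif=np.full(n_sites, "CAC", dtype=object),
    )


def simulate_hmm_bins(
    transition: np.ndarray,
    n_bins: int = 20_000,
    seed: int = 0,
    cpg_reads_mean: float = 1000.0,
    cph_reads_mean: float = 500.0,
    mcph_scale: float = 0.1,
    me_levels: tuple[float, float] = (0.02, 0.98),
    initial: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Bin-level counts from a known three-state Markov chain.

    States follow ``transition`` (order P, N, U).  Per-bin CpG levels are
    drawn from the two well-separated ``me_levels``; CpH levels follow the
    P/N coupling (U bins sit at the genome-average level).  Returns the bin
    table and the true state sequence.

    Intended for transition-matrix recovery experiments, so the default
    read depths put the data in an identifiable regime: the beta-posterior
    emission separates states at a per-bin rate that grows with
    cpg_reads^2 / cph_reads (the prior pseudo-counts must compete with the
    observed CpH ratio), hence the deep CpG-dominated coverage here.
    """
    transition = np.asarray(transition, dtype=float)
    rng = np.random.default_rng(seed)
    if initial is None:
        initial = np.full(3, 1.0 / 3.0)
    row_p = transition / transition.sum(axis=1, keepdims=True)
    states = np.empty(n_bins, dtype=np.int64)
    states[0] = rng.choice(3, p=np.asarray(initial) / np.sum(initial))
    for t in range(1, n_bins):
        states[t] = rng.choice(3, p=row_p[states[t - 1]])
    me_cpg = rng.choice(np.asarray(me_levels), size=n_bins)
    mean_me = float(np.mean(me_levels))
    me_cph = np.where(
        states == P, me_cpg, np.where(states == N, 1.0 - me_cpg, mean_me)
    ) * mcph_scale
    cpg_n = rng.poisson(cpg_reads_mean, size=n_bins)
    cph_n = rng.poisson(cph_reads_mean, size=n_bins)
    cpg_m = rng.binomial(cpg_n, me_cpg)
    cph_m = rng.binomial(cph_n, me_cph)
    bins = pd.DataFrame({
        "chrom": SIM_CHROM,
        "index": np.arange(n_bins, dtype=np.int64),
        "start": np.arange(n_bins, dtype=np.int64) * 180,
        "end": (np.arange(n_bins, dtype=np.int64) + 1) * 180,
        "cpg_m": cpg_m.astype(np.int64),
        "cpg_n": cpg_n.astype(np.int64),
        "cph_m": cph_m.astype(np.int64),
        "cph_n": cph_n.astype(np.int64),
    })
    bins["detected"] = (bins["cpg_n"] > 10) & (bins["cph_n"] > 10)
    return bins, states


def evaluate_precision_recall(
    predicted_states: np.ndarray, truth_states: np.ndarray
) -> EvaluationResult:
    """Bin-level precision and recall of N-state detection."""
    predicted_states = np.asarray(predicted_states)
    truth_states = np.asarray(truth_states)
    if predicted_states.shape != truth_states.shape:
        raise ValueError(
            f"length mismatch: predicted {predicted_states.shape} "
            f"vs truth {truth_states.shape}"
        )
    pred_n = predicted_states == N
    true_n = truth_states == N
    tp = int((pred_n & true_n).sum())
    fp = int((pred_n & ~true_n).sum())
    fn = int((~pred_n & true_n).sum())
    return EvaluationResult(tp, fp, fn)


def run_single_benchmark(
    config: SimulationConfig,
) -> dict[str, EvaluationResult]:
    """Simulate one chromosome and score both DMR callers against the truth."""
    truth = plant_truth(config)
    table = simulate_methylome(truth, config)
    bins = make_bins(
        table, bin_size=config.bin_size,
        chrom_sizes={truth.chrom: config.genome_length},
    )
    stats = genome_stats(bins)
    emissions = emission_matrix(bins, stats)
    chains = split_chains(bins, bin_size=config.bin_size)
    segmenter = HmmSegmenter(bin_size=config.bin_size)
    viterbi_states = segmenter.fit_predict(bins)
    emission_states = emission_argmax_states(emissions)
    assert len(truth.states) == len(bins)
    return {
        "emission_only": evaluate_precision_recall(emission_states, truth.states),
        "viterbi": evaluate_precision_recall(viterbi_states, truth.states),
    }


def run_benchmark(
    configs: list[SimulationConfig] | None = None,
    n_sets: int = 30,
    master_seed: int = 7,
    base_config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Precision/recall of emission-only vs full-HMM N-state calling.

    Either pass explicit ``configs`` or let ``n_sets`` replicate
    ``base_config`` with per-set seeds spawned deterministically from
    ``master_seed``.  Returns one row per (set, caller).
    """
    if configs is None:
        base = base_config or SimulationConfig()
        rng = np.random.default_rng(master_seed)
        seeds = rng.integers(0, 2**31 - 1, size=n_sets)
        configs = [replace(base, seed=int(s)) for s in seeds]
    rows = []
    for i, config in enumerate(configs):
        results = run_single_benchmark(config)
        for caller, res in results.items():
            rows.append({
                "set": i,
                "seed": config.seed,
                "caller": caller,
                "tp": res.tp,
                "fp": res.fp,
                "fn": res.fn,
                "precision": res.precision,
                "recall": res.recall,
            })
    return pd.DataFrame(rows)
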