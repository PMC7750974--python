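"""Downstream analysis of CpG-CpH DMRs.

Classifies DMRs as hyper- or hypo-mCpH by fold change against the
genome-wide mCpH level, intersects them with genome annotations
(enhancers, promoters, CpG islands, ...), tallies which trinucleotide
motifs carry the methylated CpHs, and computes the mCpG-centered CpH
methylation proximity profile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import region_methylation
from .io import CPG, CPH, GenomicInterval, MethylomeTable

logger = logging.getLogger(__name__)

#: pseudo-level guarding log/ratio operations against a zero genome level
LEVEL_GUARD = 0.0001


@dataclass
class DmrRecord:
    """An N-state region with its mCpH level and hyper/hypo class."""

    interval: GenomicInterval
    mcph_level: float | None
    fold_change: float | None
    klass: str  # hyper | hypo | neither
    n_cph: int = 0
    n_mcph: int = 0


@dataclass
class OverlapRow:
    annotation_name: str
    bp_overlap: int
    fraction_of_annotation: float | None
    fraction_of_dmr_set: float | None


@dataclass
class ProximityProfile:
    """Mean CpH methylation by distance to (un)methylated CpG centers.

    ``values[i]`` is the 50-bp sliding-window mean at ``offsets[i]`` (5'->3'
    on the center's strand); NaN where no CpH was observed in the window.
    """

    offsets: np.ndarray
    values: np.ndarray
    n_centers: int


def classify_dmrs(
    dmrs: list[GenomicInterval],
    table: MethylomeTable,
    calls: pd.DataFrame,
    genome_mcph_level: float,
) -> list[DmrRecord]:
    """Hyper-/hypo-mCpH classification by fold change.

    FC = DMR mCpH level / genome-wide mCpH level; hyper iff FC > 2, hypo iff
    FC < 0.5 (both strict), otherwise neither.  A non-positive genome level
    falls back to a +0.0001 pseudo-level.
    """
    denom = genome_mcph_level if genome_mcph_level > 0 else genome_mcph_level + LEVEL_GUARD
    out = []
    for iv in dmrs:
        rm = region_methylation(table, calls, iv)
        if rm.mcph_level is None:
            out.append(DmrRecord(iv, None, None, "neither", rm.n_cph, rm.n_mcph))
            continue
        fc = rm.mcph_level / denom
        klass = "hyper" if fc > 2.0 else ("hypo" if fc < 0.5 else "neither")
        out.append(DmrRecord(iv, rm.mcph_level, fc, klass, rm.n_cph, rm.n_mcph))
    return out


def log_fold_change(mcph_level: float, genome_mcph_level: float) -> float:
    """Display log2 fold change with the +0.0001 guard against log 0."""
    return math.log2((mcph_level + LEVEL_GUARD) / (genome_mcph_level + LEVEL_GUARD))


def _sorted_by_chrom(
    intervals: list[GenomicInterval],
) -> dict[str, list[GenomicInterval]]:
    by: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by.items():
        if any(ivs[i].start > ivs[i + 1].start for i in range(len(ivs) - 1)):
            logger.info("intersect_intervals: sorting unsorted input on %s", chrom)
        ivs.sort(key=lambda iv: (iv.start, iv.end))
    return by


def intersect_intervals(
    set_a: list[GenomicInterval], set_b: list[GenomicInterval]
) -> list[tuple[GenomicInterval, GenomicInterval, GenomicInterval]]:
    """All overlapping (a, b) pairs with their half-open overlap interval.

    Sweep over both sets sorted by start per chromosome; an active window of
    b-intervals is pruned as the a-sweep advances, so the cost is
    near-linear in the input plus output size.
    """
    by_a = _sorted_by_chrom(set_a)
    by_b = _sorted_by_chrom(set_b)
    out = []
    for chrom in sorted(set(by_a) & set(by_b)):
        a_list = by_a[chrom]
        b_list = by_b[chrom]
        active: list[GenomicInterval] = []
        j = 0
        for a in a_list:
            while j < len(b_list) and b_list[j].start < a.end:
                active.append(b_list[j])
                j += 1
            active = [b for b in active if b.end > a.start]
            for b in active:
                lo = max(a.start, b.start)
                hi = min(a.end, b.end)
                if lo < hi:
                    out.append((a, b, GenomicInterval(chrom, lo, hi)))
    return out


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping or touching intervals collapsed."""
    out: list[GenomicInterval] = []
    by = _sorted_by_chrom(intervals)
    for chrom in sorted(by):
        cur_start = cur_end = None
        for iv in by[chrom]:
            if cur_end is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_end is not None:
            out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def total_bp(intervals: list[GenomicInterval]) -> int:
    """Total merged (non-double-counted) base pairs."""
    return sum(len(iv) for iv in merge_intervals(intervals))


def overlap_fraction_table(
    dmrs: list[GenomicInterval],
    annotations: dict[str, list[GenomicInterval]],
    genome_size: int,
) -> list[OverlapRow]:
    """Fraction of each annotation (and of the whole genome) covered by DMRs.

    Base-pair arithmetic on merged intervals, so overlapping DMRs are never
    double counted.  The first row is the whole-genome fraction
    (total DMR bp / genome size).
    """
    dmrs_merged = merge_intervals(dmrs)
    dmr_bp = total_bp(dmrs_merged)
    rows = [OverlapRow(
        "whole_genome", dmr_bp,
        dmr_bp / genome_size if genome_size else None,
        1.0 if dmr_bp else None,
    )]
    for name, annot in annotations.items():
        annot_merged = merge_intervals(annot)
        annot_bp = total_bp(annot_merged)
        ov_bp = sum(
            len(ov) for _, _, ov in intersect_intervals(annot_merged, dmrs_merged)
        )
        rows.append(OverlapRow(
            name,
            ov_bp,
            ov_bp / annot_bp if annot_bp else None,
            ov_bp / dmr_bp if dmr_bp else None,
        ))
    return rows


def motif_methylation_summary(
    dmrs: list[GenomicInterval],
    table: MethylomeTable,
    calls: pd.DataFrame,
) -> dict[str, tuple[int, int]]:
    """Per-trinucleotide-motif (methylated, total) CpH counts inside DMRs."""
    if not dmrs:
        return {}
    merged = merge_intervals(dmrs)
    cph = calls[calls["context"] == CPH]
    mask = np.zeros(len(cph), dtype=bool)
    pos = cph["pos"].to_numpy()
    chrom = cph["chrom"].to_numpy()
    for iv in merged:
        mask |= (chrom == iv.chrom) & (pos >= iv.start) & (pos < iv.end)
    sub = cph[mask]
    out: dict[str, tuple[int, int]] = {}
    for motif, grp in sub.groupby("motif", sort=True):
        if not motif:
            continue
        out[str(motif)] = (int(grp["methylated"].sum()), len(grp))
    return out


def proximity_profile(
    table: MethylomeTable,
    calls: pd.DataFrame,
    center_kind: str = "mcpg",
    flank: int = 1000,
    window: int = 50,
    unmethylated_me_max: float = 0.05,
) -> ProximityProfile:
    """CpH methylation level around (un)methylated CpG centers.

    Centers are CpG sites on either strand: methylated calls
    (``center_kind='mcpg'``) or nearly unmethylated ones
    (``'unmcpg'``, Me < 0.05).  Only CpH sites on the *same strand* as the
    center contribute, at their offset in the center strand's 5'->3'
    direction (minus-strand centers are mirrored).  Per offset, the value is
    the mean CpH Me over a centered 50-bp window (offsets within
    [d - window//2, d + window//2)).
    """
    if center_kind not in ("mcpg", "unmcpg"):
        raise ValueError("center_kind must be 'mcpg' or 'unmcpg'")
    cpg = calls[calls["context"] == CPG]
    if center_kind == "mcpg":
        centers = cpg[cpg["methylated"]]
    else:
        centers = cpg[cpg["me"] < unmethylated_me_max]
    if centers.empty:
        raise ValueError(f"no {center_kind} centers found")
    cph = calls[calls["context"] == CPH]

    offsets = np.arange(-flank, flank + 1)
    sums = np.zeros(2 * flank + 1)
    counts = np.zeros(2 * flank + 1, dtype=np.int64)
    for (chrom, strand), cgrp in centers.groupby(["chrom", "strand"], sort=True):
        sgrp = cph[(cph["chrom"] == chrom) & (cph["strand"] == strand)]
        if sgrp.empty:
            continue
        spos = sgrp["pos"].to_numpy()
        sme = sgrp["me"].to_numpy()
        order = np.argsort(spos, kind="mergesort")
        spos, sme = spos[order], sme[order]
        sign = 1 if strand == "+" else -1
        for cpos in cgrp["pos"].to_numpy():
            lo = np.searchsorted(spos, cpos - flank, side="left")
            hi = np.searchsorted(spos, cpos + flank, side="right")
            rel = (spos[lo:hi] - cpos) * sign
            idx = rel + flank
            np.add.at(sums, idx, sme[lo:hi])
            np.add.at(counts, idx, 1)

    half = window // 2
    win_s = np.array([
        sums[max(i - half, 0) : i + half].sum() for i in range(2 * flank + 1)
    ])
    win_c = np.array([
        counts[max(i - half, 0) : i + half].sum() for i in range(2 * flank + 1)
    ])
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(win_c > 0, win_s / np.where(win_c > 0, win_c, 1), np.nan)
    return ProximityProfile(offsets, values, n_centers=len(centers))
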