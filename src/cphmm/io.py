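"""Read, merge, filter and write per-cytosine methylation count data.

All genomic coordinates are 0-based, half-open internally; conversion to and
from 1-based happens only at file boundaries (the Bismark CX dialect is
1-based on disk).  CpG sites on the two strands are kept as distinct records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CPG = "CpG"
CPH = "CpH"

#: chromosomes dropped by default to avoid sex-linked methylation bias
DEFAULT_EXCLUDE_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})

_CONTEXT_MAP = {"CG": CPG, "CHG": CPH, "CHH": CPH, CPG: CPG, CPH: CPH}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SITE_KEY = ["chrom", "pos", "strand"]
SITE_COLUMNS = ["chrom", "pos", "strand", "context", "motif"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MethylomeIOError(ValueError):
    """Malformed input file or inconsistent methylome data."""


@dataclass
class SampleMeta:
    """Sample-level metadata.

    ``nonconversion_rate`` (R) is the fraction of truly unmethylated
    cytosines that escape bisulfite conversion, typically estimated from
    spiked-in unmethylated lambda DNA; it acts as the error rate of the
    methylation signal.
    """

    sample_id: str
    nonconversion_rate: float = 0.0
    mapper_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonconversion_rate < 1.0:
            raise ValueError(
                f"nonconversion_rate must be in [0, 1), got {self.nonconversion_rate}"
            )


@dataclass(frozen=True)
class CytosineSiteRecord:
    """One cytosine with per-mapper methylated/total read counts.

    ``pos`` is the 0-based position of the cytosine on the forward strand of
    the reference; ``motif`` is the trinucleotide read 5'->3' on the
    cytosine's own strand, so it always starts with ``C``.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    motif: str
    counts: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.context not in (CPG, CPH):
            raise ValueError(f"context must be CpG or CpH, got {self.context!r}")
        if self.motif and not self.motif.upper().startswith("C"):
            raise ValueError(f"motif must start with C, got {self.motif!r}")
        for m, n in self.counts:
            if not 0 <= m <= n:
                raise ValueError(f"require 0 <= m <= n, got (m={m}, n={n})")

    @property
    def m(self) -> int:
        """Pooled methylated reads across mappers."""
        return sum(m for m, _ in self.counts)

    @property
    def n(self) -> int:
        """Pooled total reads across mappers."""
        return sum(n for _, n in self.counts)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


class MethylomeTable:
    """Per-cytosine count table for one sample.

    Wraps a :class:`pandas.DataFrame` with one row per (chrom, pos, strand)
    and columns ``chrom, pos, strand, context, motif`` plus one
    ``m__<mapper>``/``n__<mapper>`` pair per read mapper and pooled ``m``,
    ``n`` columns (sums over mappers that cover the site).
    """

    def __init__(self, df: pd.DataFrame, meta: SampleMeta):
        df = df.copy()
        for col in SITE_COLUMNS:
            if col not in df.columns:
                if col == "motif":
                    df["motif"] = ""
                else:
                    raise MethylomeIOError(f"missing column {col!r}")
        if not meta.mapper_ids:
            meta = SampleMeta(meta.sample_id, meta.nonconversion_rate, ["0"])
        for mid in meta.mapper_ids:
            for pre in ("m", "n"):
                col = f"{pre}__{mid}"
                if col not in df.columns:
                    raise MethylomeIOError(f"missing per-mapper column {col!r}")
        df = df.sort_values(SITE_KEY, kind="mergesort").reset_index(drop=True)
        if df.duplicated(SITE_KEY).any():
            raise MethylomeIOError("duplicate (chrom, pos, strand) keys")
        mcols = [f"m__{mid}" for mid in meta.mapper_ids]
        ncols = [f"n__{mid}" for mid in meta.mapper_ids]
        m = df[mcols].sum(axis=1, skipna=True)
        n = df[ncols].sum(axis=1, skipna=True)
        bad = (df[mcols].to_numpy(dtype=float) > df[ncols].to_numpy(dtype=float))
        if np.nansum(bad) > 0:
            raise MethylomeIOError("methylated count exceeds total count")
        df["m"] = m.astype(np.int64)
        df["n"] = n.astype(np.int64)
        self.df = df
        self.meta = meta

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylomeTable):
            return NotImplemented
        cols = SITE_COLUMNS + ["m", "n"]
        return (
            self.meta.sample_id == other.meta.sample_id
            and self.df[cols].reset_index(drop=True).equals(
                other.df[cols].reset_index(drop=True)
            )
        )

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def counts_at(self, chrom: str, pos: int, strand: str) -> tuple[tuple[int, int], ...]:
        """Per-mapper (m, n) pairs at one site, skipping non-covering mappers."""
        row = self.df[
            (self.df["chrom"] == chrom)
            & (self.df["pos"] == pos)
            & (self.df["strand"] == strand)
        ]
        if row.empty:
            raise KeyError((chrom, pos, strand))
        row = row.iloc[0]
        out = []
        for mid in self.meta.mapper_ids:
            n = row[f"n__{mid}"]
            if pd.notna(n):
                out.append((int(row[f"m__{mid}"]), int(n)))
        return tuple(out)

    def records(self) -> Iterator[CytosineSiteRecord]:
        """Iterate sites as :class:`CytosineSiteRecord` (small tables only)."""
        for row in self.df.itertuples(index=False):
            counts = []
            for mid in self.meta.mapper_ids:
                n = getattr(row, f"n__{mid}")
                if pd.notna(n):
                    counts.append((int(getattr(row, f"m__{mid}")), int(n)))
            yield CytosineSiteRecord(
                row.chrom, int(row.pos), row.strand, row.context, row.motif,
                tuple(counts),
            )

    def subset(self, mask: np.ndarray) -> "MethylomeTable":
        return MethylomeTable(self.df[mask].reset_index(drop=True), self.meta)


def table_from_arrays(
    chrom: np.ndarray | Sequence[str],
    pos: np.ndarray,
    strand: np.ndarray | Sequence[str],
    context: np.ndarray | Sequence[str],
    m: np.ndarray,
    n: np.ndarray,
    meta: SampleMeta,
    motif: np.ndarray | Sequence[str] | None = None,
) -> MethylomeTable:
    """Build a single-mapper table from parallel arrays (simulator backend)."""
    if not meta.mapper_ids:
        meta = SampleMeta(meta.sample_id, meta.nonconversion_rate, ["0"])
    if len(meta.mapper_ids) != 1:
        raise ValueError("table_from_arrays builds single-mapper tables")
    mid = meta.mapper_ids[0]
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(pos, dtype=np.int64),
            "strand": strand,
            "context": context,
            "motif": motif if motif is not None else "",
            f"m__{mid}": np.asarray(m, dtype=np.int64),
            f"n__{mid}": np.asarray(n, dtype=np.int64),
        }
    )
    return MethylomeTable(df, meta)


def read_cytosine_report(
    path: str | Path,
    dialect: str = "bismark_cx",
    sample_id: str | None = None,
    nonconversion_rate: float = 0.0,
    mapper_id: str | None = None,
) -> MethylomeTable:
    """Read one per-cytosine count report.

    ``bismark_cx`` is the Bismark cytosine/CX report (no header, tab-separated
    ``chrom, 1-based pos, strand, count-methylated, count-unmethylated,
    context, trinucleotide``); positions are converted to 0-based on read.
    ``generic_tsv`` is this package's own headered TSV with 0-based positions.
    """
    path = Path(path)
    if dialect not in ("bismark_cx", "generic_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sample_id = sample_id or path.stem
    mapper_id = mapper_id or "0"
    meta = SampleMeta(sample_id, nonconversion_rate, [mapper_id])

    rows: list[tuple] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if dialect == "generic_tsv":
        if lines and lines[0].startswith("chrom"):
            start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        try:
            if dialect == "bismark_cx":
                chrom, pos1, strand, cm, cu, ctx, motif = parts[:7]
                pos = int(pos1) - 1
                m = int(cm)
                n = m + int(cu)
                context = _CONTEXT_MAP[ctx]
            else:
                chrom, pos0, strand, context, motif, cm, cn = parts[:7]
                pos = int(pos0)
                m = int(cm)
                n = int(cn)
                context = _CONTEXT_MAP[context]
        except (ValueError, KeyError, IndexError) as exc:
            raise MethylomeIOError(
                f"{path}:{lineno}: malformed {dialect} line: {line!r}"
            ) from exc
        if pos < 0:
            raise MethylomeIOError(f"{path}:{lineno}: negative position")
        if m > n:
            raise MethylomeIOError(
                f"{path}:{lineno}: methylated count {m} exceeds total {n}"
            )
        rows.append((chrom, pos, strand, context, motif, m, n))

    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "context", "motif",
                 f"m__{mapper_id}", f"n__{mapper_id}"],
    )
    if df.empty:
        df = df.astype({"pos": np.int64, f"m__{mapper_id}": np.int64,
                        f"n__{mapper_id}": np.int64})
    return MethylomeTable(df, meta)


def write_methylome(table: MethylomeTable, path: str | Path) -> None:
    """Write the generic TSV dialect (pooled counts, 0-based positions)."""
    cols = SITE_COLUMNS + ["m", "n"]
    out = table.df[cols].copy()
    out = out[["chrom", "pos", "strand", "context", "motif", "m", "n"]]
    out.to_csv(path, sep="\t", index=False)


def merge_mapper_reports(
    tables: Sequence[MethylomeTable],
    min_reads: int = 5,
    min_mappers: int = 2,
) -> MethylomeTable:
    """Keep sites covered by more than ``min_reads`` reads in at least
    ``min_mappers`` of the per-mapper tables (strict ``n > min_reads``).

    Counts from every mapper covering a retained site are kept, in mapper
    order; pooled ``m``/``n`` sum over all of them.
    """
    if not tables:
        raise ValueError("no tables to merge")
    sample_ids = {t.meta.sample_id for t in tables}
    if len(sample_ids) != 1:
        raise MethylomeIOError(f"tables mix sample_ids: {sorted(sample_ids)}")
    mapper_ids: list[str] = []
    for i, t in enumerate(tables):
        if len(t.meta.mapper_ids) != 1:
            raise MethylomeIOError("each input table must be single-mapper")
        mid = t.meta.mapper_ids[0]
        if mid in mapper_ids:
            mid = f"{mid}.{i}"
        mapper_ids.append(mid)

    frames = []
    for t, mid in zip(tables, mapper_ids):
        f = t.df[SITE_COLUMNS + ["m", "n"]].rename(
            columns={"m": f"m__{mid}", "n": f"n__{mid}"}
        )
        frames.append(f.set_index(SITE_KEY))
    merged = frames[0]
    for f in frames[1:]:
        merged = merged.join(f, how="outer", rsuffix="__dup")
        for col in ("context", "motif"):
            dup = f"{col}__dup"
            if dup in merged.columns:
                both = merged[col].notna() & merged[dup].notna()
                if (merged.loc[both, col] != merged.loc[both, dup]).any():
                    raise MethylomeIOError(
                        f"inconsistent {col} across mapper tables at shared sites"
                    )
                merged[col] = merged[col].fillna(merged[dup])
                merged = merged.drop(columns=[dup])

    ncols = [f"n__{mid}" for mid in mapper_ids]
    support = (merged[ncols] > min_reads).sum(axis=1)
    kept = merged[support >= min_mappers].reset_index()
    n_dropped = len(merged) - len(kept)
    logger.info(
        "merge_mapper_reports: kept %d sites, dropped %d (need n>%d in >=%d mappers)",
        len(kept), n_dropped, min_reads, min_mappers,
    )
    meta0 = tables[0].meta
    meta = SampleMeta(meta0.sample_id, meta0.nonconversion_rate, mapper_ids)
    # fill m where n present but m missing cannot happen; keep NaN for absent mappers
    return MethylomeTable(kept, meta)


def annotate_context(table: MethylomeTable, genome_fasta: str | Path) -> MethylomeTable:
    """Recompute context and motif from the reference sequence.

    Minus-strand motifs are reverse-complemented so the motif is always read
    5'->3' on the cytosine's own strand.  Sites whose reference base is not a
    cytosine on their strand, or whose following base is ambiguous (N), are
    dropped and counted.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    df = table.df
    missing = set(df["chrom"].unique()) - set(fasta.keys())
    if missing:
        raise MethylomeIOError(f"chromosomes absent from FASTA: {sorted(missing)}")

    keep = np.ones(len(df), dtype=bool)
    contexts = np.empty(len(df), dtype=object)
    motifs = np.empty(len(df), dtype=object)
    n_not_c = 0
    n_ambig = 0
    for i, (chrom, pos, strand) in enumerate(
        zip(df["chrom"], df["pos"], df["strand"])
    ):
        chrom_len = len(fasta[chrom])
        if pos >= chrom_len:
            raise MethylomeIOError(
                f"position {pos} beyond end of {chrom} (length {chrom_len})"
            )
        if strand == "+":
            tri = fasta[chrom][pos : min(pos + 3, chrom_len)]
        else:
            tri = reverse_complement(fasta[chrom][max(pos - 2, 0) : pos + 1])
        if not tri or tri[0] != "C":
            n_not_c += 1
            keep[i] = False
            continue
        if len(tri) < 2 or tri[1] == "N":
            n_ambig += 1
            keep[i] = False
            continue
        contexts[i] = CPG if tri[1] == "G" else CPH
        motifs[i] = tri if len(tri) == 3 and "N" not in tri else ""
    if n_not_c:
        logger.warning("annotate_context: dropped %d sites with non-C reference base",
                       n_not_c)
    if n_ambig:
        logger.warning("annotate_context: dropped %d sites with ambiguous context",
                       n_ambig)
    out = df.copy()
    out["context"] = contexts
    out["motif"] = motifs
    out = out[keep].reset_index(drop=True)
    return MethylomeTable(out, table.meta)


def filter_chromosomes(
    table: MethylomeTable,
    exclude: Iterable[str] = DEFAULT_EXCLUDE_CHROMS,
) -> MethylomeTable:
    """Drop all sites on the excluded chromosomes (sex chromosomes by default)."""
    exclude = set(exclude)
    mask = ~table.df["chrom"].isin(exclude)
    n_removed = int((~mask).sum())
    if n_removed:
        logger.info("filter_chromosomes: removed %d sites on %s",
                    n_removed, sorted(exclude & set(table.chroms)))
    if not mask.any():
        logger.warning("filter_chromosomes: no sites remain")
    return table.subset(mask.to_numpy())


# ---------------------------------------------------------------------------
# interval / track output


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except (ValueError, IndexError) as exc:
                raise MethylomeIOError(f"{path}:{lineno}: malformed BED line") from exc
            name = parts[3] if len(parts) > 3 else None
            strand = parts[5] if len(parts) > 5 else None
            out.append(GenomicInterval(chrom, start, end, name, strand))
    return out


def write_tracks(objects: Iterable, path: str | Path, format: str = "bed") -> None:
    """Write intervals/scored intervals as BED, bedGraph or TSV.

    BED output is 0-based half-open.  ``objects`` may be
    :class:`GenomicInterval` items, ``(interval, value)`` pairs (bedGraph) or
    a DataFrame with chrom/start/end leading columns (tsv).
    """
    if format not in ("bed", "bedgraph", "tsv"):
        raise ValueError(f"unknown track format {format!r}")
    with open(path, "w") as fh:
        if format == "tsv":
            df = objects if isinstance(objects, pd.DataFrame) else pd.DataFrame(objects)
            df.to_csv(fh, sep="\t", index=False)
            return
        if format == "bedgraph":
            fh.write('track type=bedGraph\n')
            for iv, value in objects:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:.6g}\n")
            return
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for iv in objects:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.strand is not None:
                fields += [".", iv.strand]
            fh.write("\t".join(fields) + "\n")
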