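"""Core genomic coordinate types, interval algebra, and on-disk formats.

Everything downstream (enhancer stitching, gene assignment, occupancy
metrics) operates on the small set of containers defined here:

* :class:`GenomicInterval` -- 0-based half-open span (BED convention).
* :class:`SignalPeak` -- interval plus per-replicate normalized signal (RPM).
* :class:`GeneModel` -- gene body, strand-aware TSS, identity-gene flag and
  per-condition expression (FPKM/RPKM).
* :class:`CoverageTrack` -- per-chromosome binned read depth.

Any 1-based input dialect must be converted at the reader boundary; all
internal coordinates are 0-based half-open.  Strand is carried but ignored by
the interval algebra; only gene assignment and motif scanning are
strand-aware.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "SignalPeak",
    "GeneModel",
    "CoverageTrack",
    "merge_overlapping",
    "intersect_any",
    "overlap_bp",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
]

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open chromosomal span ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SignalPeak:
    """A peak interval with per-replicate normalized read signal (RPM)."""

    interval: GenomicInterval
    signal_by_replicate: tuple[float, ...] = (0.0,)
    source_mark: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.signal_by_replicate) < 1:
            raise ValueError(f"peak {self.name or self.interval} has no replicates")
        if any(s < 0 for s in self.signal_by_replicate):
            raise ValueError(
                f"peak {self.name or self.interval} has negative signal"
            )
        object.__setattr__(
            self, "signal_by_replicate", tuple(float(s) for s in self.signal_by_replicate)
        )

    @property
    def mean_signal(self) -> float:
        return float(np.mean(self.signal_by_replicate))

    @property
    def n_replicates(self) -> int:
        return len(self.signal_by_replicate)


@dataclass(frozen=True)
class GeneModel:
    """A gene with a single canonical TSS and per-condition expression."""

    gene_id: str
    interval: GenomicInterval
    tss: int
    is_id_gene: bool = False
    expression: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.tss <= self.interval.end):
            raise ValueError(
                f"gene {self.gene_id}: TSS {self.tss} outside gene body "
                f"{self.interval.start}-{self.interval.end}"
            )
        if any(v < 0 for v in self.expression.values()):
            raise ValueError(f"gene {self.gene_id}: negative expression value")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class CoverageTrack:
    """Binned read-depth vectors over a fixed chromosome-size table."""

    def __init__(
        self,
        chrom_sizes: Mapping[str, int],
        bin_size: int = 1,
        data: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.chrom_sizes = dict(chrom_sizes)
        self.bin_size = int(bin_size)
        self.data: dict[str, np.ndarray] = {}
        for chrom, size in self.chrom_sizes.items():
            n_bins = -(-size // bin_size)
            if data is not None and chrom in data:
                vec = np.asarray(data[chrom], dtype=float)
                if len(vec) != n_bins:
                    raise ValueError(
                        f"{chrom}: expected {n_bins} bins of {bin_size} bp, got {len(vec)}"
                    )
                if np.any(vec < 0):
                    raise ValueError(f"{chrom}: negative depth values")
                self.data[chrom] = vec.copy()
            else:
                self.data[chrom] = np.zeros(n_bins, dtype=float)

    def add_interval(self, interval: GenomicInterval, depth: float) -> None:
        """Add ``depth`` to every bin overlapped by ``interval``."""
        vec = self.data[interval.chrom]
        lo = interval.start // self.bin_size
        hi = -(-interval.end // self.bin_size)
        vec[lo:hi] += depth

    def value_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Depth at base positions (nan outside the chromosome)."""
        vec = self.data[chrom]
        positions = np.asarray(positions)
        out = np.full(positions.shape, np.nan)
        ok = (positions >= 0) & (positions < self.chrom_sizes[chrom])
        out[ok] = vec[positions[ok] // self.bin_size]
        return out

    def rebin(self, new_bin: int) -> "CoverageTrack":
        """Re-bin to a coarser grid; bin values are base-weighted sums."""
        if new_bin % self.bin_size != 0:
            raise ValueError("new bin size must be a multiple of the current one")
        factor = new_bin // self.bin_size
        out = CoverageTrack(self.chrom_sizes, bin_size=new_bin)
        for chrom, vec in self.data.items():
            n_new = len(out.data[chrom])
            padded = np.zeros(n_new * factor)
            padded[: len(vec)] = vec
            out.data[chrom] = padded.reshape(n_new, factor).sum(axis=1)
        return out

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in sorted(self.data)])


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def _as_interval(x) -> GenomicInterval:
    return x if isinstance(x, GenomicInterval) else x.interval


def merge_overlapping(intervals: Iterable) -> list[GenomicInterval]:
    """Union-preserving merge of overlapping or bookended intervals.

    Output is sorted and pairwise disjoint; strand is dropped (set to ``.``).
    """
    ivs = sorted(
        (iv.chrom, iv.start, iv.end) for iv in map(_as_interval, intervals)
    )
    merged: list[GenomicInterval] = []
    for chrom, start, end in ivs:
        if merged and merged[-1].chrom == chrom and start <= merged[-1].end:
            last = merged[-1]
            if end > last.end:
                merged[-1] = GenomicInterval(chrom, last.start, end)
        else:
            merged.append(GenomicInterval(chrom, start, end))
    return merged


class _OverlapIndex:
    """Query structure: does an interval overlap any member of a set?"""

    def __init__(self, intervals: Iterable) -> None:
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for iv in merge_overlapping(intervals):
            starts, ends = self._by_chrom.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    def overlaps(self, iv: GenomicInterval) -> bool:
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, ends = entry
        # rightmost merged interval starting strictly before iv.end
        idx = bisect_right(starts, iv.end - 1)
        return idx > 0 and ends[idx - 1] > iv.start


def intersect_any(a: Sequence, b: Iterable) -> list:
    """Members of ``a`` that overlap >= 1 bp with any member of ``b``.

    Whole a-records are reported (``bedtools intersect -u`` semantics): the
    overlapped regions are downstream inputs, not fragments.
    """
    index = _OverlapIndex(b)
    return [x for x in a if index.overlaps(_as_interval(x))]


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


# ---------------------------------------------------------------------------
# BED / bedGraph / TSV / FASTA readers and writers
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return format(float(x), ".6g")


def read_bed(path, source_mark: str = "") -> list[SignalPeak]:
    """Read BED3+ peaks: chrom, start, end[, name[, signal per replicate...]].

    Tab-separated; raises ``ValueError`` with the line number on malformed
    records.
    """
    peaks: list[SignalPeak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinates {fields[1]!r}/{fields[2]!r}"
                ) from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            name = fields[3] if len(fields) > 3 else ""
            try:
                signal = tuple(float(v) for v in fields[4:]) or (0.0,)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric signal column") from exc
            peaks.append(
                SignalPeak(
                    GenomicInterval(fields[0], start, end),
                    signal_by_replicate=signal,
                    source_mark=source_mark,
                    name=name,
                )
            )
    return peaks


def write_bed(peaks: Iterable[SignalPeak], path) -> None:
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            iv = pk.interval
            name = pk.name or f"peak_{i + 1}"
            cols = [iv.chrom, str(iv.start), str(iv.end), name]
            cols.extend(_fmt(s) for s in pk.signal_by_replicate)
            fh.write("\t".join(cols) + "\n")


GENE_TABLE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss", "is_id_gene"]


def read_gene_table(path) -> list[GeneModel]:
    """Read the TSV gene-model table.

    Columns: gene_id, chrom, start, end, strand, tss, is_id_gene, then one
    ``expr_<condition>`` column per expression condition.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing gene-table columns {missing}")
    expr_cols = [c for c in df.columns if c.startswith("expr_")]
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                interval=GenomicInterval(
                    str(row.chrom), int(row.start), int(row.end), str(row.strand)
                ),
                tss=int(row.tss),
                is_id_gene=bool(row.is_id_gene),
                expression={
                    c[len("expr_"):]: float(getattr(row, c)) for c in expr_cols
                },
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    conditions = sorted({c for g in genes for c in g.expression})
    rows = []
    for g in genes:
        row = {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "strand": g.strand,
            "tss": g.tss,
            "is_id_gene": int(g.is_id_gene),
        }
        for c in conditions:
            row[f"expr_{c}"] = _fmt(g.expression.get(c, 0.0))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write non-zero bins as bedGraph records (sorted, run-length merged)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            vec = track.data[chrom]
            size = track.chrom_sizes[chrom]
            bs = track.bin_size
            i = 0
            n = len(vec)
            while i < n:
                j = i
                while j < n and vec[j] == vec[i]:
                    j += 1
                if vec[i] != 0:
                    fh.write(
                        f"{chrom}\t{i * bs}\t{min(j * bs, size)}\t{_fmt(vec[i])}\n"
                    )
                i = j


def read_bedgraph(path, chrom_sizes: Mapping[str, int], bin_size: int = 1) -> CoverageTrack:
    """Read a bedGraph into a binned track (base-weighted mean per bin)."""
    track = CoverageTrack(chrom_sizes, bin_size=bin_size)
    weights = {c: np.zeros(len(v)) for c, v in track.data.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in track.data:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            vec, wt = track.data[chrom], weights[chrom]
            lo_bin, hi_bin = start // bin_size, -(-end // bin_size)
            for b in range(lo_bin, hi_bin):
                ov = min(end, (b + 1) * bin_size) - max(start, b * bin_size)
                vec[b] += value * ov
                wt[b] += ov
    for chrom, vec in track.data.items():
        wt = weights[chrom]
        nz = wt > 0
        vec[nz] /= wt[nz]
    return track


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a plain chrom -> sequence dict (upper-cased)."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}
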