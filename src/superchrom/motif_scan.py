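"""PWM motif scanning with exact null p-values, plus IUPAC consensus counting.

Scoring follows the FIMO convention: a window ``w`` of length equal to the
motif width receives the log-odds score ``sum_j log2(p_j(w_j) / bg(w_j))``
in bits, and its p-value is the probability of an equal or greater score
for an i.i.d. background sequence.  That null distribution is computed
exactly by dynamic-programming convolution of the per-position score
distributions after discretizing scores to a fixed granularity (1/1000 bit
by default), so p-values are correct to within one discretization step.

Both strands are scanned; windows containing ``N`` are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .genome_model import GenomicInterval, _as_interval, intersect_any

__all__ = [
    "PositionWeightMatrix",
    "MotifHit",
    "ScoreDistribution",
    "scan_pwm",
    "count_consensus",
    "motifs_per_gene",
    "load_bundled_motif",
    "read_meme_motifs",
    "write_meme_motif",
    "reverse_complement",
    "IUPAC_CODES",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass(frozen=True)
class PositionWeightMatrix:
    """A probability matrix over {A, C, G, T} with background and pseudocount.

    ``probabilities`` has shape (width, 4).  Scoring uses the regularized
    matrix ``(p + pseudocount * background) / (1 + pseudocount)`` so no cell
    is exactly zero (pseudocount mass distributed by background frequency).
    """

    name: str
    probabilities: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("PWM probabilities must have shape (width, 4)")
        if np.any(probs < 0) or not np.allclose(probs.sum(axis=1), 1.0, atol=1e-3):
            raise ValueError("each PWM position must be a probability distribution")
        if bg.shape != (4,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be a strictly positive distribution over ACGT")
        object.__setattr__(self, "probabilities", probs)
        object.__setattr__(self, "background", bg / bg.sum())

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    @property
    def regularized(self) -> np.ndarray:
        return (self.probabilities + self.pseudocount * self.background) / (
            1.0 + self.pseudocount
        )

    @property
    def log_odds(self) -> np.ndarray:
        """Per-position log2 odds (bits) against the background."""
        return np.log2(self.regularized / self.background)

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            name=self.name,
            probabilities=self.probabilities[::-1, ::-1].copy(),
            background=self.background,
            pseudocount=self.pseudocount,
        )

    def score_distribution(self, granularity: float = 0.001) -> "ScoreDistribution":
        return ScoreDistribution(self, granularity)


class ScoreDistribution:
    """Exact null distribution of PWM log-odds scores under i.i.d. background.

    Scores are discretized to integer multiples of ``granularity`` bits and
    the full pmf is built by convolving the four-point distributions of the
    motif positions.  ``p_value(score)`` is the exact discretized tail
    probability P(S >= score).
    """

    def __init__(self, pwm: PositionWeightMatrix, granularity: float = 0.001) -> None:
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        self.granularity = granularity
        int_scores = np.rint(pwm.log_odds / granularity).astype(np.int64)
        self._int_scores = int_scores
        offset = 0
        pmf = np.ones(1)
        bg = pwm.background
        for j in range(pwm.width):
            row = int_scores[j]
            lo, hi = int(row.min()), int(row.max())
            new = np.zeros(len(pmf) + (hi - lo))
            for b in range(4):
                shift = int(row[b]) - lo
                new[shift : shift + len(pmf)] += pmf * bg[b]
            pmf = new
            offset += lo
        self._offset = offset  # integer score of pmf[0]
        # survival[i] = P(S >= offset + i)
        self._survival = np.cumsum(pmf[::-1])[::-1]

    def int_score(self, log_odds_row_sum: float) -> int:
        return int(np.rint(log_odds_row_sum / self.granularity))

    def p_value(self, score_bits: float) -> float:
        """Exact tail probability for a (continuous) bit score."""
        return self.p_value_int(self.int_score(score_bits))

    def p_value_int(self, int_score: int) -> float:
        idx = int_score - self._offset
        if idx < 0:
            return 1.0
        if idx >= len(self._survival):
            return 0.0
        return float(min(self._survival[idx], 1.0))

    def score_threshold(self, p_threshold: float) -> int:
        """Smallest integer score whose tail probability is <= p_threshold."""
        idx = np.searchsorted(-self._survival, -p_threshold, side="left")
        return int(idx + self._offset)


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    score: float  # bits
    p_value: float

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")

    @property
    def strand(self) -> str:
        return self.interval.strand


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    codes = np.full(len(seq), -1, dtype=np.int8)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    unknown = (codes == -1) & (arr != ord("N"))
    if np.any(unknown):
        bad = seq[int(np.nonzero(unknown)[0][0])]
        raise ValueError(f"invalid sequence character {bad!r} (alphabet is ACGTN)")
    return codes


def _window_scores(codes: np.ndarray, int_lod: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer window scores and a validity mask (no N in window)."""
    w = int_lod.shape[0]
    n_win = len(codes) - w + 1
    scores = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    safe = np.where(codes >= 0, codes, 0)
    for j in range(w):
        col = safe[j : j + n_win]
        scores += int_lod[j][col]
        valid &= codes[j : j + n_win] >= 0
    return scores, valid


def scan_pwm(
    sequence: str,
    pwm: PositionWeightMatrix,
    p_threshold: float = 1e-4,
    chrom: str = "seq",
    offset: int = 0,
    distribution: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """Scan both strands for motif occurrences with exact p <= threshold.

    Hit coordinates are given on the forward strand (``offset`` shifts them
    into chromosome space); a minus-strand hit at ``[s, e)`` means the
    reverse complement of that window matches.  Hits are sorted by position,
    forward strand first at equal positions.
    """
    w = pwm.width
    if w > len(sequence):
        return []
    dist = distribution or pwm.score_distribution()
    codes = _encode(sequence)
    int_lod = np.rint(pwm.log_odds / dist.granularity).astype(np.int64)
    int_lod_rc = int_lod[::-1, ::-1]

    hits: list[MotifHit] = []
    for strand, lod in (("+", int_lod), ("-", int_lod_rc)):
        scores, valid = _window_scores(codes, lod)
        for i in np.nonzero(valid)[0]:
            p = dist.p_value_int(int(scores[i]))
            if p <= p_threshold:
                hits.append(
                    MotifHit(
                        interval=GenomicInterval(
                            chrom, offset + int(i), offset + int(i) + w, strand
                        ),
                        score=float(scores[i]) * dist.granularity,
                        p_value=p,
                    )
                )
    hits.sort(key=lambda h: (h.interval.start, h.interval.strand))
    return hits


def count_consensus(sequence: str, iupac_pattern: str) -> int:
    """Count (possibly overlapping) IUPAC consensus matches on both strands.

    A palindromic window matching both strands counts twice, mirroring
    two independent strand scans.
    """
    pattern = iupac_pattern.upper()
    bad = [c for c in pattern if c not in IUPAC_CODES]
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {bad!r}")
    total = 0
    for strand_seq in (sequence.upper(), reverse_complement(sequence.upper())):
        n = len(strand_seq) - len(pattern) + 1
        for i in range(max(n, 0)):
            if all(strand_seq[i + j] in IUPAC_CODES[c] for j, c in enumerate(pattern)):
                total += 1
    return total


def motifs_per_gene(
    assignments: Mapping[str, Sequence],
    accessible_regions: Sequence,
    sequences: Mapping[str, str],
    pwm: PositionWeightMatrix,
    p_threshold: float = 1e-4,
    by_class: bool = True,
) -> dict:
    """Per-gene motif counts within accessible enhancer regions.

    For each gene, the accessible regions (e.g. ATAC peaks) overlapping its
    assigned enhancers are selected (whole-record intersection) and motif
    hits with exact p <= threshold are counted inside them, summed per gene.
    With ``by_class`` the counts are returned per (gene, SE/TE) as
    ``{gene_id: {"SE": n, "TE": n}}`` (classes without enhancers omitted).
    """
    dist = pwm.score_distribution()
    region_hits: dict[tuple[str, int, int], int] = {}

    def hits_in(iv: GenomicInterval) -> int:
        key = (iv.chrom, iv.start, iv.end)
        if key not in region_hits:
            if iv.chrom not in sequences:
                raise KeyError(f"no sequence available for chromosome {iv.chrom!r}")
            seq = sequences[iv.chrom][iv.start : iv.end]
            region_hits[key] = len(
                scan_pwm(seq, pwm, p_threshold, chrom=iv.chrom, offset=iv.start,
                         distribution=dist)
            )
        return region_hits[key]

    out: dict = {}
    for gene_id, enhancers in assignments.items():
        if by_class:
            counts: dict[str, int] = {}
            for cls in ("SE", "TE"):
                subset = [e for e in enhancers if getattr(e, "enhancer_class", "TE") == cls]
                if not subset:
                    continue
                regions = intersect_any(accessible_regions, subset)
                counts[cls] = sum(hits_in(_as_interval(r)) for r in regions)
            out[gene_id] = counts
        else:
            regions = intersect_any(accessible_regions, enhancers)
            out[gene_id] = sum(hits_in(_as_interval(r)) for r in regions)
    return out


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_meme_motifs(path) -> list[PositionWeightMatrix]:
    """Parse PWMs from a MEME minimal-format motif file."""
    motifs: list[PositionWeightMatrix] = []
    background = UNIFORM_BACKGROUND.copy()
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("Background letter frequencies"):
            fields = lines[i + 1].split()
            background = np.array(
                [float(fields[fields.index(b) + 1]) for b in BASES]
            )
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].startswith("letter-probability"):
                i += 1
            header = lines[i]
            width = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(width):
                rows.append([float(v) for v in lines[i + 1 + j].split()])
            motifs.append(
                PositionWeightMatrix(
                    name=name, probabilities=np.array(rows), background=background.copy()
                )
            )
            i += width + 1
            continue
        i += 1
    if not motifs:
        raise ValueError(f"{path}: no MOTIF records found")
    return motifs


def write_meme_motif(pwm: PositionWeightMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {pwm.background[i]:.5f}" for i, b in enumerate(BASES)) + "\n\n"
        )
        fh.write(f"MOTIF {pwm.name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 20 E= 0\n"
        )
        for row in pwm.probabilities:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def load_bundled_motif(name: str) -> PositionWeightMatrix:
    """Load one of the bundled synthetic toy motifs ("GATA2" or "MITF").

    These matrices are synthetic stand-ins shaped like the canonical GATA
    (WGATAR) and MITF E-box (CACGTG) consensus sites; they are not database
    PWMs.
    """
    fname = f"{name.upper()}_synthetic.meme"
    ref = resources.files("superchrom") / "motifs" / fname
    with resources.as_file(ref) as path:
        return read_meme_motifs(path)[0]
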