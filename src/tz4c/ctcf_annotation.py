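"""Consensus CTCF-site calling, motif-orientation assignment, and direct vs
indirect/weak classification.

A CTCF site that is "constant" across tissues is defined operationally:
merge the peak intervals of many ChIP-seq datasets, count in how many
datasets each merged interval is called, and keep those at or above a
support threshold (14 of 31 in the default analysis; all-of-3 for an
ES-cell-only intersection).  Orientation comes from the best position-weight
-matrix hit on either strand within a window (default 200 bp) centered on
the peak midpoint.  Direct binding is declared from native-ChIP enrichment
tables by a fold-over-IgG rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .locus_model import GenomicInterval

__all__ = [
    "PeakSet",
    "ConsensusPeak",
    "Pwm",
    "EnrichmentTable",
    "merge_peaks",
    "count_support",
    "consensus_filter",
    "scan_orientation",
    "classify_binding",
    "read_pwm",
    "write_consensus_bed",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class PeakSet:
    dataset_id: str
    peaks: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))


@dataclass(frozen=True)
class ConsensusPeak:
    interval: GenomicInterval
    support: int
    orientation: str | None = None  # "+", "-", or "ambiguous"
    score: float | None = None


class Pwm:
    """Log-odds position weight matrix over A,C,G,T.

    ``matrix`` has shape (length, 4), columns in A,C,G,T order.  A count or
    frequency matrix is converted with pseudocount 0.25 per base against a
    uniform background.
    """

    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 4 or matrix.shape[0] < 4:
            raise ValueError("PWM must be (L>=4, 4)")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("PWM entries must be finite")
        self.matrix = matrix

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.25) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        probs = (counts + pseudocount) / (counts + pseudocount).sum(
            axis=1, keepdims=True
        )
        return cls(np.log2(probs / 0.25))

    @classmethod
    def from_consensus(
        cls, consensus: str, match_prob: float = 0.85
    ) -> "Pwm":
        """Degenerate PWM putting ``match_prob`` on the consensus base."""
        off = (1 - match_prob) / 3
        mat = np.full((len(consensus), 4), math.log2(off / 0.25))
        for i, b in enumerate(consensus.upper()):
            mat[i, _BASE_INDEX[b]] = math.log2(match_prob / 0.25)
        return cls(mat)

    def score(self, seq: str) -> float:
        """Log-odds score of one exact-length sequence (N scores 0 columns
        at their minimum, a conservative choice for unknown bases)."""
        if len(seq) != len(self):
            raise ValueError("sequence length must equal PWM length")
        total = 0.0
        for i, b in enumerate(seq.upper()):
            j = _BASE_INDEX.get(b)
            total += self.matrix[i].min() if j is None else self.matrix[i, j]
        return total


def merge_peaks(sets: Sequence[PeakSet]) -> list[GenomicInterval]:
    """Union of all peak intervals with overlapping or book-ended
    (end == start) intervals coalesced; sorted and disjoint on output."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for ps in sets:
        for iv in ps.peaks:
            by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def count_support(
    merged: Sequence[GenomicInterval], sets: Sequence[PeakSet]
) -> list[int]:
    """For each merged interval, the number of datasets with >=1 bp overlap.

    A dataset contributes at most once per interval however many of its
    peaks fall inside.
    """
    support = [0] * len(merged)
    for ps in sets:
        hit = [False] * len(merged)
        for pk in ps.peaks:
            for i, iv in enumerate(merged):
                if iv.overlaps(pk):
                    hit[i] = True
        for i, h in enumerate(hit):
            if h:
                support[i] += 1
    return support


def consensus_filter(
    merged: Sequence[GenomicInterval], support: Sequence[int], k: int
) -> list[ConsensusPeak]:
    """Keep merged peaks called in at least ``k`` datasets."""
    if len(merged) != len(support):
        raise ValueError("merged and support lengths differ")
    return [
        ConsensusPeak(iv, s)
        for iv, s in zip(merged, support)
        if s >= k
    ]


def scan_orientation(
    sequence: str,
    peak: GenomicInterval,
    pwm: Pwm,
    window: int = 200,
    seq_offset: int = 0,
) -> tuple[str, float]:
    """Best-strand PWM call in a window centered on the peak midpoint.

    ``sequence`` is the locus sequence starting at genomic coordinate
    ``seq_offset``.  Every offset is scored on the plus strand and, via the
    reverse complement, on the minus strand; the strand of the maximum
    log-odds wins.  An exact cross-strand tie returns "ambiguous".
    """
    L = len(pwm)
    mid = int(peak.midpoint)
    lo = max(mid - window // 2 - seq_offset, 0)
    hi = min(mid + window // 2 - seq_offset, len(sequence))
    sub = sequence[lo:hi]
    if len(sub) < L:
        raise ValueError("scan window shorter than the PWM")
    best = {"+": -math.inf, "-": -math.inf}
    rc = str(Seq(sub).reverse_complement())
    for strand, s in (("+", sub), ("-", rc)):
        for off in range(len(s) - L + 1):
            sc = pwm.score(s[off : off + L])
            if sc > best[strand]:
                best[strand] = sc
    if best["+"] == best["-"]:
        return "ambiguous", best["+"]
    strand = "+" if best["+"] > best["-"] else "-"
    return strand, best[strand]


@dataclass
class EnrichmentTable:
    """Long-format native-ChIP qPCR-style enrichment values.

    Columns: site, channel ("CTCF" or "IgG"), replicate, value (>= 0).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"site", "channel", "replicate", "value"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"enrichment table needs columns {sorted(need)}")
        if (self.data["value"] < 0).any():
            raise ValueError("enrichment values must be >= 0")

    def values_for(self, site: str, channel: str) -> np.ndarray:
        sel = (self.data["site"] == site) & (self.data["channel"] == channel)
        return self.data.loc[sel, "value"].to_numpy(float)


def classify_binding(
    table: EnrichmentTable, site: str, fold_threshold: float = 3.0
) -> str:
    """'direct' iff mean CTCF enrichment is >= fold_threshold times the mean
    IgG enrichment and exceeds it at all; else 'indirect_or_weak'."""
    ctcf = table.values_for(site, "CTCF")
    igg = table.values_for(site, "IgG")
    if len(ctcf) == 0 or len(igg) == 0:
        raise ValueError(f"site {site!r}: missing CTCF or IgG channel")
    m_c, m_i = ctcf.mean(), igg.mean()
    if m_i > 0 and m_c / m_i >= fold_threshold and m_c > m_i:
        return "direct"
    if m_i == 0 and m_c > 0:
        return "direct"
    return "indirect_or_weak"


# ---------------------------------------------------------------------------
# I/O


def read_pwm(path: str | Path, counts: bool = False) -> Pwm:
    """Read a PWM text file: one row per position, 4 whitespace-separated
    columns (A C G T).  ``counts=True`` converts a count/frequency matrix to
    log-odds with pseudocount 0.25 and uniform background."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", ">")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns")
            rows.append([float(p) for p in parts])
    mat = np.asarray(rows)
    return Pwm.from_counts(mat) if counts else Pwm(mat)


def write_consensus_bed(path: str | Path, peaks: Sequence[ConsensusPeak]) -> None:
    """BED6: support in the score column, orientation in the strand column."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, p in enumerate(peaks):
            strand = p.orientation if p.orientation in ("+", "-") else "."
            name = p.interval.name or f"peak{i}"
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{name}\t{p.support}\t{strand}\n"
            )
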