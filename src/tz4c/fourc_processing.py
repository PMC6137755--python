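"""Raw per-fragment 4C counts -> analysis-ready profiles and browser tracks.

The processing chain mirrors standard 4C practice: mask fragments near the
viewpoint (self-ligation artifacts), normalize to reads per million for
cross-library display, smooth with a centered running mean over fragments
for visualization, and count raw masked reads in named intervals for
statistics.  Smoothed/normalized values are for tracks only; the statistics
layer consumes raw masked counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .locus_model import FragmentMap, GenomicInterval, Viewpoint, assign_fragments

__all__ = [
    "ContactProfile",
    "SmoothedTrack",
    "exclude_near_viewpoint",
    "rpm_normalize",
    "smooth",
    "count_in_intervals",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_bedgraph",
    "write_bedgraph",
]


@dataclass
class ContactProfile:
    """Per-fragment read counts for one viewpoint, allele and replicate.

    ``mask`` flags fragments excluded from statistics; masked fragments keep
    their counts but are skipped by every downstream aggregation.
    """

    viewpoint: Viewpoint
    allele: str
    replicate: int
    fragment_map: FragmentMap
    counts: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or len(self.counts) != len(self.fragment_map):
            raise ValueError("counts length must equal fragment count")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(len(self.counts), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask length must equal fragment count")

    @property
    def total_reads(self) -> int:
        """Library size: total raw reads, before any masking."""
        return int(self.counts.sum())


@dataclass
class SmoothedTrack:
    """Per-fragment real values after normalization and/or smoothing."""

    fragment_map: FragmentMap
    values: np.ndarray
    mask: np.ndarray
    rpm_applied: bool = False
    smooth_window: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)


def exclude_near_viewpoint(
    profile: ContactProfile, radius: int | None = None
) -> ContactProfile:
    """Mask fragments whose midpoint lies within ``radius`` bp of the
    viewpoint position, on both sides.  Defaults to the viewpoint's own
    exclusion radius (10 kb typical, 15 kb for poorly mappable flanks).
    Masking is idempotent and accumulates with any existing mask.
    """
    r = profile.viewpoint.exclusion_radius if radius is None else radius
    dist = np.abs(profile.fragment_map.midpoints - profile.viewpoint.position)
    new_mask = profile.mask | (dist <= r)
    return replace(profile, mask=new_mask)


def rpm_normalize(profile: ContactProfile) -> SmoothedTrack:
    """Reads-per-million scaling: value_i = count_i * 1e6 / library size.

    The denominator is the total raw read count of the library before
    masking — library size is a sequencing fact, and a mask-independent
    denominator keeps tracks comparable across alleles.
    """
    total = profile.total_reads
    if total == 0:
        raise ValueError("cannot RPM-normalize an empty library")
    values = profile.counts.astype(float) * 1e6 / total
    return SmoothedTrack(
        profile.fragment_map, values, profile.mask.copy(), rpm_applied=True
    )


def smooth(track: SmoothedTrack, window: int = 11) -> SmoothedTrack:
    """Centered running mean over ``window`` fragments (fragment order, not
    base pairs).  At the edges the window truncates to available fragments;
    masked fragments are dropped from both numerator and denominator, so a
    fully masked window yields 0.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    vals = np.where(track.mask, 0.0, track.values)
    ok = (~track.mask).astype(float)
    # cumulative-sum sliding window with truncation at the edges
    cs_v = np.concatenate(([0.0], np.cumsum(vals)))
    cs_n = np.concatenate(([0.0], np.cumsum(ok)))
    n = len(vals)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    num = cs_v[hi] - cs_v[lo]
    den = cs_n[hi] - cs_n[lo]
    out = np.divide(num, den, out=np.zeros(n), where=den > 0)
    return SmoothedTrack(
        track.fragment_map,
        out,
        track.mask.copy(),
        rpm_applied=track.rpm_applied,
        smooth_window=window,
    )


def count_in_intervals(
    profile: ContactProfile, regions: Sequence[GenomicInterval]
) -> dict[str, int]:
    """Sum raw counts of unmasked fragments assigned (midpoint rule) to each
    named region."""
    assignment = assign_fragments(profile.fragment_map, regions)
    out = {}
    for name, ids in assignment.items():
        keep = ids[~profile.mask[ids]]
        out[name] = int(profile.counts[keep].sum())
    return out


# ---------------------------------------------------------------------------
# I/O

_COUNT_COLS = ["fragment_id", "chrom", "start", "end", "count"]


def write_counts_tsv(path: str | Path, profile: ContactProfile) -> None:
    fmap = profile.fragment_map
    df = pd.DataFrame(
        {
            "fragment_id": np.arange(len(fmap), dtype=np.int64),
            "chrom": fmap.chrom,
            "start": fmap.starts,
            "end": fmap.ends,
            "count": profile.counts,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(
    path: str | Path, viewpoint: Viewpoint, allele: str = "", replicate: int = 0
) -> ContactProfile:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"{path}: cannot parse counts TSV: {exc}") from exc
    missing = [c for c in _COUNT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df.sort_values("fragment_id").reset_index(drop=True)
    if df["count"].isna().any() or (df["count"] < 0).any():
        bad = int(df.index[(df["count"].isna()) | (df["count"] < 0)][0]) + 2
        raise ValueError(f"{path}: line {bad}: invalid count")
    fmap = FragmentMap(
        str(df["chrom"].iloc[0]),
        df["start"].to_numpy(np.int64),
        df["end"].to_numpy(np.int64),
    )
    return ContactProfile(
        viewpoint, allele, replicate, fmap, df["count"].to_numpy(np.int64)
    )


def write_bedgraph(
    path: str | Path, track: SmoothedTrack, name: str = "track"
) -> None:
    """BedGraph rows (0-based half-open, sorted, non-overlapping); masked
    fragments are written with their computed value so tracks stay gap-free.
    """
    fmap = track.fragment_map
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"track type=bedGraph name={name}\n")
        for s, e, v in zip(fmap.starts, fmap.ends, track.values):
            fh.write(f"{fmap.chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path: str | Path) -> tuple[str, list[tuple[str, int, int, float]]]:
    """Parse a BedGraph file; returns (track name, rows)."""
    rows: list[tuple[str, int, int, float]] = []
    name = "track"
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("track"):
                for tok in line.split():
                    if tok.startswith("name="):
                        name = tok[5:]
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 BedGraph columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
    prev_end = None
    for chrom, s, e, _ in rows:
        if prev_end is not None and s < prev_end:
            raise ValueError(f"{path}: overlapping or unsorted BedGraph rows")
        prev_end = e
    return name, rows
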