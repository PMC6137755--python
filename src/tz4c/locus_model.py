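"""Coordinate backbone of the locus: intervals, restriction-fragment maps,
viewpoints, and deletion/inversion allele algebra with liftover.

All coordinates are 0-based half-open (BED convention).  Engineered alleles
are described as ordered lists of rearrangement operations whose targets are
given in reference (wild-type) coordinates; because targets may not overlap,
the composed liftover is well defined regardless of listing order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "FragmentMap",
    "RearrangementOp",
    "AlleleSpec",
    "Viewpoint",
    "fragments_from_cuts",
    "liftover_point",
    "liftover_interval",
    "derive_allele_fragment_map",
    "assign_fragments",
    "read_bed",
    "write_bed",
]

UNMAPPED = None


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def contains(self, x: float) -> bool:
        return self.start <= x < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Viewpoint:
    """4C anchor: the position whose genome-wide contacts a library reports.

    ``exclusion_radius`` is the distance (bp) around the viewpoint within
    which fragments are masked before any counting, because self-ligation
    and over-digestion artifacts dominate there.  Default 10 kb; 15 kb for
    viewpoints flanked by poorly mappable sequence.
    """

    name: str
    position: int
    exclusion_radius: int = 10_000

    def __post_init__(self) -> None:
        if self.exclusion_radius <= 0:
            raise ValueError("exclusion_radius must be > 0")


@dataclass(frozen=True)
class RearrangementOp:
    kind: str  # "deletion" | "inversion"
    target: GenomicInterval

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "inversion"):
            raise ValueError(f"unknown rearrangement kind {self.kind!r}")


@dataclass(frozen=True)
class AlleleSpec:
    """Engineered allele: named, ordered rearrangements of the reference.

    An empty op list denotes the unmodified (wild-type / Hap) allele.
    Targets must be pairwise non-overlapping.
    """

    name: str
    ops: tuple[RearrangementOp, ...] = ()

    def __post_init__(self) -> None:
        ops = tuple(self.ops)
        object.__setattr__(self, "ops", ops)
        for i, a in enumerate(ops):
            for b in ops[i + 1 :]:
                if a.target.overlaps(b.target):
                    raise ValueError(
                        f"allele {self.name!r}: overlapping rearrangement "
                        f"targets {a.target} and {b.target}"
                    )

    @property
    def is_reference(self) -> bool:
        return len(self.ops) == 0


class FragmentMap:
    """Ordered, gap-free restriction fragments tiling one contiguous span.

    Fragment ids are their 0-based positional index; ``starts``/``ends`` are
    int64 arrays with ``ends[i] == starts[i+1]``.
    """

    def __init__(self, chrom: str, starts: Sequence[int], ends: Sequence[int]):
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if starts.ndim != 1 or starts.shape != ends.shape or len(starts) == 0:
            raise ValueError("starts/ends must be equal-length non-empty 1-D")
        if np.any(ends <= starts):
            raise ValueError("every fragment needs end > start")
        if np.any(starts[1:] != ends[:-1]):
            raise ValueError("fragments must tile the span without gaps")
        self.chrom = chrom
        self.starts = starts
        self.ends = ends

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, int(self.starts[0]), int(self.ends[-1]))

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    def fragment(self, i: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, int(self.starts[i]), int(self.ends[i]))

    def __iter__(self) -> Iterable[GenomicInterval]:
        for i in range(len(self)):
            yield self.fragment(i)

    def fragment_at(self, x: int) -> int:
        """Id of the fragment containing position x (ValueError if outside)."""
        if not (self.starts[0] <= x < self.ends[-1]):
            raise ValueError(f"position {x} outside modeled span {self.span}")
        return int(np.searchsorted(self.ends, x, side="right"))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, FragmentMap)
            and self.chrom == other.chrom
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )


def fragments_from_cuts(
    chrom: str, span: GenomicInterval, cut_sites: Sequence[int]
) -> FragmentMap:
    """Build the fragment map produced by cutting ``span`` at ``cut_sites``.

    Returns len(cut_sites)+1 contiguous fragments.  Cuts must be strictly
    increasing and strictly inside the span.
    """
    cuts = np.asarray(cut_sites, dtype=np.int64)
    if cuts.size and (np.any(np.diff(cuts) <= 0)):
        raise ValueError("cut sites must be strictly increasing")
    if cuts.size and (cuts[0] <= span.start or cuts[-1] >= span.end):
        raise ValueError("cut sites must lie strictly inside the span")
    bounds = np.concatenate(([span.start], cuts, [span.end]))
    return FragmentMap(chrom, bounds[:-1], bounds[1:])


def _split_ops(allele: AlleleSpec):
    dels = [op.target for op in allele.ops if op.kind == "deletion"]
    invs = [op.target for op in allele.ops if op.kind == "inversion"]
    return dels, invs


def liftover_point(x: int, allele: AlleleSpec) -> int | None:
    """Map a reference coordinate into the allele's coordinate system.

    Deletion [a,b): points inside are unmapped; points right of b shift
    left by the deleted length.  Inversion [a,b): points inside reflect to
    a+b-1-x (the last base of the target maps to its first position).
    Returns None for unmapped points.
    """
    dels, invs = _split_ops(allele)
    for t in dels:
        if t.contains(x):
            return UNMAPPED
    y = x
    for t in invs:
        if t.contains(x):
            y = t.start + t.end - 1 - x
            break  # targets are disjoint
    shift = sum(len(t) for t in dels if t.end <= y)
    return y - shift


def liftover_interval(
    iv: GenomicInterval, allele: AlleleSpec
) -> GenomicInterval | None:
    """Map an interval into allele coordinates, clipping deleted portions.

    Intended for analysis regions whose edges coincide with rearrangement
    breakpoints or lie outside all targets; an interval strictly inside a
    deletion maps to None.  Inversions internal to the interval leave its
    outer bounds unchanged.
    """
    dels, invs = _split_ops(allele)
    # Endpoints of the surviving (non-deleted) part in reference coordinates.
    s, e = iv.start, iv.end
    for t in dels:
        if t.start <= s < t.end:
            s = t.end
        if t.start < e <= t.end:
            e = t.start
    if s >= e:
        return UNMAPPED
    # Reflect endpoints through any inversion containing them, then shift.
    pts = []
    for x in (s, e - 1):
        y = x
        for t in invs:
            if t.contains(x):
                y = t.start + t.end - 1 - x
                break
        pts.append(y)
    lo, hi = min(pts), max(pts)
    shift_lo = sum(len(t) for t in dels if t.end <= lo)
    shift_hi = sum(len(t) for t in dels if t.end <= hi)
    return GenomicInterval(iv.chrom, lo - shift_lo, hi + 1 - shift_hi, iv.name)


def derive_allele_fragment_map(
    ref: FragmentMap, allele: AlleleSpec
) -> tuple[FragmentMap, list[int | None]]:
    """Rearranged fragment map plus old-id -> new-id mapping.

    Every rearrangement breakpoint must coincide with a fragment boundary:
    deleted fragments are dropped, inverted blocks reversed in order, and
    coordinates re-derived so the result tiles a contiguous span starting at
    the reference span start.
    """
    boundaries = set(ref.starts.tolist()) | {int(ref.ends[-1])}
    for op in allele.ops:
        if op.target.start not in boundaries or op.target.end not in boundaries:
            raise ValueError(
                f"breakpoint of {op.kind} {op.target.start}-{op.target.end} "
                "does not coincide with a fragment boundary"
            )

    n = len(ref)
    order = list(range(n))
    deleted = np.zeros(n, dtype=bool)
    for op in allele.ops:
        inside = [
            i
            for i in range(n)
            if op.target.start <= ref.starts[i] and ref.ends[i] <= op.target.end
        ]
        if op.kind == "deletion":
            deleted[inside] = True
        else:  # inversion: reverse the block's order in the current layout
            pos = [order.index(i) for i in inside]
            lo, hi = min(pos), max(pos)
            order[lo : hi + 1] = order[lo : hi + 1][::-1]

    kept = [i for i in order if not deleted[i]]
    lengths = (ref.ends - ref.starts)[kept]
    bounds = np.concatenate(([ref.starts[0]], ref.starts[0] + np.cumsum(lengths)))
    new_map = FragmentMap(ref.chrom, bounds[:-1], bounds[1:])
    old_to_new: list[int | None] = [None] * n
    for new_id, old_id in enumerate(kept):
        old_to_new[old_id] = new_id
    return new_map, old_to_new


def assign_fragments(
    fmap: FragmentMap, regions: Sequence[GenomicInterval]
) -> dict[str, np.ndarray]:
    """Assign fragments to named regions by the midpoint rule.

    A fragment belongs to a region iff its midpoint lies in [start, end);
    regions must be non-overlapping, so each fragment lands in at most one.
    Returns region name -> sorted array of fragment ids.
    """
    for i, a in enumerate(regions):
        if a.name is None:
            raise ValueError("regions must be named")
        for b in regions[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(f"overlapping regions {a.name!r} and {b.name!r}")
    mids = fmap.midpoints
    out: dict[str, np.ndarray] = {}
    for r in regions:
        if r.chrom != fmap.chrom:
            out[r.name] = np.empty(0, dtype=np.int64)
            continue
        sel = (mids >= r.start) & (mids < r.end)
        out[r.name] = np.nonzero(sel)[0].astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# BED I/O


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 BED columns")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            try:
                out.append(
                    GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
    return out


def fragment_map_to_bed(fmap: FragmentMap, path: str | Path) -> None:
    """Serialize a fragment map as BED4 with the fragment id in the name."""
    write_bed(
        path,
        (
            GenomicInterval(fmap.chrom, int(s), int(e), str(i))
            for i, (s, e) in enumerate(zip(fmap.starts, fmap.ends))
        ),
    )


def fragment_map_from_bed(path: str | Path) -> FragmentMap:
    ivs = read_bed(path)
    if not ivs:
        raise ValueError(f"{path}: empty fragment BED")
    return FragmentMap(ivs[0].chrom, [i.start for i in ivs], [i.end for i in ivs])
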