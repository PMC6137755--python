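"""Synthetic inputs for the whole pipeline: 4C contact profiles under an
extrusion-inspired barrier model, multi-dataset ChIP peak BEDs, motif-planted
locus sequence, and native-ChIP-style enrichment tables.

Contact model
-------------
Expected contact weight between a viewpoint and a fragment at midpoint
distance ``d`` is a power-law background attenuated by every CTCF barrier
strictly between them:

    w(x)  ∝  (d + d0)^(-alpha) * prod_s t(s, travel direction)

Each barrier site has a pointing direction (plus = toward increasing
coordinates / telomere).  A traversal meets the *front* of a site pointing
back toward the viewpoint and its *back* otherwise; fronts transmit with
probability ``t_front`` and backs with ``t_back >= t_front``, encoding that
extruding cohesin stalls predominantly at motifs facing it.  For a viewpoint
left of a divergent array pair (minus array, then plus array) the rightward
crossing accumulates t_front factors — strong blocking — which is what makes
a divergent CTCF array pair behave as a contact-domain boundary.

This is a stand-in for sequencing libraries, not a mechanistic cohesin
simulation: there is no explicit loading/release kinetics, no Hi-C matrix,
and no sequencing-error model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ctcf_annotation import EnrichmentTable, PeakSet
from .fourc_processing import ContactProfile
from .locus_model import (
    AlleleSpec,
    FragmentMap,
    GenomicInterval,
    RearrangementOp,
    Viewpoint,
    derive_allele_fragment_map,
    fragments_from_cuts,
    liftover_point,
)

__all__ = [
    "BarrierSite",
    "SimConfig",
    "expected_profile",
    "sample_reads",
    "simulate_library",
    "simulate_peak_datasets",
    "simulate_locus_sequence",
    "simulate_enrichment_table",
    "default_sim_config",
    "lift_sites",
    "derive_rng",
]

#: CTCF core consensus used for motif planting (non-palindromic).
DEFAULT_CONSENSUS = "CCAGCAGGGGGCGCTC"


@dataclass(frozen=True)
class BarrierSite:
    """One CTCF binding element acting as an orientation-dependent barrier.

    ``orientation`` "+" points toward the telomere (increasing coordinate),
    "-" toward the centromere.  ``occupancy`` is the probability that any
    one synthetic ChIP dataset calls the site; ``direct`` is the ground
    truth for the native-ChIP direct/indirect dichotomy.
    """

    name: str
    position: int
    orientation: str  # "+" | "-"
    t_front: float = 0.3
    t_back: float = 0.8
    occupancy: float = 0.9
    direct: bool = True

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")
        if not (0 <= self.t_front <= 1 and 0 <= self.t_back <= 1):
            raise ValueError("transmissions must be in [0, 1]")
        if self.t_front > self.t_back:
            raise ValueError("t_front must not exceed t_back (fronts block more)")
        if not (0 <= self.occupancy <= 1):
            raise ValueError("occupancy must be in [0, 1]")


@dataclass
class SimConfig:
    """Full description of the synthetic locus and its libraries."""

    chrom: str
    span: GenomicInterval
    cut_sites: list[int]
    sites: list[BarrierSite]
    viewpoints: list[Viewpoint]
    alleles: list[AlleleSpec]
    alpha: float = 1.0
    d0: float = 2000.0
    read_depth: int = 200_000
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.d0 <= 0:
            raise ValueError("alpha and d0 must be positive")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")

    @property
    def fragment_map(self) -> FragmentMap:
        return fragments_from_cuts(self.chrom, self.span, self.cut_sites)


def derive_rng(master_seed: int, *tokens: object) -> np.random.Generator:
    """Deterministic per-library RNG: hash the label tokens so adding one
    library never shifts another's stream."""
    label = "|".join(str(t) for t in tokens)
    digest = hashlib.sha256(label.encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([master_seed % (2**31), sub]))


def lift_sites(
    sites: list[BarrierSite], allele: AlleleSpec
) -> list[BarrierSite]:
    """Map barrier sites into allele coordinates.  Sites inside a deletion
    vanish; sites inside an inversion move and flip orientation."""
    out = []
    inv_targets = [op.target for op in allele.ops if op.kind == "inversion"]
    for s in sites:
        pos = liftover_point(s.position, allele)
        if pos is None:
            continue
        flipped = any(t.contains(s.position) for t in inv_targets)
        ori = s.orientation
        if flipped:
            ori = "+" if ori == "-" else "-"
        out.append(replace(s, position=int(pos), orientation=ori))
    return out


def expected_profile(
    fmap: FragmentMap,
    vp: Viewpoint,
    sites: list[BarrierSite],
    alpha: float,
    d0: float,
) -> np.ndarray:
    """Expected per-fragment contact weights, normalized to sum to 1.

    Weight of a fragment is the decay term (|mid - vp| + d0)^(-alpha) times
    the product of transmissions of every barrier strictly between the
    viewpoint and the fragment midpoint.  Rightward travel meets a
    minus-oriented site's front (t_front) and a plus site's back (t_back);
    leftward travel is the mirror image.  The viewpoint's own fragment gets
    weight 0.
    """
    if not (fmap.span.start <= vp.position < fmap.span.end):
        raise ValueError("viewpoint outside the fragment map span")
    mids = fmap.midpoints
    dist = np.abs(mids - vp.position)
    base = (dist + d0) ** (-alpha)

    pos = np.array([s.position for s in sites], dtype=float)
    order = np.argsort(pos)
    pos = pos[order]
    t_right = np.array(
        [s.t_front if s.orientation == "-" else s.t_back for s in sites]
    )[order]
    t_left = np.array(
        [s.t_front if s.orientation == "+" else s.t_back for s in sites]
    )[order]

    trans = np.ones(len(fmap))
    # rightward: sites with vp < pos < mid
    i_vp_r = np.searchsorted(pos, vp.position, side="right")
    cum_r = np.concatenate(([1.0], np.cumprod(t_right[i_vp_r:])))
    right = mids > vp.position
    k_r = np.searchsorted(pos[i_vp_r:], mids[right], side="left")
    trans[right] = cum_r[k_r]
    # leftward: sites with mid < pos < vp, crossed in decreasing order
    i_vp_l = np.searchsorted(pos, vp.position, side="left")
    cum_l = np.concatenate(([1.0], np.cumprod(t_left[:i_vp_l][::-1])))
    left = mids < vp.position
    k_l = i_vp_l - np.searchsorted(pos[:i_vp_l], mids[left], side="right")
    trans[left] = cum_l[k_l]

    w = base * trans
    w[fmap.fragment_at(vp.position)] = 0.0
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate profile: all weights zero")
    return w / total


def sample_reads(
    weights: np.ndarray, depth: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Multinomial read sampling; counts sum exactly to ``depth``."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1 within 1e-9")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    return rng.multinomial(depth, weights / weights.sum()).astype(np.int64)


def simulate_library(
    cfg: SimConfig,
    allele: AlleleSpec,
    viewpoint: Viewpoint,
    replicate: int,
) -> ContactProfile:
    """One synthetic 4C library: liftover -> expected profile -> multinomial
    sampling, with the RNG derived from (seed, allele, viewpoint, replicate).
    Raises if the viewpoint is deleted in the allele."""
    ref_map = cfg.fragment_map
    allele_map, _ = derive_allele_fragment_map(ref_map, allele)
    vp_pos = liftover_point(viewpoint.position, allele)
    if vp_pos is None:
        raise ValueError(
            f"viewpoint {viewpoint.name} is deleted in allele {allele.name}"
        )
    vp_lifted = Viewpoint(viewpoint.name, int(vp_pos), viewpoint.exclusion_radius)
    sites = lift_sites(cfg.sites, allele)
    weights = expected_profile(allele_map, vp_lifted, sites, cfg.alpha, cfg.d0)
    rng = derive_rng(cfg.seed, "4c", allele.name, viewpoint.name, replicate)
    counts = sample_reads(weights, cfg.read_depth, rng)
    return ContactProfile(vp_lifted, allele.name, replicate, allele_map, counts)


def simulate_peak_datasets(
    sites: list[BarrierSite],
    span: GenomicInterval,
    n_datasets: int = 31,
    jitter_sd: float = 25.0,
    peak_halfwidth: int = 150,
    noise_rate: float = 2.0,
    seed: int = 0,
) -> list[PeakSet]:
    """Synthetic ChIP peak BED sets.  Dataset d calls site s with
    probability ``occupancy(s)``, placing a peak of width 2*halfwidth at the
    site center plus Normal(0, jitter_sd) jitter, and adds
    Poisson(noise_rate) spurious peaks uniform over the locus."""
    out = []
    for d in range(n_datasets):
        rng = derive_rng(seed, "chip", d)
        peaks = []
        for s in sites:
            if rng.random() < s.occupancy:
                c = int(round(s.position + rng.normal(0, jitter_sd)))
                lo = max(span.start, c - peak_halfwidth)
                hi = min(span.end, c + peak_halfwidth)
                peaks.append(GenomicInterval(span.chrom, lo, hi))
        for _ in range(rng.poisson(noise_rate)):
            c = int(rng.integers(span.start + peak_halfwidth, span.end - peak_halfwidth))
            peaks.append(
                GenomicInterval(span.chrom, c - peak_halfwidth, c + peak_halfwidth)
            )
        out.append(PeakSet(f"synthetic_chip_{d:02d}", tuple(peaks)))
    return out


def simulate_locus_sequence(
    length: int,
    sites: list[BarrierSite],
    consensus: str = DEFAULT_CONSENSUS,
    seed: int = 0,
) -> str:
    """Uniform-random locus sequence with the motif consensus planted at
    each site: forward strand for plus-oriented sites, reverse complement
    for minus-oriented ones."""
    rng = derive_rng(seed, "seq")
    seq = rng.choice(list("ACGT"), size=length)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(consensus.upper()))
    for s in sites:
        planted = consensus.upper() if s.orientation == "+" else rc
        if s.position + len(planted) > length:
            raise ValueError(f"site {s.name} does not fit in the sequence")
        seq[s.position : s.position + len(planted)] = list(planted)
    return "".join(seq)


def simulate_enrichment_table(
    sites: list[BarrierSite],
    n_replicates: int = 3,
    direct_fold: float = 8.0,
    indirect_fold: float = 1.2,
    cv: float = 0.3,
    baseline: float = 1.0,
    seed: int = 0,
) -> EnrichmentTable:
    """Native-ChIP-style enrichment table: the CTCF channel is
    baseline*fold*LogNormal(0, cv) with the fold set by the site's ground
    truth class; the IgG channel is baseline*LogNormal(0, cv)."""
    rng = derive_rng(seed, "nchip")
    rows = []
    for s in sites:
        fold = direct_fold if s.direct else indirect_fold
        for r in range(n_replicates):
            ctcf = baseline * fold * (np.exp(rng.normal(0, cv)) if cv > 0 else 1.0)
            igg = baseline * (np.exp(rng.normal(0, cv)) if cv > 0 else 1.0)
            rows.append((s.name, "CTCF", r, ctcf))
            rows.append((s.name, "IgG", r, igg))
    return EnrichmentTable(
        pd.DataFrame(rows, columns=["site", "channel", "replicate", "value"])
    )


def fit_decay_exponent(profile: ContactProfile, d0: float) -> float:
    """Recover the distance-decay exponent from a contact profile by an
    ordinary least-squares fit of log(count) against log(distance + d0),
    over unmasked fragments with nonzero counts.  Meaningful only when no
    barriers attenuate the profile (pure power-law decay)."""
    mids = profile.fragment_map.midpoints
    d = np.abs(mids - profile.viewpoint.position)
    keep = (~profile.mask) & (profile.counts > 0) & (d > 0)
    x = np.log(d[keep] + d0)
    y = np.log(profile.counts[keep].astype(float))
    slope = np.polyfit(x, y, 1)[0]
    return -slope


# ---------------------------------------------------------------------------
# The default synthetic locus


def default_sim_config(seed: int = 0) -> SimConfig:
    """The canonical synthetic locus used throughout the tests and examples.

    A 900-kb span holds two contact domains separated by a boundary region
    (the transition zone, TZ, at 450–520 kb) carrying a divergent pair of
    CTCF arrays: two direct minus sites plus one weak site on the
    centromeric side, three direct plus sites on the telomeric side.
    Restriction cuts average ~2 kb and always include every rearrangement
    breakpoint, so engineered alleles stay representable on the fragment
    grid.  Alleles mirror the engineered series: whole-TZ and flanking
    deletions (del1/del2/del3) and single-array deletions/inversions
    (del-L, inv-L, del-R, inv-R).
    """
    chrom = "chrS"
    span = GenomicInterval(chrom, 0, 900_000)
    sites = [
        BarrierSite("TZ-L1", 455_000, "-", 0.3, 0.8, 0.9, True),
        BarrierSite("TZ-L2", 463_000, "-", 0.3, 0.8, 0.9, True),
        BarrierSite("TZ-ES", 471_000, "-", 0.85, 0.95, 0.1, False),
        BarrierSite("TZ-R1", 495_000, "+", 0.3, 0.8, 0.9, True),
        BarrierSite("TZ-R2", 503_000, "+", 0.3, 0.8, 0.9, True),
        BarrierSite("TZ-R3", 511_000, "+", 0.3, 0.8, 0.9, True),
    ]
    viewpoints = [
        Viewpoint("VP-Tfap2c", 155_000, 10_000),
        Viewpoint("VP-Tdom", 430_000, 15_000),
        Viewpoint("VP-TZmid", 483_000, 10_000),
        Viewpoint("VP-Bdom", 540_000, 10_000),
    ]

    def d(name, s, e):
        return AlleleSpec(name, (RearrangementOp("deletion", GenomicInterval(chrom, s, e)),))

    def i(name, s, e):
        return AlleleSpec(name, (RearrangementOp("inversion", GenomicInterval(chrom, s, e)),))

    alleles = [
        AlleleSpec("Hap"),
        d("del1", 165_000, 450_000),
        d("del2", 450_000, 520_000),
        d("del3", 520_000, 600_000),
        d("del-L", 450_000, 468_000),
        i("inv-L", 450_000, 468_000),
        d("del-R", 487_000, 520_000),
        i("inv-R", 487_000, 520_000),
    ]
    breakpoints = {op.target.start for a in alleles for op in a.ops} | {
        op.target.end for a in alleles for op in a.ops
    }
    # Deterministic 2-kb digest: the locus geometry is a fixed study
    # condition, and a regular grid keeps per-side fragment densities
    # comparable around every viewpoint.  Engineered breakpoints are always
    # cut sites so alleles remain representable on the fragment grid.
    grid = range(2000, len(span), 2000)
    cuts = sorted(({int(c) for c in grid} | breakpoints) - {span.start, span.end})
    return SimConfig(
        chrom=chrom,
        span=span,
        cut_sites=cuts,
        sites=sites,
        viewpoints=viewpoints,
        alleles=alleles,
        seed=seed,
    )


def default_regions(chrom: str = "chrS") -> dict[str, GenomicInterval]:
    """Named analysis intervals of the default locus (reference coords)."""
    return {
        "Tfap2c-cen": GenomicInterval(chrom, 0, 155_000, "Tfap2c-cen"),
        "Tfap2c-tel": GenomicInterval(chrom, 155_000, 450_000, "Tfap2c-tel"),
        "TZ": GenomicInterval(chrom, 450_000, 520_000, "TZ"),
        "Bmp7-domain": GenomicInterval(chrom, 520_000, 900_000, "Bmp7-domain"),
    }


def default_invasion_regions(
    chrom: str = "chrS",
) -> dict[str, tuple[GenomicInterval, GenomicInterval]]:
    """(invasion, control) interval pair per viewpoint, reference coords.

    Invasion = the adjacent domain beyond the TZ; control = the interval on
    the viewpoint's far side (away from the TZ) out to the locus end, which
    the TZ rearrangements leave untouched.
    """
    bmp7 = GenomicInterval(chrom, 520_000, 900_000, "invasion")
    tfap2c = GenomicInterval(chrom, 0, 450_000, "invasion")
    return {
        "VP-Tfap2c": (bmp7, GenomicInterval(chrom, 0, 144_000, "control")),
        "VP-Tdom": (bmp7, GenomicInterval(chrom, 0, 414_000, "control")),
        "VP-Bdom": (tfap2c, GenomicInterval(chrom, 556_000, 900_000, "control")),
    }
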