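"""Pipeline stages: simulate -> annotate-ctcf -> profile -> stats -> compare.

Each stage reads/writes plain-text files under the config's workdir so the
full synthetic study is reproducible file-by-file; ``run_all`` chains them
and records a manifest of seeds, parameters and output hashes.  Outputs are
deterministic for a fixed config: re-running produces byte-identical TSV
and BedGraph files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .config import PipelineConfig
from .contact_stats import (
    anova_tukey,
    directionality_score,
    interval_proportions,
    invasion_ratio,
    permutation_test_one_sided,
)
from .ctcf_annotation import (
    PeakSet,
    Pwm,
    EnrichmentTable,
    classify_binding,
    consensus_filter,
    count_support,
    merge_peaks,
    scan_orientation,
    write_consensus_bed,
)
from .fourc_processing import (
    ContactProfile,
    exclude_near_viewpoint,
    read_counts_tsv,
    rpm_normalize,
    smooth,
    write_bedgraph,
    write_counts_tsv,
)
from .locus_model import (
    GenomicInterval,
    Viewpoint,
    fragment_map_to_bed,
    liftover_interval,
    liftover_point,
    read_bed,
)
from .synthetic_data import (
    DEFAULT_CONSENSUS,
    simulate_enrichment_table,
    simulate_library,
    simulate_locus_sequence,
    simulate_peak_datasets,
)

log = logging.getLogger("tz4c")

_FLOAT_FMT = "%.10g"


def _lib_name(allele: str, vp: str, rep: int) -> str:
    return f"{allele}__{vp}__rep{rep}"


def _iter_libraries(cfg: PipelineConfig):
    """(allele, viewpoint, replicate) triples with a mappable viewpoint."""
    for allele in cfg.sim.alleles:
        for vp in cfg.sim.viewpoints:
            if liftover_point(vp.position, allele) is None:
                log.info(
                    "skipping %s x %s: viewpoint deleted in this allele",
                    allele.name,
                    vp.name,
                )
                continue
            for rep in range(cfg.sim.n_replicates):
                yield allele, vp, rep


def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    """Generate every pipeline input: counts TSV per library, one BED per
    synthetic ChIP dataset, the motif-planted locus FASTA, the enrichment
    CSV, and the reference fragment map."""
    out: list[Path] = []
    counts_dir = cfg.workdir / "counts"
    counts_dir.mkdir(parents=True, exist_ok=True)
    for allele, vp, rep in _iter_libraries(cfg):
        profile = simulate_library(cfg.sim, allele, vp, rep)
        path = counts_dir / f"{_lib_name(allele.name, vp.name, rep)}.tsv"
        write_counts_tsv(path, profile)
        out.append(path)

    peaks_dir = cfg.workdir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    ann = cfg.annotation
    for ps in simulate_peak_datasets(
        cfg.sim.sites,
        cfg.sim.span,
        n_datasets=ann.n_datasets,
        jitter_sd=ann.jitter_sd,
        peak_halfwidth=ann.peak_halfwidth,
        noise_rate=ann.noise_rate,
        seed=cfg.sim.seed,
    ):
        path = peaks_dir / f"{ps.dataset_id}.bed"
        with open(path, "w", encoding="utf-8") as fh:
            for iv in sorted(ps.peaks, key=lambda i: (i.start, i.end)):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        out.append(path)

    seq = simulate_locus_sequence(
        len(cfg.sim.span), cfg.sim.sites, DEFAULT_CONSENSUS, cfg.sim.seed
    )
    fasta = cfg.workdir / "locus.fa"
    SeqIO.write([SeqRecord(Seq(seq), id=cfg.sim.chrom, description="")], fasta, "fasta")
    out.append(fasta)

    table = simulate_enrichment_table(cfg.sim.sites, seed=cfg.sim.seed)
    enr = cfg.workdir / "enrichment.csv"
    table.data.to_csv(enr, index=False, float_format=_FLOAT_FMT)
    out.append(enr)

    frag_bed = cfg.workdir / "fragments.bed"
    fragment_map_to_bed(cfg.sim.fragment_map, frag_bed)
    out.append(frag_bed)
    return out


def stage_annotate(cfg: PipelineConfig) -> list[Path]:
    """Consensus CTCF calling + orientation scan + direct/indirect class."""
    peaks_dir = cfg.workdir / "peaks"
    sets = [
        PeakSet(p.stem, tuple(read_bed(p)))
        for p in sorted(peaks_dir.glob("*.bed"))
    ]
    if not sets:
        raise FileNotFoundError(f"no peak BED files under {peaks_dir}")
    merged = merge_peaks(sets)
    support = count_support(merged, sets)
    consensus = consensus_filter(merged, support, cfg.annotation.k)

    record = next(SeqIO.parse(cfg.workdir / "locus.fa", "fasta"))
    sequence = str(record.seq)
    pwm = Pwm.from_consensus(DEFAULT_CONSENSUS)
    table = EnrichmentTable(pd.read_csv(cfg.workdir / "enrichment.csv"))
    known_sites = {s.name: s for s in cfg.sim.sites}

    rows = []
    annotated = []
    for pk in consensus:
        ori, score = scan_orientation(
            sequence, pk.interval, pwm, window=cfg.annotation.scan_window
        )
        # attach the nearest ground-truth site name if one is covered
        name = next(
            (
                s.name
                for s in cfg.sim.sites
                if pk.interval.start <= s.position < pk.interval.end
            ),
            None,
        )
        cls = ""
        if name in known_sites:
            cls = classify_binding(table, name, cfg.annotation.fold_threshold)
        from dataclasses import replace as _rp

        annotated.append(
            _rp(
                pk,
                interval=GenomicInterval(
                    pk.interval.chrom, pk.interval.start, pk.interval.end, name
                ),
                orientation=ori,
                score=score,
            )
        )
        rows.append(
            {
                "chrom": pk.interval.chrom,
                "start": pk.interval.start,
                "end": pk.interval.end,
                "site": name or ".",
                "support": pk.support,
                "orientation": ori,
                "pwm_score": score,
                "binding_class": cls,
            }
        )
    bed = cfg.workdir / "consensus_sites.bed"
    write_consensus_bed(bed, annotated)
    tsv = cfg.workdir / "annotation.tsv"
    pd.DataFrame(rows).to_csv(tsv, sep="\t", index=False, float_format=_FLOAT_FMT)
    return [bed, tsv]


def _load_profiles(cfg: PipelineConfig):
    counts_dir = cfg.workdir / "counts"
    paths = sorted(counts_dir.glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no counts TSV files under {counts_dir}")
    vps = {v.name: v for v in cfg.sim.viewpoints}
    alleles = {a.name: a for a in cfg.sim.alleles}
    for path in paths:
        allele_name, vp_name, rep_tok = path.stem.split("__")
        rep = int(rep_tok.removeprefix("rep"))
        if allele_name not in alleles or vp_name not in vps:
            raise ValueError(f"{path}: unknown allele or viewpoint in file name")
        allele = alleles[allele_name]
        vp0 = vps[vp_name]
        vp_pos = liftover_point(vp0.position, allele)
        if vp_pos is None:
            raise ValueError(f"{path}: viewpoint deleted in allele")
        vp = Viewpoint(vp0.name, int(vp_pos), vp0.exclusion_radius)
        yield allele, read_counts_tsv(path, vp, allele_name, rep)


def stage_profile(cfg: PipelineConfig) -> list[Path]:
    """Counts -> masked, RPM-normalized, smoothed BedGraph tracks."""
    tracks_dir = cfg.workdir / "tracks"
    tracks_dir.mkdir(parents=True, exist_ok=True)
    out = []
    for allele, profile in _load_profiles(cfg):
        masked = exclude_near_viewpoint(profile)
        track = rpm_normalize(masked) if cfg.processing.rpm else _raw_track(masked)
        track = smooth(track, cfg.processing.smooth_window)
        name = _lib_name(profile.allele, profile.viewpoint.name, profile.replicate)
        path = tracks_dir / f"{name}.bedgraph"
        write_bedgraph(path, track, name=name)
        out.append(path)
    return out


def _raw_track(profile: ContactProfile):
    from .fourc_processing import SmoothedTrack

    return SmoothedTrack(
        profile.fragment_map, profile.counts.astype(float), profile.mask.copy()
    )


def stage_stats(cfg: PipelineConfig) -> Path:
    """Per-library contact statistics in long format."""
    rows = []
    for allele, profile in _load_profiles(cfg):
        masked = exclude_near_viewpoint(profile)
        vp_name = profile.viewpoint.name

        def add(metric: str, value: float) -> None:
            rows.append(
                {
                    "viewpoint": vp_name,
                    "allele": profile.allele,
                    "replicate": profile.replicate,
                    "metric": metric,
                    "value": value,
                }
            )

        if vp_name in cfg.invasion_regions:
            inv_ref, ctl_ref = cfg.invasion_regions[vp_name]
            inv = liftover_interval(inv_ref, allele)
            ctl = liftover_interval(ctl_ref, allele)
            if inv is not None and ctl is not None:
                res = invasion_ratio(masked, inv, ctl)
                add("invasion_ratio", res.ratio)

        d = directionality_score(
            masked, window=cfg.stats.directionality_window
        )
        add("directionality_score", d.score)

        if vp_name == cfg.proportions_viewpoint and cfg.regions:
            areas = []
            for r in cfg.regions.values():
                lifted = liftover_interval(r, allele)
                if lifted is not None:
                    areas.append(lifted)
            prop = interval_proportions(masked, areas)
            for area, pct in prop.percentages.items():
                add(f"pct_{area}", pct)
            if prop.tel_cen_ratio is not None:
                add("tel_cen_ratio", prop.tel_cen_ratio)

    df = pd.DataFrame(rows).sort_values(
        ["viewpoint", "metric", "allele", "replicate"]
    )
    path = cfg.workdir / "results.tsv"
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def stage_compare(cfg: PipelineConfig) -> Path:
    """Group comparisons: one-sided permutation tests of each allele against
    the reference for ratio metrics, plus ANOVA + Tukey across alleles for
    the proportion metrics."""
    df = pd.read_csv(cfg.workdir / "results.tsv", sep="\t")
    ref = cfg.stats.reference_allele
    rows = []
    for (vp, metric), sub in df.groupby(["viewpoint", "metric"]):
        groups = {
            a: g.sort_values("replicate")["value"].tolist()
            for a, g in sub.groupby("allele")
        }
        if ref not in groups or len(groups) < 2:
            continue
        if metric == "invasion_ratio":
            alternative = cfg.stats.alternative
            for allele in sorted(groups):
                if allele == ref:
                    continue
                t = permutation_test_one_sided(
                    groups[ref],
                    groups[allele],
                    alternative=alternative,
                    seed=cfg.sim.seed % (2**31),
                )
                rows.append(
                    {
                        "viewpoint": vp,
                        "metric": metric,
                        "method": t.method,
                        "group_a": ref,
                        "group_b": allele,
                        "statistic": t.statistic,
                        "p_value": t.p_value,
                        "min_p": t.min_p,
                    }
                )
        if metric.startswith("pct_") or metric == "tel_cen_ratio":
            usable = {a: v for a, v in groups.items() if len(v) >= 2}
            if len(usable) >= 2 and ref in usable:
                for t in anova_tukey(usable, reference=ref):
                    rows.append(
                        {
                            "viewpoint": vp,
                            "metric": metric,
                            "method": t.method,
                            "group_a": t.groups[0] if t.method == "tukey" else "all",
                            "group_b": t.groups[1] if t.method == "tukey" else "all",
                            "statistic": t.statistic,
                            "p_value": t.p_value,
                            "min_p": t.min_p,
                        }
                    )
    path = cfg.workdir / "tests.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


_STAGES = {
    "simulate": stage_simulate,
    "annotate-ctcf": stage_annotate,
    "profile": stage_profile,
    "stats": stage_stats,
    "compare": stage_compare,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in order and write a manifest JSON recording the
    package version, seed, parameters and the hash of every output."""
    cfg.workdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.sim.seed,
        "parameters": {
            "alpha": cfg.sim.alpha,
            "d0": cfg.sim.d0,
            "read_depth": cfg.sim.read_depth,
            "n_replicates": cfg.sim.n_replicates,
            "consensus_k": cfg.annotation.k,
            "n_datasets": cfg.annotation.n_datasets,
            "smooth_window": cfg.processing.smooth_window,
            "directionality_window": cfg.stats.directionality_window,
        },
        "stages": [],
    }
    for name, fn in _STAGES.items():
        log.info("stage %s: starting", name)
        try:
            outputs = fn(cfg)
        except Exception:
            log.error("stage %s: FAILED", name)
            raise
        if isinstance(outputs, Path):
            outputs = [outputs]
        manifest["stages"].append(
            {
                "name": name,
                "outputs": sorted(
                    {str(p.relative_to(cfg.workdir)): _sha256(p) for p in outputs}.items()
                ),
            }
        )
        log.info("stage %s: done (%d outputs)", name, len(outputs))
    path = cfg.workdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return manifest
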