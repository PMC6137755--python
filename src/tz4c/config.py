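"""Pipeline configuration: YAML/JSON loading, validation with full error
reporting, and normalization into typed objects.

The bundled default configuration (``tz4c/data/default_config.yaml``)
describes the canonical synthetic locus; a user config may either say
``locus: default`` or spell out the locus (span, cut sites, barrier sites,
viewpoints, alleles, analysis regions) explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .locus_model import AlleleSpec, GenomicInterval, RearrangementOp, Viewpoint
from .synthetic_data import (
    BarrierSite,
    SimConfig,
    default_invasion_regions,
    default_regions,
    default_sim_config,
)


class ConfigError(ValueError):
    """Raised with the complete list of validation problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


@dataclass
class AnnotationParams:
    n_datasets: int = 31
    k: int = 14
    scan_window: int = 200
    fold_threshold: float = 3.0
    jitter_sd: float = 25.0
    peak_halfwidth: int = 150
    noise_rate: float = 2.0


@dataclass
class ProcessingParams:
    smooth_window: int = 11
    rpm: bool = True


@dataclass
class StatsParams:
    directionality_window: int = 200_000
    reference_allele: str = "Hap"
    alternative: str = "greater"


@dataclass
class PipelineConfig:
    workdir: Path
    sim: SimConfig
    regions: dict[str, GenomicInterval]
    invasion_regions: dict[str, tuple[GenomicInterval, GenomicInterval]]
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    processing: ProcessingParams = field(default_factory=ProcessingParams)
    stats: StatsParams = field(default_factory=StatsParams)
    proportions_viewpoint: str = "VP-Tfap2c"
    log_level: str = "INFO"


def default_config_path() -> Path:
    return Path(str(resources.files("tz4c").joinpath("data/default_config.yaml")))


def load_config(path: str | Path | None = None, seed: int | None = None) -> PipelineConfig:
    """Load, validate and normalize a pipeline config.

    ``seed`` overrides the config's seed.  All validation errors are
    collected and reported together in a single ConfigError.
    """
    if path is None:
        path = default_config_path()
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    return normalize_config(raw, seed=seed)


def _interval(chrom: str, val: Any, name: str | None, errors: list[str], key: str):
    try:
        s, e = int(val[0]), int(val[1])
        return GenomicInterval(chrom, s, e, name)
    except Exception as exc:
        errors.append(f"{key}: cannot parse interval {val!r} ({exc})")
        return None


def normalize_config(raw: dict, seed: int | None = None) -> PipelineConfig:
    errors: list[str] = []
    eff_seed = seed if seed is not None else int(raw.get("seed", 0))

    locus = raw.get("locus", "default")
    if locus == "default" or locus is None:
        sim = default_sim_config(eff_seed)
        regions = default_regions(sim.chrom)
        invasion = default_invasion_regions(sim.chrom)
    else:
        sim, regions, invasion = _parse_locus(locus, eff_seed, errors)

    sim_over = raw.get("sim", {}) or {}
    for key in ("alpha", "d0", "read_depth", "n_replicates"):
        if key in sim_over and sim is not None:
            setattr(sim, key, type(getattr(sim, key))(sim_over[key]))
    if sim is not None:
        if sim.alpha <= 0:
            errors.append("sim.alpha: must be > 0")
        if sim.d0 <= 0:
            errors.append("sim.d0: must be > 0")
        if sim.read_depth < 1:
            errors.append("sim.read_depth: must be >= 1")
        if sim.n_replicates < 1:
            errors.append("sim.n_replicates: must be >= 1")

    ann = AnnotationParams(**(raw.get("annotation", {}) or {}))
    if ann.k < 1:
        errors.append("annotation.k: must be >= 1")
    if ann.k > ann.n_datasets:
        errors.append(
            f"annotation.k: consensus threshold {ann.k} exceeds "
            f"n_datasets {ann.n_datasets}"
        )
    proc = ProcessingParams(**(raw.get("processing", {}) or {}))
    if proc.smooth_window < 1 or proc.smooth_window % 2 == 0:
        errors.append(
            f"processing.smooth_window: must be a positive odd integer, "
            f"got {proc.smooth_window}"
        )
    st = StatsParams(**(raw.get("stats", {}) or {}))
    if st.alternative not in ("greater", "less"):
        errors.append("stats.alternative: must be 'greater' or 'less'")
    if st.directionality_window <= 0:
        errors.append("stats.directionality_window: must be > 0")
    if sim is not None and not any(a.name == st.reference_allele for a in sim.alleles):
        errors.append(
            f"stats.reference_allele: {st.reference_allele!r} is not an allele"
        )

    if errors:
        raise ConfigError(errors)

    return PipelineConfig(
        workdir=Path(raw.get("workdir", "tz4c_out")),
        sim=sim,
        regions=regions,
        invasion_regions=invasion,
        annotation=ann,
        processing=proc,
        stats=st,
        proportions_viewpoint=raw.get("proportions_viewpoint", "VP-Tfap2c"),
        log_level=str(raw.get("log_level", "INFO")),
    )


def _parse_locus(locus: dict, seed: int, errors: list[str]):
    chrom = str(locus.get("chrom", "chrS"))
    span = _interval(chrom, locus.get("span", [0, 1]), None, errors, "locus.span")
    sites = []
    for i, s in enumerate(locus.get("sites", [])):
        try:
            sites.append(
                BarrierSite(
                    s.get("name", f"site{i}"),
                    int(s["position"]),
                    s["orientation"],
                    float(s.get("t_front", 0.3)),
                    float(s.get("t_back", 0.8)),
                    float(s.get("occupancy", 0.9)),
                    bool(s.get("direct", True)),
                )
            )
        except Exception as exc:
            errors.append(f"locus.sites[{i}]: {exc}")
    viewpoints = []
    for i, v in enumerate(locus.get("viewpoints", [])):
        try:
            viewpoints.append(
                Viewpoint(v["name"], int(v["position"]), int(v.get("exclusion_radius", 10_000)))
            )
        except Exception as exc:
            errors.append(f"locus.viewpoints[{i}]: {exc}")
    alleles = []
    for i, a in enumerate(locus.get("alleles", [{"name": "Hap", "ops": []}])):
        try:
            ops = tuple(
                RearrangementOp(
                    o["kind"], GenomicInterval(chrom, int(o["start"]), int(o["end"]))
                )
                for o in a.get("ops", [])
            )
            alleles.append(AlleleSpec(a["name"], ops))
        except Exception as exc:
            errors.append(f"locus.alleles[{i}]: {exc}")
    regions = {}
    for name, iv in (locus.get("regions", {}) or {}).items():
        got = _interval(chrom, iv, name, errors, f"locus.regions.{name}")
        if got:
            regions[name] = got
    invasion = {}
    for vp_name, pair in (locus.get("invasion", {}) or {}).items():
        inv = _interval(chrom, pair.get("invasion"), "invasion", errors, f"locus.invasion.{vp_name}")
        ctl = _interval(chrom, pair.get("control"), "control", errors, f"locus.invasion.{vp_name}")
        if inv and ctl:
            invasion[vp_name] = (inv, ctl)
    sim = None
    if span is not None:
        cuts = [int(c) for c in locus.get("cut_sites", [])]
        try:
            sim = SimConfig(
                chrom=chrom,
                span=span,
                cut_sites=cuts,
                sites=sites,
                viewpoints=viewpoints,
                alleles=alleles,
                seed=seed,
            )
        except Exception as exc:
            errors.append(f"locus: {exc}")
    return sim, regions, invasion
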