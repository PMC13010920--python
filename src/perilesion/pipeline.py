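"""Run configuration, orchestration and logging for the named analyses.

A run is described by one YAML config (paths + analysis selector +
numeric parameters).  Outputs (profile TSVs, periodogram/correlation
summaries, comparison JSONs) are written to the output directory along
with a machine-parseable JSONL log; every result file records the
checksum of the config that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .genome_io import BlacklistPolicy, apply_blacklist, read_genome, read_gtf_genes, read_intervals
from .features import (
    CORRELATION_PRESETS,
    call_flanking_nucleosomes,
    count_relative_to_features,
    features_to_frame,
    pearson_window,
    standardize_tfbs_midpoint,
    stratify_by_expression,
    tss_from_annotation,
)
from .periodicity import (
    DyadMap,
    RotationalConfig,
    count_relative_to_dyads,
    enrichment_profile,
    expected_profile,
    genomewide_context_rates,
    lomb_scargle_periodogram,
    ratio_profile,
    smooth_profile,
)
from .sasa_rotation import compare_rotational_sasa, parse_structure
from .signatures import classify_nucleosomal, cosine_similarity, signature96

Analysis = Literal[
    "translational",
    "rotational",
    "strand_aligned_rotational",
    "ctcf",
    "sp1",
    "tss",
    "signature",
    "sasa",
]

_REQUIRED_PATHS: dict[str, tuple[str, ...]] = {
    "translational": ("events", "dyads"),
    "rotational": ("events", "dyads"),
    "strand_aligned_rotational": ("events", "dyads"),
    "ctcf": ("events", "features"),
    "sp1": ("events", "features"),
    "tss": ("events", "annotation"),
    "signature": ("events", "dyads", "genome"),
    "sasa": ("structure",),
}


class RunConfig(BaseModel):
    """Validated configuration for one analysis run."""

    model_config = ConfigDict(extra="forbid")

    analysis: Analysis
    output_dir: Path
    seed: int = 0

    genome: Optional[Path] = None
    events: Optional[Path] = None  # BED6 single-base events
    naked_control: Optional[Path] = None
    dyads: Optional[Path] = None
    blacklist: Optional[Path] = None
    features: Optional[Path] = None  # BED6 motif intervals
    annotation: Optional[Path] = None  # GTF
    expression: Optional[Path] = None  # gene_id<TAB>value
    structure: Optional[Path] = None  # PDB

    half_window: int = Field(default=1000, gt=0)
    core_half_width: int = Field(default=60, gt=0)
    period_min: float = Field(default=100.0, gt=0)
    period_max: float = Field(default=250.0, gt=0)
    grid_points: int = Field(default=2001, ge=16)
    smooth_width: int = 11
    context: Literal["pyrimidine", "guanine"] = "guanine"
    helical_period: float = Field(default=10.2, gt=0)
    rotational_phase: float = 0.0
    blacklist_flank: int = Field(default=1000, ge=0)
    probe_radius: float = Field(default=1.4, gt=0)
    sasa_points: int = Field(default=960, ge=92)
    nucleosome_radius: int = Field(default=73, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        problems = []
        for key in _REQUIRED_PATHS[self.analysis]:
            if getattr(self, key) is None:
                problems.append(f"analysis '{self.analysis}' requires path '{key}'")
        for key in (
            "genome", "events", "naked_control", "dyads", "blacklist",
            "features", "annotation", "expression", "structure",
        ):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                problems.append(f"{key}: path does not exist: {path}")
        if self.period_min >= self.period_max:
            problems.append("period_min must be < period_max")
        if self.smooth_width % 2 == 0:
            problems.append("smooth_width must be odd")
        if problems:
            raise ValueError("; ".join(problems))
        return self


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run config; the error report lists
    every violation, not only the first."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def config_checksum(config: RunConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in config.model_dump().items()}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class RunLogger:
    def __init__(self, path: Path):
        self.path = path

    def log(self, event: str, **fields) -> None:
        record = {"time": time.time(), "event": event, **fields}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(record) + "\n")


def _read_event_bed(path) -> pd.DataFrame:
    ivs = read_intervals(path)
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in ivs],
            "pos": [iv.start for iv in ivs],
            "strand": [iv.strand for iv in ivs],
        }
    )


def _write_profile(profile, path: Path, checksum: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_checksum: {checksum}\n")
        profile.to_frame().to_csv(fh, sep="\t", index=False)


def _write_json(obj: dict, path: Path, checksum: str) -> None:
    obj = {"config_checksum": checksum, **obj}
    path.write_text(json.dumps(obj, indent=2, default=float) + "\n")


def run(config: RunConfig) -> dict:
    """Execute the selected analysis; returns a result summary dict.

    Writes result files and a structured log under config.output_dir.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksum = config_checksum(config)
    logger = RunLogger(outdir / "run_log.jsonl")
    logger.log(
        "start",
        analysis=config.analysis,
        config_checksum=checksum,
        seed=config.seed,
        version=__version__,
    )
    try:
        summary = _dispatch(config, outdir, checksum)
    except Exception as exc:
        logger.log("failure", error=str(exc))
        raise
    _write_json(summary, outdir / f"{config.analysis}_summary.json", checksum)
    logger.log("done", analysis=config.analysis)
    return summary


def _load_dyads(config: RunConfig) -> DyadMap:
    dyads = DyadMap.read_bed(config.dyads)
    if config.blacklist:
        blk = read_intervals(config.blacklist)
        frame = apply_blacklist(
            dyads.to_frame(), blk, BlacklistPolicy(flank_bp=config.blacklist_flank)
        )
        dyads = DyadMap.from_frame(frame, label=dyads.label)
    return dyads


def _dyad_enrichment(config: RunConfig, orientation: str, half_window: int):
    events = _read_event_bed(config.events)
    dyads = _load_dyads(config)
    observed = count_relative_to_dyads(events, dyads, half_window, orientation)
    if config.naked_control is not None:
        naked = _read_event_bed(config.naked_control)
        control = count_relative_to_dyads(naked, dyads, half_window, orientation)
        return ratio_profile(observed, control), events, dyads
    if config.genome is None:
        raise ValueError(
            "normalization needs either naked_control or genome (context rates)"
        )
    genome = read_genome(config.genome)
    convention = (
        "pyrimidine_centered" if config.context == "pyrimidine" else "guanine_centered"
    )
    rates, _ = genomewide_context_rates(events, genome, convention=convention)
    expected = expected_profile(dyads, genome, rates, half_window, orientation)
    return enrichment_profile(observed, expected), events, dyads


def _dispatch(config: RunConfig, outdir: Path, checksum: str) -> dict:
    if config.analysis in ("translational", "rotational", "strand_aligned_rotational"):
        orientation = (
            "strand_aligned"
            if config.analysis == "strand_aligned_rotational"
            else "combined"
        )
        if config.analysis == "translational":
            half_window, period_range = config.half_window, (
                config.period_min, config.period_max
            )
        else:
            half_window = config.core_half_width
            period_range = (5.0, 25.0) if config.period_min >= 100 else (
                config.period_min, config.period_max
            )
        enrich, _, _ = _dyad_enrichment(config, orientation, half_window)
        _write_profile(enrich, outdir / f"{config.analysis}_profile.tsv", checksum)
        smoothed = smooth_profile(enrich, config.smooth_width)
        _write_profile(
            smoothed, outdir / f"{config.analysis}_profile_smoothed.tsv", checksum
        )
        pg = lomb_scargle_periodogram(enrich, period_range, config.grid_points)
        with open(outdir / f"{config.analysis}_periodogram.tsv", "w") as fh:
            fh.write(f"# config_checksum: {checksum}\n")
            pg.to_frame().to_csv(fh, sep="\t", index=False)
        summary = {
            "analysis": config.analysis,
            "peak_period_bp": pg.peak_period,
            "snr": pg.snr,
            "degenerate": pg.degenerate,
        }
        if config.analysis != "translational":
            rc = RotationalConfig(
                config.helical_period, config.rotational_phase, config.core_half_width
            )
            from .periodicity import rotational_summary

            rot = rotational_summary(enrich, rc)
            rot.to_csv(outdir / f"{config.analysis}_rotational_summary.tsv",
                       sep="\t", index=False)
            summary["rotational_means"] = dict(
                zip(rot["label"], rot["mean_value"])
            )
        return summary

    if config.analysis in ("ctcf", "sp1"):
        events = _read_event_bed(config.events)
        motifs = read_intervals(config.features)
        sites = features_to_frame(
            [standardize_tfbs_midpoint(m, config.analysis.upper()) for m in motifs]
        )
        if config.blacklist:
            blk = read_intervals(config.blacklist)
            sites = apply_blacklist(
                sites, blk, BlacklistPolicy(flank_bp=config.blacklist_flank)
            )
        profile = count_relative_to_features(events, sites, config.half_window)
        _write_profile(profile, outdir / f"{config.analysis}_profile.tsv", checksum)
        summary = {"analysis": config.analysis, "n_sites": int(len(sites))}
        if config.dyads is not None:
            dyad_profile = count_relative_to_features(
                _load_dyads(config).to_frame(), sites, config.half_window
            )
            segments = call_flanking_nucleosomes(dyad_profile)
            segments.to_frame().to_csv(
                outdir / f"{config.analysis}_segments.tsv", sep="\t", index=False
            )
            summary["n_nucleosome_peaks"] = int(segments.peak_positions.size)
        return summary

    if config.analysis == "tss":
        events = _read_event_bed(config.events)
        genes = read_gtf_genes(config.annotation)
        blk = read_intervals(config.blacklist) if config.blacklist else ()
        tss, skipped = tss_from_annotation(genes, blk)
        profile = count_relative_to_features(events, tss, config.half_window)
        _write_profile(profile, outdir / "tss_profile.tsv", checksum)
        summary = {
            "analysis": "tss",
            "n_tss": int(len(tss)),
            "n_skipped_no_biotype": skipped,
        }
        if config.expression is not None:
            expr = pd.read_csv(
                config.expression, sep="\t", names=["gene_id", "value"], header=None
            )
            strata = stratify_by_expression(tss, expr)
            for name, sub in strata.items():
                if len(sub):
                    p = count_relative_to_features(events, sub, config.half_window)
                    _write_profile(p, outdir / f"tss_{name}_profile.tsv", checksum)
                summary[f"n_tss_{name}"] = int(len(sub))
        return summary

    if config.analysis == "signature":
        genome = read_genome(config.genome)
        events = _read_event_bed(config.events)
        # event BED written by event_prep carries ref>alt in the name column
        ivs = read_intervals(config.events)
        refs = [iv.name.split(">")[0] for iv in ivs]
        alts = [iv.name.split(">")[1] if ">" in iv.name else "N" for iv in ivs]
        muts = events.assign(ref=refs, alt=alts, sample="pooled")
        dyads = _load_dyads(config)
        labels = classify_nucleosomal(muts, dyads, config.nucleosome_radius)
        result = {"analysis": "signature"}
        sigs = {}
        for label in ("nucleosomal", "linker"):
            sub = muts[labels == label]
            sig, skipped = signature96(sub, genome)
            sigs[label] = sig
            with open(outdir / f"signature_{label}.tsv", "w") as fh:
                fh.write(f"# config_checksum: {checksum}\n")
                sig.to_frame().to_csv(fh, sep="\t", index=False)
            result[f"n_{label}"] = int(len(sub))
        if sigs["nucleosomal"].weights.sum() > 0 and sigs["linker"].weights.sum() > 0:
            result["cosine_similarity"] = cosine_similarity(
                sigs["nucleosomal"], sigs["linker"]
            )
        return result

    if config.analysis == "sasa":
        model = parse_structure(config.structure)
        rc = RotationalConfig(
            config.helical_period, config.rotational_phase, core_half_width=10_000
        )
        comparison = compare_rotational_sasa(
            model, rc, config.probe_radius, config.sasa_points
        )
        return {"analysis": "sasa", **comparison.to_dict()}

    raise ValueError(f"unknown analysis {config.analysis!r}")
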