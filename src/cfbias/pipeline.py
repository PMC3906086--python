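"""Protocol orchestration: the four bias-correction pipelines and the
coverage-reduction evaluation harness.

Protocols (names follow the field's convention):

- ``rm_loess``:              repeat-removal -> bin -> LOESS GC correction
- ``mapcorr_loess``:         bin -> 1/mappability -> LOESS GC correction
- ``mapcorr_singlepos``:     bin -> single-position GC model -> 1/mappability
- ``mapcorr_singlepos_frag``: breakpoint-motif stratification -> per-stratum
  single-position model -> weighted combination -> 1/mappability
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aneuploidy, fragmentation, fragments as frag_ops, gc_models, reference
from .bins import BinScheme
from .reference import GenomeSequence, MappabilityTrack, RepeatAnnotation

logger = logging.getLogger(__name__)

PROTOCOLS = ("rm_loess", "mapcorr_loess", "mapcorr_singlepos", "mapcorr_singlepos_frag")


@dataclass
class RunConfig:
    """File-level configuration for a single protocol run (CLI surface)."""

    genome: str
    fragments: str
    protocol: str = "mapcorr_singlepos"
    repeats: str | None = None
    mappability: str | None = None
    bin_size: int = 50_000
    read_length: int = 50
    gc_window: int = 180
    gc_window_policy: str = "fixed"  # "fixed" | "tv-scan"
    loess_span: float = 0.3
    z_threshold: float = 3.0
    mappability_cutoff: float = 0.5
    reciprocal_mappability: bool = True
    stratum1_motifs: tuple = tuple(sorted(fragmentation.DEFAULT_STRATUM1_MOTIFS))
    sample_size: int | None = None
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "stratum1_motifs" in data:
            data["stratum1_motifs"] = tuple(data["stratum1_motifs"])
        return cls(**data)


def run_protocol(
    protocol: str,
    genome: GenomeSequence,
    frags: pd.DataFrame,
    *,
    bin_size: int = 50_000,
    track: MappabilityTrack | None = None,
    repeats: RepeatAnnotation | None = None,
    read_length: int = 50,
    gc_window: int = 180,
    gc_window_policy: str = "fixed",
    span: float = 0.3,
    sample_size: int | None = None,
    scan_sample_size: int | None = 500_000,
    seed: int = 0,
    reciprocal_mappability: bool = True,
    mappability_cutoff: float = 0.5,
    stratum1_motifs=fragmentation.DEFAULT_STRATUM1_MOTIFS,
) -> tuple[pd.DataFrame, dict]:
    """Run one bias-correction protocol; returns (BinTable, stage report).

    The returned BinTable carries the corrected values in the ``corrected``
    column; the report logs each stage with its parameters and in/out counts.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; choose from {PROTOCOLS}")
    if protocol == "rm_loess" and repeats is None:
        raise ValueError("rm_loess requires a repeat annotation")
    needs_track = protocol != "rm_loess"
    if needs_track and track is None:
        logger.info("computing mappability track at k=%d", read_length)
        track = reference.compute_unique_positions(genome, read_length)

    scheme = BinScheme.from_genome(genome, bin_size)
    report: dict = {"protocol": protocol, "stages": [], "n_input_fragments": int(len(frags))}

    def stage(name: str, **info):
        report["stages"].append({"stage": name, **info})
        logger.info("stage %s: %s", name, info)

    if protocol == "rm_loess":
        kept = frag_ops.remove_repeat_fragments(frags, repeats)
        stage("remove_repeats", n_in=len(frags), n_out=len(kept),
              n_removed=kept.attrs["n_removed"])
        bins = frag_ops.assign_bins(kept, scheme, genome=genome, track=track)
        stage("assign_bins", n_assigned=bins.attrs["n_assigned"],
              n_dropped=bins.attrs["n_dropped"], bin_size=bin_size)
        bins, fit = gc_models.loess_gc_correct(bins, span=span, count_col="raw_count")
        stage("loess", span=span, n_intervals=len(fit.gc_mid))
        report["loess_fit"] = fit
        pred = bins["raw_count_loess_pred"]
        used = bins["valid"] & pred.notna()
        report["mad"] = gc_models.mad(bins.loc[used, "raw_count"], pred[used])
    elif protocol == "mapcorr_loess":
        bins = frag_ops.assign_bins(frags, scheme, genome=genome, track=track)
        stage("assign_bins", n_assigned=bins.attrs["n_assigned"],
              n_dropped=bins.attrs["n_dropped"], bin_size=bin_size)
        bins = frag_ops.mappability_correct(bins, cutoff=mappability_cutoff)
        stage("mappability_correct", cutoff=mappability_cutoff,
              n_valid=int(bins["valid"].sum()))
        bins, fit = gc_models.loess_gc_correct(bins, span=span, count_col="map_corrected")
        stage("loess", span=span, n_intervals=len(fit.gc_mid))
        report["loess_fit"] = fit
        pred = bins["map_corrected_loess_pred"]
        used = bins["valid"] & pred.notna()
        report["mad"] = gc_models.mad(bins.loc[used, "map_corrected"], pred[used])
    else:
        bins = frag_ops.assign_bins(frags, scheme, genome=genome, track=track)
        stage("assign_bins", n_assigned=bins.attrs["n_assigned"],
              n_dropped=bins.attrs["n_dropped"], bin_size=bin_size)
        if gc_window_policy == "tv-scan":
            curve = gc_models.gc_window_scan(
                frags, genome, track, sample_size=scan_sample_size, seed=seed
            )
            l = gc_models.select_gc_window(curve)
            report["tv_curve"] = curve
        else:
            l = gc_window
        stage("gc_window", policy=gc_window_policy, window_length=l)
        report["gc_window"] = l
        if protocol == "mapcorr_singlepos":
            strata = gc_models.single_position_fit(
                frags, genome, track, l, sample_size=sample_size, seed=seed, span=span
            )
            stage("single_position_fit", n_positions=strata.n_positions,
                  occupied_strata=int((strata.n > 0).sum()))
            bins = gc_models.single_position_correct(
                bins, strata, genome, track,
                reciprocal_mappability=reciprocal_mappability,
                mappability_cutoff=mappability_cutoff,
            )
            report["strata"] = strata
            stage("single_position_correct", n_valid=int(bins["valid"].sum()))
        else:
            assignment = fragmentation.assign_strata(frags, genome, stratum1_motifs)
            stage("assign_strata", w1=assignment.w1,
                  motifs=sorted(assignment.stratum1_motifs))
            bins = fragmentation.stratified_correct(
                bins, frags, genome, track, assignment, l,
                sample_size=sample_size, seed=seed, span=span,
                reciprocal_mappability=reciprocal_mappability,
                mappability_cutoff=mappability_cutoff,
            )
            report["assignment"] = assignment
            stage("stratified_correct", n_valid=int(bins["valid"].sum()))
    bins.attrs["protocol"] = protocol
    return bins, report


def _z_for_cohort(
    proportions: dict[str, float], reference_ids: list[str], threshold: float
) -> dict[str, aneuploidy.ZScoreResult]:
    """Z-scores against the euploid reference set (leave-one-out for members)."""
    out = {}
    for sid, p in proportions.items():
        if sid in reference_ids:
            ref_vals = [proportions[r] for r in reference_ids if r != sid]
        else:
            ref_vals = [proportions[r] for r in reference_ids]
        out[sid] = aneuploidy.z_score(p, ref_vals, threshold=threshold)
    return out


def evaluate_protocols(
    samples: dict[str, pd.DataFrame],
    truth: dict[str, bool],
    genome: GenomeSequence,
    *,
    track: MappabilityTrack | None = None,
    repeats: RepeatAnnotation | None = None,
    reference_ids: list[str] | None = None,
    target: str = "chr21",
    proportions=(1.0,),
    protocols=PROTOCOLS,
    bin_size: int = 50_000,
    gc_window: int = 180,
    sample_size: int | None = None,
    z_threshold: float = 3.0,
    seed: int = 0,
    **protocol_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coverage-reduction evaluation of the correction protocols.

    Each sample is subsampled to each proportion, run through each protocol,
    and scored against the euploid references processed identically at the
    same (proportion, protocol) cell.  Returns (per-sample table, summary
    table with accuracy, discriminatory distance and MAD where defined).
    """
    if reference_ids is None:
        reference_ids = [sid for sid, tri in truth.items() if not tri]
    if len(reference_ids) < 2:
        raise ValueError("need at least 2 euploid reference samples")
    rows, summary = [], []
    sample_ids = list(samples)
    for prop in proportions:
        subsampled = {
            sid: (
                samples[sid]
                if prop >= 1.0
                else frag_ops.subsample_fragments(samples[sid], prop, seed=seed * 1000 + i)
            )
            for i, sid in enumerate(sample_ids)
        }
        for protocol in protocols:
            props: dict[str, float] = {}
            mads: list[float] = []
            for sid in sample_ids:
                bins, report = run_protocol(
                    protocol,
                    genome,
                    subsampled[sid],
                    bin_size=bin_size,
                    track=track,
                    repeats=repeats,
                    gc_window=gc_window,
                    sample_size=sample_size,
                    seed=seed,
                    **protocol_kwargs,
                )
                props[sid] = aneuploidy.chrom_proportion(bins, target)
                if "mad" in report:
                    mads.append(report["mad"])
            zres = _z_for_cohort(props, reference_ids, z_threshold)
            for sid in sample_ids:
                rows.append(
                    {
                        "proportion": prop,
                        "protocol": protocol,
                        "sample": sid,
                        "p": props[sid],
                        "z": zres[sid].z,
                        "call": zres[sid].call,
                        "trisomy_truth": truth[sid],
                    }
                )
            calls = [zres[sid].call == "trisomy" for sid in sample_ids]
            truths = [truth[sid] for sid in sample_ids]
            z_norm = [zres[sid].z for sid in sample_ids if not truth[sid]]
            z_tri = [zres[sid].z for sid in sample_ids if truth[sid]]
            summary.append(
                {
                    "proportion": prop,
                    "protocol": protocol,
                    "accuracy": aneuploidy.accuracy(calls, truths),
                    "discriminatory_distance": (
                        aneuploidy.discriminatory_distance(z_norm, z_tri)
                        if z_norm and z_tri
                        else np.nan
                    ),
                    "mad": float(np.mean(mads)) if mads else np.nan,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(summary)
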