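"""End-to-end orchestration: match → QC filter → prune → taxonomy →
markers → profiles, with the kinetics fit running independently when
steady-state observations are provided.

Every threshold application is logged with before/after counts, and the
whole run is deterministic given its inputs and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import binmatch, io, markers
from .errors import DigestaError, PipelineStageError
from .kinetics import SolubilizationKinetics

logger = logging.getLogger("digesta")

__all__ = ["run_pipeline"]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except DigestaError as exc:
                raise PipelineStageError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: io.RunConfig) -> dict:
    """Run the full analysis described by ``config``; returns the report.

    Writes the edge list TSV, pruned-network GraphML, tracks JSON,
    per-track profile TSV and a JSON summary under ``config.output_dir``.
    Stages without inputs (no observations, no ANI table, ...) are skipped
    and noted in the report.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}}

    # ----- kinetics (independent) -----------------------------------------
    if config.observations_path:
        obs = _stage("kinetics")(io.read_observations_csv)(
            config.observations_path)
        model = _stage("kinetics")(SolubilizationKinetics.from_observations)(
            obs, config.c0)
        res = _stage("kinetics")(model.fit)()
        report["stages"]["kinetics"] = res.to_dict()
        (outdir / "kinetic_fit.json").write_text(
            json.dumps(res.to_dict(), indent=2) + "\n")
        io.write_points_tsv(model.points, outdir / "kinetic_points.tsv")
        logger.info("kinetics: k=%.4f f_r=%.4f from %d points",
                    res.k, res.f_r, res.nobs)

    if not config.bins_dir:
        report["stages"]["matching"] = "skipped (no bins_dir)"
        _write_summary(report, outdir)
        return report

    # ----- matching --------------------------------------------------------
    bins = _stage("read-bins")(io.read_bins_dir)(config.bins_dir)
    logger.info("read %d bins from %s", len(bins), config.bins_dir)
    edges = _stage("matching")(binmatch.match_all)(
        bins, config.prop_threshold, config.id_threshold)
    n_called = sum(e.is_same_organism for e in edges)
    logger.info("matching: %d cross-sample pairs, %d same-organism calls "
                "(prop>=%.2f, id>%.0f%%)", len(edges), n_called,
                config.prop_threshold, config.id_threshold)
    io.write_edges_tsv(edges, outdir / "edges.tsv")
    report["stages"]["matching"] = {
        "n_bins": len(bins), "n_pairs": len(edges),
        "n_same_organism": n_called}

    # ----- QC filter --------------------------------------------------------
    qc = _stage("qc-filter")(io.read_qc_table)(config.qc_path)
    called = [e for e in edges if e.is_same_organism]
    kept = _stage("qc-filter")(binmatch.qc_filter)(
        called, qc, config.max_contamination, config.min_completeness)
    logger.info("qc-filter: %d -> %d edges (contamination<=%.0f%%, "
                "completeness>=%.0f%%)", len(called), len(kept),
                config.max_contamination, config.min_completeness)
    report["stages"]["qc_filter"] = {
        "edges_before": len(called), "edges_after": len(kept)}

    # ----- pruning / tracks -------------------------------------------------
    tracks = _stage("tracks")(binmatch.build_tracks)(
        kept, config.min_edges, config.min_samples_exclusive)
    graph = binmatch.tracks_graph(kept, config.min_edges)
    io.write_graphml(graph, outdir / "network.graphml")
    logger.info("tracks: %d components span >%d samples (min %d edges)",
                len(tracks), config.min_samples_exclusive, config.min_edges)
    report["stages"]["tracks"] = {
        "n_tracks": len(tracks),
        "n_bins_retained": graph.number_of_nodes()}

    # ----- taxonomy ---------------------------------------------------------
    if config.ani_path:
        ani = _stage("taxonomy")(io.read_ani_table)(config.ani_path)
        for t in tracks:
            call = binmatch.assign_taxonomy(
                t, ani, fallback_label=t.track_id,
                species_threshold=config.species_ani_threshold)
            t.taxonomy_label = call.label
        report["stages"]["taxonomy"] = "assigned from ANI"
    else:
        report["stages"]["taxonomy"] = "skipped (no ANI table)"

    # ----- abundance --------------------------------------------------------
    if config.coverage_path:
        cov = _stage("abundance")(io.read_coverage_table)(config.coverage_path)
        for t in tracks:
            _, mean = binmatch.track_relative_abundance(t, cov)
            t.mean_relative_abundance = mean
        report["stages"]["abundance"] = "computed from coverage"
    else:
        report["stages"]["abundance"] = "skipped (no coverage table)"

    # ----- markers / profiles ----------------------------------------------
    if config.annotations_path:
        ann = _stage("markers")(io.read_annotation_table)(
            config.annotations_path)
        for t in tracks:
            t.consensus_markers = markers.consensus_markers(t, ann)
        profiles = markers.profile_tracks(tracks, ann)
        profiles.to_csv(outdir / "track_profiles.tsv", sep="\t", index=False)
        report["stages"]["markers"] = {"n_profiled": len(tracks)}
    else:
        report["stages"]["markers"] = "skipped (no annotations)"

    io.write_tracks_json(tracks, outdir / "tracks.json")
    report["tracks"] = [
        {"track_id": t.track_id, "n_bins": len(t.member_bins),
         "samples_spanned": t.samples_spanned,
         "taxonomy_label": t.taxonomy_label,
         "mean_relative_abundance": t.mean_relative_abundance}
        for t in tracks]
    _write_summary(report, outdir)
    return report


def _write_summary(report: dict, outdir: Path) -> None:
    (outdir / "summary.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
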