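"""Readers, writers and run configuration.

Interchange dialect: tab-separated UTF-8 tables with a header row and "."
decimals, protein FASTA per bin (file stem = bin id, record id = protein
id), GraphML for the pruned match network, JSON for reports.  Annotation
coordinates are 1-based inclusive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from .binmatch import Bin, BinQC, MatchEdge, OrganismTrack
from .errors import ConfigError, DomainError, SchemaError
from .kinetics import FeedstockComposition, KineticPoint, SteadyStateObservation

logger = logging.getLogger("digesta")

__all__ = [
    "read_protein_fasta",
    "write_protein_fasta",
    "read_bins_dir",
    "read_qc_table",
    "read_annotation_table",
    "read_ani_table",
    "read_coverage_table",
    "read_observations_csv",
    "write_observations_csv",
    "write_points_tsv",
    "write_edges_tsv",
    "read_edges_tsv",
    "write_tracks_json",
    "write_graphml",
    "write_qc_table",
    "write_coverage_table",
    "write_annotation_table",
    "RunConfig",
    "load_run_config",
    "feed_composition_from_mapping",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_protein_fasta(path: str | Path, bin_id: str | None = None,
                       sample_id: str | None = None) -> Bin:
    """Read one bin's protein FASTA.

    The bin id defaults to the file stem and the sample id to the part of
    the bin id before the first ".", the convention used by the synthetic
    writers.  Sequence order is preserved; duplicate record ids are
    rejected.
    """
    from Bio import SeqIO

    path = Path(path)
    bin_id = bin_id if bin_id is not None else path.stem
    if sample_id is None:
        sample_id = bin_id.split(".", 1)[0]
    proteins = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SchemaError(
                f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        proteins.append((rec.id, str(rec.seq)))
    if not proteins:
        raise SchemaError(f"no FASTA records in {path}")
    return Bin(bin_id=bin_id, sample_id=sample_id, proteins=tuple(proteins))


def write_protein_fasta(bin_: Bin, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for pid, seq in bin_.proteins:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_bins_dir(path: str | Path,
                  samples: Mapping[str, str] | None = None) -> list[Bin]:
    """Read every ``*.faa`` / ``*.fasta`` file in a directory as a bin.

    ``samples`` optionally maps bin ids to sample ids, overriding the
    ``<sample>.<rest>`` file-stem convention.
    """
    path = Path(path)
    bins = []
    for f in sorted(path.glob("*.faa")) + sorted(path.glob("*.fasta")):
        sid = samples.get(f.stem) if samples else None
        bins.append(read_protein_fasta(f, sample_id=sid))
    if not bins:
        raise SchemaError(f"no *.faa or *.fasta files under {path}")
    return bins


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, required: dict[str, type],
                sep: str = "\t") -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty (not even a header)")
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path} lacks required column(s) {sorted(missing)}")
    if df.empty:
        logger.warning("%s has a header but no rows", path)
    for col, typ in required.items():
        if typ is float or typ is int:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise SchemaError(
                    f"{path}: non-numeric value in column {col!r} at row(s) "
                    f"{[int(b) + 2 for b in bad[:5]]} (1-based incl. header)")
            df[col] = coerced
    return df


def read_qc_table(path: str | Path) -> list[BinQC]:
    """CheckM-like QC table: bin_id, completeness, contamination[, strain_heterogeneity]."""
    df = _read_table(path, {"bin_id": str, "completeness": float,
                            "contamination": float})
    het = df["strain_heterogeneity"] if "strain_heterogeneity" in df.columns \
        else pd.Series(0.0, index=df.index)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(BinQC(bin_id=str(row["bin_id"]),
                             completeness=float(row["completeness"]),
                             contamination=float(row["contamination"]),
                             strain_heterogeneity=float(het[i])))
        except DomainError as exc:
            raise SchemaError(f"{path} row {int(i) + 2}: {exc}") from exc
    return out


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Domain annotations: protein_id, bin_id, marker_id, category, start, end."""
    df = _read_table(path, {"protein_id": str, "bin_id": str,
                            "marker_id": str, "category": str,
                            "start": int, "end": int})
    bad = df[df["start"] > df["end"]]
    if len(bad):
        raise SchemaError(
            f"{path}: start > end at row(s) {[int(i) + 2 for i in bad.index[:5]]}")
    return df


def read_ani_table(path: str | Path) -> pd.DataFrame:
    """ANI records: bin_id, reference, plus one or more ani_* columns."""
    df = _read_table(path, {"bin_id": str, "reference": str})
    ani_cols = [c for c in df.columns if c.startswith("ani")]
    if not ani_cols:
        raise SchemaError(f"{path} has no ani_* column")
    for c in ani_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def read_coverage_table(path: str | Path) -> pd.DataFrame:
    """Coverage masses: bin_id, sample_id, coverage_mass."""
    df = _read_table(path, {"bin_id": str, "sample_id": str,
                            "coverage_mass": float})
    if (df["coverage_mass"] < 0).any():
        raise SchemaError(f"{path}: negative coverage_mass")
    return df


_OBS_COLUMNS = ["reactor_id", "rt_days", "fcs_total", "fcs_glucan",
                "fcs_xylan", "ch4_frac", "co2_frac", "vfa_g_per_l", "ph"]


def read_observations_csv(path: str | Path) -> list[SteadyStateObservation]:
    """Steady-state observation CSV (comma-separated, documented header)."""
    df = _read_table(path, {"reactor_id": str, "rt_days": float,
                            "fcs_total": float}, sep=",")
    out = []
    for i, row in df.iterrows():
        def opt(col: str) -> float:
            return float(row[col]) if col in df.columns and pd.notna(row[col]) \
                else float("nan")
        try:
            out.append(SteadyStateObservation(
                rt_days=float(row["rt_days"]),
                fcs_total=float(row["fcs_total"]),
                fcs_glucan=opt("fcs_glucan"), fcs_xylan=opt("fcs_xylan"),
                ch4_frac=opt("ch4_frac"), co2_frac=opt("co2_frac"),
                vfa_g_per_l=opt("vfa_g_per_l"), ph=opt("ph"),
                reactor_id=str(row["reactor_id"])))
        except DomainError as exc:
            raise SchemaError(f"{path} row {int(i) + 2}: {exc}") from exc
    return out


def write_observations_csv(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in _OBS_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def write_points_tsv(points: Sequence[KineticPoint], path: str | Path) -> None:
    pd.DataFrame(
        [{"rt_days": p.rt_days, "c_unutilized": p.c_unutilized,
          "rate": p.rate} for p in points]
    ).to_csv(path, sep="\t", index=False)


def write_edges_tsv(edges: Iterable[MatchEdge], path: str | Path) -> None:
    pd.DataFrame(
        [{"bin_a": e.bin_a, "bin_b": e.bin_b,
          "sample_a": e.sample_a, "sample_b": e.sample_b,
          "prop_a_to_b": e.prop_a_to_b, "prop_b_to_a": e.prop_b_to_a,
          "is_same_organism": e.is_same_organism} for e in edges]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_edges_tsv(path: str | Path) -> list[MatchEdge]:
    df = _read_table(path, {"bin_a": str, "bin_b": str, "sample_a": str,
                            "sample_b": str, "prop_a_to_b": float,
                            "prop_b_to_a": float})
    return [MatchEdge(bin_a=str(r.bin_a), bin_b=str(r.bin_b),
                      sample_a=str(r.sample_a), sample_b=str(r.sample_b),
                      prop_a_to_b=float(r.prop_a_to_b),
                      prop_b_to_a=float(r.prop_b_to_a),
                      is_same_organism=bool(r.is_same_organism))
            for r in df.itertuples(index=False)]


def write_tracks_json(tracks: Sequence[OrganismTrack], path: str | Path) -> None:
    payload = [{
        "track_id": t.track_id,
        "member_bins": list(t.member_bins),
        "samples_spanned": t.samples_spanned,
        "taxonomy_label": t.taxonomy_label,
        "mean_relative_abundance": t.mean_relative_abundance,
        "consensus_markers": list(t.consensus_markers),
    } for t in tracks]
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def write_qc_table(qc: Sequence[BinQC], path: str | Path) -> None:
    pd.DataFrame(
        [{"bin_id": q.bin_id, "completeness": q.completeness,
          "contamination": q.contamination,
          "strain_heterogeneity": q.strain_heterogeneity} for q in qc]
    ).to_csv(path, sep="\t", index=False)


def write_coverage_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_annotation_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_THRESHOLD_RANGES = {
    "prop_threshold": (0.0, 1.0),
    "id_threshold": (0.0, 100.0),
    "min_completeness": (0.0, 100.0),
    "max_contamination": (0.0, 100.0),
    "min_edges": (0, 1000),
    "min_samples_exclusive": (0, 1000),
    "species_ani_threshold": (0.0, 100.0),
    "pathway_partial_threshold": (0.0, 1.0),
}


@dataclass
class RunConfig:
    """Paths, thresholds and reproducibility knobs for a pipeline run.

    Threshold defaults are the operating values of the matching rules:
    proportion 0.70, identity 90 %, completeness ≥ 40 %, contamination
    ≤ 20 %, ≥ 3 edges, > 3 samples, species ANI 95 %, pathway band 0.70.
    """

    bins_dir: str = ""
    qc_path: str = ""
    annotations_path: str = ""
    ani_path: str = ""
    coverage_path: str = ""
    observations_path: str = ""
    c0: float = 17.3
    prop_threshold: float = 0.70
    id_threshold: float = 90.0
    min_completeness: float = 40.0
    max_contamination: float = 20.0
    min_edges: int = 3
    min_samples_exclusive: int = 3
    species_ani_threshold: float = 95.0
    pathway_partial_threshold: float = 0.70
    seed: int = 0
    output_dir: str = "digesta_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        problems = []
        for name, (lo, hi) in _THRESHOLD_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                problems.append(f"{name}={v!r} outside [{lo}, {hi}]")
        if problems:
            raise ConfigError("; ".join(problems))


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must hold a mapping")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def feed_composition_from_mapping(raw: Mapping) -> FeedstockComposition:
    """Build a feed composition from a config block with percent fields.

    Accepts the feed-characterization field names (``glucose_pct``,
    ``xylose_pct``, ``arabinose_pct``, ``moisture_pct``, ``ash_pct``,
    ``cod_g_per_g``), all on an as-is basis.
    """
    try:
        return FeedstockComposition(
            glucan_frac=float(raw["glucose_pct"]) / 100.0,
            xylan_frac=float(raw["xylose_pct"]) / 100.0,
            arabinan_frac=float(raw["arabinose_pct"]) / 100.0,
            moisture_frac=float(raw.get("moisture_pct", 0.0)) / 100.0,
            ash_frac=float(raw.get("ash_pct", 0.0)) / 100.0,
            cod_per_gram=float(raw.get("cod_g_per_g", 1.0)),
        )
    except KeyError as exc:
        raise ConfigError(f"feed composition lacks field {exc}") from exc
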