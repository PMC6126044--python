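"""Consensus genetic markers, CAZyme inventories and pathway completeness.

Once bins from different samples are grouped into organism tracks, the
genetic potential of each organism is read off its member bins:

* a marker (CAZy family, pfam accession or KO id) is credited to the
  organism when a strict majority of its member bins carry it — a single
  incomplete bin cannot erase a marker, and a single contaminated bin
  cannot introduce one;
* a pathway marker set is *complete* when every member is present by
  consensus, *partial_high* when more than 70 % (but not all) members are
  present, otherwise *incomplete*;
* carbohydrate-active enzyme (CAZyme) inventories are summarized per
  track — total domains normalized by the number of member bins, family
  diversity, glycoside hydrolase count, modular enzymes (≥ 2 CAZy domains
  on one protein), dockerins/cohesins (cellulosome parts) and the GH48
  family diagnostic of crystalline-cellulose degraders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .binmatch import OrganismTrack
from .errors import DomainError

__all__ = [
    "DomainAnnotation",
    "MarkerSet",
    "CazymeProfile",
    "DEFAULT_DOCKERIN_MARKERS",
    "DEFAULT_COHESIN_MARKERS",
    "DEFAULT_MARKER_SETS",
    "consensus_marker_presence",
    "consensus_markers",
    "pathway_completeness",
    "cazyme_profile",
    "modular_architecture",
    "Architecture",
]


@dataclass(frozen=True)
class DomainAnnotation:
    """One domain hit on one protein, 1-based inclusive coordinates."""

    protein_id: str
    bin_id: str
    marker_id: str
    category: str            # "CAZy" | "pfam" | "KO"
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise DomainError("marker_id must be non-empty")
        if self.start > self.end:
            raise DomainError(
                f"start {self.start} > end {self.end} on {self.protein_id!r}")


@dataclass(frozen=True)
class MarkerSet:
    """A named set of marker ids standing for one metabolic capability."""

    set_id: str
    members: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise DomainError(f"marker set {self.set_id!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise DomainError(f"marker set {self.set_id!r} has duplicate members")


@dataclass(frozen=True)
class CazymeProfile:
    """Per-track CAZyme inventory (counts normalized per member bin)."""

    total_domains_normalized: float
    n_families: int
    n_gh_domains: int
    n_modular_enzymes: int
    n_dockerins: int
    n_cohesins: int
    has_gh48: bool

    def __post_init__(self) -> None:
        for name in ("total_domains_normalized", "n_families", "n_gh_domains",
                     "n_modular_enzymes", "n_dockerins", "n_cohesins"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.has_gh48 and self.n_gh_domains < 1:
            raise DomainError("has_gh48 implies at least one GH domain")


#: Standard pfam accessions for the cellulosome assembly modules.
DEFAULT_DOCKERIN_MARKERS = frozenset({"PF00404", "DOC"})
DEFAULT_COHESIN_MARKERS = frozenset({"PF00963", "COH"})

# Minimal default pathway marker sets.  The xylose-catabolism, acetate-
# oxidation and butyrate-oxidation anchors (PF01261 xylose isomerase,
# PF00370/PF02782 xylulokinase, PF01268 formyltetrahydrofolate synthetase,
# PF04216 FDH accessory) are completed with standard accessions for the
# remaining pathway steps.  These defaults exist so the pipeline runs out
# of the box; real studies should supply their own curated sets.
DEFAULT_MARKER_SETS: dict[str, MarkerSet] = {
    ms.set_id: ms for ms in (
        MarkerSet("xylose_catabolism",
                  ("PF01261", "PF00370", "PF02782"),
                  source="xylose isomerase + xylulokinase (FGGY N/C)"),
        MarkerSet("acetate_oxidation",
                  ("PF01268", "PF00763", "PF02219"),
                  source="reverse Wood-Ljungdahl: FTHFS, methylene-THF "
                         "dehydrogenase/cyclohydrolase, methylene-THF reductase"),
        MarkerSet("propionate_oxidation",
                  ("PF01642", "PF01144"),
                  source="methylmalonyl-CoA mutase, CoA transferase"),
        MarkerSet("butyrate_oxidation",
                  ("PF00441", "PF02770", "PF04216"),
                  source="acyl-CoA dehydrogenase C/M, FDH accessory"),
        MarkerSet("hydrogenotrophic_methanogenesis",
                  ("PF02249", "PF02745"),
                  source="methyl-coenzyme M reductase alpha subunits"),
        MarkerSet("acetoclastic_methanogenesis",
                  ("PF00871", "PF01515", "PF02249"),
                  source="acetate kinase, phosphotransacetylase, MCR alpha"),
    )
}


def _bins_with_marker(annotations: pd.DataFrame, marker_id: str) -> set[str]:
    hit = annotations[annotations["marker_id"] == marker_id]
    return set(hit["bin_id"].unique())


def consensus_marker_presence(track: OrganismTrack,
                              annotations: pd.DataFrame,
                              marker_id: str) -> bool:
    """True iff a strict majority of member bins carry ≥ 1 hit of the marker.

    Exactly half is *not* a majority: a 2-of-4 tie counts as absent.
    """
    if len(track.member_bins) < 1:
        raise DomainError(f"track {track.track_id!r} has no member bins")
    carriers = _bins_with_marker(annotations, marker_id) & set(track.member_bins)
    return len(carriers) * 2 > len(track.member_bins)


def consensus_markers(track: OrganismTrack,
                      annotations: pd.DataFrame) -> tuple[str, ...]:
    """All marker ids present in the track by the majority rule, sorted."""
    sub = annotations[annotations["bin_id"].isin(track.member_bins)]
    present = [m for m in sorted(sub["marker_id"].unique())
               if consensus_marker_presence(track, sub, m)]
    return tuple(present)


def pathway_completeness(track: OrganismTrack,
                         annotations: pd.DataFrame,
                         marker_set: MarkerSet,
                         partial_threshold: float = 0.70
                         ) -> tuple[float, str]:
    """Fraction of the set's markers present by consensus, and its class.

    ``complete`` iff the fraction is 1; ``partial_high`` iff it is strictly
    between ``partial_threshold`` and 1 (the band is *greater than* 70 %,
    so exactly 0.7 is incomplete); else ``incomplete``.
    """
    n_present = sum(
        consensus_marker_presence(track, annotations, m)
        for m in marker_set.members)
    fraction = n_present / len(marker_set.members)
    if fraction == 1.0:
        status = "complete"
    elif fraction > partial_threshold:
        status = "partial_high"
    else:
        status = "incomplete"
    return fraction, status


def cazyme_profile(track: OrganismTrack,
                   annotations: pd.DataFrame,
                   dockerin_markers: Iterable[str] = DEFAULT_DOCKERIN_MARKERS,
                   cohesin_markers: Iterable[str] = DEFAULT_COHESIN_MARKERS,
                   gh48_markers: Iterable[str] = ("GH48",),
                   ) -> CazymeProfile:
    """CAZyme inventory of a track from its CAZy-category annotations.

    Total domain counts are normalized by the number of member bins so
    tracks spanning different numbers of samples stay comparable.  A
    protein is *modular* when it carries at least two CAZy-category
    domains.  Dockerin and cohesin modules are identified by configurable
    marker ids (standard pfam accessions by default) and counted within
    the total; glycoside hydrolase domains are the ``GH*`` families.
    An empty annotation set yields an all-zero profile.
    """
    dockerin_markers = set(dockerin_markers)
    cohesin_markers = set(cohesin_markers)
    gh48_markers = set(gh48_markers)
    sub = annotations[
        annotations["bin_id"].isin(track.member_bins)
        & (annotations["category"] == "CAZy")]
    n_bins = len(track.member_bins)
    if sub.empty:
        return CazymeProfile(0.0, 0, 0, 0, 0, 0, False)
    total = len(sub)
    families = set(sub["marker_id"].unique())
    gh = sub[sub["marker_id"].str.startswith("GH")]
    per_protein = sub.groupby("protein_id").size()
    n_modular = int((per_protein >= 2).sum())
    n_dock = int(sub["marker_id"].isin(dockerin_markers).sum())
    n_coh = int(sub["marker_id"].isin(cohesin_markers).sum())
    return CazymeProfile(
        total_domains_normalized=total / n_bins,
        n_families=len(families),
        n_gh_domains=len(gh),
        n_modular_enzymes=n_modular,
        n_dockerins=n_dock,
        n_cohesins=n_coh,
        has_gh48=bool(sub["marker_id"].isin(gh48_markers).any()),
    )


class Architecture(NamedTuple):
    architecture: str
    annotated: bool


def modular_architecture(protein_id: str,
                         annotations: pd.DataFrame) -> Architecture:
    """Domain ids of one protein joined by "-" in N→C order.

    Domains are ordered by ascending start coordinate; at equal starts the
    longer domain is listed first.  An unannotated protein yields an empty
    architecture with ``annotated=False``.
    """
    sub = annotations[annotations["protein_id"] == protein_id]
    if sub.empty:
        return Architecture("", False)
    rows = sorted(sub.itertuples(index=False),
                  key=lambda r: (r.start, -(r.end - r.start)))
    return Architecture("-".join(r.marker_id for r in rows), True)


def profile_tracks(tracks: Iterable[OrganismTrack],
                   annotations: pd.DataFrame,
                   marker_sets: Mapping[str, MarkerSet] = DEFAULT_MARKER_SETS,
                   ) -> pd.DataFrame:
    """One summary row per track: abundance, CAZyme counts, pathway status.

    The tabular rendition of a community functional-profile figure:
    CAZyme columns plus a fraction and status column per pathway set.
    """
    records = []
    for track in tracks:
        prof = cazyme_profile(track, annotations)
        row: dict[str, object] = {
            "track_id": track.track_id,
            "taxonomy": track.taxonomy_label,
            "n_bins": len(track.member_bins),
            "samples_spanned": track.samples_spanned,
            "mean_relative_abundance": track.mean_relative_abundance,
            "cazyme_domains_per_bin": prof.total_domains_normalized,
            "cazyme_families": prof.n_families,
            "gh_domains": prof.n_gh_domains,
            "modular_enzymes": prof.n_modular_enzymes,
            "dockerins": prof.n_dockerins,
            "cohesins": prof.n_cohesins,
            "has_gh48": prof.has_gh48,
        }
        for set_id, mset in marker_sets.items():
            fraction, status = pathway_completeness(track, annotations, mset)
            row[f"{set_id}_fraction"] = fraction
            row[f"{set_id}_status"] = status
        records.append(row)
    return pd.DataFrame.from_records(records)
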