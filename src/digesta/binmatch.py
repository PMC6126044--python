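"""Cross-metagenome genome-bin matching.

Bins assembled independently from different metagenome samples often
represent the same organism.  This module decides which, by comparing the
predicted proteomes of every cross-sample bin pair:

1. every query protein is assigned its best-identity hit in the target bin
   (exact local alignment, BLOSUM62, affine gaps, with a lossless k-mer
   prefilter for candidate generation);
2. two bins are called the *same organism* when at least 70 % of either
   bin's proteins have a best hit above 90 % identity;
3. edges failing bin quality control (contamination > 20 % or completeness
   < 40 %) are removed;
4. the match network is pruned — bins connected by fewer than three edges
   are dropped, iteratively — and connected components spanning more than
   three samples become organism tracks.

Tracks then receive a taxonomy call from average-nucleotide-identity
records against reference genomes (> 95 % delimiting a species) and a
relative abundance from per-bin coverage mass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DomainError, MissingQCError

__all__ = [
    "AMINO_ACIDS",
    "Bin",
    "BinQC",
    "MatchEdge",
    "OrganismTrack",
    "TaxonomyCall",
    "protein_identity",
    "best_hit_identities",
    "best_hit_proportion",
    "same_organism",
    "match_all",
    "qc_filter",
    "build_tracks",
    "assign_taxonomy",
    "track_relative_abundance",
    "mapping_accuracy",
    "tracks_graph",
]

#: The 20 proteinogenic amino acids plus the ambiguity code X.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_AA = frozenset(AMINO_ACIDS + "X")

_KMER_K = 8
# base-32 integer encoding of k-mers; 32**8 < 2**63 so int64 is safe
_AA_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS + "X")}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class Bin:
    """One genome bin: its id, metagenome of origin, and predicted proteins.

    ``proteins`` is an ordered sequence of ``(protein_id, sequence)`` pairs;
    order is preserved, ids must be unique within the bin and sequences are
    over the 20-letter amino-acid alphabet plus X.
    """

    bin_id: str
    sample_id: str
    proteins: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        self.proteins = tuple((pid, seq.upper()) for pid, seq in self.proteins)
        if len(self.proteins) < 1:
            raise DomainError(f"bin {self.bin_id!r} has no proteins")
        ids = [pid for pid, _ in self.proteins]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise DomainError(
                f"bin {self.bin_id!r} has duplicate protein ids: {sorted(dupes)[:5]}")
        for pid, seq in self.proteins:
            if not seq:
                raise DomainError(f"protein {pid!r} in bin {self.bin_id!r} is empty")
            bad = set(seq) - _VALID_AA
            if bad:
                raise DomainError(
                    f"protein {pid!r} in bin {self.bin_id!r} has invalid "
                    f"residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.proteins)

    @cached_property
    def _seq_set(self) -> frozenset:
        return frozenset(seq for _, seq in self.proteins)

    @cached_property
    def _protein_kmers(self) -> tuple[np.ndarray, ...]:
        return tuple(_encode_kmers(seq) for _, seq in self.proteins)

    @cached_property
    def _kmer_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (kmer, protein index) arrays for candidate lookup."""
        kmers, pidx = [], []
        for i, km in enumerate(self._protein_kmers):
            kmers.append(km)
            pidx.append(np.full(len(km), i, dtype=np.int64))
        km = np.concatenate(kmers)
        pi = np.concatenate(pidx)
        order = np.argsort(km, kind="stable")
        return km[order], pi[order]


@dataclass(frozen=True)
class BinQC:
    """CheckM-style quality metrics for one bin, in percent."""

    bin_id: str
    completeness: float
    contamination: float
    strain_heterogeneity: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise DomainError(
                f"completeness={self.completeness!r} outside [0, 100] "
                f"for bin {self.bin_id!r}")
        if self.contamination < 0:
            raise DomainError(
                f"contamination={self.contamination!r} must be >= 0 "
                f"for bin {self.bin_id!r}")


@dataclass(frozen=True)
class MatchEdge:
    """Directed best-hit proportions between two bins from different samples."""

    bin_a: str
    bin_b: str
    sample_a: str
    sample_b: str
    prop_a_to_b: float
    prop_b_to_a: float
    is_same_organism: bool

    def __post_init__(self) -> None:
        if self.sample_a == self.sample_b:
            raise DomainError(
                f"edge {self.bin_a!r}–{self.bin_b!r} joins bins of one sample "
                f"{self.sample_a!r}; cross-sample pairs only")
        for name in ("prop_a_to_b", "prop_b_to_a"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name}={v!r} outside [0, 1]")


@dataclass
class OrganismTrack:
    """A pruned network component: one organism followed across samples."""

    track_id: str
    member_bins: tuple[str, ...]
    samples_spanned: int
    taxonomy_label: str = ""
    mean_relative_abundance: float = float("nan")
    consensus_markers: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class TaxonomyCall:
    """Outcome of the ANI species-assignment rule for one track."""

    label: str
    flag: str            # "ani" | "no-ani" | "below-threshold" | "ambiguous"
    best_reference: str = ""
    best_ani: float = float("nan")


# ---------------------------------------------------------------------------
# protein identity engine
# ---------------------------------------------------------------------------

def _make_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = None


def _aligner():
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = _make_aligner()
    return _ALIGNER


def protein_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity between two protein sequences.

    The best-scoring local alignment (BLOSUM62, gap open −11, extend −1) is
    computed exactly; identity is the number of identical aligned residues
    divided by ``max(alignment columns, min(len_a, len_b))`` × 100.  When
    the alignment spans the shorter sequence this is exactly identities
    over the local-alignment length; the floor on the denominator prevents
    a short spurious perfect match between unrelated sequences from
    reporting a high identity.  Symmetric, and 100 for identical inputs.
    """
    if not seq_a or not seq_b:
        raise DomainError("protein sequences must be non-empty")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if seq_a == seq_b:
        return 100.0
    aln = _aligner().align(seq_a, seq_b)[0]
    c = aln.counts()
    columns = c.identities + c.mismatches + c.gaps
    denom = max(columns, min(len(seq_a), len(seq_b)))
    return 100.0 * c.identities / denom


_CODE_LUT = np.zeros(128, dtype=np.int64)
for _aa, _i in _AA_CODE.items():
    _CODE_LUT[ord(_aa)] = _i


def _encode_kmers(seq: str, k: int = _KMER_K) -> np.ndarray:
    """All overlapping k-mers of ``seq`` encoded as int64 (base 32)."""
    codes = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(len(codes) - k + 1, dtype=np.int64)
    for j in range(k):
        out = (out << 5) | codes[j:len(codes) - k + 1 + j]
    return np.unique(out)


def _candidate_indices(query_kmers: np.ndarray, target: Bin) -> np.ndarray:
    """Target protein indices sharing at least one 8-mer with the query.

    Pigeonhole argument: at >90 % identity over an alignment spanning the
    shorter sequence of length L, at most ⌊0.1 L⌋ columns differ, so an
    exact run of length ≥ (L − e)/(e + 1) ≥ 8 exists for L ≥ 89.  The
    filter is therefore lossless above the 90 % threshold for the protein
    lengths this package generates (≥ 100 aa).
    """
    qk = query_kmers
    if len(qk) == 0:
        return np.empty(0, dtype=np.int64)
    tk, tp = target._kmer_index
    left = np.searchsorted(tk, qk, side="left")
    right = np.searchsorted(tk, qk, side="right")
    hits = [tp[l:r] for l, r in zip(left, right) if r > l]
    if not hits:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(hits))


def best_hit_identities(query: Bin, target: Bin) -> np.ndarray:
    """Best-hit percent identity in ``target`` for each query protein.

    Proteins with no candidate hit (no shared 8-mer) score 0; identical
    sequences short-circuit to 100 without alignment.  The candidate
    lookup is batched: one sorted-array search over all query k-mers per
    bin pair.
    """
    out = np.zeros(len(query), dtype=float)
    kmer_arrays = query._protein_kmers
    counts = np.array([len(a) for a in kmer_arrays])
    offsets = np.concatenate([[0], np.cumsum(counts)])
    all_kmers = (np.concatenate(kmer_arrays) if counts.sum()
                 else np.empty(0, dtype=np.int64))
    tk, tp = target._kmer_index
    left = np.searchsorted(tk, all_kmers, side="left")
    right = np.searchsorted(tk, all_kmers, side="right")
    hit = right > left
    for i, (_, qseq) in enumerate(query.proteins):
        if qseq in target._seq_set:
            out[i] = 100.0
            continue
        lo, hi = offsets[i], offsets[i + 1]
        if not hit[lo:hi].any():
            continue
        idx = np.nonzero(hit[lo:hi])[0] + lo
        cands = np.unique(np.concatenate(
            [tp[left[j]:right[j]] for j in idx]))
        best = 0.0
        for j in cands:
            ident = protein_identity(qseq, target.proteins[int(j)][1])
            if ident > best:
                best = ident
        out[i] = best
    return out


def best_hit_proportion(query: Bin, target: Bin,
                        id_threshold: float = 90.0) -> float:
    """Fraction of query proteins whose best hit in target is > id_threshold.

    Query proteins without any hit count in the denominator: the rule
    divides by the query's full protein count.
    """
    if query.sample_id == target.sample_id:
        raise DomainError(
            f"bins {query.bin_id!r} and {target.bin_id!r} are from the same "
            f"sample {query.sample_id!r}; only cross-sample pairs are compared")
    idents = best_hit_identities(query, target)
    return float(np.count_nonzero(idents > id_threshold)) / len(query)


def same_organism(bin_a: Bin, bin_b: Bin,
                  prop_threshold: float = 0.70,
                  id_threshold: float = 90.0) -> MatchEdge:
    """Apply the same-organism rule to a cross-sample bin pair.

    Both directional proportions are computed; the pair is called the same
    organism when either direction reaches ``prop_threshold``, so that a
    near-complete bin matches its own fragment (the lower-coverage,
    lower-completeness rendition of the same genome).
    """
    p_ab = best_hit_proportion(bin_a, bin_b, id_threshold)
    p_ba = best_hit_proportion(bin_b, bin_a, id_threshold)
    return MatchEdge(
        bin_a=bin_a.bin_id, bin_b=bin_b.bin_id,
        sample_a=bin_a.sample_id, sample_b=bin_b.sample_id,
        prop_a_to_b=p_ab, prop_b_to_a=p_ba,
        is_same_organism=max(p_ab, p_ba) >= prop_threshold)


def match_all(bins: Sequence[Bin],
              prop_threshold: float = 0.70,
              id_threshold: float = 90.0) -> list[MatchEdge]:
    """Same-organism calls for every cross-sample pair of bins.

    Returns one edge per unordered cross-sample pair, in deterministic
    (sorted bin id) order; same-sample pairs are never compared.
    """
    ordered = sorted(bins, key=lambda b: b.bin_id)
    edges = []
    for a, b in itertools.combinations(ordered, 2):
        if a.sample_id == b.sample_id:
            continue
        edges.append(same_organism(a, b, prop_threshold, id_threshold))
    return edges


# ---------------------------------------------------------------------------
# network filtering and track assembly
# ---------------------------------------------------------------------------

def qc_filter(edges: Iterable[MatchEdge],
              qc: Mapping[str, BinQC] | Iterable[BinQC],
              max_contamination: float = 20.0,
              min_completeness: float = 40.0) -> list[MatchEdge]:
    """Drop edges whose endpoints fail bin quality control.

    An edge survives iff both bins have contamination ≤ ``max_contamination``
    and completeness ≥ ``min_completeness``; boundary values survive
    (the removal rule is *greater than* 20 % contamination / *less than*
    40 % completeness).  A referenced bin without a QC record is an error.
    """
    if not isinstance(qc, Mapping):
        qc = {q.bin_id: q for q in qc}

    def passes(bin_id: str) -> bool:
        if bin_id not in qc:
            raise MissingQCError(bin_id)
        rec = qc[bin_id]
        return (rec.contamination <= max_contamination
                and rec.completeness >= min_completeness)

    return [e for e in edges if passes(e.bin_a) and passes(e.bin_b)]


def _prune_graph(graph: nx.Graph, min_edges: int) -> nx.Graph:
    """Iteratively remove nodes of degree < min_edges until stable."""
    g = graph.copy()
    while True:
        weak = [n for n, d in g.degree() if d < min_edges]
        if not weak:
            return g
        g.remove_nodes_from(weak)


def build_tracks(edges: Iterable[MatchEdge],
                 min_edges: int = 3,
                 min_samples_exclusive: int = 3) -> list[OrganismTrack]:
    """Assemble organism tracks from QC-filtered same-organism edges.

    Bins connected by fewer than ``min_edges`` passing edges are removed,
    iteratively to a fixed point (a single pass would leave bins whose
    support itself disappeared).  The surviving connected components are
    kept when they span strictly more than ``min_samples_exclusive``
    distinct samples.  An empty result is valid.
    """
    g = nx.Graph()
    for e in edges:
        if not e.is_same_organism:
            continue
        g.add_node(e.bin_a, sample=e.sample_a)
        g.add_node(e.bin_b, sample=e.sample_b)
        g.add_edge(e.bin_a, e.bin_b)
    g = _prune_graph(g, min_edges)
    tracks = []
    components = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for comp in components:
        members = tuple(sorted(comp))
        samples = {g.nodes[b]["sample"] for b in comp}
        if len(samples) <= min_samples_exclusive:
            continue
        tracks.append(OrganismTrack(
            track_id=f"track_{len(tracks) + 1:03d}",
            member_bins=members,
            samples_spanned=len(samples)))
    return tracks


def tracks_graph(edges: Iterable[MatchEdge], min_edges: int = 3) -> nx.Graph:
    """The pruned same-organism network (for GraphML export / inspection)."""
    g = nx.Graph()
    for e in edges:
        if not e.is_same_organism:
            continue
        g.add_node(e.bin_a, sample=e.sample_a)
        g.add_node(e.bin_b, sample=e.sample_b)
        g.add_edge(e.bin_a, e.bin_b,
                   prop_a_to_b=e.prop_a_to_b, prop_b_to_a=e.prop_b_to_a)
    return _prune_graph(g, min_edges)


# ---------------------------------------------------------------------------
# taxonomy and abundance
# ---------------------------------------------------------------------------

def assign_taxonomy(track: OrganismTrack,
                    ani_table: pd.DataFrame,
                    fallback_label: str,
                    species_threshold: float = 95.0) -> TaxonomyCall:
    """Species assignment from ANI records against reference genomes.

    Records (columns ``bin_id``, ``reference`` and one or more ``ani_*``
    columns) are restricted to the track's member bins.  The effective ANI
    of a record is the minimum over its ANI columns — every method must
    clear the bar.  The reference with the highest effective ANI wins when
    it exceeds ``species_threshold``; a tie between distinct references is
    flagged ambiguous; no qualifying record keeps the coarser label.
    """
    ani_cols = [c for c in ani_table.columns if c.startswith("ani")]
    sub = ani_table[ani_table["bin_id"].isin(track.member_bins)]
    if sub.empty or not ani_cols:
        return TaxonomyCall(label=fallback_label, flag="no-ani")
    eff = sub[ani_cols].min(axis=1)
    by_ref = (pd.DataFrame({"reference": sub["reference"], "ani": eff})
              .groupby("reference")["ani"].max())
    best_ani = float(by_ref.max())
    if best_ani <= species_threshold:
        return TaxonomyCall(label=fallback_label, flag="below-threshold",
                            best_reference=str(by_ref.idxmax()),
                            best_ani=best_ani)
    winners = sorted(by_ref[by_ref == best_ani].index)
    if len(winners) > 1:
        return TaxonomyCall(label=fallback_label, flag="ambiguous",
                            best_reference=";".join(winners),
                            best_ani=best_ani)
    return TaxonomyCall(label=winners[0], flag="ani",
                        best_reference=winners[0], best_ani=best_ani)


def track_relative_abundance(track: OrganismTrack,
                             coverage: pd.DataFrame
                             ) -> tuple[dict[str, float], float]:
    """Per-sample relative abundance of a track, and its mean, in percent.

    ``coverage`` holds one row per (bin_id, sample_id) with the bin's
    coverage mass (mean coverage × summed contig length, or any consistent
    proxy).  The track's share of a sample is its member-bin mass over the
    sample's total mass × 100; the mean is over the samples where the track
    is present.
    """
    required = {"bin_id", "sample_id", "coverage_mass"}
    missing = required - set(coverage.columns)
    if missing:
        raise DomainError(f"coverage table lacks columns {sorted(missing)}")
    if (coverage["coverage_mass"] < 0).any():
        raise DomainError("coverage masses must be >= 0")
    totals = coverage.groupby("sample_id")["coverage_mass"].sum()
    member = coverage[coverage["bin_id"].isin(track.member_bins)]
    shares: dict[str, float] = {}
    for sample, group in member.groupby("sample_id"):
        total = float(totals[sample])
        if total <= 0:
            raise DomainError(f"total coverage mass of sample {sample!r} is 0")
        shares[str(sample)] = 100.0 * float(group["coverage_mass"].sum()) / total
    if not shares:
        return {}, float("nan")
    return shares, float(np.mean(list(shares.values())))


def mapping_accuracy(edges: Iterable[MatchEdge],
                     bin_to_genome: Mapping[str, str]) -> float:
    """Percent of same-organism calls linking bins of one truth genome.

    The benchmark statistic for the matcher: over all edges called
    same-organism, the share whose two bins descend from the same
    ground-truth genome.  Returns NaN when no call was made.
    """
    called = [e for e in edges if e.is_same_organism]
    if not called:
        return float("nan")
    correct = sum(1 for e in called
                  if bin_to_genome[e.bin_a] == bin_to_genome[e.bin_b])
    return 100.0 * correct / len(called)
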