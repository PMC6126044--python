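"""Protein identity engine, same-organism rule, QC filter and tracks."""

import itertools

import numpy as np
import pytest

from digesta import binmatch
from digesta.binmatch import (
    Bin,
    BinQC,
    MatchEdge,
    OrganismTrack,
    assign_taxonomy,
    best_hit_identities,
    best_hit_proportion,
    build_tracks,
    mapping_accuracy,
    protein_identity,
    qc_filter,
    same_organism,
    track_relative_abundance,
)
from digesta.errors import DomainError, MissingQCError

from conftest import mutate, random_protein


# ---------------------------------------------------------------------------
# independent Gotoh (affine-gap Smith–Waterman) score oracle
# ---------------------------------------------------------------------------

def gotoh_local_score(a: str, b: str, open_=-11.0, ext=-1.0) -> float:
    """Quadratic DP local-alignment score with BLOSUM62, affine gaps.

    Gap of length L scores open_ + (L-1)*ext, matching the production
    aligner's convention.  Used only as a test oracle.
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    neg = -1e9
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), neg)   # gap in b (vertical)
    Y = np.full((n + 1, m + 1), neg)   # gap in a (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum[a[i - 1], b[j - 1]]
            diag = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1], 0.0)
            M[i, j] = diag + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + ext)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + ext)
            best = max(best, M[i, j])
    return best


def make_bin(bin_id, sample_id, seqs):
    return Bin(bin_id=bin_id, sample_id=sample_id,
               proteins=tuple((f"{bin_id}_p{i}", s)
                              for i, s in enumerate(seqs)))


class TestProteinIdentity:
    def test_self_identity(self):
        rng = np.random.default_rng(0)
        s = random_protein(rng, 200)
        assert protein_identity(s, s) == 100.0

    def test_five_substitutions_in_hundred(self):
        rng = np.random.default_rng(1)
        s = random_protein(rng, 100)
        m = mutate(rng, s, 5)
        assert protein_identity(s, m) == pytest.approx(95.0, abs=1e-9)
        assert protein_identity(m, s) == pytest.approx(95.0, abs=1e-9)

    def test_unrelated_sequences_stay_low(self):
        """Independent random 150-aa pairs never approach the 90% rule."""
        rng = np.random.default_rng(42)
        idents = [protein_identity(random_protein(rng, 150),
                                   random_protein(rng, 150))
                  for _ in range(200)]
        assert max(idents) < 40.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(DomainError):
            protein_identity("", "ACDEF")

    def test_alignment_score_matches_gotoh_oracle(self):
        """The production aligner's optimal score equals the quadratic DP."""
        from digesta.binmatch import _aligner

        rng = np.random.default_rng(3)
        for _ in range(12):
            a = random_protein(rng, int(rng.integers(20, 50)))
            b = random_protein(rng, int(rng.integers(20, 50)))
            if rng.random() < 0.5:        # include related pairs
                b = mutate(rng, a, int(rng.integers(1, 6)))
            assert _aligner().score(a, b) == pytest.approx(
                gotoh_local_score(a, b), abs=1e-9)

    def test_strain_pair_identities_cluster_near_mutation_load(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            s = random_protein(rng, 300)
            m = mutate(rng, s, 6)   # 2% substitution
            assert protein_identity(s, m) == pytest.approx(98.0, abs=1.5)


class TestBestHitProportion:
    def test_identical_bins(self):
        rng = np.random.default_rng(5)
        seqs = [random_protein(rng, 120) for _ in range(20)]
        a = make_bin("a", "s1", seqs)
        b = make_bin("b", "s2", seqs)
        assert best_hit_proportion(a, b) == 1.0

    def test_unrelated_bins(self):
        rng = np.random.default_rng(6)
        a = make_bin("a", "s1", [random_protein(rng, 120) for _ in range(20)])
        b = make_bin("b", "s2", [random_protein(rng, 120) for _ in range(20)])
        assert best_hit_proportion(a, b) <= 0.05

    def test_sixty_percent_overlap(self):
        rng = np.random.default_rng(7)
        shared = [random_protein(rng, 150) for _ in range(60)]
        own = [random_protein(rng, 150) for _ in range(40)]
        other = [random_protein(rng, 150) for _ in range(40)]
        query = make_bin("q", "s1", shared + own)
        target = make_bin("t", "s2", shared + other)
        assert best_hit_proportion(query, target) == pytest.approx(0.60)

    def test_invariant_under_protein_permutation(self):
        rng = np.random.default_rng(8)
        seqs = [random_protein(rng, 100) for _ in range(30)]
        target = make_bin("t", "s2", seqs[:20])
        q1 = make_bin("q", "s1", seqs[5:25])
        q2 = make_bin("q", "s1", list(reversed(seqs[5:25])))
        assert best_hit_proportion(q1, target) == best_hit_proportion(
            q2, target)

    def test_same_sample_pair_rejected(self):
        rng = np.random.default_rng(9)
        a = make_bin("a", "s1", [random_protein(rng, 100)])
        b = make_bin("b", "s1", [random_protein(rng, 100)])
        with pytest.raises(DomainError):
            best_hit_proportion(a, b)

    def test_kmer_prefilter_lossless_for_mutated_copies(self):
        """Every >90%-identity homolog is found despite the prefilter."""
        rng = np.random.default_rng(10)
        originals = [random_protein(rng, int(n))
                     for n in rng.integers(100, 401, size=15)]
        # ~5% substitution keeps identity > 90%
        mutated = [mutate(rng, s, max(1, len(s) // 20)) for s in originals]
        query = make_bin("q", "s1", originals)
        target = make_bin("t", "s2", mutated)
        idents = best_hit_identities(query, target)
        assert (idents > 90.0).all()


class TestSameOrganism:
    def test_identical_bins_match(self):
        rng = np.random.default_rng(11)
        seqs = [random_protein(rng, 120) for _ in range(15)]
        e = same_organism(make_bin("a", "s1", seqs), make_bin("b", "s2", seqs))
        assert e.is_same_organism
        assert e.prop_a_to_b == 1.0 and e.prop_b_to_a == 1.0

    def test_sixty_percent_overlap_is_not_a_match(self):
        rng = np.random.default_rng(12)
        shared = [random_protein(rng, 150) for _ in range(60)]
        a = make_bin("a", "s1", shared + [random_protein(rng, 150)
                                          for _ in range(40)])
        b = make_bin("b", "s2", shared + [random_protein(rng, 150)
                                          for _ in range(40)])
        e = same_organism(a, b)
        assert not e.is_same_organism

    def test_complete_bin_matches_its_fragment(self):
        """A 75%-complete subsample still matches: the subsample direction
        reaches proportion ~1."""
        rng = np.random.default_rng(13)
        seqs = [random_protein(rng, 120) for _ in range(40)]
        full = make_bin("full", "s1", seqs)
        frag = make_bin("frag", "s2", seqs[:30])
        e = same_organism(full, frag)
        assert e.is_same_organism
        assert e.prop_b_to_a == 1.0
        assert e.prop_a_to_b == pytest.approx(0.75)

    def test_symmetric_boolean(self):
        rng = np.random.default_rng(14)
        seqs = [random_protein(rng, 110) for _ in range(30)]
        a = make_bin("a", "s1", seqs[:25])
        b = make_bin("b", "s2", seqs[8:])
        assert (same_organism(a, b).is_same_organism
                == same_organism(b, a).is_same_organism)

    def test_edge_forbids_same_sample(self):
        with pytest.raises(DomainError):
            MatchEdge("a", "b", "s1", "s1", 1.0, 1.0, True)


def edge(a, b, sa, sb, match=True):
    return MatchEdge(bin_a=a, bin_b=b, sample_a=sa, sample_b=sb,
                     prop_a_to_b=1.0, prop_b_to_a=1.0,
                     is_same_organism=match)


class TestQcFilter:
    @pytest.fixture()
    def one_edge(self):
        return [edge("a", "b", "s1", "s2")]

    @pytest.mark.parametrize("qa, qb, kept", [
        ((95, 2), (90, 5), True),     # clean bins survive
        ((95, 25), (90, 5), False),   # contamination above 20%
        ((39, 2), (90, 5), False),    # completeness below 40%
        ((40, 20), (40, 20), True),   # boundary values survive
    ])
    def test_thresholds(self, one_edge, qa, qb, kept):
        qc = [BinQC("a", *qa), BinQC("b", *qb)]
        assert bool(qc_filter(one_edge, qc)) is kept

    def test_missing_qc_record_names_bin(self, one_edge):
        with pytest.raises(MissingQCError, match="b"):
            qc_filter(one_edge, [BinQC("a", 90, 1)])

    def test_monotone_in_both_thresholds(self):
        """Tightening either threshold never adds edges."""
        rng = np.random.default_rng(15)
        bins = [f"b{i}" for i in range(12)]
        samples = {b: f"s{i % 4}" for i, b in enumerate(bins)}
        edges = [edge(a, b, samples[a], samples[b])
                 for a, b in itertools.combinations(bins, 2)
                 if samples[a] != samples[b] and rng.random() < 0.5]
        qc = [BinQC(b, float(rng.uniform(20, 100)), float(rng.uniform(0, 40)))
              for b in bins]
        for cont, comp in [(30, 20), (20, 40), (10, 60), (5, 80)]:
            loose = qc_filter(edges, qc, cont, comp)
            tighter_cont = qc_filter(edges, qc, cont - 5, comp)
            tighter_comp = qc_filter(edges, qc, cont, comp + 10)
            assert set(map(id_pair, tighter_cont)) <= set(map(id_pair, loose))
            assert set(map(id_pair, tighter_comp)) <= set(map(id_pair, loose))


def id_pair(e):
    return (e.bin_a, e.bin_b)


class TestBuildTracks:
    def test_five_sample_clique(self):
        bins = [(f"b{i}", f"s{i}") for i in range(5)]
        edges = [edge(a, b, sa, sb)
                 for (a, sa), (b, sb) in itertools.combinations(bins, 2)]
        tracks = build_tracks(edges)
        assert len(tracks) == 1
        assert tracks[0].samples_spanned == 5
        assert tracks[0].member_bins == ("b0", "b1", "b2", "b3", "b4")

    def test_chain_is_fully_pruned(self):
        edges = [edge("a", "b", "s1", "s2"), edge("b", "c", "s2", "s3")]
        assert build_tracks(edges) == []

    def test_component_spanning_three_samples_dropped(self):
        # 6 bins, 2 per sample, 3 samples, fully connected across samples:
        # every bin has degree 4 >= 3 but only 3 samples are spanned
        bins = [(f"b{i}", f"s{i % 3}") for i in range(6)]
        edges = [edge(a, b, sa, sb)
                 for (a, sa), (b, sb) in itertools.combinations(bins, 2)
                 if sa != sb]
        assert build_tracks(edges) == []

    def test_pruning_is_iterative_to_fixed_point(self):
        # hub h1..h4 form a cross-sample clique; t has 3 edges into the
        # clique but its supporters lose degree once t is inspected —
        # construct a pendant chain whose support collapses iteratively
        hub = [(f"h{i}", f"s{i}") for i in range(4)]
        edges = [edge(a, b, sa, sb)
                 for (a, sa), (b, sb) in itertools.combinations(hub, 2)]
        # pendant p connected to 2 hub members only: degree 2 -> removed,
        # hub survives (degrees drop from 4 to 3)
        edges += [edge("p", "h0", "s9", "s0"), edge("p", "h1", "s9", "s1")]
        tracks = build_tracks(edges)
        assert len(tracks) == 1
        assert "p" not in tracks[0].member_bins

    def test_matches_brute_force_oracle_on_random_graphs(self):
        """Degree pruning + components equal an explicit reachability oracle
        on 100 seeded random graphs."""
        rng = np.random.default_rng(16)
        for trial in range(100):
            n = int(rng.integers(4, 31))
            bins = [f"b{i}" for i in range(n)]
            samples = {b: f"s{rng.integers(0, 6)}" for b in bins}
            edges = [edge(a, b, samples[a], samples[b])
                     for a, b in itertools.combinations(bins, 2)
                     if samples[a] != samples[b] and rng.random() < 0.25]
            got = {frozenset(t.member_bins) for t in build_tracks(edges)}
            assert got == brute_force_tracks(edges), f"trial {trial}"


def brute_force_tracks(edges, min_edges=3, min_samples=4):
    """Explicit prune-loop + breadth-first reachability oracle."""
    adj = {}
    sample = {}
    for e in edges:
        adj.setdefault(e.bin_a, set()).add(e.bin_b)
        adj.setdefault(e.bin_b, set()).add(e.bin_a)
        sample[e.bin_a] = e.sample_a
        sample[e.bin_b] = e.sample_b
    changed = True
    while changed:
        changed = False
        for b in list(adj):
            if len(adj[b]) < min_edges:
                for other in adj.pop(b):
                    adj[other].discard(b)
                changed = True
    seen, comps = set(), []
    for b in adj:
        if b in seen:
            continue
        comp, queue = set(), [b]
        while queue:
            cur = queue.pop()
            if cur in comp:
                continue
            comp.add(cur)
            queue.extend(adj[cur] - comp)
        seen |= comp
        if len({sample[x] for x in comp}) >= min_samples:
            comps.append(frozenset(comp))
    return set(comps)


class TestTaxonomyAndAbundance:
    def track(self, *bins):
        return OrganismTrack(track_id="t1", member_bins=tuple(bins),
                             samples_spanned=len(bins))

    def ani_df(self, rows):
        import pandas as pd
        return pd.DataFrame(rows, columns=["bin_id", "reference",
                                           "ani_blast", "ani_mummer"])

    def test_high_ani_assigns_species(self):
        call = assign_taxonomy(
            self.track("b1"), self.ani_df([("b1", "SpeciesR", 96.2, 96.0)]),
            fallback_label="FamilyF")
        assert call.label == "SpeciesR" and call.flag == "ani"

    def test_below_threshold_keeps_coarser_label(self):
        call = assign_taxonomy(
            self.track("b1"), self.ani_df([("b1", "SpeciesR", 94.9, 96.5)]),
            fallback_label="FamilyF")
        assert call.label == "FamilyF" and call.flag == "below-threshold"

    def test_conflicting_hits_higher_wins_tie_is_ambiguous(self):
        df = self.ani_df([("b1", "SpA", 96.0, 96.0),
                          ("b1", "SpB", 97.5, 97.5)])
        assert assign_taxonomy(self.track("b1"), df, "F").label == "SpB"
        tie = self.ani_df([("b1", "SpA", 96.0, 96.0),
                           ("b1", "SpB", 96.0, 96.0)])
        call = assign_taxonomy(self.track("b1"), tie, "F")
        assert call.flag == "ambiguous" and call.label == "F"

    def test_no_records_flags_no_ani(self):
        call = assign_taxonomy(self.track("b1"), self.ani_df([]), "FamilyF")
        assert call.label == "FamilyF" and call.flag == "no-ani"

    def test_min_over_methods_must_clear_bar(self):
        # blast says species, mummer disagrees: no assignment
        call = assign_taxonomy(
            self.track("b1"), self.ani_df([("b1", "SpA", 97.0, 93.0)]), "F")
        assert call.flag == "below-threshold"

    def test_relative_abundance_single_and_split(self):
        import pandas as pd
        cov = pd.DataFrame([
            {"bin_id": "b1", "sample_id": "s1", "coverage_mass": 3.0},
            {"bin_id": "b2", "sample_id": "s1", "coverage_mass": 1.0},
            {"bin_id": "b1", "sample_id": "s2", "coverage_mass": 2.0},
        ])
        shares, mean = track_relative_abundance(self.track("b1"), cov)
        assert shares["s1"] == pytest.approx(75.0)
        assert shares["s2"] == pytest.approx(100.0)
        assert mean == pytest.approx(87.5)
        shares2, _ = track_relative_abundance(self.track("b2"), cov)
        assert shares2 == {"s1": pytest.approx(25.0)}

    def test_zero_sample_mass_rejected(self):
        import pandas as pd
        cov = pd.DataFrame([{"bin_id": "b1", "sample_id": "s1",
                             "coverage_mass": 0.0}])
        with pytest.raises(DomainError):
            track_relative_abundance(self.track("b1"), cov)


class TestEndToEndAccuracy:
    def test_well_separated_genomes_map_perfectly(self, small_community):
        """Every same-organism call links bins of one truth genome."""
        _, sample, edges = small_community
        assert sum(e.is_same_organism for e in edges) > 0
        assert mapping_accuracy(edges, sample.truth.bin_to_genome) == 100.0

    def test_inter_genome_proportions_are_negligible(self, small_community):
        _, sample, edges = small_community
        truth = sample.truth.bin_to_genome
        cross = [max(e.prop_a_to_b, e.prop_b_to_a) for e in edges
                 if truth[e.bin_a] != truth[e.bin_b]]
        assert cross and max(cross) < 0.2
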