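import numpy as np
import pytest

from digesta import binmatch, synthetic

#: printed residence-time means used throughout: (RT days, mean total FCS)
STUDY_STEADY_STATES = ((20.0, 0.711), (10.0, 0.654), (5.0, 0.581),
                       (3.3, 0.538))
STUDY_C0 = 17.3


def random_protein(rng: np.random.Generator, length: int) -> str:
    aa = np.frombuffer(binmatch.AMINO_ACIDS.encode(), dtype=np.uint8)
    return aa[rng.integers(0, 20, size=length)].tobytes().decode()


def mutate(rng: np.random.Generator, seq: str, n_subs: int,
           interior: bool = True) -> str:
    """Substitute exactly n_subs residues, avoiding the termini if asked."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lo, hi = (5, len(arr) - 5) if interior else (0, len(arr))
    pos = rng.choice(np.arange(lo, hi), size=n_subs, replace=False)
    aa = np.frombuffer(binmatch.AMINO_ACIDS.encode(), dtype=np.uint8)
    for p in pos:
        choices = aa[aa != arr[p]]
        arr[p] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


@pytest.fixture(scope="session")
def small_community():
    """A compact matched community shared by the slower integration tests."""
    scenario = synthetic.CommunityScenario(
        n_genomes=6, proteins_per_genome=80, n_samples=4, seed=11)
    community = synthetic.generate_community(scenario)
    sample = synthetic.sample_bins(community)
    edges = binmatch.match_all(sample.bins)
    return scenario, sample, edges
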