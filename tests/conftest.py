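import numpy as np
import pytest

from dmea import EnrichmentParams, MOACatalog, RankedDrugList


@pytest.fixture
def toy_list() -> RankedDrugList:
    """Six drugs with symmetric ranks 3..-3, already a known hand case."""
    return RankedDrugList(
        drugs=("A", "B", "C", "D", "E", "F"),
        ranks=np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0]),
    ).sort_descending()


@pytest.fixture
def small_catalog() -> MOACatalog:
    return MOACatalog(
        {
            "top_pair": frozenset({"A", "B"}),
            "bottom_pair": frozenset({"E", "F"}),
            "mixed": frozenset({"A", "D"}),
        }
    )


@pytest.fixture
def fast_params() -> EnrichmentParams:
    return EnrichmentParams(n_permutations=100, min_per_set=2, seed=0)


def brute_force_es(drugs, ranks, members, alpha=1.0):
    """Independent oracle: materialize every prefix of the running sum."""
    order = sorted(range(len(drugs)), key=lambda i: (-ranks[i], drugs[i]))
    n = len(drugs)
    nh = sum(1 for i in order if drugs[i] in members)
    hit_total = sum(abs(ranks[i]) ** alpha for i in order if drugs[i] in members)
    running = 0.0
    best = 0.0
    for i in order:
        if drugs[i] in members:
            running += abs(ranks[i]) ** alpha / hit_total
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best
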