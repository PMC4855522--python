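import itertools

import pytest

from wmem.instance_model import CoverInstance, WeightedSet


def enumerate_best(instance):
    """Independent oracle: enumerate every subfamily with plain sets.

    Returns (chosen ids frozenset, coverage, weight) for the best disjoint
    subfamily under (coverage desc, weight asc, sorted-id tuple asc).
    """
    fam = [ws for ws in instance.family if ws.elements]
    best = None
    for r in range(len(fam) + 1):
        for combo in itertools.combinations(fam, r):
            covered = set()
            ok = True
            for ws in combo:
                if covered & ws.elements:
                    ok = False
                    break
                covered |= ws.elements
            if not ok:
                continue
            ids = tuple(sorted(ws.set_id for ws in combo))
            weight = sum(dict((w.set_id, w.weight) for w in combo)[i] for i in ids)
            key = (-len(covered), weight, ids)
            if best is None or key < best:
                best = key
    return frozenset(best[2]), -best[0], best[1]


@pytest.fixture
def toy_instance():
    """The worked cohort example: three sets all sharing one tumor."""
    return CoverInstance.of(
        [
            WeightedSet.of("g1", ["T1", "T2"], 0.3),
            WeightedSet.of("g2", ["T2", "T3", "T4"], 0.5),
            WeightedSet.of("g3", ["T2", "T5"], 0.1),
        ]
    )
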