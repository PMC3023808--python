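"""Shared fixtures: a hand-checkable micro-world and loader fixtures.

The micro fixture is small enough that every pipeline intermediate (coverage
proportions, chained FDRs, true-positive counts, overlap, estimate) has been
tallied by hand in the tests that use it.
"""

import pytest
from hypothesis import HealthCheck, settings

from ppisize import (
    InteractionDataset,
    InteractionRecord,
    PublicationRef,
    StudyLevels,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def _rec(a, b, pubs, codes=("two-hybrid",)):
    return InteractionRecord(
        pair=(a, b),
        evidence_codes=set(codes),
        publications={PublicationRef(pid, year) for pid, year in pubs},
    )


@pytest.fixture
def micro_lc() -> InteractionDataset:
    """12 curated pairs over proteins A..H with known publication years."""
    return InteractionDataset(
        "LowBP-LC",
        [
            _rec("A", "B", [("p1", 1998)]),
            _rec("A", "C", [("p2", 1999), ("p3", 2005)]),
            _rec("B", "D", [("p4", 1995)]),
            _rec("C", "D", [("p5", 2001)]),
            _rec("D", "E", [("p6", 1997)]),
            _rec("E", "F", [("p7", 2003)], codes=("reconstituted complex",)),
            _rec("F", "G", [("p8", 1999)]),
            _rec("G", "H", [("p9", 2006)], codes=("biochemical activity",)),
            _rec("A", "H", [("p10", 1996), ("p11", 1998)]),
            _rec("C", "F", [("p12", 1999)], codes=("biochemical activity",)),
            _rec("B", "G", [("p13", 1994)]),
            _rec("D", "G", [("p14", 2002)]),
        ],
    )


@pytest.fixture
def micro_ht() -> dict:
    """Two screens; REF is the FDR-chain anchor."""
    return {
        "REF": InteractionDataset.from_pairs(
            "REF", [("A", "B"), ("A", "C"), ("C", "D"), ("E", "F"), ("B", "G")]
        ),
        "HT2": InteractionDataset.from_pairs(
            "HT2", [("A", "B"), ("F", "G"), ("D", "G"), ("G", "H")]
        ),
    }


@pytest.fixture
def micro_levels() -> StudyLevels:
    return StudyLevels({"A": 10, "B": 5, "C": 10, "D": 1, "F": 10, "G": 2, "H": 10})
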