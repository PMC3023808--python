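"""Canonical protein pairs, interaction datasets and study levels.

An interaction is an unordered pair of proteins identified by systematic ORF
names (e.g. ``YAL002W``).  Every pair is stored in *canonical* form: both
identifiers upper-cased and sorted lexicographically, so that ``(a, b)`` and
``(b, a)`` always refer to the same interaction.  Self-pairs (homodimers) are
valid.

:class:`InteractionDataset` is a named collection of
:class:`InteractionRecord` keyed by canonical pair; its size is the number of
distinct pairs, never the number of source rows.  :class:`StudyLevels` maps a
protein to the number of distinct papers citing it and drives the
"well-studied" classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .exceptions import InputError

Pair = tuple[str, str]

__all__ = [
    "Pair",
    "PublicationRef",
    "InteractionRecord",
    "InteractionDataset",
    "StudyLevels",
    "canonical_pair",
    "restrict_before_year",
    "well_studied_set",
    "restrict_well_studied",
    "single_paper_unique",
    "intersect",
    "union_all",
]


def canonical_pair(a: str, b: str) -> Pair:
    """Return the canonical (sorted, upper-cased) form of an unordered pair.

    Idempotent: ``canonical_pair(*canonical_pair(a, b)) == canonical_pair(a, b)``.

    Raises
    ------
    InputError
        If either identifier is empty.
    """
    if not a or not b:
        raise InputError(f"protein identifiers must be non-empty (got {a!r}, {b!r})")
    a, b = a.strip().upper(), b.strip().upper()
    if not a or not b:
        raise InputError("protein identifiers must be non-empty after stripping")
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PublicationRef:
    """A supporting publication: a PubMed-style identifier plus an optional year."""

    pub_id: str
    year: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.pub_id:
            raise InputError("publication id must be non-empty")
        if self.year is not None and self.year <= 1900:
            raise InputError(f"implausible publication year {self.year}")


@dataclass
class InteractionRecord:
    """One curated interaction with its evidence codes and supporting papers.

    ``ist_count`` is the number of interaction-sequence-tag hits for library
    screen data (a per-interaction detectability proxy); ``None`` when the
    source assay does not report one.
    """

    pair: Pair
    evidence_codes: set[str] = field(default_factory=set)
    publications: set[PublicationRef] = field(default_factory=set)
    ist_count: Optional[int] = None

    def __post_init__(self) -> None:
        self.pair = canonical_pair(*self.pair)
        if self.ist_count is not None and self.ist_count < 0:
            raise InputError("ist_count must be non-negative")

    def merged_with(self, other: "InteractionRecord") -> "InteractionRecord":
        """Union of metadata for two records of the same canonical pair."""
        if other.pair != self.pair:
            raise InputError("cannot merge records for different pairs")
        ist = self.ist_count
        if other.ist_count is not None:
            ist = other.ist_count if ist is None else max(ist, other.ist_count)
        return InteractionRecord(
            pair=self.pair,
            evidence_codes=self.evidence_codes | other.evidence_codes,
            publications=self.publications | other.publications,
            ist_count=ist,
        )

    @property
    def years(self) -> set[int]:
        return {p.year for p in self.publications if p.year is not None}


class InteractionDataset:
    """A named set of interactions keyed by canonical pair.

    Ingesting several records for the same pair merges their metadata, so no
    two records ever share a canonical pair.  Supports set algebra
    (:func:`intersect`, :func:`union_all`) and the restriction operations used
    throughout the pipeline.
    """

    def __init__(
        self,
        name: str,
        records: Iterable[InteractionRecord] = (),
        attrs: Optional[dict] = None,
    ):
        self.name = name
        self._records: dict[Pair, InteractionRecord] = {}
        self.attrs: dict = dict(attrs or {})
        for rec in records:
            self.add(rec)

    def add(self, rec: InteractionRecord) -> None:
        existing = self._records.get(rec.pair)
        self._records[rec.pair] = rec if existing is None else existing.merged_with(rec)

    @classmethod
    def from_pairs(
        cls, name: str, pairs: Iterable[tuple[str, str]], attrs: Optional[dict] = None
    ) -> "InteractionDataset":
        ds = cls(name, attrs=attrs)
        for a, b in pairs:
            ds.add(InteractionRecord(pair=(a, b)))
        return ds

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __getitem__(self, pair: tuple[str, str]) -> InteractionRecord:
        return self._records[canonical_pair(*pair)]

    @property
    def pairs(self) -> set[Pair]:
        return set(self._records)

    @property
    def proteins(self) -> set[str]:
        out: set[str] = set()
        for a, b in self._records:
            out.add(a)
            out.add(b)
        return out

    def degrees(self) -> dict[str, int]:
        """Number of distinct interactions each protein participates in."""
        deg: dict[str, int] = {}
        for a, b in self._records:
            deg[a] = deg.get(a, 0) + 1
            if b != a:
                deg[b] = deg.get(b, 0) + 1
        return deg

    def subset(self, pairs: Iterable[Pair], name: Optional[str] = None) -> "InteractionDataset":
        """Dataset restricted to ``pairs`` (records keep full metadata)."""
        keep = set(pairs) & set(self._records)
        ds = InteractionDataset(name or self.name, attrs=dict(self.attrs))
        ds._records = {p: self._records[p] for p in keep}
        return ds

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"InteractionDataset({self.name!r}, n={len(self)})"


class StudyLevels:
    """Papers-per-protein counts; proteins absent from the table count as 0."""

    def __init__(self, papers_per_protein: Mapping[str, int]):
        self._counts: dict[str, int] = {}
        for prot, n in papers_per_protein.items():
            if n < 0:
                raise InputError(f"negative paper count for {prot}")
            self._counts[prot.strip().upper()] = int(n)

    def __getitem__(self, protein: str) -> int:
        return self._counts.get(protein.strip().upper(), 0)

    def __len__(self) -> int:
        return len(self._counts)

    def items(self):
        return self._counts.items()

    def well_studied(self, cutoff: int) -> set[str]:
        return well_studied_set(self, cutoff)


# ---------------------------------------------------------------------------
# restriction / algebra operations
# ---------------------------------------------------------------------------

def restrict_before_year(ds: InteractionDataset, year: int = 2000) -> InteractionDataset:
    """Keep pairs with at least one supporting publication strictly before ``year``.

    Publications without a year never qualify.  Retained records keep their
    full metadata (all publications, not only the pre-cutoff ones).
    """
    keep = [rec.pair for rec in ds if any(y < year for y in rec.years)]
    return ds.subset(keep, name=f"{ds.name}-pre{year}")


def well_studied_set(levels: StudyLevels, cutoff: int) -> set[str]:
    """Proteins cited in at least ``cutoff`` papers (inclusive threshold)."""
    if cutoff < 1:
        raise InputError("well-studied cutoff must be >= 1")
    return {p for p, n in levels.items() if n >= cutoff}


def restrict_well_studied(
    ds: InteractionDataset, ws: set[str], mode: str = "any"
) -> InteractionDataset:
    """Keep pairs involving well-studied proteins.

    ``mode='any'`` requires at least one endpoint in ``ws`` (the default),
    ``mode='both'`` requires both.
    """
    if mode not in ("any", "both"):
        raise InputError(f"mode must be 'any' or 'both', got {mode!r}")
    op = any if mode == "any" else all
    keep = [p for p in ds.pairs if op(e in ws for e in p)]
    return ds.subset(keep, name=f"{ds.name}-ws")


def single_paper_unique(lc: InteractionDataset, ht: InteractionDataset) -> InteractionDataset:
    """LC pairs supported by exactly one publication and absent from ``ht``.

    This is the subset assigned the recuration-derived false-positive rate.
    """
    ht_pairs = ht.pairs
    keep = [
        p
        for p in lc.pairs
        if len(lc[p].publications) == 1 and p not in ht_pairs
    ]
    return lc.subset(keep, name=f"{lc.name}-unique")


def intersect(ds1: InteractionDataset, ds2: InteractionDataset) -> InteractionDataset:
    """Set intersection on canonical pairs; metadata taken from ``ds1``."""
    return ds1.subset(ds1.pairs & ds2.pairs, name=f"{ds1.name}&{ds2.name}")


def union_all(
    datasets: Iterable[InteractionDataset], name: str = "union"
) -> InteractionDataset:
    """Set union on canonical pairs with metadata merged across datasets."""
    out = InteractionDataset(name)
    for ds in datasets:
        for rec in ds:
            out.add(rec)
    return out


def warn_if_empty(ds: InteractionDataset) -> None:
    if len(ds) == 0:
        warnings.warn(f"dataset {ds.name!r} is empty", stacklevel=2)
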