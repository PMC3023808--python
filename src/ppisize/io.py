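"""Loaders and filters for curated-interaction inputs.

Three plain-text dialects are supported:

* the legacy BioGRID organism ``.tab`` layout (tab-delimited, columns
  ``INTERACTOR_A  INTERACTOR_B  OFFICIAL_SYMBOL_A  OFFICIAL_SYMBOL_B
  ALIASES_FOR_A  ALIASES_FOR_B  EXPERIMENTAL_SYSTEM  SOURCE  PUBMED_ID ...``;
  a column map adapts other layouts),
* a gene–literature association table (``gene<TAB>paper_id[<TAB>year]``),
* two-column edge lists with an optional third IST-count column.

The curation filter follows a two-stage rule: publications supporting more
than ``ht_paper_threshold`` distinct pairs in the loaded file are classified
high-throughput and their rows dropped; among the remaining rows only those
whose experimental system is in the binary-physical whitelist are kept.
Throughput is classified over the *whole* file, before evidence filtering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .exceptions import ConfigurationError, InputError
from .pairs import (
    InteractionDataset,
    InteractionRecord,
    PublicationRef,
    StudyLevels,
    canonical_pair,
)

logger = logging.getLogger(__name__)

#: BioGRID "Experimental System" values regarded as direct binary physical
#: evidence.  Matching is case-insensitive; "PCA" also matches the spelled-out
#: "Protein-fragment Complementation Assay" used by some BioGRID releases.
DEFAULT_EVIDENCE_WHITELIST = frozenset(
    {
        "reconstituted complex",
        "two-hybrid",
        "far western",
        "biochemical activity",
        "co-crystal structure",
        "protein-peptide",
        "pca",
        "fret",
    }
)

_PCA_ALIASES = {"protein-fragment complementation assay", "protein fragment complementation assay"}

#: Column indices for the legacy BioGRID organism .tab dialect.
DEFAULT_BIOGRID_COLUMNS = {
    "interactor_a": 0,
    "interactor_b": 1,
    "experimental_system": 6,
    "source": 7,
    "pubmed_id": 8,
    "organism_a": 9,
    "organism_b": 10,
}

_YEAR_RE = re.compile(r"\((\d{4})\)|(?<!\d)(19\d{2}|20\d{2})(?!\d)")


@dataclass
class RawInteraction:
    """One pre-filtering row of an interaction file."""

    a: str
    b: str
    evidence: str
    pub_id: str
    year: Optional[int] = None

    @property
    def pair(self):
        return canonical_pair(self.a, self.b)


def _parse_year(text: str) -> Optional[int]:
    if not text:
        return None
    m = _YEAR_RE.search(text)
    if not m:
        return None
    year = int(m.group(1) or m.group(2))
    return year if year > 1900 else None


def load_biogrid_tab(
    path,
    organism_filter: Optional[str] = None,
    columns: Optional[dict] = None,
    year_source: str = "source",
) -> list[RawInteraction]:
    """Parse a BioGRID organism tab file into raw per-row records.

    Header lines (starting with ``#`` or the literal ``INTERACTOR_A`` header)
    are skipped; malformed rows are logged and dropped.  ``year_source``
    selects where the publication year is parsed from: the author/year
    ``source`` column (default) or a dedicated ``year`` column if the column
    map provides one.
    """
    cols = dict(DEFAULT_BIOGRID_COLUMNS)
    if columns:
        cols.update(columns)
    need = max(cols["interactor_a"], cols["interactor_b"], cols["experimental_system"], cols["pubmed_id"])
    records: list[RawInteraction] = []
    n_skipped = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].strip().upper() in {"INTERACTOR_A", "#BIOGRID INTERACTION ID"}:
                continue
            if len(fields) <= need:
                logger.warning("skipping malformed row %d of %s", lineno, path)
                n_skipped += 1
                continue
            a = fields[cols["interactor_a"]].strip()
            b = fields[cols["interactor_b"]].strip()
            evidence = fields[cols["experimental_system"]].strip()
            pub = fields[cols["pubmed_id"]].strip()
            if not a or not b or not pub:
                logger.warning("skipping incomplete row %d of %s", lineno, path)
                n_skipped += 1
                continue
            if organism_filter is not None:
                org_cols = [cols.get("organism_a"), cols.get("organism_b")]
                orgs = [fields[c].strip() for c in org_cols if c is not None and c < len(fields)]
                if orgs and any(o != organism_filter for o in orgs):
                    continue
            if year_source == "year" and "year" in cols and cols["year"] < len(fields):
                year = _parse_year(fields[cols["year"]])
            else:
                src_col = cols.get("source")
                year = _parse_year(fields[src_col]) if src_col is not None and src_col < len(fields) else None
            records.append(RawInteraction(a=a, b=b, evidence=evidence, pub_id=pub, year=year))
    logger.info("loaded %d rows from %s (%d skipped)", len(records), path, n_skipped)
    return records


def classify_publication_throughput(
    raws: Iterable[RawInteraction], ht_paper_threshold: int = 100
) -> dict[str, str]:
    """Classify each publication as low- or high-throughput.

    A publication is high-throughput iff it supports strictly more than
    ``ht_paper_threshold`` distinct canonical pairs in the loaded file.
    """
    if ht_paper_threshold < 1:
        raise ConfigurationError("ht_paper_threshold must be >= 1")
    pairs_per_pub: dict[str, set] = {}
    for r in raws:
        pairs_per_pub.setdefault(r.pub_id, set()).add(r.pair)
    return {
        pub: ("high" if len(pairs) > ht_paper_threshold else "low")
        for pub, pairs in pairs_per_pub.items()
    }


def _normalize_evidence(code: str) -> str:
    code = code.strip().lower()
    return "pca" if code in _PCA_ALIASES else code


def filter_binary_physical_low_throughput(
    raws: Sequence[RawInteraction],
    evidence_whitelist: Iterable[str] = DEFAULT_EVIDENCE_WHITELIST,
    ht_paper_threshold: int = 100,
    name: str = "LowBP-LC",
    keep_self_pairs: bool = True,
) -> InteractionDataset:
    """Build the low-throughput binary-physical curated dataset.

    Rows from high-throughput publications are dropped first (so only
    low-throughput publications ever attach to a record), then rows whose
    experimental system is outside the whitelist; remaining rows are merged
    into one record per canonical pair, unioning evidence codes and papers.
    """
    whitelist = {_normalize_evidence(c) for c in evidence_whitelist}
    if not whitelist:
        raise ConfigurationError("evidence whitelist must not be empty")
    throughput = classify_publication_throughput(raws, ht_paper_threshold)
    ds = InteractionDataset(name)
    n_ht = n_evidence = n_kept = 0
    for r in raws:
        if throughput[r.pub_id] == "high":
            n_ht += 1
            continue
        if _normalize_evidence(r.evidence) not in whitelist:
            n_evidence += 1
            continue
        pair = r.pair
        if not keep_self_pairs and pair[0] == pair[1]:
            continue
        ds.add(
            InteractionRecord(
                pair=pair,
                evidence_codes={_normalize_evidence(r.evidence)},
                publications={PublicationRef(r.pub_id, r.year)},
            )
        )
        n_kept += 1
    logger.info(
        "filter %s: %d rows kept, %d high-throughput rows dropped, "
        "%d non-binary-physical rows dropped, %d distinct pairs",
        name, n_kept, n_ht, n_evidence, len(ds),
    )
    ds.attrs["filter_audit"] = {
        "rows_kept": n_kept,
        "rows_dropped_high_throughput": n_ht,
        "rows_dropped_evidence": n_evidence,
        "distinct_pairs": len(ds),
    }
    return ds


def load_study_levels(path) -> StudyLevels:
    """Load a gene–literature association table into papers-per-protein counts.

    Counts *distinct* paper ids per gene; duplicate (gene, paper) rows do not
    inflate the count.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str,
            usecols=[0, 1], names=["gene", "paper"],
        )
    except pd.errors.EmptyDataError:
        return StudyLevels({})
    df = df.dropna()
    counts = df.groupby(df["gene"].str.strip().str.upper())["paper"].nunique()
    return StudyLevels(counts.to_dict())


def load_edge_list(path, name: str, with_ist: bool = False) -> InteractionDataset:
    """Load a two-column edge-list TSV (optional third IST-count column)."""
    ds = InteractionDataset(name)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return ds
    if df.shape[1] < 2:
        raise InputError(f"edge list {path} needs at least two columns")
    for row in df.itertuples(index=False):
        a, b = str(row[0]).strip(), str(row[1]).strip()
        if not a or not b or a == "nan" or b == "nan":
            continue
        ist = None
        if with_ist and len(row) > 2 and str(row[2]) not in ("", "nan"):
            ist = int(float(row[2]))
        ds.add(InteractionRecord(pair=(a, b), ist_count=ist))
    logger.info("loaded %d pairs into %s from %s", len(ds), name, path)
    return ds


def load_recuration_scores(path) -> pd.DataFrame:
    """Load a recuration score table ``protein_a<TAB>protein_b<TAB>score``.

    Scores are 0 (no confidence), 1 (low confidence / unsubstantiated) or
    2 (substantiated / high confidence).
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["protein_a", "protein_b", "score"],
        dtype={"protein_a": str, "protein_b": str, "score": int},
    )
    bad = ~df["score"].isin([0, 1, 2])
    if bad.any():
        raise InputError(f"recuration scores must be in {{0,1,2}}; offending rows: {df[bad].index.tolist()}")
    return df


def write_dataset_tsv(ds: InteractionDataset, path, header_comment: str = "") -> None:
    """Write a dataset as a deterministic, sorted TSV edge list with metadata."""
    with open(path, "wt", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# protein_a\tprotein_b\tn_publications\tyears\tevidence_codes\tist_count\n")
        for pair in sorted(ds.pairs):
            rec = ds[pair]
            years = ",".join(str(y) for y in sorted(rec.years))
            codes = ",".join(sorted(rec.evidence_codes))
            ist = "" if rec.ist_count is None else str(rec.ist_count)
            fh.write(
                f"{pair[0]}\t{pair[1]}\t{len(rec.publications)}\t{years}\t{codes}\t{ist}\n"
            )
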