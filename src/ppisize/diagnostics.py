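"""Bias diagnostics for curated-vs-screen interaction data.

The overlap estimator assumes screens sample the interactome independently of
curation.  These diagnostics probe the ways that assumption fails and how the
well-studied restriction repairs it:

* coverage of a library screen by curated data as a function of IST count
  (detectability bias),
* log-log regression between a protein's degree and how many papers cite it
  (study bias),
* screen coverage of the curated well-studied subset across cutoffs,
* the well-studied census curve,
* evidence-code enrichment in the well-studied subset,
* the well-studied share among recurated false/true positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError, InputError
from .pairs import (
    InteractionDataset,
    StudyLevels,
    canonical_pair,
    well_studied_set,
)

__all__ = [
    "RegressionSummary",
    "bin_by_ist",
    "ist_coverage_curve",
    "binned_loglog_regression",
    "degree_vs_study_regression",
    "ht_coverage_vs_cutoff",
    "well_studied_count_curve",
    "evidence_code_enrichment",
    "recuration_ws_proportions",
]


def bin_by_ist(records, min_bin_size: int = 200) -> list[list]:
    """Partition records into ascending-IST bins of at least ``min_bin_size``.

    Records sharing an IST value are never split across bins: a bin closes at
    the first IST value where the cumulative size reaches ``min_bin_size`` and
    the next value differs.  A trailing short bin is merged into its
    predecessor.  Returns a list of lists of records.
    """
    records = list(records)
    if any(r.ist_count is None or r.ist_count < 1 for r in records):
        raise InputError("all records must carry an IST count >= 1")
    if not records:
        return []
    if len(records) < min_bin_size:
        warnings.warn(
            f"only {len(records)} records (< min_bin_size={min_bin_size}); single bin",
            stacklevel=2,
        )
        return [records]
    records.sort(key=lambda r: (r.ist_count, r.pair))
    bins: list[list] = []
    current: list = []
    i = 0
    n = len(records)
    while i < n:
        # consume the whole run of equal IST values
        j = i
        while j < n and records[j].ist_count == records[i].ist_count:
            j += 1
        current.extend(records[i:j])
        if len(current) >= min_bin_size:
            bins.append(current)
            current = []
        i = j
    if current:
        if bins:
            bins[-1].extend(current)
        else:
            bins.append(current)
    return bins


def ist_coverage_curve(
    screen: InteractionDataset,
    lc: InteractionDataset,
    min_bin_size: int = 200,
) -> pd.DataFrame:
    """Curated coverage of a library screen, binned by IST count.

    One row per bin: the size-weighted mean IST count, the bin size and the
    fraction of bin members present in the curated dataset.
    """
    bins = bin_by_ist(list(screen), min_bin_size=min_bin_size)
    lc_pairs = lc.pairs
    rows = []
    for members in bins:
        ists = np.array([r.ist_count for r in members], dtype=float)
        covered = sum(1 for r in members if r.pair in lc_pairs)
        rows.append(
            {
                "weighted_mean_ist": float(ists.mean()),
                "n_interactions": len(members),
                "lc_coverage": covered / len(members),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionSummary:
    """OLS summary for the binned log-log degree-vs-study regression."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_bins: int


def binned_loglog_regression(
    x: np.ndarray, y: np.ndarray, bin_size: int = 5, tiebreak: np.ndarray | None = None
) -> RegressionSummary:
    """OLS on (log10 bin-mean x, log10 bin-mean y) over consecutive x-sorted bins.

    Points are sorted by ``x`` (ties broken by ``tiebreak`` for determinism),
    grouped into consecutive bins of ``bin_size`` (a trailing short bin is
    merged into its predecessor), and bins with non-positive means are
    dropped before taking logs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.lexsort((tiebreak, x)) if tiebreak is not None else np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    n = len(x)
    edges = list(range(0, n, bin_size))
    if len(edges) > 1 and n - edges[-1] < bin_size:
        edges.pop()  # merge trailing short bin into its predecessor
    mx, my = [], []
    for start, stop in zip(edges, edges[1:] + [n]):
        mx.append(x[start:stop].mean())
        my.append(y[start:stop].mean())
    mx, my = np.array(mx), np.array(my)
    keep = (mx > 0) & (my > 0)
    if keep.sum() < 3:
        raise EstimationError(
            f"only {int(keep.sum())} usable bins (need >= 3) for the log-log regression"
        )
    res = stats.linregress(np.log10(mx[keep]), np.log10(my[keep]))
    return RegressionSummary(
        slope=res.slope,
        intercept=res.intercept,
        r_squared=res.rvalue**2,
        p_value=res.pvalue,
        n_bins=int(keep.sum()),
    )


def degree_vs_study_regression(
    ds: InteractionDataset, levels: StudyLevels, bin_size: int = 5
) -> RegressionSummary:
    """Binned log-log regression of protein degree on papers-per-protein.

    Proteins with zero degree in ``ds`` never appear (degree is computed from
    the dataset itself); proteins are sorted by paper count with ties broken
    by identifier.
    """
    if len(ds) == 0:
        raise EstimationError("empty dataset for degree-vs-study regression")
    degrees = ds.degrees()
    prots = sorted(degrees)
    papers = np.array([levels[p] for p in prots], dtype=float)
    degs = np.array([degrees[p] for p in prots], dtype=float)
    ids = np.array(prots)
    return binned_loglog_regression(papers, degs, bin_size=bin_size, tiebreak=ids)


def ht_coverage_vs_cutoff(
    lc: InteractionDataset,
    ht_datasets: dict[str, InteractionDataset],
    cutoffs,
    levels: StudyLevels,
    mode: str = "any",
) -> pd.DataFrame:
    """Screen coverage of the curated well-studied subset, per cutoff and screen."""
    from .pairs import restrict_well_studied

    rows = []
    for cutoff in sorted(set(int(c) for c in cutoffs)):
        ws = well_studied_set(levels, cutoff)
        lc_ws = restrict_well_studied(lc, ws, mode)
        for name, ht in ht_datasets.items():
            if len(lc_ws) == 0:
                rows.append({"cutoff": cutoff, "dataset": name,
                             "coverage": float("nan"), "flag": "empty LC_WS"})
            else:
                cov = len(lc_ws.pairs & ht.pairs) / len(lc_ws)
                rows.append({"cutoff": cutoff, "dataset": name, "coverage": cov, "flag": ""})
    return pd.DataFrame(rows)


def well_studied_count_curve(levels: StudyLevels, cutoffs) -> pd.DataFrame:
    """Number of well-studied proteins at each cutoff (non-increasing)."""
    counts = np.array([n for _, n in levels.items()])
    rows = [
        {"cutoff": c, "n_proteins": int((counts >= c).sum())}
        for c in sorted(set(int(c) for c in cutoffs))
    ]
    return pd.DataFrame(rows)


def evidence_code_enrichment(
    lc: InteractionDataset,
    lc_ws: InteractionDataset,
    codes,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Per-code support fraction in the full vs well-studied curated dataset.

    An interaction counts once per code regardless of how many papers support
    it.  The p-value is a two-sided two-proportion chi-square test (no
    continuity correction by default).
    """
    if len(lc) == 0 or len(lc_ws) == 0:
        raise EstimationError("enrichment needs non-empty datasets")
    rows = []
    for code in codes:
        code_n = code.strip().lower()
        n_all = sum(1 for rec in lc if code_n in rec.evidence_codes)
        n_ws = sum(1 for rec in lc_ws if code_n in rec.evidence_codes)
        p_all, p_ws = n_all / len(lc), n_ws / len(lc_ws)
        table = np.array(
            [[n_ws, len(lc_ws) - n_ws], [n_all, len(lc) - n_all]], dtype=float
        )
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            pval = 1.0
        else:
            pval = stats.chi2_contingency(table, correction=continuity_correction)[1]
        rows.append(
            {"code": code, "prop_all": p_all, "prop_ws": p_ws,
             "delta": p_ws - p_all, "p_value": pval}
        )
    return pd.DataFrame(rows)


def recuration_ws_proportions(
    scores: pd.DataFrame, ws: set[str], mode: str = "any"
) -> tuple[float, float]:
    """Well-studied share among recurated false and true positives.

    Score 0 rows are false positives, score 2 true positives, score 1 ignored.
    Returns ``(fp_ws_fraction, tp_ws_fraction)``; an empty class yields NaN
    with a warning.
    """
    if mode not in ("any", "both"):
        raise InputError(f"mode must be 'any' or 'both', got {mode!r}")
    op = any if mode == "any" else all
    ws_upper = {p.strip().upper() for p in ws}

    def frac(subset: pd.DataFrame, label: str) -> float:
        if len(subset) == 0:
            warnings.warn(f"no recurated {label}; fraction undefined", stacklevel=3)
            return float("nan")
        hits = 0
        for row in subset.itertuples(index=False):
            pair = canonical_pair(str(row.protein_a), str(row.protein_b))
            if op(p in ws_upper for p in pair):
                hits += 1
        return hits / len(subset)

    fp = frac(scores[scores["score"] == 0], "false positives")
    tp = frac(scores[scores["score"] == 2], "true positives")
    return fp, tp
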