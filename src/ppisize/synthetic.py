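"""Synthetic interactome worlds with study-level and detectability structure.

A world is a ground-truth set of ``N_true`` protein pairs with two kinds of
heterogeneity the real data exhibit:

* **degree/study correlation** — pairs are drawn with heavy-tailed protein
  weights, and each protein's papers-per-protein count is a rank-correlated
  noisy transform of its degree (well-connected proteins attract study);
* **detectability** — every true pair carries a score in (0, 1] describing
  how easily widely-used assays (Y2H-like) find it; IST counts act as its
  observable proxy.

Samplers draw literature-curated (LC) and high-throughput (HT) datasets from
a world.  HT capture scales with ``detectability ** assay_sensitivity_exponent``
and false pairs are injected to a target FDR.  LC capture can be biased both
toward detectable interactions and toward well-studied proteins; setting
``ws_assay_agnostic`` makes capture of pairs with a well-studied endpoint
independent of detectability, modeling the wider variety of assays applied to
thoroughly studied proteins.  ``recovery_experiment`` replays the full
estimation on many sampled worlds and reports bias, RMSE and CI coverage of
the naive and well-studied-restricted estimators.

Worlds export to the same text dialects the real loaders consume, so the
whole pipeline can run end-to-end without external downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .error_rates import lc_ws_true_positives
from .estimation import confidence_interval, estimate_size
from .exceptions import ConfigurationError, EstimationError, InputError
from .pairs import (
    InteractionDataset,
    InteractionRecord,
    PublicationRef,
    StudyLevels,
    restrict_well_studied,
    single_paper_unique,
)

__all__ = [
    "SyntheticWorld",
    "AssaySamplingConfig",
    "DEFAULT_WORLD_PARAMS",
    "generate_world",
    "sample_ht_dataset",
    "sample_lc_dataset",
    "recovery_experiment",
    "unbiased_benchmark",
    "biased_benchmark",
]

_EVIDENCE_VOCAB = ("two-hybrid", "biochemical activity", "reconstituted complex")

#: Standard benchmark world: a yeast-scale truth of 20,000 interactions among
#: 2,500 proteins with heavy-tailed degrees and study levels rank-correlated
#: 0.6 with degree.
DEFAULT_WORLD_PARAMS: dict = {
    "n_proteins": 2500,
    "n_true": 20000,
    "degree_concentration": 1.0,
    "study_degree_correlation": 0.6,
}


def unbiased_benchmark() -> dict:
    """Study conditions for the parameter-recovery benchmark.

    LC (~6,000 pairs) and HT (~2,500 pairs at FDR 0.25) are both drawn
    uniformly from the truth; no curation errors; the estimator assumes none.
    Pass to :func:`recovery_experiment` as keyword arguments.
    """
    return {
        "world_params": dict(DEFAULT_WORLD_PARAMS),
        "lc_cfg": AssaySamplingConfig(expected_size=6000),
        "ht_cfg": AssaySamplingConfig(expected_size=2500, target_fdr=0.25),
        "assumed_fp_rate": 0.0,
        "ws_quantile": 0.9,
    }


def biased_benchmark() -> dict:
    """Study conditions for the bias-correction benchmark.

    HT capture scales with detectability; LC capture is detectability-biased
    except for pairs touching a well-studied protein (top decile by papers),
    which are sampled assay-agnostically.  Single-paper curation errors occur
    at rate 0.30 while the estimator applies the canonical 0.35 correction —
    a deliberately conservative convention that keeps the corrected estimate
    at or below the truth.
    """
    return {
        "world_params": dict(DEFAULT_WORLD_PARAMS),
        "lc_cfg": AssaySamplingConfig(
            expected_size=6000,
            detectability_bias_weight=1.0,
            ws_assay_agnostic=True,
            single_paper_prob=0.6,
            fp_single_rate=0.30,
        ),
        "ht_cfg": AssaySamplingConfig(
            expected_size=2500, target_fdr=0.25, assay_sensitivity_exponent=1.0
        ),
        "assumed_fp_rate": 0.35,
        "ws_quantile": 0.9,
    }


@dataclass
class SyntheticWorld:
    """Ground-truth interactome plus study levels and per-pair detectability."""

    proteins: list[str]
    pair_i: np.ndarray
    pair_j: np.ndarray
    detectability: np.ndarray
    papers: np.ndarray
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self._pair_names: Optional[list] = None

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_true(self) -> int:
        return len(self.pair_i)

    @property
    def pair_names(self) -> list:
        """Canonical name tuples of the true pairs (cached)."""
        if self._pair_names is None:
            prot = self.proteins
            self._pair_names = [
                (prot[i], prot[j]) for i, j in zip(self.pair_i, self.pair_j)
            ]
        return self._pair_names

    @property
    def true_pairs(self) -> set:
        return set(self.pair_names)

    def study_levels(self) -> StudyLevels:
        return StudyLevels(
            {p: int(n) for p, n in zip(self.proteins, self.papers)}
        )

    def degree(self) -> np.ndarray:
        deg = np.bincount(self.pair_i, minlength=self.n_proteins)
        off_diag = self.pair_i != self.pair_j
        deg += np.bincount(self.pair_j[off_diag], minlength=self.n_proteins)
        return deg

    def papers_cutoff_for_quantile(self, q: float) -> int:
        """Paper-count cutoff placing roughly a ``1-q`` fraction in the WS set."""
        return max(1, int(np.quantile(self.papers, q)))

    def manifest(self) -> dict:
        return {
            "n_proteins": self.n_proteins,
            "n_true": self.n_true,
            "seed": self.seed,
            "params": self.params,
        }

    # -- exports (same dialects the real loaders read) ----------------------
    def export_manifest(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)

    def export_study_levels(self, path) -> None:
        """Gene–literature association table; one synthetic paper id per citation."""
        with open(path, "wt", encoding="utf-8") as fh:
            for prot, n in zip(self.proteins, self.papers):
                for k in range(int(n)):
                    fh.write(f"{prot}\tSPMID-{prot}-{k}\n")


@dataclass(frozen=True)
class AssaySamplingConfig:
    """How a dataset is sampled from a world.

    ``expected_size`` is the target dataset size (including false positives at
    ``target_fdr``).  ``assay_sensitivity_exponent`` shapes HT capture as a
    power of detectability; ``detectability_bias_weight`` and
    ``study_bias_weight`` shape LC capture; ``ws_assay_agnostic`` removes the
    detectability bias for pairs with a well-studied endpoint.
    ``fp_single_rate`` is the fraction of single-paper LC records that are
    false, and ``single_paper_prob`` the chance a captured LC interaction is
    supported by exactly one paper.
    """

    expected_size: int
    target_fdr: float = 0.0
    assay_sensitivity_exponent: float = 0.0
    detectability_bias_weight: float = 0.0
    study_bias_weight: float = 0.0
    ws_assay_agnostic: bool = False
    single_paper_prob: float = 0.6
    fp_single_rate: float = 0.0
    pre2000_frac: float = 0.5
    ist_scale: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("target_fdr", "single_paper_prob", "fp_single_rate", "pre2000_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name}={v} outside [0, 1]")
        if self.target_fdr >= 1.0:
            raise InputError("target_fdr must be < 1")
        if self.expected_size < 1:
            raise InputError("expected_size must be >= 1")


def generate_world(
    n_proteins: int,
    n_true: int,
    degree_concentration: float = 1.0,
    study_degree_correlation: float = 0.6,
    detectability_shape: tuple[float, float] = (1.0, 3.0),
    papers_log_mean: float = 2.5,
    papers_log_sd: float = 1.5,
    seed: int = 0,
) -> SyntheticWorld:
    """Sample a ground-truth world.

    Pairs are drawn with per-protein lognormal weights (``degree_concentration``
    is the log-sd, controlling degree heterogeneity); papers-per-protein is a
    Gaussian-copula transform of degree at rank correlation
    ``study_degree_correlation`` mapped to a lognormal count; detectability is
    Beta-distributed (skewed low by default, like IST counts).
    """
    max_pairs = n_proteins * (n_proteins + 1) // 2
    if n_true > max_pairs:
        raise InputError(f"n_true={n_true} infeasible for {n_proteins} proteins")
    if not -1.0 <= study_degree_correlation <= 1.0:
        raise InputError("study_degree_correlation outside [-1, 1]")
    rng = np.random.default_rng(seed)
    weights = rng.lognormal(0.0, degree_concentration, n_proteins)
    prob = weights / weights.sum()

    codes = np.empty(0, dtype=np.int64)
    attempts = 0
    while len(codes) < n_true:
        draw = max(4 * (n_true - len(codes)), 1024)
        i = rng.choice(n_proteins, size=draw, p=prob)
        j = rng.choice(n_proteins, size=draw, p=prob)
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        new = lo.astype(np.int64) * n_proteins + hi
        codes = np.unique(np.concatenate([codes, new]))
        attempts += 1
        if attempts > 200:
            raise EstimationError(
                "could not reach the requested number of true pairs; "
                "increase n_proteins or decrease degree_concentration"
            )
    codes = rng.permutation(codes)[:n_true]
    pair_i = (codes // n_proteins).astype(np.int32)
    pair_j = (codes % n_proteins).astype(np.int32)

    deg = np.bincount(pair_i, minlength=n_proteins) + np.bincount(
        pair_j[pair_j != pair_i], minlength=n_proteins
    )
    # Gaussian copula: normal scores of (jittered) degree, mixed with noise at
    # the requested correlation, mapped to a lognormal paper count.
    jitter = rng.uniform(0.0, 1e-6, n_proteins)
    ranks = stats.rankdata(deg + jitter, method="ordinal")
    z_deg = stats.norm.ppf((ranks - 0.5) / n_proteins)
    rho = study_degree_correlation
    z_pap = rho * z_deg + np.sqrt(1.0 - rho**2) * rng.standard_normal(n_proteins)
    papers = np.round(np.exp(papers_log_mean + papers_log_sd * z_pap)).astype(np.int64)
    papers = np.maximum(papers, 0)

    a, b = detectability_shape
    detectability = np.clip(rng.beta(a, b, n_true), 1e-6, 1.0)

    width = len(str(n_proteins))
    proteins = [f"P{i:0{width}d}" for i in range(n_proteins)]
    return SyntheticWorld(
        proteins=proteins,
        pair_i=pair_i,
        pair_j=pair_j,
        detectability=detectability,
        papers=papers,
        seed=seed,
        params={
            "n_proteins": n_proteins,
            "n_true": n_true,
            "degree_concentration": degree_concentration,
            "study_degree_correlation": study_degree_correlation,
            "detectability_shape": list(detectability_shape),
            "papers_log_mean": papers_log_mean,
            "papers_log_sd": papers_log_sd,
        },
    )


def _capture_probabilities(weight: np.ndarray, expected: float) -> np.ndarray:
    """Scale weights to capture probabilities summing to ``expected`` (clipped)."""
    p = np.minimum(weight * (expected / weight.sum()), 1.0)
    for _ in range(4):  # re-spread mass lost to clipping
        deficit = expected - p.sum()
        if deficit <= 1e-9:
            break
        room = p < 1.0
        if not room.any():
            break
        p[room] = np.minimum(p[room] * (1.0 + deficit / p[room].sum()), 1.0)
    return p


def _draw_false_pairs(
    world: SyntheticWorld, n_fp: int, rng: np.random.Generator
) -> list:
    """Uniform random pairs outside the ground truth."""
    if n_fp == 0:
        return []
    n = world.n_proteins
    truth = np.sort(world.pair_i.astype(np.int64) * n + world.pair_j)
    out: list[int] = []
    seen: set[int] = set()
    while len(out) < n_fp:
        draw = max(4 * (n_fp - len(out)), 64)
        i = rng.integers(0, n, draw)
        j = rng.integers(0, n, draw)
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        cand = lo.astype(np.int64) * n + hi
        # membership test against the sorted truth array
        idx = np.searchsorted(truth, cand)
        in_truth = (idx < len(truth)) & (truth[np.minimum(idx, len(truth) - 1)] == cand)
        for c in cand[~in_truth]:
            c = int(c)
            if c not in seen:
                seen.add(c)
                out.append(c)
                if len(out) == n_fp:
                    break
    prot = world.proteins
    return [(prot[c // n], prot[c % n]) for c in out]


def sample_ht_dataset(
    world: SyntheticWorld,
    cfg: AssaySamplingConfig,
    name: str = "HT-synth",
    with_ist: bool = False,
) -> InteractionDataset:
    """Draw an HT screen: detectability-weighted capture plus injected FPs.

    The returned dataset carries ``attrs['true_fdr']`` (the realized rate) for
    oracle use, and pseudo-IST counts when ``with_ist`` is set.
    """
    rng = np.random.default_rng(cfg.seed)
    d = world.detectability
    weight = d**cfg.assay_sensitivity_exponent
    expected_tp = cfg.expected_size * (1.0 - cfg.target_fdr)
    p = _capture_probabilities(weight, expected_tp)
    mask = rng.random(world.n_true) < p
    tp_idx = np.flatnonzero(mask)
    n_tp = len(tp_idx)
    n_fp = int(round(n_tp * cfg.target_fdr / (1.0 - cfg.target_fdr)))

    ds = InteractionDataset(name)
    names = world.pair_names
    if with_ist:
        ists = 1 + rng.poisson(cfg.ist_scale * d[tp_idx])
    for pos, idx in enumerate(tp_idx):
        ds.add(
            InteractionRecord(
                pair=names[idx],
                ist_count=int(ists[pos]) if with_ist else None,
            )
        )
    for pair in _draw_false_pairs(world, n_fp, rng):
        ds.add(
            InteractionRecord(
                pair=pair,
                ist_count=int(1 + rng.poisson(0.5)) if with_ist else None,
            )
        )
    total = n_tp + n_fp
    ds.attrs.update(
        true_fdr=(n_fp / total if total else 0.0), n_tp=n_tp, n_fp=n_fp,
        target_fdr=cfg.target_fdr,
    )
    return ds


def sample_lc_dataset(
    world: SyntheticWorld,
    cfg: AssaySamplingConfig,
    ws: Optional[set] = None,
    name: str = "LC-synth",
) -> InteractionDataset:
    """Draw a literature-curated dataset with configurable biases.

    Capture probability per true pair is proportional to
    ``detectability ** detectability_bias_weight`` times a study factor
    ``((papers_a + papers_b) / mean) ** study_bias_weight``.  With
    ``ws_assay_agnostic`` and a well-studied set, pairs touching a
    well-studied protein ignore the detectability term.  Curation errors are
    modeled per record: each single-paper record is false with probability
    ``fp_single_rate``, keeping one true endpoint and a random false partner
    (so the false rate is uniform across protein strata); publication counts
    and years are synthesized per record.
    """
    rng = np.random.default_rng(cfg.seed)
    d = world.detectability
    det_term = d**cfg.detectability_bias_weight
    if cfg.ws_assay_agnostic and ws:
        ws_mask = np.array([p in ws for p in world.proteins])
        pair_ws = ws_mask[world.pair_i] | ws_mask[world.pair_j]
        det_term = np.where(pair_ws, 1.0, det_term)
    s = world.papers[world.pair_i] + world.papers[world.pair_j] + 1.0
    study_term = (s / s.mean()) ** cfg.study_bias_weight
    weight = det_term * study_term
    p = _capture_probabilities(weight, float(cfg.expected_size))
    mask = rng.random(world.n_true) < p
    tp_idx = np.flatnonzero(mask)
    n_cap = len(tp_idx)

    singles = rng.random(n_cap) < cfg.single_paper_prob
    n_pubs = np.where(singles, 1, 2 + rng.poisson(0.7, n_cap))
    is_fp = singles & (rng.random(n_cap) < cfg.fp_single_rate)

    names = world.pair_names
    ds = InteractionDataset(name)
    pub_counter = 0
    n_prot = world.n_proteins
    truth_codes = set(
        (world.pair_i.astype(np.int64) * n_prot + world.pair_j).tolist()
    )
    used_fp_codes: set[int] = set()

    def miscurated_pair(idx: int):
        """A false pair keeping the more-studied endpoint of the true pair.

        Curation errors plausibly arise in papers about a (usually
        well-studied) protein, misreporting its partner; keeping the
        more-studied endpoint preserves the record's study stratum.
        """
        i, j = int(world.pair_i[idx]), int(world.pair_j[idx])
        keep = i if world.papers[i] >= world.papers[j] else j
        for _ in range(100):
            partner = int(rng.integers(0, n_prot))
            lo, hi = min(keep, partner), max(keep, partner)
            code = lo * n_prot + hi
            if code not in truth_codes and code not in used_fp_codes:
                used_fp_codes.add(code)
                return (world.proteins[lo], world.proteins[hi])
        return None  # pathological density; drop the record

    def make_pubs(k: int) -> set:
        nonlocal pub_counter
        pubs = set()
        for _ in range(k):
            pre = rng.random() < cfg.pre2000_frac
            year = int(rng.integers(1985, 2000) if pre else rng.integers(2000, 2010))
            pubs.add(PublicationRef(f"SP{cfg.seed}-{pub_counter}", year))
            pub_counter += 1
        return pubs

    def make_codes(det: float) -> set:
        codes = set()
        if rng.random() < 0.35 + 0.45 * det:
            codes.add("two-hybrid")
        if rng.random() < 0.10 + 0.20 * (1.0 - det):
            codes.add("biochemical activity")
        if rng.random() < 0.30:
            codes.add("reconstituted complex")
        if not codes:
            codes.add(_EVIDENCE_VOCAB[int(rng.integers(0, len(_EVIDENCE_VOCAB)))])
        return codes

    n_tp = n_fp = 0
    for pos, idx in enumerate(tp_idx):
        if is_fp[pos]:
            pair = miscurated_pair(int(idx))
            if pair is None:
                continue
            n_fp += 1
        else:
            pair = names[idx]
            n_tp += 1
        ds.add(
            InteractionRecord(
                pair=pair,
                evidence_codes=make_codes(float(d[idx])),
                publications=make_pubs(int(n_pubs[pos])),
            )
        )
    ds.attrs.update(n_tp=n_tp, n_fp=n_fp, fp_single_rate=cfg.fp_single_rate)
    return ds


def export_edge_list(ds: InteractionDataset, path, with_ist: bool = False) -> None:
    """Write a dataset in the two/three-column edge-list dialect."""
    with open(path, "wt", encoding="utf-8") as fh:
        for pair in sorted(ds.pairs):
            rec = ds[pair]
            if with_ist:
                fh.write(f"{pair[0]}\t{pair[1]}\t{rec.ist_count or 1}\n")
            else:
                fh.write(f"{pair[0]}\t{pair[1]}\n")


def export_biogrid_tab(ds: InteractionDataset, path) -> None:
    """Write a dataset in the legacy BioGRID organism .tab dialect.

    One row per (pair, publication, evidence code), so the file round-trips
    through the curation filter.
    """
    header = (
        "INTERACTOR_A\tINTERACTOR_B\tOFFICIAL_SYMBOL_A\tOFFICIAL_SYMBOL_B\t"
        "ALIASES_FOR_A\tALIASES_FOR_B\tEXPERIMENTAL_SYSTEM\tSOURCE\tPUBMED_ID\t"
        "ORGANISM_A_ID\tORGANISM_B_ID\n"
    )
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(header)
        for pair in sorted(ds.pairs):
            rec = ds[pair]
            pubs = sorted(rec.publications, key=lambda p: p.pub_id) or [
                PublicationRef("SP-UNKNOWN", 2005)
            ]
            codes = sorted(rec.evidence_codes) or ["two-hybrid"]
            for pub in pubs:
                year = pub.year if pub.year is not None else 2005
                for code in codes:
                    fh.write(
                        f"{pair[0]}\t{pair[1]}\t{pair[0]}\t{pair[1]}\t-\t-\t"
                        f"{code.title()}\tSynth A ({year})\t{pub.pub_id}\t559292\t559292\n"
                    )


def _one_replicate(
    world_params: dict,
    lc_cfg: AssaySamplingConfig,
    ht_cfg: AssaySamplingConfig,
    seeds: tuple[int, int, int],
    assumed_fp_rate: float,
    ws_quantile: float,
    ws_mode: str,
    ci_method: str,
    ci_level: float,
) -> dict:
    world = generate_world(**world_params, seed=int(seeds[0]))
    cutoff = world.papers_cutoff_for_quantile(ws_quantile)
    levels = world.study_levels()
    ws = levels.well_studied(cutoff)
    lc = sample_lc_dataset(world, replace(lc_cfg, seed=int(seeds[1])), ws=ws)
    ht = sample_ht_dataset(world, replace(ht_cfg, seed=int(seeds[2])))
    tp_ht = len(ht) * (1.0 - ht_cfg.target_fdr)
    row: dict = {"true_n": world.n_true, "ws_cutoff": cutoff}

    def run(lc_sub: InteractionDataset, label: str) -> None:
        unique = single_paper_unique(lc_sub, ht)
        tp_lc = lc_ws_true_positives(len(lc_sub), len(unique), assumed_fp_rate)
        overlap = len(lc_sub.pairs & ht.pairs)
        try:
            est = estimate_size(tp_ht, tp_lc, overlap)
            low, high = confidence_interval(est, level=ci_level, method=ci_method)
            row[f"{label}_estimate"] = est.interactome_size
            row[f"{label}_ci_low"] = low
            row[f"{label}_ci_high"] = high
            row[f"{label}_covered"] = low <= world.n_true <= high
        except EstimationError:
            row[f"{label}_estimate"] = float("nan")
            row[f"{label}_ci_low"] = float("nan")
            row[f"{label}_ci_high"] = float("nan")
            row[f"{label}_covered"] = False

    run(lc, "naive")
    run(restrict_well_studied(lc, ws, ws_mode), "ws")
    return row


def recovery_experiment(
    world_params: dict,
    lc_cfg: AssaySamplingConfig,
    ht_cfg: AssaySamplingConfig,
    n_replicates: int = 200,
    seed: int = 0,
    assumed_fp_rate: float = 0.35,
    ws_quantile: float = 0.8,
    ws_mode: str = "any",
    ci_method: str = "transformed_overlap",
    ci_level: float = 0.95,
) -> dict:
    """Run the naive and well-studied-restricted estimators on sampled worlds.

    Returns a report with the per-replicate table and summary statistics
    (mean estimate, relative bias, RMSE and CI coverage for each estimator).
    Fully deterministic given ``seed``.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    seed_table = rng.integers(0, 2**31 - 1, size=(n_replicates, 3))
    rows = [
        _one_replicate(
            world_params, lc_cfg, ht_cfg, tuple(seed_table[r]),
            assumed_fp_rate, ws_quantile, ws_mode, ci_method, ci_level,
        )
        for r in range(n_replicates)
    ]
    df = pd.DataFrame(rows)
    true_n = float(df["true_n"].mean())
    report = {"replicates": df, "true_n": true_n, "n_replicates": n_replicates}
    for label in ("naive", "ws"):
        est = df[f"{label}_estimate"].dropna()
        report[f"{label}_mean"] = float(est.mean())
        report[f"{label}_relative_bias"] = float((est.mean() - true_n) / true_n)
        report[f"{label}_rmse"] = float(np.sqrt(((est - df.loc[est.index, "true_n"]) ** 2).mean()))
        report[f"{label}_ci_coverage"] = float(df[f"{label}_covered"].mean())
        report[f"{label}_n_valid"] = int(len(est))
    return report
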