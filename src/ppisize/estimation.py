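"""The overlap (capture–recapture) interactome-size estimator.

Treat the true-positive HT interactions as a first capture of size ``n`` and
the true-positive curated well-studied interactions as a second capture of
size ``m'`` from an interactome of unknown size ``N``.  If the HT sample is
drawn independently of curation, the overlap ``k`` follows a hypergeometric
distribution H(N, m', n) with mean ``n * m' / N``; moment matching yields the
Lincoln–Petersen estimator

    Is = TP_HT * TP_LC_WS / TP_overlap.

Two normal-approximation confidence intervals are provided: a delta-method
interval on ``Is`` directly, and an interval obtained by a normal CI on the
overlap count ``k`` transformed endpoint-wise through ``Is = m'*n/k`` (the
default, since the transformation makes the interval asymmetric like the
sampling distribution of ``Is``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from scipy import stats

from .error_rates import ErrorRateTable, ht_true_positives
from .exceptions import ConfigurationError, EstimationError, InputError
from .pairs import InteractionDataset

__all__ = [
    "SizeEstimate",
    "FnrEstimate",
    "estimate_size",
    "estimate_size_expanded",
    "confidence_interval",
    "lc_ws_false_negative_rate",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (report convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class SizeEstimate:
    """A point estimate of the interactome size with its three components.

    ``tp_ht`` (n), ``tp_lc_ws`` (m') and ``tp_overlap`` (k) are the
    true-positive counts entering the estimator; ``config_snapshot`` records
    the parameters that produced them.
    """

    interactome_size: float
    tp_ht: float
    tp_lc_ws: float
    tp_overlap: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_method: Optional[str] = None
    ci_level: Optional[float] = None
    config_snapshot: dict = field(default_factory=dict)

    @property
    def rounded(self) -> int:
        return round_half_away(self.interactome_size)


def estimate_size(
    tp_ht: float,
    tp_lc_ws: float,
    tp_overlap: float,
    config_snapshot: Optional[dict] = None,
) -> SizeEstimate:
    """Lincoln–Petersen point estimate ``Is = tp_ht * tp_lc_ws / tp_overlap``."""
    if tp_ht <= 0 or tp_lc_ws <= 0:
        raise InputError("true-positive counts must be positive")
    if tp_overlap < 1:
        raise EstimationError(
            "overlap between the HT and curated well-studied datasets is zero; "
            "the overlap estimator is unbounded. Use a larger HT dataset, a "
            "lower well-studied cutoff, or merge HT datasets."
        )
    size = tp_ht * tp_lc_ws / tp_overlap
    return SizeEstimate(
        interactome_size=size,
        tp_ht=tp_ht,
        tp_lc_ws=tp_lc_ws,
        tp_overlap=tp_overlap,
        config_snapshot=dict(config_snapshot or {}),
    )


def estimate_size_expanded(
    tp_reference: float,
    tp_lc_ws: float,
    ht_pre2000_overlap: float,
    ref_pre2000_overlap: float,
    ht_lc_ws_overlap: float,
) -> SizeEstimate:
    """Expanded form of the estimator in terms of reference-dataset quantities.

    ``Is = TP_ref * TP_LC_WS * |HT ∩ LC-pre2000| /
    (|ref ∩ LC-pre2000| * |HT ∩ LC_WS|)``.  Exactly equivalent to chaining the
    target FDR from the reference and applying the plain estimator when HT is
    a single dataset.
    """
    if ref_pre2000_overlap <= 0 or ht_lc_ws_overlap <= 0:
        raise EstimationError("expanded form requires non-zero overlap denominators")
    if tp_reference <= 0 or tp_lc_ws <= 0 or ht_pre2000_overlap <= 0:
        raise InputError("all expanded-form counts must be positive")
    size = (
        tp_reference * tp_lc_ws * ht_pre2000_overlap
        / (ref_pre2000_overlap * ht_lc_ws_overlap)
    )
    tp_ht = tp_reference * ht_pre2000_overlap / ref_pre2000_overlap
    return SizeEstimate(
        interactome_size=size,
        tp_ht=tp_ht,
        tp_lc_ws=tp_lc_ws,
        tp_overlap=ht_lc_ws_overlap,
        config_snapshot={"form": "expanded"},
    )


def _overlap_sd(estimate: SizeEstimate) -> float:
    """Hypergeometric standard deviation of the overlap count at the estimate.

    ``Var(k) = n * (m'/Is) * (1 - m'/Is) * (Is - n)/(Is - 1)`` evaluated at
    the estimated size.
    """
    n, m, size = estimate.tp_ht, estimate.tp_lc_ws, estimate.interactome_size
    if size <= 1:
        return 0.0
    p = m / size
    var = n * p * (1.0 - p) * (size - n) / (size - 1.0)
    return math.sqrt(max(var, 0.0))


def confidence_interval(
    estimate: SizeEstimate,
    level: float = 0.95,
    method: str = "transformed_overlap",
) -> tuple[float, float]:
    """Normal-approximation confidence interval for the size estimate.

    ``transformed_overlap`` (default) builds a normal CI on the overlap count
    and maps its endpoints through ``Is = m'*n/k``, giving an asymmetric
    interval; ``delta`` propagates the overlap variance to ``Is`` by the delta
    method (``Var(Is) ~ m'^2 n^2 Var(k) / k^4``) and is symmetric.  The bounds
    are stored on ``estimate`` as a side effect.
    """
    if not 0.0 < level < 1.0:
        raise ConfigurationError(f"confidence level must be in (0, 1), got {level}")
    if method not in ("delta", "transformed_overlap"):
        raise ConfigurationError(f"unknown CI method {method!r}")
    if estimate.tp_overlap < 1:
        raise EstimationError("confidence interval undefined for zero overlap")
    z = stats.norm.ppf(0.5 + level / 2.0)
    k = estimate.tp_overlap
    sd_k = _overlap_sd(estimate)
    mn = estimate.tp_ht * estimate.tp_lc_ws
    if method == "delta":
        sd_size = mn * sd_k / k**2
        low = estimate.interactome_size - z * sd_size
        high = estimate.interactome_size + z * sd_size
    else:
        k_low, k_high = k - z * sd_k, k + z * sd_k
        high = math.inf if k_low <= 0 else mn / k_low
        low = mn / k_high
    low = max(low, 0.0)
    estimate.ci_low, estimate.ci_high = low, high
    estimate.ci_method, estimate.ci_level = method, level
    return low, high


@dataclass
class FnrEstimate:
    """False-negative rate of well-studied curated data against HT evidence."""

    fnr: float
    tp_ht_ws: float
    tp_overlap_ws: float


def lc_ws_false_negative_rate(
    ht_ws: InteractionDataset,
    lc: InteractionDataset,
    fdr_ht_ws: Optional[float] = None,
    component_sizes: Optional[dict] = None,
    fdrs: Optional[ErrorRateTable] = None,
    components: Optional[list] = None,
) -> FnrEstimate:
    """FNR of curated data among well-studied HT true positives.

    ``FNR = 1 - TP(HT_WS ∩ LC) / TP(HT_WS)``, where ``TP(HT_WS)`` is the HT
    dataset restricted to well-studied pairs corrected for its FDR (a single
    rate ``fdr_ht_ws``, or the component sum for union datasets via
    ``component_sizes``/``fdrs``/``components``), and every intersection pair
    counts as true positive.  Clamped to [0, 1].
    """
    if component_sizes is not None:
        if fdrs is None or components is None:
            raise ConfigurationError("component_sizes requires fdrs and components")
        tp_ht_ws = ht_true_positives(component_sizes, fdrs, components, union_size=len(ht_ws))
    else:
        if fdr_ht_ws is None:
            raise ConfigurationError("either fdr_ht_ws or component_sizes must be given")
        if len(ht_ws) == 0:
            raise EstimationError("empty well-studied HT dataset")
        tp_ht_ws = len(ht_ws) * (1.0 - fdr_ht_ws)
    if tp_ht_ws <= 0:
        raise EstimationError("zero estimated true positives in well-studied HT data")
    overlap = len(ht_ws.pairs & lc.pairs)
    fnr = 1.0 - overlap / tp_ht_ws
    return FnrEstimate(fnr=min(1.0, max(0.0, fnr)), tp_ht_ws=tp_ht_ws, tp_overlap_ws=overlap)
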