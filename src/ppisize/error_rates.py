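"""False-discovery-rate chaining and true-positive accounting.

High-throughput (HT) interaction datasets have unknown error rates, but their
relative coverage by an independent literature-curated reference constrains
them jointly.  Partition each HT dataset into true positives found in the
reference (A), true positives not found (B) and false positives (C), and
assume the reference covers the same fraction of true positives in every HT
dataset (A1/B1 = A2/B2).  Writing ``alpha`` for the ratio of the two
observable coverage proportions A/(A+B+C), the false-discovery rates obey

    FDR_1 = alpha * FDR_2 + 1 - alpha.

Anchoring one dataset's FDR (the proteome-wide Y2H screen CCSB-YI1, by
default at 0.25) therefore fixes all the others.  True-positive counts then
follow by subtracting the expected false positives:

* HT (possibly a union): ``TP = |HT| - sum_i |HT_i| * FDR_i`` over components,
* curated well-studied data: ``TP = |LC_WS| - fp_rate * |LC_WS_unique|``
  where the unique subset (single paper, absent from HT) carries the
  recuration-derived false-positive rate (35% by default),
* the HT/LC intersection is counted entirely as true positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .exceptions import ConfigurationError, EstimationError, InputError
from .pairs import InteractionDataset

__all__ = [
    "FdrChainInput",
    "ErrorRateTable",
    "coverage_proportion",
    "alpha_ratio",
    "chain_fdr",
    "ht_true_positives",
    "lc_ws_true_positives",
    "overlap_true_positives",
]


@dataclass(frozen=True)
class FdrChainInput:
    """Inputs of the chaining relation.

    ``prop_target``/``prop_ref``: fraction of the target / reference HT
    dataset found in the pre-2000 curated reference (A/(A+B+C));
    ``fdr_ref``: the anchored reference FDR.
    """

    prop_target: float
    prop_ref: float
    fdr_ref: float

    def __post_init__(self):
        for name in ("prop_target", "prop_ref", "fdr_ref"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name}={v} outside [0, 1]")
        if self.prop_ref == 0:
            raise InputError("reference coverage proportion must be > 0")


def coverage_proportion(ht: InteractionDataset, lc_ref: InteractionDataset) -> float:
    """Fraction of HT pairs present in the curated reference, |HT ∩ LC| / |HT|."""
    if len(ht) == 0:
        raise EstimationError(f"coverage proportion undefined for empty dataset {ht.name!r}")
    return len(ht.pairs & lc_ref.pairs) / len(ht)


def alpha_ratio(prop_target: float, prop_ref: float) -> float:
    """Ratio of coverage proportions, target over reference."""
    if prop_ref == 0:
        raise InputError("reference proportion must be non-zero")
    return prop_target / prop_ref


def chain_fdr(inp: FdrChainInput) -> float:
    """Derive the target dataset's FDR from the reference FDR.

    ``FDR_target = alpha * FDR_ref + 1 - alpha``.  Raw values outside [0, 1]
    (possible when the rounded input proportions make alpha > 1/(1-FDR_ref))
    are clamped with a warning.
    """
    alpha = alpha_ratio(inp.prop_target, inp.prop_ref)
    raw = alpha * inp.fdr_ref + 1.0 - alpha
    if raw < 0.0 or raw > 1.0:
        warnings.warn(
            f"chained FDR {raw:.4f} outside [0, 1]; clamping "
            f"(alpha={alpha:.4f}, fdr_ref={inp.fdr_ref})",
            stacklevel=2,
        )
        return min(1.0, max(0.0, raw))
    return raw


@dataclass
class ErrorRateTable:
    """Per-dataset FDRs anchored on a reference dataset.

    ``lc_unique_fp_rate`` is the false-positive rate applied to single-paper
    curated interactions absent from HT data.
    """

    fdr_per_dataset: dict[str, float] = field(default_factory=dict)
    reference_dataset: str = "CCSB-YI1"
    reference_fdr: float = 0.25
    lc_unique_fp_rate: float = 0.35

    def __post_init__(self):
        for name, v in self.fdr_per_dataset.items():
            if not 0.0 <= v <= 1.0:
                raise InputError(f"FDR for {name} outside [0, 1]: {v}")
        if not 0.0 <= self.reference_fdr <= 1.0:
            raise InputError("reference FDR outside [0, 1]")
        if not 0.0 <= self.lc_unique_fp_rate <= 1.0:
            raise InputError("lc_unique_fp_rate outside [0, 1]")
        self.fdr_per_dataset.setdefault(self.reference_dataset, self.reference_fdr)

    @classmethod
    def from_coverage(
        cls,
        coverages: Mapping[str, float],
        reference_dataset: str = "CCSB-YI1",
        reference_fdr: float = 0.25,
        lc_unique_fp_rate: float = 0.35,
    ) -> "ErrorRateTable":
        """Chain every dataset's FDR from its coverage proportion."""
        if reference_dataset not in coverages:
            raise ConfigurationError(
                f"reference dataset {reference_dataset!r} missing from coverages"
            )
        p_ref = coverages[reference_dataset]
        fdrs = {
            name: chain_fdr(FdrChainInput(p, p_ref, reference_fdr))
            for name, p in coverages.items()
        }
        fdrs[reference_dataset] = reference_fdr
        return cls(
            fdr_per_dataset=fdrs,
            reference_dataset=reference_dataset,
            reference_fdr=reference_fdr,
            lc_unique_fp_rate=lc_unique_fp_rate,
        )

    def __getitem__(self, dataset: str) -> float:
        try:
            return self.fdr_per_dataset[dataset]
        except KeyError:
            raise ConfigurationError(f"no FDR configured for dataset {dataset!r}") from None

    def to_tsv(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("dataset\tfdr\tis_reference\n")
            for name in sorted(self.fdr_per_dataset):
                ref = int(name == self.reference_dataset)
                fh.write(f"{name}\t{self.fdr_per_dataset[name]:.6f}\t{ref}\n")

    @classmethod
    def from_tsv(cls, path, lc_unique_fp_rate: float = 0.35) -> "ErrorRateTable":
        fdrs: dict[str, float] = {}
        reference = None
        with open(path, "rt", encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("dataset"):
                raise InputError(f"unexpected header in {path}")
            for line in fh:
                name, fdr, is_ref = line.rstrip("\n").split("\t")
                fdrs[name] = float(fdr)
                if int(is_ref):
                    reference = name
        if reference is None:
            raise InputError(f"no reference dataset flagged in {path}")
        return cls(
            fdr_per_dataset=fdrs,
            reference_dataset=reference,
            reference_fdr=fdrs[reference],
            lc_unique_fp_rate=lc_unique_fp_rate,
        )


def ht_true_positives(
    component_sizes: Mapping[str, int],
    fdrs: ErrorRateTable,
    components: Iterable[str],
    union_size: Optional[int] = None,
) -> float:
    """Expected true positives in an HT dataset or union of HT datasets.

    ``|HT| - sum_i |HT_i| * FDR_i`` where ``|HT|`` is the deduplicated union
    size and the false-positive sum runs over components at their full sizes
    (no overlap correction).  For a single dataset this is ``|HT|*(1-FDR)``.
    """
    components = list(components)
    if not components:
        raise ConfigurationError("at least one HT component required")
    for c in components:
        if c not in component_sizes:
            raise ConfigurationError(f"no size given for HT component {c!r}")
    if union_size is None:
        if len(components) != 1:
            raise ConfigurationError("union_size required for multi-component HT data")
        union_size = component_sizes[components[0]]
    fp = sum(component_sizes[c] * fdrs[c] for c in components)
    return union_size - fp


def lc_ws_true_positives(
    lc_ws_size: float, unique_ws_size: float, fp_rate: float = 0.35
) -> float:
    """Expected true positives among curated well-studied interactions."""
    if not 0.0 <= fp_rate <= 1.0:
        raise InputError(f"fp_rate {fp_rate} outside [0, 1]")
    if unique_ws_size > lc_ws_size:
        raise InputError(
            f"unique subset ({unique_ws_size}) larger than its superset ({lc_ws_size})"
        )
    return lc_ws_size - fp_rate * unique_ws_size


def overlap_true_positives(ht: InteractionDataset, lc_ws: InteractionDataset) -> int:
    """Size of the HT / curated-well-studied intersection (all true positive)."""
    return len(ht.pairs & lc_ws.pairs)
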