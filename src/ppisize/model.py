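"""Model/Results interface tying the full estimation pipeline together.

:class:`InteractomeSizeModel` holds the curated dataset, the high-throughput
roster and the study-level table together with the analysis parameters;
:meth:`InteractomeSizeModel.fit` runs the whole pipeline — pre-2000
restriction, coverage proportions, FDR chaining, well-studied restriction,
unique-subset accounting, true-positive counts, the overlap estimator and its
confidence interval — and returns an :class:`InteractomeSizeResults` carrying
the estimate, the chained error rates, all intermediates and a calculation
table with one column per HT dataset.  Sensitivity sweeps over the
well-studied cutoff and the reference FDR hang off the model.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

from . import error_rates as er
from .estimation import (
    FnrEstimate,
    SizeEstimate,
    confidence_interval,
    estimate_size,
    lc_ws_false_negative_rate,
    round_half_away,
)
from .exceptions import ConfigurationError, EstimationError, InputError
from .pairs import (
    InteractionDataset,
    StudyLevels,
    restrict_before_year,
    restrict_well_studied,
    single_paper_unique,
    union_all,
    well_studied_set,
)

__all__ = ["InteractomeSizeModel", "InteractomeSizeResults"]

UNION_NAME = "HT-Union"


class InteractomeSizeModel:
    """Overlap-based interactome size model.

    Parameters
    ----------
    lc
        Curated low-throughput binary-physical dataset.
    ht_datasets
        Mapping of HT dataset name to dataset.  The union of all of them is
        available under the name ``"HT-Union"``.
    study_levels
        Papers-per-protein table.
    reference_dataset, reference_fdr
        Anchor of the FDR chain (default CCSB-YI1 at 0.25).
    well_studied_cutoff
        Minimum number of citing papers for a protein to count as
        well-studied (default 125).
    ws_mode
        ``'any'`` (default) keeps curated pairs with at least one well-studied
        endpoint, ``'both'`` requires both.
    unique_fp_rate
        False-positive rate of single-paper curated interactions absent from
        HT data (default 0.35).
    pre2000_year
        Publication-year cutoff for the FDR-chaining reference (default 2000,
        the publication date of the oldest HT screen).
    """

    def __init__(
        self,
        lc: InteractionDataset,
        ht_datasets: dict[str, InteractionDataset],
        study_levels: StudyLevels,
        *,
        reference_dataset: str = "CCSB-YI1",
        reference_fdr: float = 0.25,
        well_studied_cutoff: int = 125,
        ws_mode: str = "any",
        unique_fp_rate: float = 0.35,
        pre2000_year: int = 2000,
    ):
        if reference_dataset not in ht_datasets:
            raise ConfigurationError(
                f"reference dataset {reference_dataset!r} not in the HT roster "
                f"{sorted(ht_datasets)}"
            )
        self.lc = lc
        self.ht_datasets = dict(ht_datasets)
        self.study_levels = study_levels
        self.reference_dataset = reference_dataset
        self.reference_fdr = reference_fdr
        self.well_studied_cutoff = well_studied_cutoff
        self.ws_mode = ws_mode
        self.unique_fp_rate = unique_fp_rate
        self.pre2000_year = pre2000_year
        self._lc_pre2000 = restrict_before_year(lc, pre2000_year)
        self._union = union_all(self.ht_datasets.values(), name=UNION_NAME)

    # -- pieces -------------------------------------------------------------
    @property
    def lc_pre2000(self) -> InteractionDataset:
        return self._lc_pre2000

    def ht(self, target: str) -> InteractionDataset:
        if target == UNION_NAME:
            return self._union
        try:
            return self.ht_datasets[target]
        except KeyError:
            raise ConfigurationError(f"unknown HT dataset {target!r}") from None

    def components(self, target: str) -> list[str]:
        return list(self.ht_datasets) if target == UNION_NAME else [target]

    def error_rate_table(self, reference_fdr: Optional[float] = None) -> er.ErrorRateTable:
        """Chain all HT FDRs from pre-2000 coverage proportions."""
        coverages = {
            name: er.coverage_proportion(ds, self._lc_pre2000)
            for name, ds in self.ht_datasets.items()
        }
        return er.ErrorRateTable.from_coverage(
            coverages,
            reference_dataset=self.reference_dataset,
            reference_fdr=self.reference_fdr if reference_fdr is None else reference_fdr,
            lc_unique_fp_rate=self.unique_fp_rate,
        )

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        target: str = UNION_NAME,
        *,
        ci_method: str = "transformed_overlap",
        ci_level: float = 0.95,
        reference_fdr: Optional[float] = None,
        well_studied_cutoff: Optional[int] = None,
    ) -> "InteractomeSizeResults":
        """Run the full pipeline for one HT dataset (or the union)."""
        cutoff = self.well_studied_cutoff if well_studied_cutoff is None else well_studied_cutoff
        fdr_table = self.error_rate_table(reference_fdr)
        ws = well_studied_set(self.study_levels, cutoff)
        lc_ws = restrict_well_studied(self.lc, ws, self.ws_mode)
        ht = self.ht(target)
        comps = self.components(target)
        sizes = {name: len(self.ht_datasets[name]) for name in comps}
        tp_ht = er.ht_true_positives(sizes, fdr_table, comps, union_size=len(ht))
        unique_ws = single_paper_unique(lc_ws, ht)
        tp_lc = er.lc_ws_true_positives(len(lc_ws), len(unique_ws), self.unique_fp_rate)
        overlap = er.overlap_true_positives(ht, lc_ws)
        snapshot = {
            "ht_dataset": target,
            "well_studied_cutoff": cutoff,
            "ws_mode": self.ws_mode,
            "reference_dataset": self.reference_dataset,
            "reference_fdr": fdr_table.reference_fdr,
            "unique_fp_rate": self.unique_fp_rate,
            "pre2000_year": self.pre2000_year,
            "lc_ws_size": len(lc_ws),
            "lc_ws_unique_size": len(unique_ws),
            "ht_size": len(ht),
        }
        est = estimate_size(tp_ht, tp_lc, overlap, config_snapshot=snapshot)
        confidence_interval(est, level=ci_level, method=ci_method)
        return InteractomeSizeResults(self, target, est, fdr_table, ws, lc_ws, unique_ws)

    # -- sweeps -------------------------------------------------------------
    def sweep_well_studied_cutoff(
        self,
        cutoffs: Sequence[int],
        targets: Optional[Iterable[str]] = None,
    ) -> pd.DataFrame:
        """One full estimate per (cutoff, HT dataset); zero-overlap rows flagged."""
        cutoffs = sorted(set(int(c) for c in cutoffs))
        if not cutoffs:
            raise ConfigurationError("cutoff sweep needs at least one value")
        targets = list(targets) if targets is not None else [*self.ht_datasets, UNION_NAME]
        rows = []
        for cutoff in cutoffs:
            for target in targets:
                rows.append(self._sweep_row(target, cutoff=cutoff))
        return pd.DataFrame(rows)

    def sweep_reference_fdr(
        self,
        fdr_values: Sequence[float],
        targets: Optional[Iterable[str]] = None,
    ) -> pd.DataFrame:
        """One full estimate per (reference FDR, HT dataset)."""
        values = sorted(set(float(v) for v in fdr_values))
        if not values:
            raise ConfigurationError("FDR sweep needs at least one value")
        targets = list(targets) if targets is not None else [*self.ht_datasets, UNION_NAME]
        rows = []
        for fdr in values:
            for target in targets:
                rows.append(self._sweep_row(target, reference_fdr=fdr))
        return pd.DataFrame(rows)

    def _sweep_row(self, target: str, cutoff: Optional[int] = None,
                   reference_fdr: Optional[float] = None) -> dict:
        row = {
            "well_studied_cutoff": cutoff if cutoff is not None else self.well_studied_cutoff,
            "reference_fdr": reference_fdr if reference_fdr is not None else self.reference_fdr,
            "dataset": target,
        }
        try:
            res = self.fit(target, well_studied_cutoff=cutoff, reference_fdr=reference_fdr)
            est = res.estimate
            row.update(
                interactome_size=est.interactome_size,
                tp_ht=est.tp_ht,
                tp_lc_ws=est.tp_lc_ws,
                tp_overlap=est.tp_overlap,
                flag="",
            )
        except EstimationError as exc:
            row.update(
                interactome_size=float("nan"), tp_ht=float("nan"),
                tp_lc_ws=float("nan"), tp_overlap=0, flag=f"unbounded: {exc}",
            )
        except InputError as exc:
            row.update(
                interactome_size=float("nan"), tp_ht=float("nan"),
                tp_lc_ws=float("nan"), tp_overlap=0, flag=f"degenerate: {exc}",
            )
        return row

    def fit_all(self, **kwargs) -> pd.DataFrame:
        """Calculation table with one column per HT dataset plus the union."""
        results = {
            name: self.fit(name, **kwargs) for name in [*self.ht_datasets, UNION_NAME]
        }
        table = {}
        for name, res in results.items():
            est = res.estimate
            table[name] = {
                "LC well-studied size": est.config_snapshot["lc_ws_size"],
                "LC well-studied TPs": round(est.tp_lc_ws, 2),
                "HT TPs": round(est.tp_ht, 2),
                "HT ∩ LC well-studied": int(est.tp_overlap),
                "Estimated size": est.rounded,
            }
        return pd.DataFrame(table)


class InteractomeSizeResults:
    """Results of a fitted interactome-size model."""

    def __init__(
        self,
        model: InteractomeSizeModel,
        target: str,
        estimate: SizeEstimate,
        error_rates: er.ErrorRateTable,
        well_studied: set[str],
        lc_ws: InteractionDataset,
        lc_ws_unique: InteractionDataset,
    ):
        self.model = model
        self.target = target
        self.estimate = estimate
        self.error_rates = error_rates
        self.well_studied = well_studied
        self.lc_ws = lc_ws
        self.lc_ws_unique = lc_ws_unique

    @property
    def interactome_size(self) -> float:
        return self.estimate.interactome_size

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.estimate.ci_low, self.estimate.ci_high)

    def false_negative_rate(self) -> FnrEstimate:
        """FNR of curated well-studied data against the target HT dataset."""
        ht = self.model.ht(self.target)
        ht_ws = restrict_well_studied(ht, self.well_studied, self.model.ws_mode)
        comps = self.model.components(self.target)
        ws_sizes = {
            name: len(restrict_well_studied(self.model.ht_datasets[name],
                                            self.well_studied, self.model.ws_mode))
            for name in comps
        }
        return lc_ws_false_negative_rate(
            ht_ws, self.model.lc,
            component_sizes=ws_sizes, fdrs=self.error_rates, components=comps,
        )

    def summary_frame(self) -> pd.DataFrame:
        est = self.estimate
        rows = [
            ("LC well-studied size", est.config_snapshot["lc_ws_size"]),
            ("LC well-studied unique size", est.config_snapshot["lc_ws_unique_size"]),
            ("LC well-studied TPs", round(est.tp_lc_ws, 2)),
            ("HT size", est.config_snapshot["ht_size"]),
            ("HT TPs", round(est.tp_ht, 2)),
            ("HT ∩ LC well-studied", int(est.tp_overlap)),
            ("Estimated size", est.rounded),
            (f"CI {est.ci_level:.0%} low ({est.ci_method})", round_half_away(est.ci_low)),
            (f"CI {est.ci_level:.0%} high ({est.ci_method})",
             round_half_away(est.ci_high) if est.ci_high != float("inf") else "inf"),
        ]
        return pd.DataFrame(rows, columns=["quantity", self.target]).set_index("quantity")

    def summary(self) -> str:
        """Human-readable calculation report for the fitted target."""
        est = self.estimate
        lines = [
            "Interactome size estimate (overlap method)",
            "=" * 44,
            f"HT dataset:            {self.target}",
            f"well-studied cutoff:   {est.config_snapshot['well_studied_cutoff']} papers "
            f"(mode={est.config_snapshot['ws_mode']}, {len(self.well_studied)} proteins)",
            f"reference FDR:         {self.error_rates.reference_dataset} = "
            f"{self.error_rates.reference_fdr:.2f}",
            "chained FDRs:          "
            + ", ".join(f"{k}={v:.2f}" for k, v in sorted(self.error_rates.fdr_per_dataset.items())),
            "-" * 44,
        ]
        for name, value in self.summary_frame()[self.target].items():
            if isinstance(value, float) and value.is_integer():
                value = int(value)
            lines.append(f"{name:<36}{value}")
        return "\n".join(lines)
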