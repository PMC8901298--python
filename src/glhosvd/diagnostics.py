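"""Diagnostic-concordance statistics for 2x2 contingency tables.

A modality's calls (here: penumbra present / absent on DWI) are compared
against a gold standard (PET) via the four-cell table

                    gold +   gold -
    modality +        TP       FP
    modality -        FN       TN

from which sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/N, and Cohen's chance-corrected kappa

    kappa = (p_o - p_e) / (1 - p_e),
    p_o = (TP+TN)/N,
    p_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / N^2

are derived.  Kappa interpretation bands: >= 0.75 quite satisfactory,
0.4 to 0.75 relatively satisfactory, < 0.4 not ideal.

Published tables sometimes print marginal totals that disagree with their
own cells; :class:`ConfusionTable` accepts the printed marginals, reports
any inconsistency explicitly, and can compute statistics from either
reading, never silently correcting one with the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionTable",
    "UndefinedStatisticError",
    "sen_spec_acc",
    "cohen_kappa",
    "kappa_interpretation",
    "table_from_calls",
    "call_penumbra",
]


class UndefinedStatisticError(ZeroDivisionError):
    """A requested statistic has a zero denominator (or p_e = 1 for kappa)."""


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FP/TN/FN counts, with optional printed marginals for cross-checks.

    ``printed_gold_totals`` are the (gold-positive, gold-negative) column
    totals as published; ``printed_call_totals`` the (call-positive,
    call-negative) row totals; ``printed_total`` the grand total.  These
    are retained verbatim so that disagreement with the cells can be
    surfaced rather than resolved.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    printed_gold_totals: tuple[int, int] | None = None
    printed_call_totals: tuple[int, int] | None = None
    printed_total: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.total < 1:
            raise ValueError("table must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def gold_positive(self) -> int:
        return self.tp + self.fn

    @property
    def gold_negative(self) -> int:
        return self.fp + self.tn

    @property
    def call_positive(self) -> int:
        return self.tp + self.fp

    @property
    def call_negative(self) -> int:
        return self.fn + self.tn

    def marginal_report(self) -> list[str]:
        """Human-readable list of printed-marginal/cell inconsistencies."""
        issues: list[str] = []
        if self.printed_gold_totals is not None:
            for printed, cells, label in zip(
                self.printed_gold_totals,
                (self.gold_positive, self.gold_negative),
                ("gold-positive", "gold-negative"),
            ):
                if printed != cells:
                    issues.append(
                        f"{label} column: cells sum to {cells} but printed total is {printed}"
                    )
        if self.printed_call_totals is not None:
            for printed, cells, label in zip(
                self.printed_call_totals,
                (self.call_positive, self.call_negative),
                ("call-positive", "call-negative"),
            ):
                if printed != cells:
                    issues.append(
                        f"{label} row: cells sum to {cells} but printed total is {printed}"
                    )
        if self.printed_total is not None and self.printed_total != self.total:
            issues.append(
                f"grand total: cells sum to {self.total} but printed total is "
                f"{self.printed_total}"
            )
        return issues

    def sensitivity(self, use_printed_marginal: bool = False) -> float:
        """TP over gold-positives; optionally over the printed column total.

        When a table's cells and printed marginals disagree, the two
        denominators give different sensitivities; both readings are
        exposed and neither is preferred.
        """
        denom = self.gold_positive
        if use_printed_marginal:
            if self.printed_gold_totals is None:
                raise ValueError("table carries no printed gold totals")
            denom = self.printed_gold_totals[0]
        if denom == 0:
            raise UndefinedStatisticError("no gold-positive samples")
        return self.tp / denom

    def specificity(self) -> float:
        if self.gold_negative == 0:
            raise UndefinedStatisticError("no gold-negative samples")
        return self.tn / self.gold_negative

    def accuracy(self, use_printed_total: bool = False) -> float:
        """Correct calls over all samples; optionally over the printed total.

        When the cells do not sum to the printed grand total, the published
        accuracy may divide by the printed figure; both readings are
        exposed.
        """
        denom = self.total
        if use_printed_total:
            if self.printed_total is None:
                raise ValueError("table carries no printed grand total")
            denom = self.printed_total
        return (self.tp + self.tn) / denom

    def prevalence(self, use_printed_marginal: bool = False) -> float:
        """Gold-positive fraction of the cohort."""
        if use_printed_marginal and self.printed_gold_totals is not None:
            num = self.printed_gold_totals[0]
            denom = self.printed_total if self.printed_total is not None else self.total
        else:
            num, denom = self.gold_positive, self.total
        return num / denom


def sen_spec_acc(t: ConfusionTable) -> tuple[float, float, float]:
    """Sensitivity, specificity, accuracy as proportions in [0, 1]."""
    return t.sensitivity(), t.specificity(), t.accuracy()


def cohen_kappa(t: ConfusionTable) -> float:
    """Cohen's unweighted kappa for a 2x2 table, in [-1, 1]."""
    n = t.total
    p_o = (t.tp + t.tn) / n
    p_e = (t.call_positive * t.gold_positive + t.call_negative * t.gold_negative) / n**2
    if p_e == 1.0:
        raise UndefinedStatisticError("kappa undefined: expected agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def kappa_interpretation(kappa: float) -> str:
    """Agreement band for a kappa value.

    >= 0.75: "quite satisfactory"; 0.4 to < 0.75: "relatively
    satisfactory"; < 0.4: "not ideal".
    """
    if kappa >= 0.75:
        return "quite satisfactory"
    if kappa >= 0.4:
        return "relatively satisfactory"
    return "not ideal"


def table_from_calls(
    truth: Sequence[int] | np.ndarray, calls: Sequence[int] | np.ndarray
) -> ConfusionTable:
    """Build a confusion table from parallel binary truth/call sequences."""
    t = np.asarray(truth).astype(bool)
    c = np.asarray(calls).astype(bool)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("truth and calls must be equal-length 1-D sequences")
    if t.size < 1:
        raise ValueError("need at least one sample")
    return ConfusionTable(
        tp=int(np.sum(t & c)),
        fp=int(np.sum(~t & c)),
        fn=int(np.sum(t & ~c)),
        tn=int(np.sum(~t & ~c)),
    )


def call_penumbra(
    adc: np.ndarray,
    lesion_mask: np.ndarray,
    core_threshold: float = 0.55,
    penumbra_band: tuple[float, float] = (0.55, 1.0),
    min_band_pixels: int = 1,
) -> bool:
    """Rule-based penumbra call from an ADC map (1e-3 mm^2/s).

    Flags the lesion as containing an ischemic penumbra when it holds both
    a sub-threshold infarct core (ADC < ``core_threshold``) and at least
    ``min_band_pixels`` pixels inside the open penumbra ADC band.  A core
    without a surrounding band, or normal tissue alone, is called negative.
    """
    lo, hi = penumbra_band
    if not core_threshold <= lo < hi:
        raise ValueError("require core_threshold <= band_low < band_high")
    adc = np.asarray(adc, dtype=np.float64)
    mask = np.asarray(lesion_mask, dtype=bool)
    if adc.shape != mask.shape:
        raise ValueError("adc and lesion_mask must share a shape")
    if not mask.any():
        raise ValueError("penumbra call undefined on an empty lesion mask")
    vals = adc[mask]
    vals = vals[np.isfinite(vals)]
    n_core = int(np.sum(vals < core_threshold))
    n_band = int(np.sum((vals > lo) & (vals < hi)))
    return n_core >= 1 and n_band >= min_band_pixels
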