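"""Bundled reference contingency tables from the clinical evaluation.

Two cohorts of 105 acute-cerebral-infarction patients each were screened
for ischemic penumbra, one read on conventional DWI and one on GL-HOSVD
denoised DWI, with PET as the gold standard.  The four-cell tables are
reproduced here together with their printed marginal totals, which for the
denoised-DWI table disagree with the cells (79 + 8 = 87 gold-positives by
cells vs 89 printed; grand total 103 vs 105 printed).  The tables keep both
readings so downstream statistics can surface the inconsistency.
"""

from __future__ import annotations

from .diagnostics import ConfusionTable

__all__ = ["conventional_dwi_table", "denoised_dwi_table"]


def conventional_dwi_table() -> ConfusionTable:
    """Conventional-DWI penumbra detection vs PET (n = 105).

    Sensitivity 57.78%, specificity 53.33%, accuracy 57.14%.
    """
    return ConfusionTable(
        tp=52,
        fp=7,
        fn=38,
        tn=8,
        printed_gold_totals=(90, 15),
        printed_call_totals=(59, 46),
        printed_total=105,
    )


def denoised_dwi_table() -> ConfusionTable:
    """Denoised-DWI penumbra detection vs PET (n = 105, as printed).

    Specificity 81.25%.  Sensitivity is 79/87 = 90.80% by the cells but
    79/89 = 88.76% by the printed gold-positive marginal; accuracy is
    92/103 = 89.32% by the cells but 92/105 = 87.62% by the printed grand
    total — the published figures use the printed marginals.
    ``marginal_report`` lists the cell/marginal disagreements.
    """
    return ConfusionTable(
        tp=79,
        fp=3,
        fn=8,
        tn=13,
        printed_gold_totals=(89, 16),
        printed_call_totals=(82, 21),
        printed_total=105,
    )
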