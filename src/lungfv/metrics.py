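"""Cohort-level summaries, pulmonary-function classification, and the
normal-vs-abnormal group comparison.

A patient is classified as having pre-existing lung disease when either
FEV1/FVC < 0.7 (airway obstruction, the GOLD cutoff) or DLCO < 60% of
predicted (diffusion impairment). Missing values give status ``"missing"``
— never silently normal — and such patients are excluded from group
comparisons.

Summaries report median, interquartile range (linear interpolation between
order statistics, the common spreadsheet convention, fixed here so IQRs are
reproducible), min, max and n. The group comparison is a two-sided
two-sample Student's t-test with pooled variance (df = n_a + n_b - 2);
Welch's unequal-variance variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import LungFVError

__all__ = [
    "PatientRecord",
    "SummaryRow",
    "classify_pft",
    "summarize",
    "summarize_values",
    "compare_groups",
]


def classify_pft(fev1_fvc_ratio: Optional[float], dlco_pct_predicted: Optional[float]) -> str:
    """Classify pulmonary function as ``"normal"`` / ``"abnormal"`` / ``"missing"``.

    Abnormal iff FEV1/FVC < 0.7 or DLCO < 60% predicted. Any missing or
    non-finite input yields ``"missing"``.
    """
    def _bad(x):
        return x is None or not np.isfinite(x) or x <= 0

    if _bad(fev1_fvc_ratio) or _bad(dlco_pct_predicted):
        return "missing"
    return "abnormal" if (fev1_fvc_ratio < 0.7 or dlco_pct_predicted < 60.0) else "normal"


@dataclass
class PatientRecord:
    """Scalar per-patient results (no masks) plus pulmonary function tests.

    ``measurements`` maps a label such as ``"FV50%"`` or ``"30%pmax"`` to
    that patient's value (e.g. volume as % of the AV).
    """

    patient_id: str
    measurements: Dict[str, float] = field(default_factory=dict)
    fev1_fvc_ratio: Optional[float] = None
    dlco_pct_predicted: Optional[float] = None

    @property
    def pft_status(self) -> str:
        return classify_pft(self.fev1_fvc_ratio, self.dlco_pct_predicted)


@dataclass
class SummaryRow:
    label: str
    median: float
    iqr_lo: float
    iqr_hi: float
    min: float
    max: float
    n: int


def summarize_values(values: Sequence[float], label: str) -> SummaryRow:
    """Median / IQR / range summary of a list of values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise LungFVError(f"no values to summarize for {label!r}")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return SummaryRow(label, float(med), float(q1), float(q3), float(arr.min()), float(arr.max()), int(arr.size))


def summarize(records: Sequence[PatientRecord], label: str) -> SummaryRow:
    """Summarize one labeled measurement across patient records carrying it."""
    vals = [r.measurements[label] for r in records if label in r.measurements]
    if not vals:
        raise LungFVError(f"no record carries measurement {label!r}")
    return summarize_values(vals, label)


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], welch: bool = False
) -> Tuple[float, float, float]:
    """Two-sided two-sample t-test; returns ``(t, df, p)``.

    Default is Student's pooled-variance t (df = n_a + n_b - 2); the sign
    convention is mean(a) - mean(b). ``welch=True`` drops the equal-variance
    assumption (Welch-Satterthwaite df).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise LungFVError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise LungFVError("degenerate groups: both have zero variance")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if welch else float(a.size + b.size - 2)
    return float(res.statistic), df, float(res.pvalue)
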