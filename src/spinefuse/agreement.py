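"""Agreement statistics: per-unit difference distributions and patient-level ICC.

Two descriptive tables mirror the study design:

- inter-reader differences: reader1 - reader2 change score per
  (patient, vertebral unit), summarized per unit level across patients;
- inter-method sign differences: sign(mean fusion-based change of two
  readers) - sign(mean Berlin change of two readers) per (patient, unit),
  bounded in -2..+2; |d| <= 1 means the two methods never assert opposite
  directions of change.

Patient-level inter-reader agreement uses the intraclass correlation
coefficient ICC(A,1): two-way model, single measures, absolute agreement,
with the McGraw-Wong F-based 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import BerlinSheet, ScoreSheet, berlin_change, change_sign

__all__ = [
    "DifferenceTable",
    "IccResult",
    "IccUndefinedError",
    "inter_reader_differences",
    "inter_method_sign_differences",
    "patient_level_sum",
    "icc_two_way_absolute_single",
]


@dataclass
class DifferenceTable:
    """Row-level differences plus per-unit-level summaries across patients."""

    rows: pd.DataFrame  # patient_id, vu_index, difference
    summary: pd.DataFrame  # per vu_index: mean, sd, n

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def overall_range(self) -> tuple[float, float]:
        d = self.rows["difference"]
        return float(d.min()), float(d.max())

    @property
    def n_within_one(self) -> int:
        """Count of units where the difference lies in [-1, 1] (no opposing directions)."""
        return int((self.rows["difference"].abs() <= 1).sum())

    def recompute_summary(self) -> pd.DataFrame:
        g = self.rows.groupby("vu_index")["difference"]
        out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="count")
        return out.reset_index()


def _match_patients(a: list, b: list, what: str) -> list[tuple]:
    by_a = {s.patient_id: s for s in a}
    by_b = {s.patient_id: s for s in b}
    if set(by_a) != set(by_b):
        only_a = sorted(set(by_a) - set(by_b))
        only_b = sorted(set(by_b) - set(by_a))
        raise ValueError(f"{what}: unmatched patients (only first: {only_a}, only second: {only_b})")
    return [(by_a[p], by_b[p]) for p in sorted(by_a)]


def _finish(records: list[dict]) -> DifferenceTable:
    rows = pd.DataFrame.from_records(records, columns=["patient_id", "vu_index", "difference"])
    table = DifferenceTable(rows, pd.DataFrame())
    table.summary = table.recompute_summary()
    return table


def inter_reader_differences(
    sheets_r1: list[ScoreSheet], sheets_r2: list[ScoreSheet]
) -> DifferenceTable:
    """Reader1 - reader2 change score per (patient, unit); missing units drop pairwise."""
    records = []
    for s1, s2 in _match_patients(sheets_r1, sheets_r2, "inter_reader_differences"):
        d = s1.scores - s2.scores
        for vu, val in d.dropna().items():
            records.append({"patient_id": s1.patient_id, "vu_index": int(vu), "difference": int(val)})
    return _finish(records)


def inter_method_sign_differences(
    ca_sheets_r1: list[ScoreSheet],
    ca_sheets_r2: list[ScoreSheet],
    berlin_sheets_r1: list[BerlinSheet],
    berlin_sheets_r2: list[BerlinSheet],
    convention: str = "ca_minus_berlin",
) -> DifferenceTable:
    """Difference between the methods' directions of change per (patient, unit).

    d = sign(mean fusion change of two readers) - sign(mean Berlin change
    of two readers) under the default convention; ``convention=
    'berlin_minus_ca'`` flips the order. A unit with d = +1 under the
    default is a change detected only by the fusion-based reading.
    """
    if convention not in ("ca_minus_berlin", "berlin_minus_ca"):
        raise ValueError("convention must be 'ca_minus_berlin' or 'berlin_minus_ca'")
    ca = _match_patients(ca_sheets_r1, ca_sheets_r2, "inter_method (CA readers)")
    be = _match_patients(berlin_sheets_r1, berlin_sheets_r2, "inter_method (Berlin readers)")
    be_by_pid = {s1.patient_id: (s1, s2) for s1, s2 in be}
    if set(be_by_pid) != {s1.patient_id for s1, _ in ca}:
        raise ValueError("inter_method: CA and Berlin cohorts contain different patients")
    records = []
    for c1, c2 in ca:
        bsheets = be_by_pid[c1.patient_id]
        ca_mean = pd.concat([c1.scores, c2.scores], axis=1).mean(axis=1)
        bchange = pd.concat([berlin_change(b) for b in bsheets], axis=1).mean(axis=1)
        for vu in ca_mean.index:
            if pd.isna(ca_mean[vu]) or pd.isna(bchange[vu]):
                continue
            d = change_sign(ca_mean[vu]) - change_sign(bchange[vu])
            if convention == "berlin_minus_ca":
                d = -d
            records.append({"patient_id": c1.patient_id, "vu_index": int(vu), "difference": int(d)})
    return _finish(records)


def patient_level_sum(sheet: ScoreSheet) -> int:
    """Total change for one patient: sum of non-missing unit change scores."""
    s = sheet.scores.dropna()
    if s.empty:
        raise ValueError(f"patient {sheet.patient_id}: all unit scores are missing")
    return int(s.sum())


class IccUndefinedError(ValueError):
    """ICC is undefined because the score matrix has zero total variance."""


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    ms: dict[str, float]  # ANOVA mean squares, retained for audit


def icc_two_way_absolute_single(scores: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(A,1): two-way model, single measures, absolute agreement.

    ``scores`` is an (n subjects x k raters) matrix with no missing cells
    (apply listwise deletion upstream). From the two-way ANOVA
    decomposition with mean squares MSR (subjects), MSC (raters) and MSE:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    The confidence interval is the McGraw-Wong F-based interval with
    Satterthwaite degrees of freedom, matching mainstream statistical
    packages' "two-way, absolute agreement, single measures" output.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2:
        raise ValueError("scores must be a 2D (subjects x raters) matrix")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if k < 2:
        raise ValueError("need at least 2 raters")
    if not np.isfinite(x).all():
        raise ValueError("scores contain missing/non-finite cells; delete listwise upstream")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    ms = {"ms_rows": float(msr), "ms_cols": float(msc), "ms_error": float(mse)}

    if ss_total <= 1e-12 * max(1.0, abs(grand)):
        raise IccUndefinedError("all scores identical: zero total variance, ICC undefined")

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    if mse <= 1e-300 and msc <= 1e-300:
        # Perfect absolute agreement with between-subject variance: the
        # F-interval degenerates; agreement is exact.
        return IccResult(1.0, 1.0, 1.0, n, k, ms)

    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isinf(a) or np.isinf(b):
        v = (n - 1.0) * (k - 1.0)
    else:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        )
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lo = (n * (msr - f_l * mse)) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = (n * (f_u * msr - mse)) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    lo = float(np.clip(lo, -1.0, 1.0))
    hi = float(np.clip(hi, -1.0, 1.0))
    return IccResult(float(icc), lo, hi, n, k, ms)
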