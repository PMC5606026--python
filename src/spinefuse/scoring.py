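"""Change-score data model: reader score sheets, Berlin status scores, and
a quantitative per-unit change statistic.

Two scoring systems coexist:

- the fusion-based change score: one integer per vertebral unit on a
  -2 (dramatic decrease of inflammation) .. +2 (dramatic increase) scale,
  with 0 meaning no net change; an extra flag records the presence of
  inflammation in no-net-change units;
- the Berlin method: a status score 0..3 per unit and time point (0 normal,
  1 under 25% of the unit edematous, 2 25-50%, 3 over 50%), with change
  defined as the status difference once the time order is unblinded, hence
  on a -3..+3 scale.

Sheets are interchanged as CSV (spreadsheet-compatible for clinical
readers) with columns ``patient_id, reader_id, vu_index, change_score,
inflammation_present`` and, for Berlin sheets, ``status_tp1, status_tp2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_VU = 23
CHANGE_SCALE = (-2, -1, 0, 1, 2)
BERLIN_SCALE = (0, 1, 2, 3)

__all__ = [
    "N_VU",
    "ScoreSheet",
    "BerlinSheet",
    "berlin_change",
    "change_sign",
    "VuChangeStat",
    "quantify_vu_change",
    "simulate_cohort_sheets",
    "empty_score_sheet",
]


def _check_vu_index(entries: pd.DataFrame) -> None:
    vu = entries["vu_index"].to_numpy()
    if sorted(vu.tolist()) != list(range(1, N_VU + 1)):
        raise ValueError(
            f"sheet must contain vu_index 1..{N_VU} exactly once each, got {sorted(set(vu))}"
        )


@dataclass
class ScoreSheet:
    """One reader's fusion-based change scores for one patient.

    ``entries`` is indexed by ``vu_index`` (1..23) with a nullable-integer
    ``change_score`` column (missing = the unit was excluded) and a boolean
    ``inflammation_present`` column, meaningful when the change score is 0.
    """

    patient_id: str
    reader_id: str
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        e = self.entries.reset_index() if "vu_index" not in self.entries.columns else self.entries
        _check_vu_index(e)
        scores = e["change_score"]
        bad = scores.dropna()[~scores.dropna().isin(CHANGE_SCALE)]
        if len(bad):
            raise ValueError(f"change scores outside {CHANGE_SCALE}: {sorted(set(bad))}")
        out = e.set_index("vu_index").sort_index()
        out["change_score"] = out["change_score"].astype("Int64")
        if "inflammation_present" in out.columns:
            flag = out["inflammation_present"].fillna(False).astype(bool)
        else:
            flag = pd.Series(False, index=out.index)
        out["inflammation_present"] = flag
        self.entries = out[["change_score", "inflammation_present"]]

    @classmethod
    def from_scores(
        cls,
        patient_id: str,
        reader_id: str,
        scores: dict[int, int | None],
        inflammation: dict[int, bool] | None = None,
    ) -> "ScoreSheet":
        inflammation = inflammation or {}
        df = pd.DataFrame(
            {
                "vu_index": list(range(1, N_VU + 1)),
                "change_score": [scores.get(v) for v in range(1, N_VU + 1)],
                "inflammation_present": [bool(inflammation.get(v, False)) for v in range(1, N_VU + 1)],
            }
        )
        return cls(patient_id, reader_id, df)

    @property
    def scores(self) -> pd.Series:
        return self.entries["change_score"]

    def to_frame(self) -> pd.DataFrame:
        df = self.entries.reset_index()
        df.insert(0, "reader_id", self.reader_id)
        df.insert(0, "patient_id", self.patient_id)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def read_csv(path) -> "list[ScoreSheet]":
        df = pd.read_csv(path)
        sheets = []
        for (pid, rid), grp in df.groupby(["patient_id", "reader_id"], sort=True):
            sheets.append(ScoreSheet(str(pid), str(rid), grp.drop(columns=["patient_id", "reader_id"])))
        return sheets


@dataclass
class BerlinSheet:
    """One reader's Berlin status scores (both time points) for one patient."""

    patient_id: str
    reader_id: str
    entries: pd.DataFrame  # index vu_index; columns status_tp1, status_tp2 (Int64)

    def __post_init__(self) -> None:
        e = self.entries.reset_index() if "vu_index" not in self.entries.columns else self.entries
        _check_vu_index(e)
        out = e.set_index("vu_index").sort_index()
        for col in ("status_tp1", "status_tp2"):
            s = out[col]
            bad = s.dropna()[~s.dropna().isin(BERLIN_SCALE)]
            if len(bad):
                raise ValueError(f"{col} outside {BERLIN_SCALE}: {sorted(set(bad))}")
            out[col] = s.astype("Int64")
        self.entries = out[["status_tp1", "status_tp2"]]

    def to_frame(self) -> pd.DataFrame:
        df = self.entries.reset_index()
        df.insert(0, "reader_id", self.reader_id)
        df.insert(0, "patient_id", self.patient_id)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def read_csv(path) -> "list[BerlinSheet]":
        df = pd.read_csv(path)
        sheets = []
        for (pid, rid), grp in df.groupby(["patient_id", "reader_id"], sort=True):
            sheets.append(BerlinSheet(str(pid), str(rid), grp.drop(columns=["patient_id", "reader_id"])))
        return sheets


def berlin_change(sheet: BerlinSheet) -> pd.Series:
    """Per-unit change = status(TP2) - status(TP1), on the -3..+3 scale.

    Units with a missing status at either time point get a missing change.
    """
    return (sheet.entries["status_tp2"] - sheet.entries["status_tp1"]).astype("Int64")


def change_sign(x: float) -> int:
    """Strict sign of a (mean) change score: -1 decrease, 0 no change, +1 increase."""
    try:
        x = float(x)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"change value must be a finite number, got {x!r}") from exc
    if not np.isfinite(x):
        raise ValueError("change value must be finite")
    return int(np.sign(x))


@dataclass
class VuChangeStat:
    """Quantitative surrogate for the reader: mean normalized intensity change."""

    vu_index: int
    value: float
    n_voxels: int


def quantify_vu_change(
    tp1: "VolumeGrid",
    tp2_aligned: "VolumeGrid",
    vu,
    valid: np.ndarray | None = None,
    window: float | str = "shared_max",
) -> VuChangeStat:
    """Mean normalized intensity difference (TP2 - TP1) within a vertebral unit.

    A machine-readable stand-in for the human change reading: positive
    values mean the unit got brighter at TP2 (inflammation increase on a
    STIR-like contrast). Only voxels with valid resampling contribute.
    """
    from .fusion import normalize_pair

    sel = vu.voxel_mask if valid is None else (vu.voxel_mask & valid)
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"{vu.name}: no valid voxels to quantify")
    pair = normalize_pair(tp1, tp2_aligned, window)
    value = float((pair.tp2[sel] - pair.tp1[sel]).mean())
    return VuChangeStat(vu.vu_index, value, n)


def empty_score_sheet(patient_id: str, reader_id: str) -> ScoreSheet:
    """A blank 23-unit sheet (all scores missing) to hand to a reader."""
    return ScoreSheet.from_scores(patient_id, reader_id, {})


def simulate_cohort_sheets(
    n_patients: int = 25,
    seed: int = 0,
    p_nonzero: float = 0.10,
    p_dramatic: float = 0.2,
    lower_spine_weight: float = 2.0,
    reader_flip_prob: float = 0.10,
    berlin_miss_prob: float = 0.5,
) -> tuple[list[ScoreSheet], list[ScoreSheet], list[BerlinSheet], list[BerlinSheet]]:
    """Simulate a complete early-disease cohort read by two reader pairs.

    Emulates a cohort with low inflammatory activity: most units show no
    change, nonzero true changes are sparse (base probability ``p_nonzero``,
    weighted toward the lower thoracic and lumbar spine where early axial
    disease is most active) and rarely dramatic. Each fusion reader reports
    the true change, occasionally off by one unit of the scale
    (``reader_flip_prob``); each Berlin reader derives statuses consistent
    with the change but misses mild (one-step) changes with probability
    ``berlin_miss_prob`` — mimicking how small gradual changes in an
    existing lesion often leave coarse status scores unchanged.
    """
    rng = np.random.default_rng(seed)
    ca1, ca2, b1, b2 = [], [], [], []
    for p in range(n_patients):
        pid = f"P{p + 1:03d}"
        truth = np.zeros(N_VU, dtype=int)
        for v in range(N_VU):
            w = lower_spine_weight if v + 1 >= 12 else 1.0
            if rng.random() < min(1.0, p_nonzero * w):
                mag = 2 if rng.random() < p_dramatic else 1
                truth[v] = mag * (1 if rng.random() < 0.5 else -1)

        def read(truth_v):
            s = int(truth_v)
            if rng.random() < reader_flip_prob:
                s += 1 if rng.random() < 0.5 else -1
            return int(np.clip(s, -2, 2))

        ca1.append(
            ScoreSheet.from_scores(pid, "R1", {v + 1: read(truth[v]) for v in range(N_VU)})
        )
        ca2.append(
            ScoreSheet.from_scores(pid, "R2", {v + 1: read(truth[v]) for v in range(N_VU)})
        )

        def berlin(truth_v):
            tp1 = int(rng.choice([0, 1], p=[0.8, 0.2]))
            delta = int(truth_v)
            if abs(delta) == 1 and rng.random() < berlin_miss_prob:
                delta = 0
            tp2 = int(np.clip(tp1 + delta, 0, 3))
            return tp1, tp2

        for sheets, rid in ((b1, "B1"), (b2, "B2")):
            rows = [berlin(truth[v]) for v in range(N_VU)]
            df = pd.DataFrame(
                {
                    "vu_index": list(range(1, N_VU + 1)),
                    "status_tp1": [r[0] for r in rows],
                    "status_tp2": [r[1] for r in rows],
                }
            )
            sheets.append(BerlinSheet(pid, rid, df))
    return ca1, ca2, b1, b2
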