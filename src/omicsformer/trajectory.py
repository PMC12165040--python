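"""Longitudinal pre-onset risk trajectories.

Dated blood records of eventual cases are binned by time-to-onset
(half-open year bins [a, b), left-closed), every record is assigned a
risk level with a fitted blood-panel model, and the per-bin risk-group
proportions are summarized with a least-squares trend of the high-risk
proportion toward onset.  A positive slope is the signature expected of
a risk score that climbs as disease onset approaches.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_DAYS_PER_YEAR = 365.25


@dataclass
class LongitudinalRecord:
    """One dated blood-panel record of a patient, with optional onset date."""

    patient_id: str
    record_date: _dt.date
    panel: np.ndarray
    onset_date: _dt.date | None = None

    def __post_init__(self) -> None:
        self.panel = np.asarray(self.panel, dtype=float)

    @property
    def time_to_onset_years(self) -> float:
        if self.onset_date is None:
            raise ValueError(f"record of {self.patient_id!r} has no onset date")
        return (self.onset_date - self.record_date).days / _DAYS_PER_YEAR


@dataclass
class BinnedRecords:
    """Records grouped into time-to-onset bins plus bookkeeping counts."""

    bins: list[list[LongitudinalRecord]]
    bin_edges: list[float]
    n_dropped_beyond: int
    n_excluded_post_onset: int

    @property
    def n_input(self) -> int:
        return (
            sum(len(b) for b in self.bins)
            + self.n_dropped_beyond
            + self.n_excluded_post_onset
        )


@dataclass
class TrajectoryTable:
    """Per-bin risk-level proportions, ordered by decreasing time-to-onset."""

    rows: list[dict]
    k: int
    bin_edges: list[float]
    slope: float | None = None
    increasing_toward_onset: bool | None = None

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            rec = {"bin": row["label"], "midpoint_years": row["midpoint"], "n": row["n"]}
            for level in range(1, self.k + 1):
                rec[f"risk_{level}"] = row["proportions"].get(level) if row["n"] else None
            recs.append(rec)
        return pd.DataFrame(recs)


def bin_by_time_to_onset(
    records: list[LongitudinalRecord], bin_edges_years: list[float]
) -> BinnedRecords:
    """Group records into half-open [e_j, e_{j+1}) bins of years before onset.

    Records past the last edge are dropped (counted); records dated after
    onset are excluded with a warning.  Binning conserves records:
    sum of bin counts + dropped + excluded == input count.
    """
    edges = [float(e) for e in bin_edges_years]
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing with >= 2 entries")
    bins: list[list[LongitudinalRecord]] = [[] for _ in range(len(edges) - 1)]
    dropped = excluded = 0
    for rec in records:
        if rec.onset_date is None:
            raise ValueError(f"record of {rec.patient_id!r} has no onset date")
        t = rec.time_to_onset_years
        if t < 0:
            warnings.warn(
                f"record of {rec.patient_id!r} dated after onset; excluded"
            )
            excluded += 1
            continue
        j = int(np.searchsorted(edges, t, side="right")) - 1
        if j < 0 or j >= len(bins) or t >= edges[-1]:
            dropped += 1
            continue
        bins[j].append(rec)
    return BinnedRecords(bins, edges, dropped, excluded)


def risk_proportions(binned: BinnedRecords, model) -> TrajectoryTable:
    """Assign every record a risk level and tabulate per-bin proportions.

    All records are embedded as one canonically-sorted batch (so the
    result is invariant to input order), then counted per bin.  Bins are
    reported from the most distant to the nearest to onset; empty bins
    carry n=0 and no proportions.
    """
    from .blood_risk import assign_risk
    from .dataio import OmicsMatrix

    tagged = []
    for j, bin_recs in enumerate(binned.bins):
        for rec in bin_recs:
            tagged.append((rec.patient_id, rec.record_date.isoformat(), j, rec))
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))

    levels_per_bin: dict[int, list[int]] = {j: [] for j in range(len(binned.bins))}
    if tagged:
        values = np.stack([t[3].panel for t in tagged])
        ids = [f"r{i}" for i in range(len(tagged))]
        matrix = OmicsMatrix(values, ids, list(model.feature_ids), "blood_panel")
        assignments = assign_risk(matrix, model)
        for (pid, date, j, rec), asg in zip(tagged, assignments):
            levels_per_bin[j].append(asg.risk_level)

    rows = []
    for j in reversed(range(len(binned.bins))):  # decreasing time-to-onset
        lo, hi = binned.bin_edges[j], binned.bin_edges[j + 1]
        levels = levels_per_bin[j]
        n = len(levels)
        props = {}
        if n:
            counts = np.bincount(levels, minlength=model.k + 1)[1:]
            props = {lvl + 1: float(c / n) for lvl, c in enumerate(counts)}
        rows.append(
            {
                "label": f"[{lo:g},{hi:g})y",
                "midpoint": (lo + hi) / 2.0,
                "n": n,
                "proportions": props,
            }
        )
    return TrajectoryTable(rows, model.k, binned.bin_edges)


def trend_test(table: TrajectoryTable) -> tuple[float, bool]:
    """Least-squares slope of the high-risk proportion toward onset.

    The high-risk proportion of each non-empty bin is regressed on the
    negated bin midpoint (so onset is to the right); a positive slope
    flags the expected rising pre-onset pattern.  Requires >= 3 non-empty
    bins.  The slope and flag are also stored on the table.
    """
    pts = [
        (-row["midpoint"], row["proportions"][table.k])
        for row in table.rows
        if row["n"] > 0
    ]
    if len(pts) < 3:
        raise ValueError(f"trend test needs >= 3 non-empty bins, got {len(pts)}")
    x, y = map(np.asarray, zip(*pts))
    slope = float(np.polyfit(x, y, deg=1)[0])
    table.slope = slope
    table.increasing_toward_onset = slope > 0
    return slope, slope > 0


def read_longitudinal(path, feature_ids: list[str] | None = None) -> list[LongitudinalRecord]:
    """Read records from CSV: patient_id, record_date, onset_date, panel...

    Dates are ISO-8601; an empty onset_date marks a non-case.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    meta = {"patient_id", "record_date", "onset_date"}
    if not meta <= set(df.columns):
        raise ValueError(f"longitudinal CSV needs columns {sorted(meta)}")
    panel_cols = [c for c in df.columns if c not in meta]
    if feature_ids is not None:
        panel_cols = list(feature_ids)
    out = []
    for _, row in df.iterrows():
        onset = row["onset_date"]
        out.append(
            LongitudinalRecord(
                patient_id=str(row["patient_id"]),
                record_date=_dt.date.fromisoformat(str(row["record_date"])),
                panel=row[panel_cols].to_numpy(dtype=float),
                onset_date=None if pd.isna(onset) or onset == "" else _dt.date.fromisoformat(str(onset)),
            )
        )
    return out


def write_longitudinal(records: list[LongitudinalRecord], path, feature_ids: list[str]) -> None:
    rows = []
    for rec in records:
        row = {
            "patient_id": rec.patient_id,
            "record_date": rec.record_date.isoformat(),
            "onset_date": "" if rec.onset_date is None else rec.onset_date.isoformat(),
        }
        row.update(dict(zip(feature_ids, rec.panel)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
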