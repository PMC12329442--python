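"""Reading, validation and preparation of anthropometric measurement data.

Conventions used throughout the package:

* ages are *total* ages in years since conception; measurements recorded as
  age since birth are shifted by a gestation of 0.75 yr (nine months);
* heights in cm, weights in grams;
* each prepared person carries a *conception anchor* — a pseudo-observation
  at t = 0 fixing height and weight to those of an egg cell (0.012 cm,
  1.02e-6 g) — so every trajectory is pinned at its biological origin;
* optionally, a person's last observed height and weight are carried forward
  at yearly intervals up to a target age since birth (26 by default in the
  dense design), stabilizing the adult plateau during estimation.

Raw measurements are never smoothed or otherwise altered; preparation only
adds tagged rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EGG_HEIGHT_CM",
    "EGG_WEIGHT_G",
    "GESTATION_YR",
    "MeasurementRecord",
    "LoadReport",
    "PreparedDataset",
    "load_measurements",
    "prepare_dataset",
    "records_to_frame",
    "frame_to_records",
    "write_dataset",
    "read_dataset",
]

#: Egg-cell diameter used as every person's height at conception (cm).
EGG_HEIGHT_CM = 0.012
#: Egg-cell weight used as every person's weight at conception (g).
EGG_WEIGHT_G = 1.02e-6
#: Gestation length (yr): birth at 0.75 on the total-age scale.
GESTATION_YR = 0.75

_COLUMNS = ["person_id", "group", "sex", "t", "height_cm", "weight_g", "provenance"]
_PROVENANCE = ("observed", "conception_anchor", "carried_forward")


@dataclass(frozen=True)
class MeasurementRecord:
    """One observation of one person at one total age.

    At least one of ``height_cm`` / ``weight_g`` must be present (NaN marks a
    missing modality) and present values must be positive.
    """

    person_id: str
    group: str
    sex: str
    t: float
    height_cm: float = np.nan
    weight_g: float = np.nan
    provenance: str = "observed"

    def __post_init__(self) -> None:
        if not np.isfinite(self.t) or self.t < 0:
            raise ValueError(f"total age must be finite and >= 0, got {self.t!r}")
        h_ok = np.isfinite(self.height_cm)
        w_ok = np.isfinite(self.weight_g)
        if not (h_ok or w_ok):
            raise ValueError("at least one of height/weight must be present")
        if h_ok and self.height_cm <= 0:
            raise ValueError(f"height must be > 0, got {self.height_cm!r}")
        if w_ok and self.weight_g <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight_g!r}")
        if self.provenance not in _PROVENANCE:
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class LoadReport:
    """Itemized record of problems found while loading a measurement file."""

    n_read: int = 0
    n_accepted: int = 0
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    rows = [
        (r.person_id, r.group, r.sex, r.t, r.height_cm, r.weight_g, r.provenance)
        for r in records
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[MeasurementRecord]:
    return [
        MeasurementRecord(
            person_id=str(row.person_id),
            group=str(row.group),
            sex=str(row.sex),
            t=float(row.t),
            height_cm=float(row.height_cm) if pd.notna(row.height_cm) else np.nan,
            weight_g=float(row.weight_g) if pd.notna(row.weight_g) else np.nan,
            provenance=str(row.provenance),
        )
        for row in frame.itertuples(index=False)
    ]


def load_measurements(
    path,
    age_basis: str = "birth",
    weight_unit: str = "g",
    gestation: float = GESTATION_YR,
) -> tuple[list[MeasurementRecord], LoadReport]:
    """Read a delimited measurement file into validated records.

    The file must have a header with columns ``person_id, group, sex, age``
    and at least one of ``height_cm`` / ``weight_g`` (``weight_kg`` accepted
    with ``weight_unit="kg"``).  An optional per-row ``age_basis`` column
    (``birth`` or ``conception``) overrides the dialect-level flag, and an
    optional ``provenance`` column is honoured.  Ages given since birth are
    shifted to the total-age scale by ``gestation``.

    Invalid rows are dropped and itemized, with line numbers, in the
    returned :class:`LoadReport`; a file-level problem (missing column)
    raises immediately.
    """
    if age_basis not in ("birth", "conception"):
        raise ValueError("age_basis must be 'birth' or 'conception'")
    report = LoadReport()
    try:
        df = pd.read_csv(path, dtype={"person_id": str, "group": str, "sex": str})
    except pd.errors.EmptyDataError:
        report.warnings.append(f"{path}: empty file")
        logger.warning("%s: empty file", path)
        return [], report

    required = {"person_id", "group", "sex", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    weight_col = "weight_kg" if weight_unit == "kg" else "weight_g"
    if "height_cm" not in df.columns and weight_col not in df.columns:
        raise ValueError(f"{path}: need at least one of height_cm / {weight_col}")

    records: list[MeasurementRecord] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        report.n_read += 1
        try:
            age = float(getattr(row, "age"))
            basis = str(getattr(row, "age_basis", age_basis) or age_basis)
            if basis not in ("birth", "conception"):
                raise ValueError(f"bad age_basis {basis!r}")
            t = age + gestation if basis == "birth" else age
            h = float(getattr(row, "height_cm", np.nan))
            w = float(getattr(row, weight_col, np.nan))
            if weight_unit == "kg" and np.isfinite(w):
                w *= 1000.0
            rec = MeasurementRecord(
                person_id=str(row.person_id),
                group=str(row.group),
                sex=str(row.sex),
                t=t,
                height_cm=h,
                weight_g=w,
                provenance=str(getattr(row, "provenance", "observed") or "observed"),
            )
        except (ValueError, TypeError) as err:
            report.errors.append(f"line {line}: {err}")
            continue
        records.append(rec)
    report.n_accepted = len(records)
    if not records and report.n_read == 0:
        report.warnings.append(f"{path}: no data rows")
        logger.warning("%s: no data rows", path)
    return records, report


@dataclass
class PreparedDataset:
    """Validated, augmented measurements ready for estimation.

    ``frame`` holds one row per record with columns
    ``person_id, group, sex, t, height_cm, weight_g, provenance``; the index
    maps assign contiguous integer codes to person and group labels.
    """

    frame: pd.DataFrame
    person_index: dict[str, int]
    group_index: dict[str, int]
    options: dict = field(default_factory=dict)

    @property
    def n_persons(self) -> int:
        return len(self.person_index)

    @property
    def n_groups(self) -> int:
        return len(self.group_index)

    def person_codes(self) -> np.ndarray:
        return self.frame["person_id"].map(self.person_index).to_numpy(dtype=int)

    def group_codes(self) -> np.ndarray:
        return self.frame["group"].map(self.group_index).to_numpy(dtype=int)

    def person_group_codes(self) -> np.ndarray:
        """Group code of each person, indexed by person code."""
        sub = self.frame.drop_duplicates("person_id")
        out = np.empty(self.n_persons, dtype=int)
        for pid, grp in zip(sub["person_id"], sub["group"]):
            out[self.person_index[pid]] = self.group_index[grp]
        return out


def _build_indices(frame: pd.DataFrame) -> tuple[dict[str, int], dict[str, int]]:
    persons = {p: k for k, p in enumerate(pd.unique(frame["person_id"]))}
    groups = {g: k for k, g in enumerate(pd.unique(frame["group"]))}
    return persons, groups


def prepare_dataset(
    records,
    add_conception: bool = True,
    carry_forward_to: Optional[float] = None,
    gestation: float = GESTATION_YR,
) -> PreparedDataset:
    """Augment validated records with conception anchors and carry-forwards.

    Parameters
    ----------
    records : iterable of MeasurementRecord or DataFrame
    add_conception : bool
        Insert, per person, one record at t = 0 with egg-cell height and
        weight, tagged ``conception_anchor``.  Persons that already carry an
        anchor are left untouched (the operation is idempotent).
    carry_forward_to : float or None
        If given (age in years since birth, e.g. 26), append copies of each
        person's last observed height and weight at integer since-birth ages
        up to this age, tagged ``carried_forward``.  A person already
        measured beyond this age is skipped (logged).

    Observed records are never modified.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if frame.empty:
        raise ValueError("cannot prepare an empty dataset")
    frame = frame.copy()

    new_rows: list[dict] = []
    for pid, sub in frame.groupby("person_id", sort=False):
        first = sub.iloc[0]
        if add_conception and not (sub["provenance"] == "conception_anchor").any():
            new_rows.append(
                dict(
                    person_id=pid,
                    group=first["group"],
                    sex=first["sex"],
                    t=0.0,
                    height_cm=EGG_HEIGHT_CM,
                    weight_g=EGG_WEIGHT_G,
                    provenance="conception_anchor",
                )
            )
        if carry_forward_to is not None:
            obs = sub[sub["provenance"] == "observed"]
            if obs.empty:
                continue
            last = obs.loc[obs["t"].idxmax()]
            last_age_sb = last["t"] - gestation
            if last_age_sb >= carry_forward_to:
                logger.info(
                    "person %s already measured at age %.2f >= %.2f; no carry-forward",
                    pid,
                    last_age_sb,
                    carry_forward_to,
                )
                continue
            have = set(
                np.round(
                    sub.loc[sub["provenance"] == "carried_forward", "t"] - gestation
                ).astype(int)
            )
            for age in range(int(np.floor(last_age_sb)) + 1, int(carry_forward_to) + 1):
                if age in have:
                    continue
                new_rows.append(
                    dict(
                        person_id=pid,
                        group=first["group"],
                        sex=first["sex"],
                        t=age + gestation,
                        height_cm=last["height_cm"],
                        weight_g=last["weight_g"],
                        provenance="carried_forward",
                    )
                )

    if new_rows:
        frame = pd.concat([frame, pd.DataFrame(new_rows)], ignore_index=True)
    # index order follows first appearance in the *input* records, so the
    # first group in the data is the model's baseline (reference) group
    persons, groups = _build_indices(frame)
    order = frame["person_id"].map(persons)
    frame = (
        frame.assign(_order=order)
        .sort_values(["_order", "t"], kind="stable")
        .drop(columns="_order")
        .reset_index(drop=True)
    )
    return PreparedDataset(
        frame=frame,
        person_index=persons,
        group_index=groups,
        options=dict(
            add_conception=add_conception,
            carry_forward_to=carry_forward_to,
            gestation=gestation,
        ),
    )


def write_dataset(ds: PreparedDataset, path) -> None:
    """Write a prepared dataset as CSV (ages on the since-conception scale)."""
    out = ds.frame.copy()
    out = out.rename(columns={"t": "age"})
    out.insert(4, "age_basis", "conception")
    out.to_csv(path, index=False, float_format="%.12g")


def read_dataset(path) -> PreparedDataset:
    """Read a CSV written by :func:`write_dataset` back into a dataset."""
    records, report = load_measurements(path, age_basis="conception")
    if not report.ok:
        raise ValueError(f"invalid dataset file {path}: {report.errors[:5]}")
    frame = records_to_frame(records)
    persons, groups = _build_indices(frame)
    return PreparedDataset(frame=frame, person_index=persons, group_index=groups)
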