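"""The packaged PBDE study data and CSV/JSON dataset I/O.

The study dataset comprises 22 PBDE congeners with experimental base-10
log octanol/air partition coefficients (lgK_OA), split once into a
16-congener calibration group (Group I) and a 6-congener external test
group (Group II).  The tabulated descriptor values and the published
per-congener predictions are packaged alongside so that the reported
error statistics can be recomputed from the printed columns as well as
from fresh fits.  Descriptors are recomputed from the congener structure
on every load and cross-checked against the stored values.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd

from .congener_graph import CongenerSpec, parse_congener
from .errors import DatasetError, FixtureIntegrityError
from .mdev import compute_mdev

__all__ = [
    "QsprRecord",
    "load_paper_dataset",
    "group_records",
    "published_predictions",
    "read_dataset",
    "write_records_csv",
    "write_report",
]

# One row per congener: locant string, tabulated (mu1, mu2), experimental
# lgK_OA, and the published LOO/external predictions and percent relative
# errors for the linear-regression (mlr) and linear-network (ann) models.
# Asterisked rows in the source tables form the external Group II.
_STUDY_ROWS: tuple[tuple[str, float, float, float, str, float, float, float, float], ...] = (
    ("2",             0.0,    1.1111,  7.24, "I",   7.56,  7.45,  4.42,  3.59),
    ("3",             0.0,    1.0625,  7.36, "II",  7.38,  7.40,  0.27,  0.54),
    ("2,4",           0.0625, 2.1511,  8.37, "I",   8.43,  8.43,  0.72,  0.36),
    ("2,4'",          0.0204, 2.1511,  8.47, "I",   8.46,  8.45, -0.12, -0.12),
    ("2,6",           0.0625, 2.2222,  8.12, "I",   8.54,  8.50,  5.17,  5.05),
    ("3,4",           0.1111, 2.1025,  8.55, "II",  8.40,  8.35, -1.75, -2.34),
    ("3,4'",          0.0156, 2.1025,  8.57, "I",   8.39,  8.41, -2.10, -1.63),
    ("4,4'",          0.0123, 2.0800,  8.64, "I",   8.35,  8.39, -3.36, -3.01),
    ("2,3,4",         0.2847, 3.2136,  9.49, "I",   9.22,  9.33, -2.85, -2.42),
    ("2,4,6",         0.1875, 3.2622,  9.02, "II",  9.53,  9.44,  5.65,  4.66),
    ("2,4',6",        0.1033, 3.2622,  9.28, "I",   9.54,  9.49,  2.80,  2.26),
    ("3,3',4",        0.1471, 3.1650,  9.61, "I",   9.34,  9.37, -2.81, -2.81),
    ("3,4,4'",        0.1391, 3.1425,  9.68, "I",   9.32,  9.35, -3.72, -3.82),
    ("2,2',4,4'",     0.2182, 4.3022, 10.34, "II", 10.41, 10.44,  0.68,  0.97),
    ("2,3',4,4'",     0.2498, 4.2536, 10.49, "I",  10.34, 10.37, -1.43, -1.05),
    ("2,3',4,6",      0.2587, 4.3247, 10.23, "I",  10.45, 10.43,  2.15,  1.96),
    ("2,4,4',6",      0.2407, 4.3022, 10.13, "I",  10.47, 10.42,  3.36,  2.96),
    ("3,3',4,4'",     0.2862, 4.2050, 10.70, "II", 10.27, 10.30, -4.02, -3.74),
    ("2,2',3,3',4",   0.5478, 5.3872, 11.14, "I",  11.38, 11.29,  2.15,  2.15),
    ("2,2',4,4',5",   0.4127, 5.3647, 11.28, "I",  11.35, 11.36,  0.62,  0.27),
    ("2,3',4,4',6",   0.4230, 5.3647, 11.52, "I",  11.28, 11.35, -2.08, -1.39),
    ("2,2',4,4',5,5'", 0.6276, 6.4272, 12.15, "II", 12.23, 12.26,  0.66,  0.91),
)

_LGKOA_WINDOW = (0.0, 20.0)


@dataclass(frozen=True)
class QsprRecord:
    """One congener with its descriptors and experimental lgK_OA."""

    congener: CongenerSpec
    mu1: float
    mu2: float
    lgkoa_exp: float
    group: str | None = None

    def __post_init__(self) -> None:
        lo, hi = _LGKOA_WINDOW
        if not lo <= self.lgkoa_exp <= hi:
            raise DatasetError(
                f"lgK_OA {self.lgkoa_exp} outside the sanity window {_LGKOA_WINDOW}"
            )
        if self.group not in (None, "I", "II"):
            raise DatasetError(f"unknown group label {self.group!r}")

    @property
    def name(self) -> str:
        return self.congener.name


def record_from_spec(
    spec: CongenerSpec, lgkoa_exp: float, group: str | None = None
) -> QsprRecord:
    """Build a record with descriptors computed from the structure."""
    idx = compute_mdev(spec)
    return QsprRecord(spec, idx.mu1, idx.mu2, lgkoa_exp, group)


def load_paper_dataset() -> list[QsprRecord]:
    """The 22-congener study dataset with group labels.

    Descriptors are recomputed from the congener structures and verified
    against the tabulated values at 4-decimal precision; disagreement
    raises :class:`FixtureIntegrityError`.
    """
    records = []
    for locants, mu1_tab, mu2_tab, lgkoa, group, *_ in _STUDY_ROWS:
        spec = parse_congener(locants)
        idx = compute_mdev(spec)
        if idx.rounded(4) != (mu1_tab, mu2_tab):
            raise FixtureIntegrityError(
                f"{spec.name}: recomputed descriptors {idx.rounded(4)} "
                f"disagree with stored ({mu1_tab}, {mu2_tab})"
            )
        records.append(QsprRecord(spec, idx.mu1, idx.mu2, lgkoa, group))
    return records


def group_records(records: list[QsprRecord], group: str) -> list[QsprRecord]:
    return [r for r in records if r.group == group]


def published_predictions() -> pd.DataFrame:
    """The published per-congener predictions and percent relative errors.

    Columns ``pred_mlr``/``pred_ann`` hold the leave-one-out predictions
    for Group I rows and the external (Group-I-trained) predictions for
    Group II rows, as printed in the study tables; ``re_mlr``/``re_ann``
    are the corresponding signed percent relative errors.
    """
    rows = []
    for locants, _mu1, _mu2, lgkoa, group, pm, pa, rm, ra in _STUDY_ROWS:
        rows.append(
            {
                "name": parse_congener(locants).name,
                "lgkoa_exp": lgkoa,
                "group": group,
                "pred_mlr": pm,
                "pred_ann": pa,
                "re_mlr": rm,
                "re_ann": ra,
            }
        )
    return pd.DataFrame(rows)


def read_dataset(path: str | Path) -> list[QsprRecord]:
    """Read records from a CSV with columns ``congener,lgkoa[,group]``.

    Descriptors are computed on the fly from the congener strings.  Parse
    failures report the offending row number.
    """
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "congener" not in reader.fieldnames:
            raise DatasetError(f"{path}: missing 'congener' column")
        if "lgkoa" not in reader.fieldnames:
            raise DatasetError(f"{path}: missing 'lgkoa' column")
        for i, row in enumerate(reader, start=2):
            try:
                spec = parse_congener(row["congener"])
                lgkoa = float(row["lgkoa"])
                group = row.get("group") or None
                records.append(record_from_spec(spec, lgkoa, group))
            except (DatasetError, ValueError, KeyError) as exc:
                raise DatasetError(f"{path} row {i}: {exc}") from exc
            except Exception as exc:
                raise DatasetError(f"{path} row {i}: {exc}") from exc
    if not records:
        raise DatasetError(f"{path}: no data rows")
    return records


def write_records_csv(records: list[QsprRecord], path: str | Path) -> None:
    """Write records as ``congener,lgkoa,group`` CSV (round-trips with
    :func:`read_dataset`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["congener", "lgkoa", "group"])
        for r in records:
            locants = r.name.split("-")[0] if r.congener.n_bromines else ""
            writer.writerow([locants, repr(r.lgkoa_exp), r.group or ""])


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, CongenerSpec):
        return obj.name
    if isinstance(obj, frozenset):
        return sorted(obj)
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: Any, path: str | Path) -> None:
    """Serialize a model or validation report as JSON (UTF-8)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, ensure_ascii=False)
        fh.write("\n")
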