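"""Cohort data model and plain-text IO.

A cohort is an ordered list of per-subject, per-hemisphere tables of mean
cortical-attribute values (one value per ROI x attribute).  Two on-disk
layouts are supported:

* ``long_csv`` — columns ``subject_id,hemisphere,label,roi,attribute,value``,
  one measurement per row;
* ``wide_csv`` — one row per subject with columns ``subject_id, hemisphere,
  label`` plus one ``<roi>__<attribute>`` column per measurement.

Subjects are kept in lexicographic ``subject_id`` order and all downstream
matrices are indexed in that order.  ROI and attribute order is canonical
(sorted for long CSV, column order for wide CSV) and enforced across the
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right")
LABELS = ("ASD", "NC", "unknown")

LONG_COLUMNS = ["subject_id", "hemisphere", "label", "roi", "attribute", "value"]


@dataclass
class AttributeTable:
    """One subject-hemisphere's ROI x attribute matrix of mean measurements.

    ``values[i, k]`` is the mean of attribute ``attribute_names[k]`` over ROI
    ``roi_names[i]`` (mm for thickness/depth, 1/mm for curvatures).
    """

    subject_id: str
    hemisphere: str
    label: str
    values: np.ndarray
    roi_names: list[str]
    attribute_names: list[str]
    subgroup: int | None = None  # planted subgroup id for synthetic cohorts

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D ROI x attribute matrix")
        n_r, n_v = self.values.shape
        if n_r < 2 or n_v < 2:
            raise ValueError(f"need n_r >= 2 and n_v >= 2, got {n_r} x {n_v}")
        if len(self.roi_names) != n_r or len(self.attribute_names) != n_v:
            raise ValueError("roi_names/attribute_names do not match values shape")
        if len(set(self.roi_names)) != n_r:
            raise ValueError("roi_names must be unique")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value for subject {self.subject_id!r}, "
                f"ROI {self.roi_names[bad[0]]!r}, attribute "
                f"{self.attribute_names[bad[1]]!r}"
            )

    @property
    def n_r(self) -> int:
        return self.values.shape[0]

    @property
    def n_v(self) -> int:
        return self.values.shape[1]


@dataclass
class Cohort:
    """Ordered collection of :class:`AttributeTable` with consistent layout."""

    subjects: list[AttributeTable] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("cohort must contain at least one subject")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_id values must be unique within a cohort")
        ref = self.subjects[0]
        for s in self.subjects[1:]:
            if s.roi_names != ref.roi_names:
                raise ValueError(
                    f"subject {s.subject_id!r} has an inconsistent ROI set"
                )
            if s.attribute_names != ref.attribute_names:
                raise ValueError(
                    f"subject {s.subject_id!r} has inconsistent attributes"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def n_r(self) -> int:
        return self.subjects[0].n_r

    @property
    def n_v(self) -> int:
        return self.subjects[0].n_v

    @property
    def roi_names(self) -> list[str]:
        return self.subjects[0].roi_names

    @property
    def attribute_names(self) -> list[str]:
        return self.subjects[0].attribute_names

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects])

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def subgroups(self) -> np.ndarray | None:
        sg = [s.subgroup for s in self.subjects]
        if any(g is None for g in sg):
            return None
        return np.array(sg, dtype=int)

    def stacked_values(self) -> np.ndarray:
        """n x n_r x n_v array of all subjects' attribute matrices."""
        return np.stack([s.values for s in self.subjects])


@dataclass
class RoiAtlas:
    """Ordered ROI names; indices are 0-based internally."""

    names: list[str]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("atlas ROI names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def from_file(cls, path: str | Path) -> "RoiAtlas":
        names = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        return cls(names)

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "RoiAtlas":
        return cls(list(cohort.roi_names))


def _cohort_from_long(df: pd.DataFrame) -> Cohort:
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"long CSV is missing columns: {missing}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.index[values.isna() & df["value"].notna()]
    if len(bad):
        raise ValueError(f"non-numeric value at row {int(bad[0]) + 2} of long CSV")
    df = df.assign(value=values)

    roi_names = sorted(df["roi"].astype(str).unique())
    attr_names = sorted(df["attribute"].astype(str).unique())
    subjects = []
    for sid in sorted(df["subject_id"].astype(str).unique()):
        sub = df[df["subject_id"].astype(str) == sid]
        hemi = sub["hemisphere"].iloc[0]
        label = sub["label"].iloc[0]
        pivot = sub.pivot_table(
            index="roi", columns="attribute", values="value", aggfunc="first"
        )
        pivot = pivot.reindex(index=roi_names, columns=attr_names)
        if pivot.isna().any().any():
            r, a = np.argwhere(pivot.isna().values)[0]
            raise ValueError(
                f"subject {sid!r} is missing ROI {roi_names[r]!r} / "
                f"attribute {attr_names[a]!r}"
            )
        subjects.append(
            AttributeTable(
                subject_id=sid,
                hemisphere=str(hemi),
                label=str(label),
                values=pivot.values,
                roi_names=list(roi_names),
                attribute_names=list(attr_names),
            )
        )
    return Cohort(subjects)


def _cohort_from_wide(df: pd.DataFrame) -> Cohort:
    meta = ["subject_id", "hemisphere", "label"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f"wide CSV is missing columns: {missing}")
    measure_cols = [c for c in df.columns if c not in meta]
    pairs = []
    for c in measure_cols:
        if "__" not in c:
            raise ValueError(f"wide CSV column {c!r} is not of the form roi__attribute")
        roi, attr = c.split("__", 1)
        pairs.append((roi, attr))
    roi_names = sorted({r for r, _ in pairs})
    attr_names = sorted({a for _, a in pairs})
    expected = {(r, a) for r in roi_names for a in attr_names}
    if set(pairs) != expected:
        raise ValueError("wide CSV columns do not form a complete ROI x attribute grid")

    df = df.sort_values("subject_id", kind="stable")
    subjects = []
    for _, row in df.iterrows():
        vals = np.empty((len(roi_names), len(attr_names)))
        for i, r in enumerate(roi_names):
            for k, a in enumerate(attr_names):
                v = row[f"{r}__{a}"]
                try:
                    vals[i, k] = float(v)
                except (TypeError, ValueError) as exc:
                    raise ValueError(
                        f"non-numeric value for subject {row['subject_id']!r}, "
                        f"column {r}__{a}"
                    ) from exc
        subjects.append(
            AttributeTable(
                subject_id=str(row["subject_id"]),
                hemisphere=str(row["hemisphere"]),
                label=str(row["label"]),
                values=vals,
                roi_names=list(roi_names),
                attribute_names=list(attr_names),
            )
        )
    return Cohort(subjects)


def read_cohort(path: str | Path, format: str = "long_csv") -> Cohort:
    """Read a cohort from a CSV file (or directory of per-subject long CSVs)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        frames = [pd.read_csv(p) for p in sorted(path.glob("*.csv"))]
        if not frames:
            raise FileNotFoundError(f"no CSV files under {path}")
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.read_csv(path)
    if format == "long_csv":
        return _cohort_from_long(df)
    if format == "wide_csv":
        return _cohort_from_wide(df)
    raise ValueError(f"unknown cohort format {format!r}")


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the long-CSV layout."""
    rows = []
    for s in cohort:
        for i, roi in enumerate(s.roi_names):
            for k, attr in enumerate(s.attribute_names):
                rows.append(
                    (s.subject_id, s.hemisphere, s.label, roi, attr,
                     repr(float(s.values[i, k])))
                )
    pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(path, index=False)


def write_matrix(
    M: np.ndarray,
    path: str | Path,
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> None:
    """Write a finite real matrix as labeled CSV (17 significant digits)."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("write_matrix expects a 2-D matrix")
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix contains non-finite entries")
    if row_labels is None:
        row_labels = [str(i) for i in range(M.shape[0])]
    if col_labels is None:
        col_labels = [str(j) for j in range(M.shape[1])]
    df = pd.DataFrame(M, index=list(row_labels), columns=list(col_labels))
    df.to_csv(path, float_format="%.17g")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return df.values.astype(float), [str(i) for i in df.index], [str(c) for c in df.columns]
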