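"""Elective-THA cohort extraction from coded discharge records.

Inclusion: ICD9-CM procedure code 81.51 (total hip replacement) in the
principal or any secondary procedure slot. Exclusion: any diagnosis
(principal or secondary) in the 820.xx family (fracture of neck of femur),
which marks an urgent, non-elective admission. Matching on the diagnosis is
prefix-based with the dot removed, so "820.21", "820.8" and bare "820" all
trigger the exclusion.

One record counts one procedure: a record with 81.51 in several slots still
contributes a single case, and bilateral same-admission surgeries are not
disambiguated (the source counts records).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import RECORD_COLUMNS, TABLE_AGE_CLASSES

PROC_COLS = ["proc_main"] + [f"proc_sec_{i}" for i in range(1, 11)]
DIAG_COLS = ["diag_main"] + [f"diag_sec_{i}" for i in range(1, 6)]

THA_CODE = "81.51"
FRACTURE_PREFIX = "820"

_CODE_RE = re.compile(r"^\d{2,3}(\.\d{1,2})?[A-Za-z]?$")


class Classification(enum.Enum):
    ELECTIVE_THA = "elective_tha"
    EXCLUDED_FRACTURE = "excluded_fracture"
    NOT_THA = "not_tha"


@dataclass
class RejectsLog:
    """Line-numbered log of malformed records (kept, classified NOT_THA)."""

    entries: list[tuple[int, str]] = field(default_factory=list)

    def add(self, line: int, reason: str) -> None:
        self.entries.append((line, reason))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for line, reason in self.entries:
                fh.write(f"{line}\t{reason}\n")

    def __len__(self) -> int:
        return len(self.entries)


def _norm(code: object) -> str:
    if code is None or (isinstance(code, float) and np.isnan(code)):
        return ""
    return str(code).strip()


def _is_malformed(code: str) -> bool:
    return bool(code) and _CODE_RE.match(code) is None


def classify_record(record: "pd.Series | dict") -> Classification:
    """Classify one discharge record.

    ELECTIVE_THA if 81.51 appears in any procedure slot and no diagnosis
    starts with 820; EXCLUDED_FRACTURE if 81.51 is present alongside an
    820.xx diagnosis; NOT_THA otherwise. Malformed code strings are treated
    as non-matching (use :func:`classify_records` for a rejects log).
    """
    procs = [_norm(record.get(c, "")) for c in PROC_COLS]
    diags = [_norm(record.get(c, "")) for c in DIAG_COLS]
    has_tha = any(p == THA_CODE for p in procs)
    if not has_tha:
        return Classification.NOT_THA
    has_fracture = any(
        d.replace(".", "").startswith(FRACTURE_PREFIX) for d in diags if d
    )
    return Classification.EXCLUDED_FRACTURE if has_fracture else Classification.ELECTIVE_THA


def classify_records(
    records: pd.DataFrame, rejects: RejectsLog | None = None
) -> pd.Series:
    """Vectorised classification of a record table.

    Records containing a malformed procedure or diagnosis code are logged
    in ``rejects`` (1-based positional line numbers) and classified NOT_THA.
    """
    # code columns draw on a small vocabulary: factorise each column and
    # evaluate the per-code predicates on the unique values only
    n = len(records)
    has_tha = np.zeros(n, dtype=bool)
    has_fx = np.zeros(n, dtype=bool)
    malformed = np.zeros(n, dtype=bool)

    def _accumulate(col: str, out: np.ndarray, pred) -> None:
        codes, uniq = pd.factorize(records[col])
        norm = [_norm(u) for u in uniq]
        flag_u = np.fromiter((pred(v) for v in norm), dtype=bool, count=len(norm))
        if flag_u.any():
            valid = codes >= 0
            out[valid] |= flag_u[codes[valid]]

    for c in PROC_COLS:
        _accumulate(c, has_tha, lambda v: v == THA_CODE)
        _accumulate(c, malformed, _is_malformed)
    for c in DIAG_COLS:
        _accumulate(
            c, has_fx,
            lambda v: bool(v) and v.replace(".", "").startswith(FRACTURE_PREFIX),
        )
        _accumulate(c, malformed, _is_malformed)
    if rejects is not None:
        for pos in np.flatnonzero(malformed):
            rejects.add(int(pos) + 1, "malformed ICD9-CM code")
    malformed = pd.Series(malformed, index=records.index)
    has_tha = pd.Series(has_tha, index=records.index)
    has_fx = pd.Series(has_fx, index=records.index)
    out = pd.Series(Classification.NOT_THA, index=records.index, dtype=object)
    ok = has_tha & ~malformed
    out[ok & ~has_fx] = Classification.ELECTIVE_THA
    out[ok & has_fx] = Classification.EXCLUDED_FRACTURE
    return out


def extract_elective(
    records: pd.DataFrame, rejects: RejectsLog | None = None
) -> pd.DataFrame:
    """Return the elective-THA cohort rows of ``records``."""
    cls = classify_records(records, rejects)
    return records.loc[cls == Classification.ELECTIVE_THA]


def build_annual_series(
    records: pd.DataFrame,
    span: tuple[int, int] | None = None,
    rejects: RejectsLog | None = None,
) -> pd.Series:
    """Annual elective-THA counts; one count per elective record.

    ``span=(first, last)`` forces a contiguous, zero-filled index over the
    inclusive range; otherwise the range of years seen in the cohort is
    used. The returned series has contiguous year keys.
    """
    cohort = extract_elective(records, rejects)
    counts = cohort.groupby(cohort["year"].astype(int)).size()
    if span is None:
        if counts.empty:
            return pd.Series(dtype=int, name="count").rename_axis("year")
        span = (int(counts.index.min()), int(counts.index.max()))
    idx = pd.RangeIndex(span[0], span[1] + 1, name="year")
    out = counts.reindex(idx, fill_value=0).astype(int)
    out.name = "count"
    return out


def assign_age_class(age: int) -> str:
    """Map an age in years onto the demographics-table age classes.

    Boundaries: <45 is age <= 44; then decades 45-54, 55-64, 65-74, 75-84;
    >84 is age >= 85.
    """
    if age < 0:
        raise ValueError(f"negative age: {age}")
    if age <= 44:
        return "<45"
    if age <= 54:
        return "45-54"
    if age <= 64:
        return "55-64"
    if age <= 74:
        return "65-74"
    if age <= 84:
        return "75-84"
    return ">84"


def _demographics_layout(cells: pd.DataFrame) -> pd.DataFrame:
    """Arrange sex x age-class cell counts into the demographics table.

    ``cells``: long frame with columns age_class, sex, count. Output has
    the six age-class rows plus a Total row, with N and column-% for each
    sex and overall. Margins are always recomputed from the cells.
    """
    wide = (
        cells.pivot_table(index="age_class", columns="sex", values="count", aggfunc="sum", fill_value=0)
        .reindex(TABLE_AGE_CLASSES, fill_value=0)
        .reindex(columns=["F", "M"], fill_value=0)
        .astype(int)
    )
    wide["Total"] = wide.sum(axis=1)
    table = pd.DataFrame(index=wide.index)
    for col, label in [("F", "F"), ("M", "M"), ("Total", "Total")]:
        tot = wide[col].sum()
        table[f"{label}_N"] = wide[col]
        table[f"{label}_pct"] = 100.0 * wide[col] / tot if tot else 0.0
    total_row = {c: (table[c].sum() if c.endswith("_N") else 100.0) for c in table.columns}
    table.loc["Total"] = total_row
    for c in table.columns:
        if c.endswith("_N"):
            table[c] = table[c].astype(int)
    table.index.name = "age_class"
    return table


def build_demographics_table(
    records: pd.DataFrame, rejects: RejectsLog | None = None
) -> pd.DataFrame:
    """Cross-tabulate the elective cohort by age class and sex.

    Unknown sex codes go to the rejects log and are dropped from the
    table. Margins (row, column and grand totals, column percentages) are
    derived from the cells on every build.
    """
    cohort = extract_elective(records).copy()
    bad_sex = ~cohort["sex"].isin(["F", "M"])
    if rejects is not None:
        for pos in np.flatnonzero(bad_sex.to_numpy()):
            rejects.add(int(cohort.index[pos]) + 1, "unknown sex code")
    cohort = cohort.loc[~bad_sex]
    ages = cohort["age"].astype(int)
    if (ages < 0).any():
        raise ValueError("negative age in cohort")
    cells = pd.DataFrame(
        {
            "age_class": ages.map(assign_age_class),
            "sex": cohort["sex"],
        }
    ).value_counts().rename("count").reset_index()
    return _demographics_layout(cells)


def demographics_from_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Build the demographics table from pre-tabulated sex x age-class cells.

    Used for published aggregate tables where record-level data are not
    available; margins and percentages are recomputed from the cells rather
    than copied from print (printed margins can carry typos).
    """
    return _demographics_layout(cells)


def check_table_margins(table: pd.DataFrame) -> None:
    """Assert every margin of a demographics table equals its cell sum."""
    body = table.drop(index="Total")
    for col in ["F_N", "M_N", "Total_N"]:
        assert int(table.at["Total", col]) == int(body[col].sum())
    assert (body["F_N"] + body["M_N"] == body["Total_N"]).all()
    for col in ["F_pct", "M_pct", "Total_pct"]:
        assert abs(body[col].sum() - 100.0) < 1e-9 or body[col].sum() == 0.0
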