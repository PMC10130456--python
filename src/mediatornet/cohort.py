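"""Cohort container, CSV I/O and cohort summarisation.

A cohort is a case-control collection of serum samples: each sample belongs
to a study group (``HC`` healthy controls, ``COVID`` convalescent patients)
and a pregnancy trimester (1, 2 or 3), and carries concentrations (pg/mL)
for the 27-analyte panel. Missing concentrations are allowed and kept
explicit (NaN); downstream stages define their own complete-case rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .panel import DEFAULT_PANEL, MediatorPanel

GROUPS = ("HC", "COVID")
TRIMESTERS = (1, 2, 3)

LONG_COLUMNS = ["subject_id", "group", "trimester", "mediator", "concentration_pg_ml"]


class CohortError(ValueError):
    """Raised for malformed cohort inputs; carries all offending rows."""


@dataclass(frozen=True)
class SubgroupKey:
    """A (group, trimester) cell; ``trimester="ALL"`` pools across trimesters."""

    group: str
    trimester: int | str = "ALL"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.trimester != "ALL" and self.trimester not in TRIMESTERS:
            raise ValueError(f"trimester must be 1, 2, 3 or 'ALL', got {self.trimester!r}")

    def label(self) -> str:
        t = self.trimester if self.trimester != "ALL" else "all"
        return f"{self.group}_t{t}"


@dataclass
class SampleRecord:
    subject_id: str
    group: str
    trimester: int
    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.trimester not in TRIMESTERS:
            raise ValueError(f"trimester must be in {TRIMESTERS}, got {self.trimester!r}")
        for analyte, value in self.concentrations.items():
            if value is not None and not math.isnan(value) and value < 0:
                raise ValueError(
                    f"negative concentration {value} for {analyte} in {self.subject_id}")


@dataclass
class Cohort:
    """A validated panel + sample collection."""

    panel: MediatorPanel
    samples: list[SampleRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        panel_set = set(self.panel.mediators)
        seen: set[tuple[str, str, int]] = set()
        for s in self.samples:
            extra = set(s.concentrations) - panel_set
            if extra:
                raise CohortError(f"analytes {sorted(extra)} not in the 27-plex panel")
            key = (s.subject_id, s.group, s.trimester)
            if key in seen:
                raise CohortError(f"duplicate subject {key} within a subgroup")
            seen.add(key)

    def subgroup(self, key: SubgroupKey) -> list[SampleRecord]:
        return [s for s in self.samples
                if s.group == key.group
                and (key.trimester == "ALL" or s.trimester == key.trimester)]

    def subgroup_sizes(self) -> dict[tuple[str, int], int]:
        sizes: dict[tuple[str, int], int] = {}
        for s in self.samples:
            sizes[(s.group, s.trimester)] = sizes.get((s.group, s.trimester), 0) + 1
        return sizes

    def group_size(self, group: str) -> int:
        return sum(1 for s in self.samples if s.group == group)

    def to_wide(self) -> pd.DataFrame:
        """Sample-per-row table: subject_id, group, trimester, one column per analyte."""
        rows = []
        for s in self.samples:
            row = {"subject_id": s.subject_id, "group": s.group, "trimester": s.trimester}
            for a in self.panel.mediators:
                row[a] = s.concentrations.get(a, np.nan)
            rows.append(row)
        return pd.DataFrame(rows, columns=["subject_id", "group", "trimester",
                                           *self.panel.mediators])

    def to_long(self) -> pd.DataFrame:
        wide = self.to_wide()
        return wide.melt(id_vars=["subject_id", "group", "trimester"],
                         var_name="mediator", value_name="concentration_pg_ml")


def _normalize_group(value: object) -> str:
    g = str(value).strip().upper()
    if g in {"HC", "CONTROL", "HEALTHY"}:
        return "HC"
    if g in {"COVID", "COVID-19", "COVID19", "CASE"}:
        return "COVID"
    raise CohortError(f"unrecognised group label {value!r} (expected HC or COVID)")


def _records_from_wide(frame: pd.DataFrame, panel: MediatorPanel) -> list[SampleRecord]:
    required = {"subject_id", "group", "trimester"}
    missing = required - set(frame.columns)
    if missing:
        raise CohortError(f"missing required column(s): {sorted(missing)}")
    analyte_cols = [c for c in frame.columns if c not in required]
    mapping: dict[str, str] = {}
    unknown: list[str] = []
    for col in analyte_cols:
        try:
            mapping[col] = panel.normalize(col)
        except KeyError:
            unknown.append(col)
    if unknown:
        raise CohortError(f"analyte column(s) {unknown} not in the 27-plex panel")
    bad_rows: list[str] = []
    records = []
    for i, row in frame.iterrows():
        try:
            conc = {}
            for col, canonical in mapping.items():
                v = row[col]
                conc[canonical] = float(v) if pd.notna(v) else float("nan")
            records.append(SampleRecord(str(row["subject_id"]),
                                        _normalize_group(row["group"]),
                                        int(row["trimester"]), conc))
        except (ValueError, TypeError) as exc:
            bad_rows.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    if bad_rows:
        raise CohortError("unparseable rows:\n" + "\n".join(bad_rows))
    return records


def load_cohort(path: str | Path, layout: str = "long",
                panel: MediatorPanel = DEFAULT_PANEL,
                provenance: str | None = None) -> Cohort:
    """Read a cohort CSV in ``long`` or ``wide`` layout.

    Long layout columns: subject_id, group, trimester, mediator,
    concentration_pg_ml. Wide layout: subject_id, group, trimester plus one
    column per analyte. Analyte spellings are normalised to the panel's
    canonical names; unknown analytes, missing columns and negative
    concentrations raise :class:`CohortError` listing every offender.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if layout == "long":
        missing = set(LONG_COLUMNS) - set(frame.columns)
        if missing:
            raise CohortError(f"missing required column(s): {sorted(missing)}")
        unknown = []
        normalized = []
        for name in frame["mediator"].astype(str):
            try:
                normalized.append(panel.normalize(name))
            except KeyError:
                unknown.append(name)
                normalized.append(name)
        if unknown:
            raise CohortError(
                f"analyte(s) {sorted(set(unknown))} not in the 27-plex panel")
        frame = frame.assign(mediator=normalized)
        try:
            wide = frame.pivot(index=["subject_id", "group", "trimester"],
                               columns="mediator",
                               values="concentration_pg_ml").reset_index()
        except ValueError as exc:
            raise CohortError(f"duplicate (subject, mediator) rows: {exc}") from exc
        records = _records_from_wide(wide, panel)
    elif layout == "wide":
        records = _records_from_wide(frame, panel)
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    return Cohort(panel=panel, samples=records,
                  provenance=provenance if provenance is not None else str(path))


def write_cohort(cohort: Cohort, path: str | Path, layout: str = "long") -> Path:
    """Write a cohort CSV; round-trips with :func:`load_cohort`.

    Missing concentrations are serialised as empty cells and reload as NaN.
    """
    path = Path(path)
    if layout == "long":
        frame = cohort.to_long()
    elif layout == "wide":
        frame = cohort.to_wide()
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (97% from 86/89)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_cohort(cohort: Cohort,
                     flags: Mapping[str, Mapping[str, bool]] | pd.DataFrame,
                     ) -> pd.DataFrame:
    """Tabulate per-group "% (n)" cells for binary subject conditions.

    Parameters
    ----------
    flags:
        Either ``{subject_id: {condition: bool}}`` or a DataFrame indexed by
        subject_id with one boolean column per condition. Every flagged
        subject must exist in the cohort. Percentages are relative to the
        full group size and rounded half away from zero to an integer.

    Returns
    -------
    DataFrame indexed by condition with one "% (n)" string column per group.
    """
    if isinstance(flags, pd.DataFrame):
        flag_map: dict[str, dict[str, bool]] = {
            str(idx): {c: bool(v) for c, v in row.items()}
            for idx, row in flags.iterrows()}
    else:
        flag_map = {k: dict(v) for k, v in flags.items()}

    subject_group: dict[str, str] = {}
    for s in cohort.samples:
        if s.subject_id in subject_group and subject_group[s.subject_id] != s.group:
            raise CohortError(
                f"subject {s.subject_id!r} appears in more than one group; "
                "summarisation needs cohort-wide unique subject ids")
        subject_group[s.subject_id] = s.group
    unknown = sorted(set(flag_map) - set(subject_group))
    if unknown:
        raise CohortError(f"flagged subject(s) not in cohort: {unknown}")

    group_sizes = {g: cohort.group_size(g) for g in GROUPS}
    for g, n in group_sizes.items():
        if n == 0:
            raise CohortError(f"group {g} is empty")

    conditions: list[str] = []
    for v in flag_map.values():
        for c in v:
            if c not in conditions:
                conditions.append(c)
    out = {}
    for g in GROUPS:
        col = []
        for cond in conditions:
            n = sum(1 for subj, v in flag_map.items()
                    if subject_group[subj] == g and v.get(cond, False))
            pct = round_half_away(100.0 * n / group_sizes[g])
            col.append(f"{pct}% ({n})")
        out[g] = col
    return pd.DataFrame(out, index=pd.Index(conditions, name="condition"))
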