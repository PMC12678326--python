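"""Study-level data model for rare-event proportion meta-analysis.

One row per study: how many children received a peripheral vasopressor
infusion (``n``) and how many experienced a local adverse event
(``events``), plus the metadata used by subgroup and sensitivity
analyses (care setting, design, methodological-quality score, agent
counts, infusion duration).

The bundled 11-study dataset ships as a versioned CSV inside the
package.  Its source table prints event *percentages* only, so the
per-study counts are derived by nearest-integer rounding; the
accompanying free text reports slightly different totals (31 events in
1,575 patients, vs. 29 in 1,510 summed over the table rows).  Both
conventions are preserved — the table-level counts as the records, the
text-level totals as module constants — because they cannot be
reconciled from the printed data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Iterator

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import InconsistencyError, SchemaError, ValidationError

__all__ = [
    "StudyRecord",
    "StudyTable",
    "CrudeProportion",
    "derive_event_count",
    "load_study_table",
    "bundled_dataset",
    "crude_pooled_proportion",
    "TEXT_TOTAL_EVENTS",
    "TEXT_TOTAL_PATIENTS",
    "TEXT_NO_DOPAMINE_EVENTS",
    "TEXT_NO_DOPAMINE_PATIENTS",
]

#: Totals as stated in the source's results text.  They disagree with the
#: sums over the bundled table rows (29 events / 1,510 patients) and are
#: deliberately not derived from them.
TEXT_TOTAL_EVENTS = 31
TEXT_TOTAL_PATIENTS = 1575
#: Subgroup of patients who received epinephrine/norepinephrine without
#: dopamine, again as stated in the text.
TEXT_NO_DOPAMINE_EVENTS = 4
TEXT_NO_DOPAMINE_PATIENTS = 141

VALID_SETTINGS = frozenset({"PICU", "ER", "WARD", "TRANSPORT"})
VALID_DESIGNS = frozenset({"prospective", "retrospective"})
AGENTS = ("epinephrine", "norepinephrine", "dopamine", "dobutamine")

#: Printed percentages carry one decimal; this slack absorbs that rounding.
PCT_TOL = 0.15

REQUIRED_COLUMNS = (
    "study_id",
    "year",
    "n",
    "events",
    "event_pct",
    "settings",
    "design",
    "bias_score",
)
OPTIONAL_COLUMNS = (
    "duration_median_h",
    "duration_iqr_lo_h",
    "duration_iqr_hi_h",
    "epi_n",
    "norepi_n",
    "dopa_n",
    "dobu_n",
)
_AGENT_COLUMNS = {
    "epi_n": "epinephrine",
    "norepi_n": "norepinephrine",
    "dopa_n": "dopamine",
    "dobu_n": "dobutamine",
}


def bias_class_from_score(score: int) -> str:
    """JBI prevalence-checklist classification: low >=7, moderate 4-6, high <=3."""
    if score >= 7:
        return "low"
    if score >= 4:
        return "moderate"
    return "high"


def derive_event_count(n: int, pct: float, *, tol: float = PCT_TOL) -> int:
    """Derive an integer event count from a printed percentage.

    Returns ``round(n * pct / 100)`` with ties rounded away from zero.
    Raises :class:`InconsistencyError` when even the nearest integer
    re-derives to a percentage more than ``tol`` points away from the
    printed one, i.e. the printed percentage is internally inconsistent
    with *any* count (a caller holding an explicit count may simply use
    it instead).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"pct must be in [0, 100], got {pct}")
    count = math.floor(n * pct / 100.0 + 0.5)  # ties away from zero (pct >= 0)
    rederived = 100.0 * count / n
    if abs(rederived - pct) > tol:
        raise InconsistencyError(
            f"count {count} re-derives to {rederived:.2f}% which differs from the "
            f"printed {pct}% by more than {tol} points (n={n})"
        )
    return count


@dataclass(frozen=True)
class StudyRecord:
    """One study's counts, size and metadata."""

    study_id: str
    year: int
    n: int
    events: int
    event_pct: float | None
    settings: frozenset[str]
    design: str
    bias_score: int
    duration_median_h: float | None = None
    duration_iqr_h: tuple[float, float] | None = None
    agent_counts: dict[str, int] = field(default_factory=dict)

    @property
    def bias_class(self) -> str:
        return bias_class_from_score(self.bias_score)

    @property
    def crude_rate(self) -> float:
        return self.events / self.n

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"{self.study_id}: n must be >= 1, got {self.n}")
        if not 0 <= self.events <= self.n:
            raise ValidationError(
                f"{self.study_id}: events must satisfy 0 <= events <= n "
                f"(events={self.events}, n={self.n})"
            )
        if not self.settings:
            raise ValidationError(f"{self.study_id}: settings must be nonempty")
        unknown = set(self.settings) - VALID_SETTINGS
        if unknown:
            raise ValidationError(f"{self.study_id}: unknown settings {sorted(unknown)}")
        if self.design not in VALID_DESIGNS:
            raise ValidationError(f"{self.study_id}: unknown design {self.design!r}")
        if not 0 <= self.bias_score <= 9:
            raise ValidationError(
                f"{self.study_id}: bias_score must be 0-9, got {self.bias_score}"
            )
        if self.event_pct is not None:
            if not 0.0 <= self.event_pct <= 100.0:
                raise ValidationError(
                    f"{self.study_id}: event_pct out of [0, 100]: {self.event_pct}"
                )
            # Printed percentages are occasionally inconsistent with every
            # possible count (e.g. 2.0% of 56); accept the stored count when
            # it is at least the nearest integer to n * pct / 100.
            nearest = math.floor(self.n * self.event_pct / 100.0 + 0.5)
            within_tol = abs(100.0 * self.events / self.n - self.event_pct) <= PCT_TOL
            if not within_tol and self.events != nearest:
                raise ValidationError(
                    f"{self.study_id}: events={self.events} disagrees with "
                    f"event_pct={self.event_pct}% (n={self.n})"
                )


@dataclass(frozen=True)
class StudyTable:
    """An ordered collection of study records with provenance."""

    records: tuple[StudyRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.study_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate study_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    @property
    def total_n(self) -> int:
        return sum(r.n for r in self.records)

    @property
    def total_events(self) -> int:
        return sum(r.events for r in self.records)

    @property
    def study_ids(self) -> tuple[str, ...]:
        return tuple(r.study_id for r in self.records)

    def select(self, predicate: Callable[[StudyRecord], bool], label: str = "") -> "StudyTable":
        kept = tuple(r for r in self.records if predicate(r))
        note = f"{self.provenance}; selection={label}" if label else self.provenance
        return StudyTable(records=kept, provenance=note)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "study_id": r.study_id,
                "year": r.year,
                "n": r.n,
                "events": r.events,
                "event_pct": r.event_pct,
                "settings": ";".join(sorted(r.settings)),
                "design": r.design,
                "bias_score": r.bias_score,
                "bias_class": r.bias_class,
                "duration_median_h": r.duration_median_h,
                "duration_iqr_lo_h": r.duration_iqr_h[0] if r.duration_iqr_h else None,
                "duration_iqr_hi_h": r.duration_iqr_h[1] if r.duration_iqr_h else None,
            }
            for col, agent in _AGENT_COLUMNS.items():
                row[col] = r.agent_counts.get(agent)
            rows.append(row)
        return pd.DataFrame(rows)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def load_study_table(path, schema_mode: str = "strict") -> StudyTable:
    """Read and validate a study-table CSV.

    ``schema_mode="lenient"`` derives missing event counts from
    ``event_pct`` via :func:`derive_event_count`; ``"strict"`` requires
    the ``events`` column to be filled for every row.
    """
    if schema_mode not in ("strict", "lenient"):
        raise ValueError(f"schema_mode must be 'strict' or 'lenient', got {schema_mode!r}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records = []
    for _, row in df.iterrows():
        study_id = str(row["study_id"])
        n = int(row["n"])
        events = _opt_float(row["events"])
        pct = _opt_float(row["event_pct"])
        if events is None:
            if schema_mode == "strict":
                raise SchemaError(
                    f"{study_id}: events is missing (strict mode requires explicit counts)"
                )
            if pct is None:
                raise SchemaError(f"{study_id}: neither events nor event_pct given")
            events = derive_event_count(n, pct)
        agent_counts = {}
        for col, agent in _AGENT_COLUMNS.items():
            if col in df.columns:
                val = _opt_float(row[col])
                if val is not None:
                    agent_counts[agent] = int(val)
        lo = _opt_float(row.get("duration_iqr_lo_h"))
        hi = _opt_float(row.get("duration_iqr_hi_h"))
        records.append(
            StudyRecord(
                study_id=study_id,
                year=int(row["year"]),
                n=n,
                events=int(events),
                event_pct=pct,
                settings=frozenset(str(row["settings"]).split(";")),
                design=str(row["design"]),
                bias_score=int(row["bias_score"]),
                duration_median_h=_opt_float(row.get("duration_median_h")),
                duration_iqr_h=(lo, hi) if lo is not None and hi is not None else None,
                agent_counts=agent_counts,
            )
        )
    return StudyTable(records=tuple(records), provenance=f"loaded from {path}")


def bundled_dataset() -> StudyTable:
    """The packaged 11-study peripheral-vasopressor dataset."""
    source = resources.files("raremeta.data").joinpath("studies.csv")
    with resources.as_file(source) as path:
        table = load_study_table(path, schema_mode="strict")
    return replace(table, provenance="bundled 11-study peripheral vasopressor table")


@dataclass(frozen=True)
class CrudeProportion:
    estimate: float
    ci_low: float
    ci_high: float
    events: int
    n: int
    ci_method: str = "wilson"


def crude_pooled_proportion(
    total_events: int, total_n: int, ci_method: str = "wilson"
) -> CrudeProportion:
    """Crude pooled proportion with a 95% Wilson score interval."""
    if total_n < 1:
        raise ValueError(f"total_n must be >= 1, got {total_n}")
    if not 0 <= total_events <= total_n:
        raise ValueError(f"need 0 <= events <= n, got {total_events}/{total_n}")
    if ci_method != "wilson":
        raise ValueError(f"unsupported ci_method {ci_method!r}")
    low, high = proportion_confint(total_events, total_n, alpha=0.05, method="wilson")
    # snap the deterministic boundary cases and keep bounds inside [0, 1]
    low = 0.0 if total_events == 0 else min(max(float(low), 0.0), 1.0)
    high = 1.0 if total_events == total_n else min(max(float(high), 0.0), 1.0)
    return CrudeProportion(
        estimate=total_events / total_n,
        ci_low=low,
        ci_high=high,
        events=total_events,
        n=total_n,
    )
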