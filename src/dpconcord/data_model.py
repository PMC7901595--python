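"""Domain types and delimited-text I/O for multi-rater diagnostic-concordance studies.

The study layout modelled here: a panel of pathologists (each with one
career level) reviews a fixed set of digitised cases and answers up to five
diagnostic questions per case.  Which questions a case admits depends on its
lesion class: every case takes the screening question ("neoplastic or not?")
and the free-text diagnosis; only neoplastic cases take the benign/malignant
question; only malignant cases take histotype and grade.  Each answer is
scored against the original glass-slide diagnosis as correct or erroneous,
or recorded as missing when the rater skipped it.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "LEVELS",
    "SUBSPECIALTIES",
    "SPECIMENS",
    "LESION_CLASSES",
    "CATEGORIES",
    "CATEGORY_LABELS",
    "OUTCOMES",
    "GROUPINGS",
    "Participant",
    "CaseRecord",
    "ResponseItem",
    "StudyDesign",
    "GroupErrorTable",
    "MarginalReport",
    "ValidationError",
    "read_response_table",
    "write_response_table",
    "read_marginal_tables",
    "write_marginal_tables",
    "validate_against_marginals",
    "items_to_frame",
    "load_table1",
    "load_items_fixture",
]

LEVELS: tuple[str, ...] = ("resident", "junior", "expert", "senior")
SUBSPECIALTIES: tuple[str, ...] = ("breast", "urology", "gastrointestinal")
SPECIMENS: tuple[str, ...] = ("biopsy", "surgery")
LESION_CLASSES: tuple[str, ...] = ("nontumoral", "benign", "malignant")
CATEGORIES: tuple[int, ...] = (1, 2, 3, 4, 5)
CATEGORY_LABELS: dict[int, str] = {
    1: "Neoplasia?",
    2: "Malignant/benign?",
    3: "Histopathological diagnosis?",
    4: "Histotype?",
    5: "Grade?",
}
OUTCOMES: tuple[str, ...] = ("correct", "error", "missing")

#: The five ways responses are marginalised in the descriptive tables.
GROUPINGS: tuple[str, ...] = (
    "pathologist",
    "level",
    "category",
    "specimen",
    "subspecialty",
)

_CSV_COLUMNS = [
    "participant",
    "level",
    "case",
    "subspecialty",
    "specimen",
    "category",
    "outcome",
]


class ValidationError(ValueError):
    """Raised when data violate the study-domain invariants."""


@dataclass(frozen=True)
class Participant:
    """A rater: a pathologist or resident with exactly one career level."""

    id: str
    career_level: str

    def __post_init__(self) -> None:
        if self.career_level not in LEVELS:
            raise ValidationError(
                f"unknown career level {self.career_level!r} for participant "
                f"{self.id!r}; expected one of {LEVELS}"
            )


@dataclass(frozen=True)
class CaseRecord:
    """A digitised case with its attributes and admissible question set.

    ``grade`` may be ``None`` even for malignant lesions (it is not carried
    by the item-level interchange format); it must be ``None`` for anything
    that is not malignant.
    """

    id: int
    subspecialty: str
    specimen: str
    lesion_class: str
    grade: int | None = None
    eligible_categories: frozenset[int] = frozenset({1, 3})

    def __post_init__(self) -> None:
        if self.subspecialty not in SUBSPECIALTIES:
            raise ValidationError(f"case {self.id}: unknown subspecialty {self.subspecialty!r}")
        if self.specimen not in SPECIMENS:
            raise ValidationError(f"case {self.id}: unknown specimen {self.specimen!r}")
        if self.lesion_class not in LESION_CLASSES:
            raise ValidationError(f"case {self.id}: unknown lesion class {self.lesion_class!r}")
        if self.grade is not None:
            if self.lesion_class != "malignant":
                raise ValidationError(f"case {self.id}: grade given for non-malignant lesion")
            if self.grade not in (2, 3):
                raise ValidationError(f"case {self.id}: grade must be 2 or 3, got {self.grade}")
        elig = self.eligible_categories
        if not elig <= set(CATEGORIES):
            raise ValidationError(f"case {self.id}: eligible categories {sorted(elig)} outside 1-5")
        if not {1, 3} <= elig:
            raise ValidationError(f"case {self.id}: categories 1 and 3 are asked for every case")
        if 2 in elig and self.lesion_class == "nontumoral":
            raise ValidationError(f"case {self.id}: category 2 admissible only for neoplastic lesions")
        if (4 in elig or 5 in elig) and self.lesion_class != "malignant":
            raise ValidationError(f"case {self.id}: categories 4-5 admissible only for malignant lesions")


@dataclass(frozen=True)
class ResponseItem:
    """One diagnostic answer, scored against the gold standard."""

    participant_id: str
    case_id: int
    category: int
    outcome: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"item ({self.participant_id}, case {self.case_id}): "
                f"category {self.category} outside 1-5"
            )
        if self.outcome not in OUTCOMES:
            raise ValidationError(
                f"item ({self.participant_id}, case {self.case_id}, "
                f"category {self.category}): unknown outcome {self.outcome!r}"
            )

    @property
    def answered(self) -> bool:
        return self.outcome != "missing"

    @property
    def is_error(self) -> bool:
        return self.outcome == "error"


@dataclass(frozen=True)
class StudyDesign:
    """The factorial layout: participants, cases, and question eligibility."""

    participants: tuple[Participant, ...]
    cases: tuple[CaseRecord, ...]

    def __post_init__(self) -> None:
        pids = [p.id for p in self.participants]
        if len(set(pids)) != len(pids):
            raise ValidationError("duplicate participant ids in design")
        cids = [c.id for c in self.cases]
        if len(set(cids)) != len(cids):
            raise ValidationError("duplicate case ids in design")

    def participant(self, pid: str) -> Participant:
        for p in self.participants:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def case(self, cid: int) -> CaseRecord:
        for c in self.cases:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def participant_ids(self) -> tuple[str, ...]:
        return tuple(p.id for p in self.participants)

    @property
    def case_ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self.cases)

    def eligible_triples(self) -> list[tuple[str, int, int]]:
        """All (participant, case, category) combinations the design asks for."""
        return [
            (p.id, c.id, q)
            for p in self.participants
            for c in self.cases
            for q in sorted(c.eligible_categories)
        ]

    @property
    def n_questions_per_participant(self) -> int:
        return sum(len(c.eligible_categories) for c in self.cases)

    @property
    def n_items(self) -> int:
        return len(self.participants) * self.n_questions_per_participant


@dataclass
class GroupErrorTable:
    """Marginal error counts for one grouping, mirroring a published table.

    ``rows`` maps group label -> (n_tasks, n_errors).  Rates are derived,
    never stored, so internal arithmetic is exact.
    """

    grouping: str
    rows: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.grouping not in GROUPINGS and self.grouping != "total":
            raise ValidationError(f"unknown grouping {self.grouping!r}")
        for label, (n, e) in self.rows.items():
            if not 0 <= e <= n:
                raise ValidationError(
                    f"{self.grouping}/{label}: need 0 <= n_errors <= n_tasks, got {e}/{n}"
                )

    def rate(self, label: str) -> float:
        n, e = self.rows[label]
        return e / n if n else float("nan")

    @property
    def totals(self) -> tuple[int, int]:
        return (
            sum(n for n, _ in self.rows.values()),
            sum(e for _, e in self.rows.values()),
        )

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {"grouping": self.grouping, "group": g, "n_tasks": n, "n_errors": e,
             "rate": e / n if n else float("nan")}
            for g, (n, e) in self.rows.items()
        ]
        return pd.DataFrame(recs, columns=["grouping", "group", "n_tasks", "n_errors", "rate"])


@dataclass
class MarginalReport:
    """Outcome of checking item-level data against reference marginal tables."""

    rows: list[dict]

    @property
    def mismatches(self) -> list[dict]:
        return [r for r in self.rows if not r["match"]]

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)

    @property
    def ok(self) -> bool:
        return self.n_mismatches == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


# ---------------------------------------------------------------------------
# I/O


def items_to_frame(items: Iterable[ResponseItem], design: StudyDesign) -> pd.DataFrame:
    """Item-level data as a DataFrame with design attributes joined in."""
    levels = {p.id: p.career_level for p in design.participants}
    cases = {c.id: c for c in design.cases}
    recs = []
    for it in items:
        c = cases[it.case_id]
        recs.append(
            {
                "participant": it.participant_id,
                "level": levels[it.participant_id],
                "case": it.case_id,
                "subspecialty": c.subspecialty,
                "specimen": c.specimen,
                "category": it.category,
                "outcome": it.outcome,
            }
        )
    return pd.DataFrame(recs, columns=_CSV_COLUMNS)


def write_response_table(
    items: Sequence[ResponseItem], design: StudyDesign, path: str | Path
) -> None:
    """Write items as UTF-8 CSV with a mandatory header.

    Career level and case attributes are carried redundantly per row; the
    reader checks them for consistency.
    """
    frame = items_to_frame(items, design)
    frame.to_csv(path, index=False, encoding="utf-8")


def read_response_table(path: str | Path) -> tuple[list[ResponseItem], StudyDesign]:
    """Read an item-level CSV, validating every row.

    The design is reconstructed from the file: participants from the
    (participant, level) columns, cases from (case, subspecialty, specimen),
    with a case's eligible categories taken to be exactly the categories that
    appear for it.  Lesion class is inferred from eligibility (categories 4-5
    imply malignant, category 2 implies neoplastic); grade is unknown.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _CSV_COLUMNS:
            raise ValidationError(
                f"{path}: expected header {','.join(_CSV_COLUMNS)}, got {reader.fieldnames}"
            )
        raw = list(reader)

    items: list[ResponseItem] = []
    part_levels: dict[str, str] = {}
    case_attrs: dict[int, tuple[str, str]] = {}
    case_cats: dict[int, set[int]] = {}
    seen: set[tuple[str, int, int]] = set()
    for i, row in enumerate(raw, start=2):  # header is line 1
        pid = row["participant"].strip()
        level = row["level"].strip()
        subsp = row["subspecialty"].strip()
        spec = row["specimen"].strip()
        try:
            cid = int(row["case"])
            cat = int(row["category"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path} line {i}: non-integer case or category") from exc
        outcome = row["outcome"].strip()
        if level not in LEVELS:
            raise ValidationError(f"{path} line {i}: unknown level {level!r}")
        if subsp not in SUBSPECIALTIES:
            raise ValidationError(f"{path} line {i}: unknown subspecialty {subsp!r}")
        if spec not in SPECIMENS:
            raise ValidationError(f"{path} line {i}: unknown specimen {spec!r}")
        if cat not in CATEGORIES:
            raise ValidationError(f"{path} line {i}: category {cat} outside 1-5")
        if outcome not in OUTCOMES:
            raise ValidationError(f"{path} line {i}: unknown outcome {outcome!r}")
        if pid in part_levels and part_levels[pid] != level:
            raise ValidationError(
                f"{path} line {i}: participant {pid} listed with levels "
                f"{part_levels[pid]!r} and {level!r}"
            )
        part_levels[pid] = level
        if cid in case_attrs and case_attrs[cid] != (subsp, spec):
            raise ValidationError(f"{path} line {i}: case {cid} has inconsistent attributes")
        case_attrs[cid] = (subsp, spec)
        case_cats.setdefault(cid, set()).add(cat)
        key = (pid, cid, cat)
        if key in seen:
            raise ValidationError(
                f"{path} line {i}: duplicate item (participant {pid}, case {cid}, category {cat})"
            )
        seen.add(key)
        items.append(ResponseItem(pid, cid, cat, outcome))

    participants = tuple(
        Participant(pid, lvl) for pid, lvl in sorted(part_levels.items(), key=_pid_key)
    )
    cases = []
    for cid in sorted(case_attrs):
        subsp, spec = case_attrs[cid]
        # categories 1 and 3 are asked for every case even if this file only
        # partially observes the case
        cats = case_cats[cid] | {1, 3}
        if 4 in cats or 5 in cats:
            lesion = "malignant"
        elif 2 in cats:
            lesion = "benign"
        else:
            lesion = "nontumoral"
        cases.append(
            CaseRecord(
                id=cid,
                subspecialty=subsp,
                specimen=spec,
                lesion_class=lesion,
                eligible_categories=frozenset(cats),
            )
        )
    design = StudyDesign(participants=participants, cases=tuple(cases))
    for it in items:
        if it.category not in design.case(it.case_id).eligible_categories:
            raise ValidationError(
                f"item ({it.participant_id}, {it.case_id}, {it.category}) "
                "outside the case's eligible categories"
            )
    return items, design


def _pid_key(entry: tuple[str, str]) -> tuple[int, str]:
    """Sort P2 before P10; fall back to lexicographic for other schemes."""
    pid = entry[0]
    if pid.startswith("P") and pid[1:].isdigit():
        return (int(pid[1:]), "")
    return (10**9, pid)


def write_marginal_tables(tables: dict[str, GroupErrorTable], path: str | Path) -> None:
    """Write a set of grouping tables as one long-format CSV."""
    frames = [tables[g].to_frame() for g in tables]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, encoding="utf-8")


def read_marginal_tables(path: str | Path) -> dict[str, GroupErrorTable]:
    """Read grouping tables from long-format CSV (grouping,group,n_tasks,n_errors[,rate])."""
    frame = pd.read_csv(path)
    required = {"grouping", "group", "n_tasks", "n_errors"}
    if not required <= set(frame.columns):
        raise ValidationError(f"{path}: columns {sorted(required)} required")
    tables: dict[str, GroupErrorTable] = {}
    for grouping, sub in frame.groupby("grouping", sort=False):
        rows = {
            str(r.group): (int(r.n_tasks), int(r.n_errors)) for r in sub.itertuples()
        }
        tables[str(grouping)] = GroupErrorTable(grouping=str(grouping), rows=rows)
    return tables


def load_table1() -> dict[str, GroupErrorTable]:
    """The packaged reference marginal tables (the published error-count table)."""
    path = Path(__file__).parent / "fixtures" / "table1_marginals.csv"
    return read_marginal_tables(path)


def load_items_fixture() -> tuple[list[ResponseItem], StudyDesign]:
    """The packaged synthetic item-level table whose marginals match the
    published counts (a seeded reconstruction; the real per-item data are
    not printed, so any dataset passing marginal validation is equivalent).
    """
    path = Path(__file__).parent / "fixtures" / "items_fixture.csv"
    return read_response_table(path)


# ---------------------------------------------------------------------------
# Marginal validation


def _observed_tables(
    items: Sequence[ResponseItem], design: StudyDesign
) -> dict[str, GroupErrorTable]:
    # Local import: descriptives depends on this module for types.
    from .descriptives import error_table

    if not any(it.outcome != "missing" for it in items):
        return {g: GroupErrorTable(grouping=g, rows={}) for g in GROUPINGS}
    return {g: error_table(items, design, g) for g in GROUPINGS}


def validate_against_marginals(
    items: Sequence[ResponseItem],
    design: StudyDesign,
    reference: dict[str, GroupErrorTable],
) -> MarginalReport:
    """Compare observed (n_tasks, n_errors) per group against reference tables.

    Every group present in the reference is reported; a group label absent
    from the observed data counts as observed (0, 0) and a mismatch, except
    that a grouping entirely absent from the reference is an error.
    """
    observed = _observed_tables(items, design)
    rows: list[dict] = []
    for grouping, ref in reference.items():
        if grouping == "total":
            continue
        if grouping not in observed:
            raise ValidationError(f"grouping {grouping!r} not computable from items")
        obs = observed[grouping]
        for label, (n_ref, e_ref) in ref.rows.items():
            n_obs, e_obs = obs.rows.get(label, (0, 0))
            rows.append(
                {
                    "grouping": grouping,
                    "group": label,
                    "n_tasks_ref": n_ref,
                    "n_errors_ref": e_ref,
                    "n_tasks_obs": n_obs,
                    "n_errors_obs": e_obs,
                    "match": (n_ref, e_ref) == (n_obs, e_obs),
                }
            )
    return MarginalReport(rows=rows)
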