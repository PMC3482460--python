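"""Peptide-table I/O, dataset curation and class monomer-overlap statistics.

Peptide tables are delimited text (TSV by default) with the header columns
``id``, ``name``, ``activities`` (";"-separated labels; "," is reserved for
compositions) and ``composition`` (comma/semicolon-separated monomer codes).

Curation applies three sequential rules, in order:

1. class size — activity labels carried by fewer than ``min_class_size``
   peptides are dropped; peptides left without any label are removed;
2. composition dedup — within each activity class, peptides whose sets of
   *distinct* monomers are identical (occurrence counts ignored: the same
   positions are "on" in the fingerprint) collapse to one representative;
3. single activity — only peptides with exactly one remaining label are
   kept.  Their multi-activity complement forms the held-out evaluation set.

The stage order matters (class sizes are counted before dedup and before
the single-activity restriction) and is part of the contract.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fingerprint import CompositionParseError, PeptideRecord, parse_composition

__all__ = [
    "REQUIRED_COLUMNS",
    "DEFAULT_EXCLUDED_LABELS",
    "FilterReport",
    "OverlapMatrix",
    "load_peptides",
    "save_peptides",
    "filter_dataset",
    "build_evaluation_set",
    "records_by_class",
    "monomer_overlap",
]

REQUIRED_COLUMNS = ("id", "name", "activities", "composition")

# Surfactant behaviour is a physico-chemical property (being a lipopeptide)
# rather than a biological activity, so it is excluded from activity classes
# by default; pass exclude_labels=() to retain it.
DEFAULT_EXCLUDED_LABELS = ("surfactant",)

_ACTIVITY_SEP = ";"


def _parse_activities(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    labels = [a.strip() for a in str(cell).split(_ACTIVITY_SEP)]
    return frozenset(a for a in labels if a)


def load_peptides(
    path: str | Path,
    sep: str = "\t",
    errors: str = "raise",
) -> list[PeptideRecord] | tuple[list[PeptideRecord], list[tuple[str, str]]]:
    """Read a peptide table into :class:`PeptideRecord` objects.

    ``errors='raise'`` (default) fails on the first malformed row;
    ``errors='report'`` returns ``(records, problems)`` where *problems* is
    a list of ``(row id, message)`` pairs — malformed rows are collected and
    reported, never silently dropped.
    """
    if errors not in ("raise", "report"):
        raise ValueError("errors must be 'raise' or 'report'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"peptide table not found: {path}")
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"peptide table {path} lacks required column(s): {', '.join(missing)}"
        )
    records: list[PeptideRecord] = []
    problems: list[tuple[str, str]] = []
    for i, row in table.iterrows():
        rid = str(row["id"]).strip() or f"<row {i + 2}>"
        try:
            composition = parse_composition(str(row["composition"]))
            records.append(
                PeptideRecord(
                    id=rid,
                    name=str(row["name"]).strip(),
                    activities=_parse_activities(row["activities"]),
                    composition=tuple(composition),
                )
            )
        except (CompositionParseError, ValueError) as exc:
            if errors == "raise":
                raise CompositionParseError(f"row {rid}: {exc}") from exc
            problems.append((rid, str(exc)))
    if errors == "report":
        return records, problems
    return records


def save_peptides(
    records: Iterable[PeptideRecord], path: str | Path, sep: str = "\t"
) -> None:
    """Write records to a delimited peptide table (inverse of load)."""
    rows = [
        {
            "id": r.id,
            "name": r.name,
            "activities": _ACTIVITY_SEP.join(sorted(r.activities)),
            "composition": r.composition_string(),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(
        path, sep=sep, index=False
    )


@dataclass
class FilterReport:
    """Per-stage accounting for one curation run."""

    n_input: int
    n_after_class_size: int
    n_after_dedup: int
    n_after_single_activity: int
    removed: list[tuple[str, str]] = field(default_factory=list)
    class_sizes: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_input": self.n_input,
            "n_after_class_size": self.n_after_class_size,
            "n_after_dedup": self.n_after_dedup,
            "n_after_single_activity": self.n_after_single_activity,
            "removed": [{"id": i, "reason": r} for i, r in self.removed],
            "class_sizes": self.class_sizes,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def filter_dataset(
    records: Sequence[PeptideRecord],
    min_class_size: int = 20,
    dedup: bool = True,
    single_activity_only: bool = True,
    exclude_labels: Sequence[str] = DEFAULT_EXCLUDED_LABELS,
) -> tuple[list[PeptideRecord], FilterReport]:
    """Apply the three curation stages in order; see the module docstring.

    Excluded labels (surfactant by default) are stripped from every record
    before class sizes are counted.  The dedup representative within a class
    is the record with the lexicographically smallest id.  Returns the
    surviving records (input order preserved) and a :class:`FilterReport`.
    """
    if min_class_size < 1:
        raise ValueError("min_class_size must be >= 1")
    excluded = set(exclude_labels)
    removed: list[tuple[str, str]] = []

    # stage 1: strip excluded labels, then drop small classes
    stage1: list[PeptideRecord] = []
    working = [
        PeptideRecord(r.id, r.name, r.activities - excluded, r.composition)
        for r in records
    ]
    label_counts: dict[str, int] = {}
    for r in working:
        for a in r.activities:
            label_counts[a] = label_counts.get(a, 0) + 1
    kept_labels = {a for a, n in label_counts.items() if n >= min_class_size}
    for orig, r in zip(records, working):
        acts = r.activities & kept_labels
        if not acts:
            reason = (
                "no activity label outside excluded set"
                if not r.activities
                else "all activity classes below minimum size"
            )
            removed.append((r.id, reason))
            continue
        stage1.append(PeptideRecord(r.id, r.name, acts, r.composition))
    n_after_class_size = len(stage1)

    # stage 2: collapse identical distinct-monomer sets within each class
    stage2 = stage1
    if dedup:
        drop: set[str] = set()
        reps: dict[tuple[str, frozenset[str]], str] = {}
        for r in sorted(stage1, key=lambda r: r.id):
            for label in r.activities:
                key = (label, r.monomer_set)
                if key in reps:
                    drop.add(r.id)
                else:
                    reps[key] = r.id
        stage2 = []
        for r in stage1:
            if r.id in drop:
                removed.append(
                    (r.id, "duplicate distinct-monomer set within a class")
                )
            else:
                stage2.append(r)
    n_after_dedup = len(stage2)

    # stage 3: single-activity restriction
    stage3 = stage2
    if single_activity_only:
        stage3 = []
        for r in stage2:
            if len(r.activities) == 1:
                stage3.append(r)
            else:
                removed.append((r.id, "more than one known activity"))
    n_after_single = len(stage3)

    final_sizes: dict[str, int] = {}
    for r in stage3:
        for a in r.activities:
            final_sizes[a] = final_sizes.get(a, 0) + 1

    report = FilterReport(
        n_input=len(records),
        n_after_class_size=n_after_class_size,
        n_after_dedup=n_after_dedup,
        n_after_single_activity=n_after_single,
        removed=removed,
        class_sizes=dict(sorted(final_sizes.items())),
    )
    return stage3, report


def build_evaluation_set(
    records: Sequence[PeptideRecord],
    exclude_labels: Sequence[str] = DEFAULT_EXCLUDED_LABELS,
) -> list[PeptideRecord]:
    """Peptides with at least two (non-excluded) activity labels.

    This is the complement of the single-activity restriction: a held-out
    multi-label set on which a prediction counts as correct if it matches
    any of the known activities.
    """
    excluded = set(exclude_labels)
    out = []
    for r in records:
        acts = r.activities - excluded
        if len(acts) >= 2:
            out.append(PeptideRecord(r.id, r.name, acts, r.composition))
    return out


def records_by_class(
    records: Iterable[PeptideRecord],
) -> dict[str, list[PeptideRecord]]:
    """Group records by activity label (a multi-label record joins each of
    its classes)."""
    groups: dict[str, list[PeptideRecord]] = {}
    for r in records:
        for a in sorted(r.activities):
            groups.setdefault(a, []).append(r)
    return groups


@dataclass
class OverlapMatrix:
    """Row-normalized monomer sharing between activity classes.

    ``common[i][j]`` is the percentage of class *i*'s distinct monomers that
    also occur in class *j* (rows do not sum to 100: a monomer can be shared
    with several classes); ``specific[i]`` is the percentage of class *i*'s
    monomers found in no other class.
    """

    labels: tuple[str, ...]
    common: list[list[float]]
    specific: list[float]

    def to_dataframe(self) -> pd.DataFrame:
        """Matrix with the class-specific percentage on the diagonal, mirroring
        the usual published layout (read by row)."""
        df = pd.DataFrame(self.common, index=self.labels, columns=self.labels)
        for i, lab in enumerate(self.labels):
            df.loc[lab, lab] = self.specific[i]
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().round(2).to_csv(path, sep="\t", index_label="class")


def monomer_overlap(
    groups: Mapping[str, Sequence[PeptideRecord]],
) -> OverlapMatrix:
    """Common/specific monomer percentages across activity classes.

    For class *i* with distinct-monomer union M_i:
    ``common[i][j] = 100 |M_i ∩ M_j| / |M_i|`` and
    ``specific[i] = 100 |M_i \\ U_{j≠i} M_j| / |M_i|``.
    """
    if len(groups) < 2:
        raise ValueError("monomer overlap needs at least two classes")
    labels = tuple(groups.keys())
    monomer_sets: dict[str, set[str]] = {}
    for label in labels:
        recs = groups[label]
        if not recs:
            raise ValueError(f"activity class {label!r} is empty")
        monomer_sets[label] = set().union(*(r.monomer_set for r in recs))
    common = []
    specific = []
    for li in labels:
        mi = monomer_sets[li]
        common.append(
            [100.0 * len(mi & monomer_sets[lj]) / len(mi) for lj in labels]
        )
        others: set[str] = set()
        for lj in labels:
            if lj != li:
                others |= monomer_sets[lj]
        specific.append(100.0 * len(mi - others) / len(mi))
    return OverlapMatrix(labels=labels, common=common, specific=specific)
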