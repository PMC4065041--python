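"""Diagnosis-code grouping and composite phenotype definitions.

Raw ICD-9-style codes are aggregated into groups of related codes; cancer
groups are excluded throughout because molecular tumour phenotypes in the
model-organism resources cannot be mapped onto specific cancer types.
Composite phenotypes are sets of diagnosis groups, optionally restricted
by age at last encounter (e.g. cataract only counted above age 50).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .cohort import Cohort

__all__ = [
    "CodeGroupMap",
    "PhenotypeDef",
    "map_codes_to_groups",
    "build_diagnosis_matrix",
    "evaluate_phenotype",
]

log = logging.getLogger(__name__)


class CodeGroupMap:
    """Mapping from raw diagnosis codes to aggregated diagnosis groups.

    Each code maps to exactly one group; groups flagged as cancer are
    dropped from all downstream analyses.
    """

    def __init__(
        self,
        entries: Mapping[str, str],
        labels: Mapping[str, str] | None = None,
        cancer_groups: Iterable[str] = (),
    ) -> None:
        if not entries:
            raise ValueError("code-group map is empty")
        self.entries = dict(entries)
        self.labels = dict(labels or {})
        self.cancer_groups = frozenset(cancer_groups)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CodeGroupMap":
        """Build from a table with columns code, group_id, label, is_cancer."""
        if frame["code"].duplicated().any():
            dups = frame.loc[frame["code"].duplicated(), "code"].tolist()
            raise ValueError(f"codes mapped to more than one group: {dups[:5]}")
        entries = dict(zip(frame["code"].astype(str), frame["group_id"].astype(str)))
        labels = (
            frame.drop_duplicates("group_id").set_index("group_id")["label"].astype(str).to_dict()
            if "label" in frame
            else {}
        )
        cancer = (
            frame.loc[frame["is_cancer"].astype(int) == 1, "group_id"].astype(str).unique()
            if "is_cancer" in frame
            else ()
        )
        return cls(entries, labels, cancer)

    @property
    def groups(self) -> frozenset[str]:
        return frozenset(self.entries.values())


def map_codes_to_groups(codes: Iterable[str], cgm: CodeGroupMap) -> set[str]:
    """Aggregate raw codes into diagnosis groups, dropping cancer groups.

    Unknown codes are logged and skipped (EMR dumps are dirty); duplicates
    collapse because the result is a set.
    """
    groups: set[str] = set()
    unknown: list[str] = []
    for code in codes:
        gid = cgm.entries.get(str(code))
        if gid is None:
            unknown.append(str(code))
        elif gid not in cgm.cancer_groups:
            groups.add(gid)
    if unknown:
        log.warning("dropped %d unknown diagnosis codes (e.g. %s)", len(unknown), unknown[:3])
    return groups


def build_diagnosis_matrix(
    diagnoses: pd.DataFrame, cgm: CodeGroupMap, subject_ids: pd.Index
) -> pd.DataFrame:
    """Long (subject_id, code) table -> boolean subjects x groups matrix.

    Every group in the map gets a column, so downstream phenotype
    definitions can reference groups nobody carries.
    """
    cols = sorted(cgm.groups - cgm.cancer_groups)
    mat = pd.DataFrame(False, index=subject_ids, columns=cols)
    known = diagnoses[diagnoses["subject_id"].isin(subject_ids)]
    for sid, codes in known.groupby("subject_id")["code"]:
        for gid in map_codes_to_groups(codes, cgm):
            mat.loc[sid, gid] = True
    return mat


@dataclass(frozen=True)
class PhenotypeDef:
    """A composite clinical phenotype: a set of diagnosis groups.

    A subject is a case when they carry at least one group in ``groups``
    and, when ``age_min`` is set, their age at last encounter is strictly
    greater than ``age_min`` (the "cataract (age>50)" convention).
    """

    name: str
    groups: frozenset[str] = field(default_factory=frozenset)
    age_min: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", frozenset(self.groups))
        if not self.groups:
            raise ValueError(f"phenotype {self.name!r} has no groups")
        if self.age_min is not None and self.age_min < 0:
            raise ValueError("age_min must be >= 0")


def evaluate_phenotype(cohort: Cohort, pdef: PhenotypeDef) -> pd.Series:
    """Per-subject case indicator for a composite phenotype definition."""
    unknown = pdef.groups - set(cohort.diagnoses.columns)
    if unknown:
        raise ValueError(f"phenotype {pdef.name!r} references unknown groups: {sorted(unknown)}")
    case = cohort.diagnoses[list(pdef.groups)].any(axis=1)
    if pdef.age_min is not None:
        case &= cohort.demographics["age"] > pdef.age_min
    return case.rename(pdef.name)
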