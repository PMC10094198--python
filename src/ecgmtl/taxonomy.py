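"""Two-level diagnostic label hierarchies and auxiliary-task construction.

A multi-task ECG classifier needs two related label spaces.  This module
represents the fine/coarse (subclass/superclass) hierarchy, derives
auxiliary labels by merging fine classes upward (CPSC2018-style: 9 classes
into 5 superclasses) or reusing the finer level downward (PTB-XL-style:
5 superclasses split over 23 subclasses), and builds clinically meaningless
random groupings as the control condition for the multi-task experiment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LabelHierarchy", "TaskLabeling", "build_hierarchy", "derive_aux_labels",
    "derive_split_labels", "random_hierarchy", "class_count_summary",
    "cpsc_hierarchy", "ptbxl_hierarchy", "CPSC_CLASS_COUNTS", "PTBXL_CLASS_COUNTS",
]

# CPSC2018: 9 arrhythmia classes grouped into 5 superclasses, with the
# published per-class record counts (6877 records in total).
_CPSC_PAIRS = [
    ("SNR", "NORM"), ("AF", "AF"),
    ("IAVB", "QRS"), ("LBBB", "QRS"), ("RBBB", "QRS"),
    ("PAC", "V"), ("PVC", "V"),
    ("STE", "ST"), ("STD", "ST"),
]
CPSC_CLASS_COUNTS = {
    "SNR": 918, "AF": 1098, "IAVB": 704, "LBBB": 207, "RBBB": 1695,
    "PAC": 556, "PVC": 672, "STE": 825, "STD": 202,
}

# PTB-XL: 23 diagnostic subclasses nested in 5 superclasses, with the
# published per-subclass label counts (30,560 label assignments over
# 21,837 records; records may carry several labels).
_PTBXL_PAIRS = [
    ("NORM", "NORM"),
    ("LAFB/LPFB", "CD"), ("IRBBB", "CD"), ("ILBBB", "CD"), ("CLBBB", "CD"),
    ("CRBBB", "CD"), ("_AVB", "CD"), ("IVCD", "CD"), ("WPW", "CD"),
    ("LVH", "HYP"), ("RVH", "HYP"), ("LAO/LAE", "HYP"), ("RAO/RAE", "HYP"),
    ("SEHYP", "HYP"),
    ("AMI", "MI"), ("IMI", "MI"), ("LMI", "MI"), ("PMI", "MI"),
    ("ISCA", "STTC"), ("ISCI", "STTC"), ("ISC_", "STTC"), ("STTC", "STTC"),
    ("NST_", "STTC"),
]
PTBXL_CLASS_COUNTS = {
    "NORM": 9528, "LAFB/LPFB": 1803, "IRBBB": 1118, "ILBBB": 77, "CLBBB": 536,
    "CRBBB": 542, "_AVB": 827, "IVCD": 789, "WPW": 80, "LVH": 2137, "RVH": 126,
    "LAO/LAE": 427, "RAO/RAE": 99, "SEHYP": 30, "AMI": 3172, "IMI": 3263,
    "LMI": 201, "PMI": 17, "ISCA": 1016, "ISCI": 398, "ISC_": 1275,
    "STTC": 2329, "NST_": 770,
}


@dataclass(frozen=True)
class LabelHierarchy:
    """A two-level taxonomy: each fine class has exactly one coarse parent."""

    fine_classes: tuple[str, ...]
    coarse_classes: tuple[str, ...]
    parent_of: dict[str, str]

    def children_of(self, coarse: str) -> tuple[str, ...]:
        if coarse not in self.coarse_classes:
            raise KeyError(f"unknown coarse class: {coarse!r}")
        return tuple(f for f in self.fine_classes if self.parent_of[f] == coarse)

    def group_sizes(self) -> tuple[int, ...]:
        """Group sizes in coarse-class order."""
        return tuple(len(self.children_of(c)) for c in self.coarse_classes)

    def to_pairs(self) -> list[tuple[str, str]]:
        return [(f, self.parent_of[f]) for f in self.fine_classes]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fine", "coarse"])
            writer.writerows(self.to_pairs())

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabelHierarchy":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        if rows and rows[0] == ["fine", "coarse"]:
            rows = rows[1:]
        return build_hierarchy([(r[0], r[1]) for r in rows])


@dataclass
class TaskLabeling:
    """Main/auxiliary label assignment of one record."""

    record_id: str
    main_labels: set[str]
    aux_labels: set[str] = field(default_factory=set)
    direction: str = "merge"


def build_hierarchy(pairs: list[tuple[str, str]]) -> LabelHierarchy:
    """Build a hierarchy from (fine, coarse) pairs, preserving input order."""
    if not pairs:
        raise ValueError("cannot build a hierarchy from an empty pair list")
    fine: list[str] = []
    coarse: list[str] = []
    parent: dict[str, str] = {}
    for f, c in pairs:
        if f in parent:
            raise ValueError(f"duplicate fine class: {f!r}")
        parent[f] = c
        fine.append(f)
        if c not in coarse:
            coarse.append(c)
    return LabelHierarchy(tuple(fine), tuple(coarse), parent)


def cpsc_hierarchy() -> LabelHierarchy:
    """The CPSC2018 taxonomy: 9 classes in 5 superclasses."""
    return build_hierarchy(_CPSC_PAIRS)


def ptbxl_hierarchy() -> LabelHierarchy:
    """The PTB-XL diagnostic taxonomy: 23 subclasses in 5 superclasses."""
    return build_hierarchy(_PTBXL_PAIRS)


def derive_aux_labels(main_labels: set[str], h: LabelHierarchy) -> set[str]:
    """Merge direction: map each fine label to its coarse parent, deduplicated."""
    for c in main_labels:
        if c not in h.parent_of:
            raise KeyError(f"unknown fine class: {c!r}")
    return {h.parent_of[c] for c in main_labels}

def derive_split_labels(main_labels: set[str], h: LabelHierarchy,
                        fine_labels: set[str]) -> set[str]:
    """Split direction: keep the fine labels whose parent is a main label.

    Used when the main task is the coarse level and the auxiliary task reuses
    the finer level of the same hierarchy.
    """
    for c in main_labels:
        if c not in h.coarse_classes:
            raise KeyError(f"unknown coarse class: {c!r}")
    out = {f for f in fine_labels if h.parent_of.get(f) in main_labels}
    unknown = fine_labels - set(h.fine_classes)
    if unknown:
        raise KeyError(f"unknown fine class: {sorted(unknown)[0]!r}")
    return out


def random_hierarchy(h: LabelHierarchy, seed: int) -> LabelHierarchy:
    """Regroup the fine classes at random, keeping the group-size multiset.

    This is the control auxiliary task: same number of groups, same sizes,
    but membership drawn by a seeded shuffle, so the grouping carries no
    clinical meaning.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    shuffled = [h.fine_classes[i] for i in rng.permutation(len(h.fine_classes))]
    pairs: list[tuple[str, str]] = []
    pos = 0
    for coarse in h.coarse_classes:
        size = len(h.children_of(coarse))
        for f in shuffled[pos:pos + size]:
            pairs.append((f, coarse))
        pos += size
    # same fine and coarse orderings as the input: only parent_of changes
    parent = dict(pairs)
    return LabelHierarchy(h.fine_classes, h.coarse_classes,
                          {f: parent[f] for f in h.fine_classes})


def class_count_summary(labelings: list[TaskLabeling],
                        h: LabelHierarchy) -> dict[str, int]:
    """Per-class label-assignment counts at both levels, plus totals.

    Returns a map with one entry per fine class, one ``coarse:<name>`` entry
    per coarse class (prefixed because a one-member group may share its
    class's name), a ``total_fine`` entry (number of fine label assignments)
    and a ``total_coarse`` entry.
    """
    counts = {c: 0 for c in h.fine_classes}
    counts.update({f"coarse:{c}": 0 for c in h.coarse_classes})
    total_fine = total_coarse = 0
    for lab in labelings:
        fine = lab.main_labels if lab.direction == "merge" else lab.aux_labels
        coarse = lab.aux_labels if lab.direction == "merge" else lab.main_labels
        for c in fine:
            if c not in h.parent_of:
                raise KeyError(f"unknown fine class: {c!r}")
            counts[c] += 1
            total_fine += 1
        for c in coarse:
            counts[f"coarse:{c}"] += 1
            total_coarse += 1
    counts["total_fine"] = total_fine
    counts["total_coarse"] = total_coarse
    return counts
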