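"""HER2 scoring from per-nucleus signal counts.

The score is the pooled HER2/CEP17 ratio (sum over nuclei / sum over
nuclei), which is standard in situ hybridization practice and robust to
individual nuclei with zero CEP17 signals. Status is Pos iff the ratio
reaches the ASCO/CAP cut-off of 2.0.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

__all__ = [
    "EmptyTableError",
    "CaseScore",
    "POSITIVITY_THRESHOLD",
    "RatioUndefinedError",
    "SignalCountTable",
    "grade_case",
    "status_from_score",
]

POSITIVITY_THRESHOLD = 2.0
POS = "Pos"
NEG = "Neg"


class EmptyTableError(ValueError):
    pass


class RatioUndefinedError(ValueError):
    pass


@dataclass
class SignalCountTable:
    nucleus_ids: list[int] = field(default_factory=list)
    her2_counts: list[int] = field(default_factory=list)
    cep17_counts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not len(self.nucleus_ids) == len(self.her2_counts) == len(self.cep17_counts):
            raise ValueError("columns have unequal lengths")
        if any(c < 0 for c in self.her2_counts) or any(c < 0 for c in self.cep17_counts):
            raise ValueError("signal counts must be non-negative")

    def __len__(self) -> int:
        return len(self.nucleus_ids)

    def to_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["nucleus_id", "her2_count", "cep17_count"])
            for row in zip(self.nucleus_ids, self.her2_counts, self.cep17_counts):
                writer.writerow(row)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "SignalCountTable":
        ids, her2, cep17 = [], [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                ids.append(int(row["nucleus_id"]))
                her2.append(int(row["her2_count"]))
                cep17.append(int(row["cep17_count"]))
        return cls(ids, her2, cep17)


@dataclass(frozen=True)
class CaseScore:
    case_id: str
    her2_mean_per_nucleus: float
    her2_cep17_ratio: float
    status: str


def status_from_score(score: float) -> str:
    """Pos iff the HER2/CEP17 ratio is >= 2.0."""
    if score < 0:
        raise ValueError(f"score must be non-negative, got {score}")
    return POS if score >= POSITIVITY_THRESHOLD else NEG


def grade_case(table: SignalCountTable, case_id: str = "") -> CaseScore:
    """Mean HER2 copies per nucleus, pooled HER2/CEP17 ratio and status."""
    if len(table) == 0:
        raise EmptyTableError("cannot grade an empty signal table")
    total_her2 = sum(table.her2_counts)
    total_cep17 = sum(table.cep17_counts)
    if total_cep17 == 0:
        raise RatioUndefinedError("total CEP17 count is zero: ratio undefined")
    ratio = total_her2 / total_cep17
    return CaseScore(
        case_id=case_id,
        her2_mean_per_nucleus=total_her2 / len(table),
        her2_cep17_ratio=ratio,
        status=status_from_score(ratio),
    )
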