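"""Wilting-phenotype scores: morbidity and disease index over 0-4 grade tables.

Grades: 0 healthy, 1-4 increasing wilting severity (4 = worst or dead).
Morbidity is the percentage of plants with any symptom (grade >= 1).  The
disease index is::

    100 * sum(grade_g * n_plants_at_g) / (4 * n_plants)

with the denominator's 4 the scale maximum, not the observed maximum, so an
all-grade-4 table scores exactly 100.
"""
from __future__ import annotations

from dataclasses import dataclass, field

MAX_GRADE = 4


@dataclass(frozen=True)
class GradeTable:
    """Per-plant disease grades for one treatment (optionally one day)."""

    treatment: str
    grades: tuple[int, ...]
    day: int = 0

    def __post_init__(self) -> None:
        if not self.grades:
            raise ValueError("grade table needs at least one plant")
        for g in self.grades:
            if not isinstance(g, (int,)) or not 0 <= g <= MAX_GRADE:
                raise ValueError(f"grade {g!r} outside the integral 0..{MAX_GRADE} scale")

    @property
    def n_plants(self) -> int:
        return len(self.grades)


@dataclass(frozen=True)
class DiseaseScore:
    morbidity: float  # percent of plants with grade >= 1
    index: float  # 0..100

    def __post_init__(self) -> None:
        if not (0 <= self.morbidity <= 100 and 0 <= self.index <= 100):
            raise ValueError("scores must lie in [0, 100]")


def morbidity(table: GradeTable) -> float:
    """100 x diseased plants (grade >= 1) / total plants."""
    diseased = sum(1 for g in table.grades if g >= 1)
    return 100.0 * diseased / table.n_plants


def disease_index(table: GradeTable) -> float:
    """100 x sum(grade x plants at that grade) / (4 x total plants)."""
    weighted = sum(table.grades)
    return 100.0 * weighted / (MAX_GRADE * table.n_plants)


def score(table: GradeTable) -> DiseaseScore:
    return DiseaseScore(morbidity(table), disease_index(table))
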