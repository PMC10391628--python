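"""Macromorbidity index from necropsy findings.

Each mouse receives a neoplasia grade (0 = tumor-free, 1 = one organ
affected, 2 = two or more organs, i.e. metastatic disease) and one point
per macroscopic non-neoplastic pathological finding; the macromorbidity
index is their sum. Findings are drawn from a closed vocabulary of
macro-pathologies scored at dissection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "FINDINGS_VOCABULARY",
    "PathologyRecord",
    "MorbidityIndex",
    "neoplasia_grade",
    "macromorbidity",
    "morbidity_table",
]

# Closed vocabulary of macroscopic non-neoplastic findings. Bilateral organs
# (kidneys, adrenals) count as a single label. A different study can pass its
# own vocabulary to the readers/scorers.
FINDINGS_VOCABULARY: tuple[str, ...] = (
    "kyphosis",
    "enlarged spleen",
    "WAT discoloration",
    "granular pancreas",
    "uterine cysts",
    "enlarged kidneys",
    "enlarged adrenal glands",
)


@dataclass(frozen=True)
class PathologyRecord:
    """Necropsy result for one mouse."""

    mouse_id: str
    n_tumor_organs: int
    non_neoplastic_findings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_tumor_organs < 0:
            raise ValueError(
                f"mouse {self.mouse_id}: negative tumor-organ count "
                f"{self.n_tumor_organs}"
            )
        if len(set(self.non_neoplastic_findings)) != len(self.non_neoplastic_findings):
            raise ValueError(f"mouse {self.mouse_id}: duplicate findings")


@dataclass(frozen=True)
class MorbidityIndex:
    mouse_id: str
    neoplasia_grade: int
    non_neoplastic_burden: int
    macromorbidity: int


def neoplasia_grade(n_tumor_organs: int) -> int:
    """Grade tumor load: 0 organs -> 0, 1 organ -> 1, >= 2 organs -> 2."""
    n = int(n_tumor_organs)
    if n < 0:
        raise ValueError(f"negative tumor-organ count: {n}")
    return min(n, 2)


def macromorbidity(
    record: PathologyRecord,
    vocabulary: tuple[str, ...] = FINDINGS_VOCABULARY,
) -> MorbidityIndex:
    """Neoplasia grade plus one point per non-neoplastic finding."""
    unknown = [f for f in record.non_neoplastic_findings if f not in vocabulary]
    if unknown:
        raise ValueError(
            f"mouse {record.mouse_id}: unknown finding label(s): {unknown}"
        )
    grade = neoplasia_grade(record.n_tumor_organs)
    burden = len(record.non_neoplastic_findings)
    return MorbidityIndex(record.mouse_id, grade, burden, grade + burden)


def morbidity_table(
    records: list[PathologyRecord],
    vocabulary: tuple[str, ...] = FINDINGS_VOCABULARY,
) -> pd.DataFrame:
    """One row per mouse: mouse_id, neoplasia_grade, burden, macromorbidity."""
    rows = [macromorbidity(r, vocabulary) for r in records]
    return pd.DataFrame(
        {
            "mouse_id": [r.mouse_id for r in rows],
            "neoplasia_grade": [r.neoplasia_grade for r in rows],
            "non_neoplastic_burden": [r.non_neoplastic_burden for r in rows],
            "macromorbidity": [r.macromorbidity for r in rows],
        }
    )
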