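"""Serology utilities: ImmunoCAP class assignment, sensitization and
house-dust-mite eligibility rules.

The CAP system bins allergen-specific IgE (kU/l) into 7 ordinal classes.
The printed class bounds leave small gaps (0.70 -> 0.71 etc.); bins here
are half-open at the printed lower bounds, with class 5 closed at 50:
class 0 < 0.35 <= class 1 < 0.71 <= class 2 < 3.51 <= class 3 < 7.6 <=
class 4 < 17.6 <= class 5 <= 50 < class 6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .formats import FormatError, ValidationError

#: exclusion comorbidity flags
EXCLUSION_FLAGS = {
    "asthma": "co-morbid asthma",
    "eczema": "co-morbid eczema",
    "other_allergic": "other allergic disease",
    "hypertension_diabetes_chronic": "hypertension/diabetes/chronic disease",
    "nasal_disease": "nasal tumor or inflammatory nasal disease",
}

_CLASS_LOWER_BOUNDS = (0.35, 0.71, 3.51, 7.6, 17.6)  # classes 1..5


@dataclass(frozen=True)
class SerologyRecord:
    subject_id: str
    specific_ige: Mapping[str, float]  # allergen -> kU/l
    total_ige: float
    comorbidity_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.total_ige < 0 or any(v < 0 for v in self.specific_ige.values()):
            raise ValidationError(
                f"{self.subject_id}: IgE concentrations must be >= 0"
            )
        bad = set(self.comorbidity_flags) - set(EXCLUSION_FLAGS)
        if bad:
            raise ValidationError(f"unknown comorbidity flags: {sorted(bad)}")

    @property
    def total_ige_positive(self) -> bool:
        """Annotation flag only (> 100 kU/l); not an eligibility criterion."""
        return self.total_ige > 100.0


def cap_class(sige_ku_per_l: float) -> int:
    """CAP class 0-6 for a specific-IgE concentration in kU/l."""
    x = float(sige_ku_per_l)
    if x < 0:
        raise ValidationError(f"specific IgE must be >= 0, got {x}")
    if x > 50.0:
        return 6
    cls = 0
    for i, lower in enumerate(_CLASS_LOWER_BOUNDS, start=1):
        if x >= lower:
            cls = i
    return cls


def is_sensitized(record: SerologyRecord, allergen: str) -> bool:
    """Sensitized iff allergen-specific IgE >= 0.35 kU/l."""
    if allergen not in record.specific_ige:
        raise KeyError(f"allergen {allergen!r} not measured for {record.subject_id}")
    return record.specific_ige[allergen] >= 0.35


def dm_eligible(
    record: SerologyRecord, conjunctive: bool = True
) -> tuple[bool, list[str]]:
    """Dust-mite eligibility: Der f and Der p at or above CAP class 2, and
    no exclusion comorbidity. Returns (eligible, reasons for every failed
    criterion). ``conjunctive=False`` relaxes to either mite species
    (sensitivity analysis)."""
    for allergen in ("Der f", "Der p"):
        if allergen not in record.specific_ige:
            raise KeyError(
                f"{allergen!r} missing from serology of {record.subject_id}"
            )
    reasons = []
    classes = {a: cap_class(record.specific_ige[a]) for a in ("Der f", "Der p")}
    below = [a for a, c in classes.items() if c < 2]
    if conjunctive:
        reasons.extend(f"{a} below class 2" for a in below)
    elif len(below) == 2:
        reasons.append("Der f and Der p both below class 2")
    for flag in sorted(record.comorbidity_flags):
        reasons.append(EXCLUSION_FLAGS[flag])
    return (not reasons, reasons)


def read_serology(path: str | Path) -> list[SerologyRecord]:
    """Read a serology TSV: subject, Der f, Der p, total IgE, flags.

    Columns: subject_id, der_f, der_p, total_ige, comorbidity flags as a
    comma-separated list ("-" for none).
    """
    records = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 columns")
        subject, der_f, der_p, total, flags = cols
        records.append(
            SerologyRecord(
                subject_id=subject,
                specific_ige={"Der f": float(der_f), "Der p": float(der_p)},
                total_ige=float(total),
                comorbidity_flags=frozenset(
                    f for f in flags.split(",") if f and f != "-"
                ),
            )
        )
    return records


def write_serology(records: list[SerologyRecord], path: str | Path) -> None:
    lines = []
    for r in records:
        flags = ",".join(sorted(r.comorbidity_flags)) or "-"
        lines.append(
            "\t".join(
                [
                    r.subject_id,
                    f"{r.specific_ige['Der f']:g}",
                    f"{r.specific_ige['Der p']:g}",
                    f"{r.total_ige:g}",
                    flags,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
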