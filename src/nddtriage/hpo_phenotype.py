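"""Patient stratification from HPO term sets.

Patients are split into an ASD subset (autistic-behaviour terms present,
no intellectual-disability / developmental-delay terms) and an ID/GDD
subset (everyone else).  Each HPO term is additionally mapped to one of 16
clinical categories; the per-patient category flags, the number of affected
categories and sex are the predictors consumed by :mod:`nddtriage.profiling`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "Subset",
    "AUTISM_CODES",
    "ID_GDD_CODES",
    "CATEGORIES",
    "DEFAULT_CATEGORY_MAP",
    "CategoryMap",
    "PatientPhenotype",
    "classify_subset",
    "categorize",
    "build_phenotype",
]


class Sex(str, Enum):
    M = "M"
    F = "F"


class Subset(str, Enum):
    ID_GDD = "ID_GDD"
    ASD = "ASD"


#: Terms indicating autistic behaviour.
AUTISM_CODES = frozenset(
    {
        "HP:0000729",
        "HP:0000735",
        "HP:0000728",
        "HP:0008763",
        "HP:0000758",
        "HP:0000717",
        "HP:0031433",
        "HP:0000723",
        "HP:0000753",
    }
)

#: Terms indicating intellectual disability / global developmental delay.
#: Any of these vetoes ASD membership.
ID_GDD_CODES = frozenset(
    {
        "HP:0001249",
        "HP:0001256",
        "HP:0010864",
        "HP:0006887",
        "HP:0006889",
        "HP:0002187",
        "HP:0002342",
        "HP:0001263",
        "HP:0012758",
        "HP:0100543",
    }
)

#: The 16 clinical categories used as phenotype predictors.
CATEGORIES: tuple[str, ...] = (
    "Abnormality of metabolism/homeostasis",
    "Abnormality of prenatal development or birth",
    "Abnormality of the cardiovascular system",
    "Abnormality of the digestive system",
    "Abnormality of the ear",
    "Abnormality of the endocrine system",
    "Abnormality of the eye",
    "Abnormality of the genitourinary system",
    "Abnormality of the head",
    "Abnormality of the integument",
    "Abnormality of the musculoskeletal system",
    "Abnormality of the respiratory system",
    "Abnormal nervous system morphology",
    "Abnormal nervous system physiology",
    "Behavioral abnormality",
    "Intellectual disability",
)

# Built-in approximate assignments for the literal subset-defining codes so
# the classifier is usable without an ontology file; full cohorts should
# supply their own code -> category TSV.
DEFAULT_CATEGORY_MAP: dict[str, str] = {
    **{code: "Behavioral abnormality" for code in AUTISM_CODES},
    "HP:0001249": "Intellectual disability",
    "HP:0001256": "Intellectual disability",
    "HP:0010864": "Intellectual disability",
    "HP:0006887": "Intellectual disability",
    "HP:0006889": "Intellectual disability",
    "HP:0002187": "Intellectual disability",
    "HP:0002342": "Intellectual disability",
    "HP:0001263": "Abnormal nervous system physiology",
    "HP:0012758": "Abnormal nervous system physiology",
    "HP:0100543": "Abnormal nervous system physiology",
}


class CategoryMap:
    """HPO code -> category label (each code maps to at most one category)."""

    def __init__(self, mapping: Mapping[str, str]):
        bad = sorted(set(mapping.values()) - set(CATEGORIES))
        if bad:
            raise ValueError(f"unknown category labels: {bad}")
        self._map = dict(mapping)

    @classmethod
    def default(cls) -> "CategoryMap":
        return cls(DEFAULT_CATEGORY_MAP)

    def __getitem__(self, code: str) -> str:
        return self._map[code]

    def __contains__(self, code: str) -> bool:
        return code in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


def classify_subset(hpo_terms: Iterable[str]) -> Subset:
    """ASD iff >=1 autistic-behaviour term and no ID/GDD term; else ID/GDD."""
    terms = set(hpo_terms)
    if not terms:
        logger.warning("patient with empty HPO term set; defaulting to ID/GDD")
        return Subset.ID_GDD
    if terms & AUTISM_CODES and not terms & ID_GDD_CODES:
        return Subset.ASD
    return Subset.ID_GDD


def categorize(
    hpo_terms: Iterable[str], category_map: Optional[CategoryMap] = None
) -> tuple[dict[str, bool], int, set[str]]:
    """Per-category flags for a term set.

    Returns (flags keyed by category label, number of affected categories,
    codes the map does not cover).  A category is affected when at least one
    term maps to it; duplicate terms in one category count once.
    """
    cmap = category_map or CategoryMap.default()
    flags = {c: False for c in CATEGORIES}
    unmapped: set[str] = set()
    for code in set(hpo_terms):
        if code in cmap:
            flags[cmap[code]] = True
        else:
            unmapped.add(code)
    return flags, sum(flags.values()), unmapped


@dataclass
class PatientPhenotype:
    patient_id: str
    sex: Sex
    hpo_terms: frozenset[str]
    subset: Subset
    category_flags: dict[str, bool]
    n_categories: int
    diagnosed: bool = False
    unmapped_codes: frozenset[str] = field(default_factory=frozenset)


def build_phenotype(
    patient_id: str,
    sex: Sex | str,
    hpo_terms: Iterable[str],
    diagnosed: bool = False,
    category_map: Optional[CategoryMap] = None,
) -> PatientPhenotype:
    terms = frozenset(hpo_terms)
    flags, n, unmapped = categorize(terms, category_map)
    return PatientPhenotype(
        patient_id=patient_id,
        sex=Sex(sex),
        hpo_terms=terms,
        subset=classify_subset(terms),
        category_flags=flags,
        n_categories=n,
        diagnosed=bool(diagnosed),
        unmapped_codes=frozenset(unmapped),
    )
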