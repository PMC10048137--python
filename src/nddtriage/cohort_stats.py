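"""Diagnostic-yield summaries and cohort association statistics.

Two chi-square flavours are exposed because they match different designs:
2x2 group comparisons use the Yates continuity correction
(:func:`chi2_2x2_yates`) while the equal-probability goodness-of-fit test
(:func:`chi2_gof_equal`) applies none.  Both choices are configurable at the
call site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .hpo_phenotype import PatientPhenotype, Sex, Subset

__all__ = [
    "ContingencyTable2x2",
    "Chi2Result",
    "diagnostic_yield",
    "chi2_2x2",
    "chi2_2x2_yates",
    "chi2_gof_equal",
    "phi_coefficient",
    "glass_rank_biserial",
    "VariantClass",
    "CohortSummary",
    "build_summary",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = group, columns = outcome: [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    pvalue: float
    dof: int = 1


def diagnostic_yield(diagnosed: int, total: int) -> float:
    """Percentage of diagnosed patients, 100 * diagnosed / total."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= diagnosed <= total:
        raise ValueError("diagnosed must be between 0 and total")
    return 100.0 * diagnosed / total


def chi2_2x2(table: ContingencyTable2x2, correction: bool = True) -> Chi2Result:
    """Chi-square test of independence on a 2x2 table (df = 1).

    With ``correction`` (default) the Yates continuity correction
    ``sum((|O-E| - 0.5)^2 / E)`` is applied.
    """
    if 0 in table.margins:
        raise ValueError("table has a zero margin")
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    r = obs.sum(axis=1, keepdims=True)
    c = obs.sum(axis=0, keepdims=True)
    expected = r @ c / obs.sum()
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    return Chi2Result(stat, float(stats.chi2.sf(stat, 1)))


def chi2_2x2_yates(table: ContingencyTable2x2) -> Chi2Result:
    return chi2_2x2(table, correction=True)


def chi2_gof_equal(counts: Sequence[int]) -> Chi2Result:
    """Goodness of fit against equal expected counts, no continuity correction."""
    obs = np.asarray(counts, dtype=float)
    n = obs.sum()
    if n <= 0:
        raise ValueError("empty counts")
    expected = n / len(obs)
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = len(obs) - 1
    return Chi2Result(stat, float(stats.chi2.sf(stat, dof)), dof)


def phi_coefficient(table: ContingencyTable2x2) -> float:
    """phi = (ad - bc) / sqrt of the margin product; in [-1, 1]."""
    r1, r2, c1, c2 = table.margins
    if 0 in (r1, r2, c1, c2):
        raise ValueError("phi undefined: table has a zero margin")
    num = table.a * table.d - table.b * table.c
    return num / np.sqrt(float(r1) * r2 * c1 * c2)


def glass_rank_biserial(
    values: Sequence[float], labels: Sequence[int]
) -> float:
    """Glass rank-biserial correlation of a binary grouping with ranked values.

    r = 2 * (mean rank in group 1 - mean rank in group 0) / n, with midranks
    for ties.  +1 when every group-1 value exceeds every group-0 value.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    g1 = labels == 1
    g0 = ~g1
    if not g1.any() or not g0.any():
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(values)
    return float(2.0 * (ranks[g1].mean() - ranks[g0].mean()) / len(values))


@dataclass(frozen=True)
class VariantClass:
    """Classification labels for one pathogenic/likely pathogenic variant."""

    inheritance: str  # de_novo | inherited | uncertain_na
    vtype: str  # lof | missense | inframe | cryptic_splicing | cnv_del | cnv_dup
    x_linked: bool = False
    carrier_sex: Optional[Sex] = None
    subset: Optional[Subset] = None

    INHERITANCE_CLASSES = ("de_novo", "inherited", "uncertain_na")
    VTYPE_CLASSES = ("lof", "missense", "inframe", "cryptic_splicing", "cnv_del", "cnv_dup")

    def __post_init__(self) -> None:
        if self.inheritance not in self.INHERITANCE_CLASSES:
            raise ValueError(f"unknown inheritance class {self.inheritance!r}")
        if self.vtype not in self.VTYPE_CLASSES:
            raise ValueError(f"unknown variant type {self.vtype!r}")


def _pct(num: int, den: int) -> float:
    return round(100.0 * num / den, 1) if den else 0.0


@dataclass
class CohortSummary:
    """Table-shaped cohort summary: yields plus variant breakdowns.

    Inheritance and variant-type percentages use the total variant count as
    denominator.  The X-linked row is an overlay (X-linked variants also
    count in their inheritance class), so it is reported separately and the
    exclusive inheritance block still sums to 100%.
    """

    n_patients: int
    n_diagnosed: int
    patients_by_sex: dict[str, int]
    diagnosed_by_sex: dict[str, int]
    patients_by_subset: dict[str, int]
    diagnosed_by_subset: dict[str, int]
    yield_overall: float
    yield_by_sex: dict[str, float]
    yield_by_subset: dict[str, float]
    n_variants: int
    inheritance_counts: dict[str, int]
    inheritance_pct: dict[str, float]
    x_linked_count: int
    x_linked_by_sex: dict[str, int]
    x_linked_pct: float
    #: 100 * (female X-linked variant carriers) / (female patients)
    x_linked_detection_rate_f: Optional[float]
    x_linked_detection_rate_m: Optional[float]
    vtype_counts: dict[str, int]
    vtype_pct: dict[str, float]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def build_summary(
    patients: Sequence[PatientPhenotype],
    variants: Sequence[VariantClass],
) -> CohortSummary:
    """Diagnostic yields by subset/sex plus inheritance and type breakdowns."""
    n_diag_flags = sum(p.diagnosed for p in patients)
    n_pat = len(patients)
    by_sex = {s.value: sum(1 for p in patients if p.sex == s) for s in Sex}
    diag_sex = {
        s.value: sum(1 for p in patients if p.sex == s and p.diagnosed) for s in Sex
    }
    by_sub = {s.value: sum(1 for p in patients if p.subset == s) for s in Subset}
    diag_sub = {
        s.value: sum(1 for p in patients if p.subset == s and p.diagnosed)
        for s in Subset
    }

    n_var = len(variants)
    inh_counts = {
        k: sum(1 for v in variants if v.inheritance == k)
        for k in VariantClass.INHERITANCE_CLASSES
    }
    if sum(inh_counts.values()) != n_var:
        raise ValueError("inheritance classes do not partition the variant set")
    vt_counts = {
        k: sum(1 for v in variants if v.vtype == k) for k in VariantClass.VTYPE_CLASSES
    }
    xl = [v for v in variants if v.x_linked]
    xl_sex = {
        s.value: sum(1 for v in xl if v.carrier_sex == s) for s in Sex
    }

    def det_rate(sex: Sex) -> Optional[float]:
        denom = by_sex[sex.value]
        return _pct(xl_sex[sex.value], denom) if denom else None

    return CohortSummary(
        n_patients=n_pat,
        n_diagnosed=n_diag_flags,
        patients_by_sex=by_sex,
        diagnosed_by_sex=diag_sex,
        patients_by_subset=by_sub,
        diagnosed_by_subset=diag_sub,
        yield_overall=_pct(n_diag_flags, n_pat),
        yield_by_sex={s: _pct(diag_sex[s], by_sex[s]) for s in by_sex},
        yield_by_subset={s: _pct(diag_sub[s], by_sub[s]) for s in by_sub},
        n_variants=n_var,
        inheritance_counts=inh_counts,
        inheritance_pct={k: _pct(c, n_var) for k, c in inh_counts.items()},
        x_linked_count=len(xl),
        x_linked_by_sex=xl_sex,
        x_linked_pct=_pct(len(xl), n_var),
        x_linked_detection_rate_f=det_rate(Sex.F),
        x_linked_detection_rate_m=det_rate(Sex.M),
        vtype_counts=vt_counts,
        vtype_pct={k: _pct(c, n_var) for k, c in vt_counts.items()},
    )
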