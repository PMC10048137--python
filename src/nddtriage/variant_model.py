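"""Domain types shared by every triage stage.

All filter thresholds live in :class:`FilterThresholds`; the rule logic that
consumes them is in :mod:`nddtriage.snv_triage`.

Coordinate conventions
----------------------
Internal intervals are half-open 0-based.  Variant positions (``pos``) are
1-based as in VCF.  BED input is 0-based half-open per the BED convention.

VAF is defined as ``alt_reads / depth`` with the *total* read depth at the
site as denominator; it is undefined (``None``) when depth is zero.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional

__all__ = [
    "Consequence",
    "LOF_CONSEQUENCES",
    "ClinvarStatus",
    "PREDICTORS",
    "SPLICE_TOOLS",
    "DELETERIOUS",
    "TOLERATED",
    "GenotypeEvidence",
    "PopulationEvidence",
    "FunctionalAnnotation",
    "VariantRecord",
    "FilterThresholds",
    "TriageStatus",
    "TriageDecision",
    "PanelDefinition",
    "PanelError",
    "is_lof",
    "in_panel",
]


class Consequence(str, Enum):
    """Collapsed functional consequence classes used by the cascade."""

    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical_splice"
    START_LOSS = "start_loss"
    STOP_LOSS = "stop_loss"
    INFRAME_INDEL = "inframe_indel"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    OTHER = "other"


#: The four loss-of-function classes.
LOF_CONSEQUENCES = frozenset(
    {
        Consequence.STOP_GAIN,
        Consequence.FRAMESHIFT,
        Consequence.CANONICAL_SPLICE,
        Consequence.START_LOSS,
    }
)


class ClinvarStatus(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    OTHER = "other"
    ABSENT = "absent"


#: Categorical call values for the per-predictor deleteriousness columns.
DELETERIOUS = "D"
TOLERATED = "T"

#: Deleteriousness predictors consulted by the missense majority vote.
#: 27 function-based predictors followed by 9 conservation-based scores.
#: Raw scores are interpreted upstream; the pipeline only sees D/T/missing.
PREDICTORS: tuple[str, ...] = (
    "SIFT",
    "SIFT4G",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "LRT",
    "MutationTaster2",
    "MutationAssessor",
    "FATHMM",
    "MetaSVM",
    "MetaLR",
    "CADD",
    "VEST4",
    "PROVEAN",
    "FATHMM_MKL",
    "FATHMM_XF",
    "fitCons",
    "DANN",
    "GenoCanyon",
    "Eigen",
    "Eigen_PC",
    "M_CAP",
    "REVEL",
    "MutPred",
    "MVP",
    "MPC",
    "PrimateAI",
    "DEOGEN2",
    "bStatistic",
    "phyloP100way_vertebrate",
    "phyloP30way_mammal",
    "phyloP17way_primate",
    "phastCons100way_vertebrate",
    "phastCons30way_mammal",
    "phastCons17way_primate",
    "GERP",
    "SiPhy",
)

#: Splice-effect ensemble members (any score >= cutoff marks a splice effect).
SPLICE_TOOLS: tuple[str, ...] = ("squirls", "spliceai", "ada", "rf")


@dataclass(frozen=True)
class GenotypeEvidence:
    """Read-level support for one called allele in one sample.

    ``zygosity`` ("het"/"hom") is optional and only consumed by the
    recessive filter; panel-mode triage never reads it.
    """

    depth: int
    alt_reads: int
    zygosity: Optional[str] = None

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth})"
            )

    @property
    def vaf(self) -> Optional[float]:
        """Alternate-allele fraction, or None when the site has no coverage."""
        if self.depth == 0:
            return None
        return self.alt_reads / self.depth


@dataclass(frozen=True)
class PopulationEvidence:
    """gnomAD-style population counts; all fields may be absent (None)."""

    ac: Optional[int] = None
    af: Optional[float] = None
    hom: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ac is not None and self.ac < 0:
            raise ValueError("allele count must be >= 0")
        if self.hom is not None and self.hom < 0:
            raise ValueError("homozygote count must be >= 0")
        if self.af is not None and self.af == 0 and self.ac not in (None, 0):
            raise ValueError("af=0 is only consistent with ac=0 or absent ac")

    @property
    def absent(self) -> bool:
        """True when the variant is absent from the population resource.

        Both "no matching record" (``ac is None``) and an explicit zero
        count qualify as absent.
        """
        return self.ac is None or self.ac == 0


@dataclass(frozen=True)
class FunctionalAnnotation:
    consequence: Consequence
    clinvar: ClinvarStatus = ClinvarStatus.ABSENT
    #: predictor name -> "D"/"T"; names missing from the map (or mapped to
    #: None) are treated as unavailable for that variant.
    predictor_calls: Mapping[str, Optional[str]] = field(default_factory=dict)
    provean: Optional[float] = None
    #: tool name -> score in [0,1]; missing entries mean no score.
    splice_scores: Mapping[str, Optional[float]] = field(default_factory=dict)


@dataclass(frozen=True)
class VariantRecord:
    """One called small variant in one sample."""

    sample_id: str
    chrom: str
    pos: int  # 1-based, per VCF
    ref: str
    alt: str
    gene: str
    genotype: GenotypeEvidence
    population: PopulationEvidence
    annotation: FunctionalAnnotation

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        """Identity of the variant irrespective of carrier."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt, self.sample_id)


@dataclass
class FilterThresholds:
    """Every tunable of the SNV cascade, with the published defaults."""

    min_depth: int = 10
    max_gnomad_ac: int = 4
    min_vaf_primary: float = 0.30
    #: exclusive upper bound of the low-depth band in re-analysis mode
    lowdp_max: int = 50
    min_vaf_lof_lowdp: float = 0.20
    min_vaf_nonlof_lowdp: float = 0.25
    mosaic_min_vaf: float = 0.10
    #: distinct gnomAD-absent carriers needed to raise the artifact flag
    artifact_min_carriers: int = 4
    splice_cutoff: float = 0.5
    provean_cutoff: float = -2.5
    majority_fraction: float = 0.5
    recessive_max_af: float = 0.001
    recessive_max_hom: int = 4
    #: how the three priority routes combine: "any" (default) or "conjunction"
    priority_mode: str = "any"

    def __post_init__(self) -> None:
        if self.priority_mode not in ("any", "conjunction"):
            raise ValueError(f"unknown priority_mode: {self.priority_mode!r}")

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterThresholds":
        unknown = set(d) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**dict(d))

    def replace(self, **kw) -> "FilterThresholds":
        return replace(self, **kw)


class TriageStatus(str, Enum):
    """Terminal status of one variant after the cascade.

    ``DISCARDED_PANEL`` marks variants outside the virtual-panel target
    regions; it only occurs when a panel restriction is applied.
    """

    DISCARDED_PANEL = "discarded_panel"
    DISCARDED_QUALITY = "discarded_quality"
    DISCARDED_FREQUENCY = "discarded_frequency"
    DISCARDED_CONSEQUENCE = "discarded_consequence"
    RETAINED = "retained"
    CANDIDATE = "candidate"

    @property
    def kept(self) -> bool:
        return self in (TriageStatus.RETAINED, TriageStatus.CANDIDATE)


@dataclass
class TriageDecision:
    status: TriageStatus
    reasons: list[str] = field(default_factory=list)
    artifact_flag: bool = False


class PanelError(ValueError):
    """Raised for malformed panel definitions."""


class PanelDefinition:
    """A virtual panel: gene symbols plus target regions.

    Regions are coding exons padded by 20 bp on each side.  They are merged
    per gene on construction; a position overlapping regions assigned to two
    different genes is rejected as a configuration error.
    """

    def __init__(
        self,
        regions: Iterable[tuple[str, int, int, str]],
        genes: Optional[Iterable[str]] = None,
    ) -> None:
        per_gene: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for chrom, start, end, gene in regions:
            if end <= start or start < 0:
                raise PanelError(f"malformed interval {chrom}:{start}-{end}")
            per_gene.setdefault((chrom, gene), []).append((int(start), int(end)))

        merged: dict[str, list[tuple[int, int, str]]] = {}
        for (chrom, gene), ivs in per_gene.items():
            ivs.sort()
            out = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged.setdefault(chrom, []).extend((s, e, gene) for s, e in out)

        self._regions: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, ivs in merged.items():
            ivs.sort()
            for (s1, e1, g1), (s2, e2, g2) in zip(ivs, ivs[1:]):
                if s2 < e1 and g1 != g2:
                    raise PanelError(
                        f"regions of {g1} and {g2} overlap at {chrom}:{s2}"
                    )
            self._regions[chrom] = ivs
        self._starts = {c: [iv[0] for iv in ivs] for c, ivs in self._regions.items()}

        region_genes = {g for ivs in self._regions.values() for _, _, g in ivs}
        self.genes: frozenset[str] = frozenset(genes) if genes is not None else frozenset(region_genes)

    def __len__(self) -> int:
        return sum(len(v) for v in self._regions.values())

    def regions(self) -> Iterable[tuple[str, int, int, str]]:
        for chrom in sorted(self._regions):
            for s, e, g in self._regions[chrom]:
                yield chrom, s, e, g

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position in any target region."""
        ivs = self._regions.get(chrom)
        if not ivs:
            return False
        i = bisect.bisect_right(self._starts[chrom], pos0) - 1
        if i < 0:
            return False
        s, e, _ = ivs[i]
        return s <= pos0 < e

    def gene_at(self, chrom: str, pos0: int) -> Optional[str]:
        ivs = self._regions.get(chrom)
        if not ivs:
            return None
        i = bisect.bisect_right(self._starts[chrom], pos0) - 1
        if i >= 0:
            s, e, g = ivs[i]
            if s <= pos0 < e:
                return g
        return None


def is_lof(annotation: FunctionalAnnotation) -> bool:
    """True iff the consequence is one of the four loss-of-function classes.

    Stop loss is protein-affecting but deliberately *not* LoF.
    """
    return annotation.consequence in LOF_CONSEQUENCES


def in_panel(variant: VariantRecord, panel: PanelDefinition) -> bool:
    """True iff the variant's (1-based) position falls in a target region."""
    return panel.contains(variant.chrom, variant.pos - 1)
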