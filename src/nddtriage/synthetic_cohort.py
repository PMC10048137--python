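"""Synthetic cohort generator with known truth labels.

Produces everything the triage CLIs consume — variant table, two CNV call
tables, a population SV table, a patient HPO table and a virtual panel —
with planted pathogenic variants that satisfy the candidate definition by
construction, plus a :class:`TruthTable` whose expected statuses are
computed by a *straight-line restatement* of the filter rules (deliberately
independent of :mod:`nddtriage.snv_triage`), so pipeline output can be
checked against it.

All annotation generators are finite discrete distributions, which keeps
:func:`expected_counts` exact: the analytic expectations are obtained by
enumerating the joint support and integrating the filter rules against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binom

from .cnv_triage import Caller, CnvCall, CnvType, PopulationSv
from .hpo_phenotype import (
    AUTISM_CODES,
    CATEGORIES,
    ID_GDD_CODES,
    CategoryMap,
    DEFAULT_CATEGORY_MAP,
)
from .variant_model import (
    ClinvarStatus,
    Consequence,
    FunctionalAnnotation,
    GenotypeEvidence,
    PanelDefinition,
    PopulationEvidence,
    PREDICTORS,
    SPLICE_TOOLS,
    VariantRecord,
)

__all__ = [
    "Discrete",
    "SimConfig",
    "TruthTable",
    "CohortBundle",
    "ExpectedCounts",
    "generate",
    "expected_counts",
]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class Discrete:
    """A finite weighted distribution (values may include None)."""

    values: tuple
    probs: tuple

    def __post_init__(self) -> None:
        if len(self.values) != len(self.probs):
            raise ValueError("values/probs length mismatch")
        if any(p < 0 for p in self.probs):
            raise ValueError("negative probability")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    def sample(self, rng: np.random.Generator):
        i = rng.choice(len(self.values), p=np.asarray(self.probs, dtype=float))
        return self.values[int(i)]

    def items(self):
        return zip(self.values, self.probs)


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 50
    male_fraction: float = 0.62
    asd_fraction: float = 0.19
    #: Poisson mean of background variants per sample
    background_mean: float = 8.0
    #: probability a patient carries one planted candidate-defining variant
    planted_prob: float = 0.3
    #: probability of a planted mosaic variant (VAF 0.10-0.25, depth >= 50)
    mosaic_prob: float = 0.0
    #: number of samples sharing one gnomAD-absent site (artifact scenario)
    artifact_carriers: int = 0
    in_panel_prob: float = 0.9
    depth_dist: Discrete = Discrete((5, 30, 80, 150), (0.10, 0.30, 0.30, 0.30))
    vaf_dist: Discrete = Discrete(
        (0.05, 0.15, 0.22, 0.35, 0.50, 1.00),
        (0.10, 0.10, 0.15, 0.20, 0.35, 0.10),
    )
    ac_dist: Discrete = Discrete((None, 0, 2, 6, 20), (0.30, 0.05, 0.20, 0.20, 0.25))
    consequence_dist: Discrete = Discrete(
        (
            Consequence.STOP_GAIN,
            Consequence.FRAMESHIFT,
            Consequence.MISSENSE,
            Consequence.INFRAME_INDEL,
            Consequence.SYNONYMOUS,
            Consequence.INTRONIC,
        ),
        (0.08, 0.07, 0.40, 0.05, 0.25, 0.15),
    )
    clinvar_dist: Discrete = Discrete(
        (
            ClinvarStatus.ABSENT,
            ClinvarStatus.OTHER,
            ClinvarStatus.PATHOGENIC,
            ClinvarStatus.LIKELY_PATHOGENIC,
        ),
        (0.70, 0.20, 0.05, 0.05),
    )
    predictor_missing_prob: float = 0.2
    deleterious_prob: float = 0.45
    splice_dist: Discrete = Discrete((None, 0.10, 0.70), (0.30, 0.62, 0.08))
    provean_dist: Discrete = Discrete((None, -3.0, -1.0), (0.20, 0.30, 0.50))
    # panel geometry
    n_genes: int = 20
    exons_per_gene: int = 5
    exon_len: int = 150
    pad: int = 20
    # CNV layer
    cnv_background_mean: float = 1.0
    cnv_plant_prob: float = 0.2
    # HPO layer: per-category affected probabilities
    category_base_prob: float = 0.25
    category_diag_boost: float = 0.0
    seed: int = 0

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class TruthTable:
    """Expected outcomes computed independently of the pipeline."""

    #: index-aligned with CohortBundle.variants
    statuses_primary: list[str]
    statuses_reanalysis: list[str]
    #: site keys expected to be artifact-flagged in re-analysis mode
    artifact_sites: set
    #: patient_id -> site key of the planted candidate variant
    planted: dict
    #: patient_id -> site key of the planted mosaic variant
    planted_mosaic: dict
    #: patient_id -> (chrom, start, end, type) of the planted CNV
    planted_cnv: dict
    diagnosed: dict


@dataclass
class CohortBundle:
    config: SimConfig
    panel: PanelDefinition
    variants: list[VariantRecord]
    patients: list[dict]
    category_map: CategoryMap
    cnv_a: list[CnvCall]
    cnv_b: list[CnvCall]
    popsv: list[PopulationSv]
    truth: TruthTable


# --- panel geometry ---------------------------------------------------------

_GENE_SPACING = 100_000
_EXON_SPACING = 1_000


def _panel_regions(cfg: SimConfig) -> list[tuple[str, int, int, str]]:
    regions = []
    for g in range(cfg.n_genes):
        chrom = f"chr{g % 4 + 1}"
        gene = f"GENE{g + 1:03d}"
        base = 10_000 + (g // 4) * _GENE_SPACING
        for e in range(cfg.exons_per_gene):
            s = base + e * _EXON_SPACING
            regions.append((chrom, s - cfg.pad, s + cfg.exon_len + cfg.pad, gene))
    return regions


# --- straight-line truth restatement ---------------------------------------
# Default-threshold constants are repeated literally on purpose: the truth
# table must not be derived from the objects it validates.


def _truth_in_panel(chrom: str, pos: int, regions: Sequence[tuple]) -> bool:
    p0 = pos - 1
    for c, s, e, _g in regions:
        if c == chrom and s <= p0 < e:
            return True
    return False


def _truth_status(v: VariantRecord, regions: Sequence[tuple], mode: str) -> str:
    if not _truth_in_panel(v.chrom, v.pos, regions):
        return "discarded_panel"
    depth = v.genotype.depth
    vaf = v.genotype.alt_reads / depth if depth else None
    lof = v.annotation.consequence in (
        Consequence.STOP_GAIN,
        Consequence.FRAMESHIFT,
        Consequence.CANONICAL_SPLICE,
        Consequence.START_LOSS,
    )
    if depth == 0 or depth < 10:
        return "discarded_quality"
    if mode == "primary":
        if vaf < 0.30:
            return "discarded_quality"
    else:
        if depth < 50:
            if vaf < (0.20 if lof else 0.25):
                return "discarded_quality"
        elif vaf < 0.10:
            return "discarded_quality"
    if v.population.ac is not None and v.population.ac > 4:
        return "discarded_frequency"
    scores = [s for s in v.annotation.splice_scores.values() if s is not None]
    splice = bool(scores) and max(scores) >= 0.5
    protein = v.annotation.consequence in (
        Consequence.STOP_GAIN,
        Consequence.FRAMESHIFT,
        Consequence.CANONICAL_SPLICE,
        Consequence.START_LOSS,
        Consequence.STOP_LOSS,
        Consequence.INFRAME_INDEL,
        Consequence.MISSENSE,
    )
    if not (protein or splice):
        return "discarded_consequence"
    calls = [c for c in v.annotation.predictor_calls.values() if c in ("D", "T")]
    majority = bool(calls) and sum(c == "D" for c in calls) / len(calls) >= 0.5
    strong = (
        lof
        or (
            v.annotation.consequence == Consequence.INFRAME_INDEL
            and v.annotation.provean is not None
            and v.annotation.provean <= -2.5
        )
        or (v.annotation.consequence == Consequence.MISSENSE and majority)
        or splice
    )
    clinvar_plp = v.annotation.clinvar in (
        ClinvarStatus.PATHOGENIC,
        ClinvarStatus.LIKELY_PATHOGENIC,
    )
    absent = v.population.ac is None or v.population.ac == 0
    if clinvar_plp or absent or strong:
        return "candidate"
    return "retained"


# --- generation -------------------------------------------------------------


def _alt_reads(vaf: float, depth: int) -> int:
    return min(depth, int(math.floor(vaf * depth + 0.5)))


def _draw_predictors(rng: np.random.Generator, cfg: SimConfig) -> dict:
    u = rng.random(len(PREDICTORS))
    v = rng.random(len(PREDICTORS))
    calls = {}
    for name, mu, dv in zip(PREDICTORS, u, v):
        if mu < cfg.predictor_missing_prob:
            continue
        calls[name] = "D" if dv < cfg.deleterious_prob else "T"
    return calls


def generate(config: SimConfig, seed: Optional[int] = None) -> CohortBundle:
    """Generate a full cohort bundle, deterministic given the seed."""
    cfg = config if seed is None else config.replace(seed=seed)
    if cfg.planted_prob > 0 and cfg.background_mean < 0:
        raise ValueError("infeasible config")
    if cfg.n_patients < 1:
        raise ValueError("need at least one patient")
    rng = np.random.default_rng(cfg.seed)
    regions = _panel_regions(cfg)
    panel = PanelDefinition(regions)
    region_list = list(regions)

    # synthetic HPO codes, one per category, alongside the literal subset codes
    synth_codes = {f"HP:99000{k:02d}": cat for k, cat in enumerate(CATEGORIES)}
    category_map = CategoryMap({**DEFAULT_CATEGORY_MAP, **synth_codes})
    code_of_category = {cat: code for code, cat in synth_codes.items()}
    autism_codes = sorted(AUTISM_CODES)
    id_codes = sorted(ID_GDD_CODES)

    variants: list[VariantRecord] = []
    patients: list[dict] = []
    planted: dict = {}
    planted_mosaic: dict = {}
    planted_cnv: dict = {}
    diagnosed: dict = {}
    cnv_a: list[CnvCall] = []
    cnv_b: list[CnvCall] = []

    # population SV resource: common records in a dedicated band of chr9,
    # plus rare records that must never cause a discard
    popsv = [
        PopulationSv("chr9", 1_000_000, 1_050_000, CnvType.DEL, ac=50, af=0.01, source="DGV"),
        PopulationSv("chr9", 2_000_000, 2_040_000, CnvType.DUP, af=0.02, source="gnomAD_SV"),
        PopulationSv("chr9", 3_000_000, 3_030_000, CnvType.DEL, ac=2, af=1e-6, source="DGV"),
    ]

    used_sites_per_sample: dict[str, set] = {}

    def draw_site(sample_id: str, in_panel_flag: bool) -> tuple[str, int, str, str, str]:
        used = used_sites_per_sample.setdefault(sample_id, set())
        for _ in range(100):
            if in_panel_flag:
                c, s, e, g = region_list[int(rng.integers(len(region_list)))]
                pos = int(rng.integers(s, e)) + 1
            else:
                c = f"chr{int(rng.integers(4)) + 1}"
                pos = int(rng.integers(5_000_000, 6_000_000)) + 1
                g = "OFFPANEL"
            ref = _BASES[int(rng.integers(4))]
            alt = _BASES[int(rng.integers(4))]
            if alt == ref:
                alt = _BASES[(_BASES.index(ref) + 1) % 4]
            if (c, pos, ref, alt) not in used:
                used.add((c, pos, ref, alt))
                return c, pos, ref, alt, g
        raise RuntimeError("could not draw a unique site")

    # shared artifact site: gnomAD-absent, carried by the first k samples
    artifact_region = region_list[0]
    artifact_site = (artifact_region[0], artifact_region[1] + 5 + 1, "G", "C")

    n_regions = len(region_list)
    plant_slot = 0

    for i in range(cfg.n_patients):
        pid = f"P{i + 1:04d}"
        sex = "M" if rng.random() < cfg.male_fraction else "F"
        is_asd = rng.random() < cfg.asd_fraction
        has_plant = rng.random() < cfg.planted_prob
        has_mosaic = rng.random() < cfg.mosaic_prob
        diagnosed[pid] = bool(has_plant)

        # HPO terms
        terms: set[str] = set()
        if is_asd:
            terms.update(rng.choice(autism_codes, size=int(rng.integers(1, 3)), replace=False))
        else:
            terms.update(rng.choice(id_codes, size=int(rng.integers(1, 3)), replace=False))
            if rng.random() < 0.3:
                terms.add(autism_codes[int(rng.integers(len(autism_codes)))])
        p_cat = cfg.category_base_prob + (cfg.category_diag_boost if has_plant else 0.0)
        for cat in CATEGORIES:
            if rng.random() < p_cat:
                terms.add(code_of_category[cat])
        patients.append({"patient_id": pid, "sex": sex, "hpo_terms": sorted(terms)})

        # background variants
        n_bg = int(rng.poisson(cfg.background_mean))
        for _ in range(n_bg):
            in_p = rng.random() < cfg.in_panel_prob
            chrom, pos, ref, alt, gene = draw_site(pid, in_p)
            depth = cfg.depth_dist.sample(rng)
            vaf = cfg.vaf_dist.sample(rng)
            alt_reads = _alt_reads(vaf, depth)
            actual_vaf = alt_reads / depth if depth else 0.0
            ac = cfg.ac_dist.sample(rng)
            pop = PopulationEvidence(
                ac=ac,
                af=None if ac is None else ac / 141_456,
                hom=None if ac is None else 0,
            )
            ann = FunctionalAnnotation(
                consequence=cfg.consequence_dist.sample(rng),
                clinvar=cfg.clinvar_dist.sample(rng),
                predictor_calls=_draw_predictors(rng, cfg),
                provean=cfg.provean_dist.sample(rng),
                splice_scores={
                    t: s
                    for t in SPLICE_TOOLS
                    if (s := cfg.splice_dist.sample(rng)) is not None
                },
            )
            variants.append(
                VariantRecord(
                    sample_id=pid,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    genotype=GenotypeEvidence(
                        depth=depth,
                        alt_reads=alt_reads,
                        zygosity="hom" if actual_vaf > 0.85 else "het",
                    ),
                    population=pop,
                    annotation=ann,
                )
            )

        def _plant_site() -> tuple[str, int, str, str, str]:
            nonlocal plant_slot
            c, s, e, g = region_list[plant_slot % n_regions]
            offset = 30 + (plant_slot // n_regions) % (e - s - 30)
            plant_slot += 1
            return c, s + offset + 1, "A", "G", g

        if has_plant:
            chrom, pos, ref, alt, gene = _plant_site()
            depth = int(rng.choice([100, 150, 200]))
            vaf = float(rng.choice([0.45, 0.50]))
            alt_reads = _alt_reads(vaf, depth)
            variants.append(
                VariantRecord(
                    sample_id=pid,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    genotype=GenotypeEvidence(depth, alt_reads, "het"),
                    population=PopulationEvidence(),  # gnomAD-absent
                    annotation=FunctionalAnnotation(
                        consequence=Consequence(
                            rng.choice([Consequence.STOP_GAIN.value, Consequence.FRAMESHIFT.value])
                        ),
                        clinvar=ClinvarStatus.ABSENT,
                    ),
                )
            )
            planted[pid] = (chrom, pos, ref, alt)

        if has_mosaic:
            chrom, pos, ref, alt, gene = _plant_site()
            depth = int(rng.choice([80, 120, 200]))
            vaf = float(rng.choice([0.12, 0.18, 0.22]))
            alt_reads = _alt_reads(vaf, depth)
            variants.append(
                VariantRecord(
                    sample_id=pid,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    genotype=GenotypeEvidence(depth, alt_reads, "het"),
                    population=PopulationEvidence(),
                    annotation=FunctionalAnnotation(consequence=Consequence.STOP_GAIN),
                )
            )
            planted_mosaic[pid] = (chrom, pos, ref, alt)

        if i < cfg.artifact_carriers:
            chrom, pos, ref, alt = artifact_site
            variants.append(
                VariantRecord(
                    sample_id=pid,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=artifact_region[3],
                    genotype=GenotypeEvidence(100, 50, "het"),
                    population=PopulationEvidence(),
                    annotation=FunctionalAnnotation(
                        consequence=Consequence.MISSENSE,
                        predictor_calls={p: "D" for p in PREDICTORS},
                    ),
                )
            )

        # CNV layer -----------------------------------------------------
        if rng.random() < cfg.cnv_plant_prob:
            # distinct reserved slot per patient on chr8; dual-caller,
            # high quality, far from the popsv common band
            base = 1_000_000 + i * 200_000
            length = int(rng.integers(20_000, 40_000))
            ctype = CnvType.DEL if rng.random() < 0.5 else CnvType.DUP
            jitter = int(0.05 * length)
            cnv_a.append(CnvCall(pid, "chr8", base, base + length, ctype, Caller.A, float(rng.integers(35, 70))))
            cnv_b.append(
                CnvCall(pid, "chr8", base + jitter, base + length + jitter, ctype, Caller.B, float(rng.integers(22, 40)))
            )
            planted_cnv[pid] = ("chr8", base, base + length + jitter, ctype.value)

        n_cnv_bg = int(rng.poisson(cfg.cnv_background_mean))
        for _ in range(n_cnv_bg):
            kind = rng.random()
            if kind < 0.35:
                # single caller A, low quality -> concordance discard
                s = int(rng.integers(10_000_000, 20_000_000))
                cnv_a.append(CnvCall(pid, "chr7", s, s + int(rng.integers(5_000, 20_000)), CnvType.DEL, Caller.A, float(rng.integers(0, 20))))
            elif kind < 0.6:
                # overlaps the common DGV deletion (RO ~1) -> population discard
                cnv_b.append(CnvCall(pid, "chr9", 1_000_500, 1_049_500, CnvType.DEL, Caller.B, float(rng.integers(5, 30))))
            elif kind < 0.8:
                # single caller, adequate quality -> retained
                s = int(rng.integers(30_000_000, 40_000_000))
                cnv_a.append(CnvCall(pid, "chr7", s, s + int(rng.integers(5_000, 20_000)), CnvType.DUP, Caller.A, float(rng.integers(20, 29))))
            else:
                # recurrent interval shared across samples -> recurrence discard
                cnv_a.append(CnvCall(pid, "chr6", 5_000_000, 5_050_000, CnvType.DUP, Caller.A, float(rng.integers(30, 60))))

    truth = TruthTable(
        statuses_primary=[_truth_status(v, region_list, "primary") for v in variants],
        statuses_reanalysis=[_truth_status(v, region_list, "reanalysis") for v in variants],
        artifact_sites=_truth_artifact_sites(variants),
        planted=planted,
        planted_mosaic=planted_mosaic,
        planted_cnv=planted_cnv,
        diagnosed=diagnosed,
    )
    return CohortBundle(
        config=cfg,
        panel=panel,
        variants=variants,
        patients=[
            {**p, "diagnosed": diagnosed[p["patient_id"]]} for p in patients
        ],
        category_map=category_map,
        cnv_a=cnv_a,
        cnv_b=cnv_b,
        popsv=popsv,
        truth=truth,
    )


def _truth_artifact_sites(variants: Sequence[VariantRecord]) -> set:
    carriers: dict = {}
    for v in variants:
        if v.population.ac is None or v.population.ac == 0:
            carriers.setdefault(v.site_key, set()).add(v.sample_id)
    return {k for k, s in carriers.items() if len(s) >= 4}


# --- analytic expectations --------------------------------------------------


@dataclass(frozen=True)
class ExpectedCounts:
    mean_total_per_sample: float
    mean_kept_per_sample: float
    mean_candidates_per_sample: float
    eliminated_fraction: float


def _p_majority(cfg: SimConfig) -> float:
    """P(deleterious majority) for iid predictor calls over the 36 tools."""
    n = len(PREDICTORS)
    p_avail = 1.0 - cfg.predictor_missing_prob
    total = 0.0
    for a in range(1, n + 1):
        pa = binom.pmf(a, n, p_avail)
        need = math.ceil(a / 2)
        total += pa * binom.sf(need - 1, a, cfg.deleterious_prob)
    return float(total)


def _p_splice(cfg: SimConfig) -> float:
    p_hit = sum(p for v, p in cfg.splice_dist.items() if v is not None and v >= 0.5)
    return 1.0 - (1.0 - p_hit) ** len(SPLICE_TOOLS)


def expected_counts(config: SimConfig, mode: str = "primary") -> ExpectedCounts:
    """Exact per-sample expectations under the generator distributions.

    Obtained by enumerating the joint discrete support of the background
    annotation generators and applying the filter rules to each atom,
    including the deterministic read-count rounding the generator applies.
    """
    cfg = config
    p_spl = _p_splice(cfg)
    p_maj = _p_majority(cfg)
    lof_set = {Consequence.STOP_GAIN, Consequence.FRAMESHIFT,
               Consequence.CANONICAL_SPLICE, Consequence.START_LOSS}
    protein_set = lof_set | {Consequence.STOP_LOSS, Consequence.INFRAME_INDEL,
                             Consequence.MISSENSE}

    p_kept_bg = 0.0
    p_cand_bg = 0.0
    for depth, p_d in cfg.depth_dist.items():
        for vaf, p_v in cfg.vaf_dist.items():
            alt = _alt_reads(vaf, depth)
            a_vaf = alt / depth if depth else 0.0
            for cons, p_c in cfg.consequence_dist.items():
                lof = cons in lof_set
                # quality rule
                if depth < 10:
                    continue
                if mode == "primary":
                    if a_vaf < 0.30:
                        continue
                else:
                    if depth < 50:
                        if a_vaf < (0.20 if lof else 0.25):
                            continue
                    elif a_vaf < 0.10:
                        continue
                for ac, p_a in cfg.ac_dist.items():
                    if ac is not None and ac > 4:
                        continue
                    absent = ac is None or ac == 0
                    for clin, p_cl in cfg.clinvar_dist.items():
                        plp = clin in (ClinvarStatus.PATHOGENIC,
                                       ClinvarStatus.LIKELY_PATHOGENIC)
                        for prov, p_p in cfg.provean_dist.items():
                            base = p_d * p_v * p_c * p_a * p_cl * p_p
                            for splice, p_s in ((True, p_spl), (False, 1 - p_spl)):
                                if not (cons in protein_set or splice):
                                    continue
                                for major, p_m in ((True, p_maj), (False, 1 - p_maj)):
                                    w = base * p_s * p_m
                                    strong = (
                                        lof
                                        or (cons == Consequence.INFRAME_INDEL
                                            and prov is not None and prov <= -2.5)
                                        or (cons == Consequence.MISSENSE and major)
                                        or splice
                                    )
                                    p_kept_bg += w
                                    if plp or absent or strong:
                                        p_cand_bg += w

    p_kept_bg *= cfg.in_panel_prob
    p_cand_bg *= cfg.in_panel_prob

    mosaic_kept = cfg.mosaic_prob if mode == "reanalysis" else 0.0
    mean_total = cfg.background_mean + cfg.planted_prob + cfg.mosaic_prob
    mean_kept = cfg.background_mean * p_kept_bg + cfg.planted_prob + mosaic_kept
    mean_cand = cfg.background_mean * p_cand_bg + cfg.planted_prob + mosaic_kept
    eliminated = 1.0 - mean_kept / mean_total if mean_total > 0 else 0.0
    return ExpectedCounts(mean_total, mean_kept, mean_cand, eliminated)
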