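"""Readers/writers for the flat-table, VCF, BED and caller-specific formats.

The flat variant TSV carries one row per (sample, variant) with a named
column per field; predictor calls occupy one ``pred_<NAME>`` column each
("D"/"T"/empty).  VCF input is read through cyvcf2 with a configurable
mapping from annotation fields to INFO keys, because annotation dialects
vary between pipelines.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cnv_triage import (
    Caller,
    CnvCall,
    CnvDecision,
    CnvType,
    PopulationSv,
)
from .hpo_phenotype import CategoryMap, PatientPhenotype, Sex, build_phenotype
from .variant_model import (
    ClinvarStatus,
    Consequence,
    FunctionalAnnotation,
    GenotypeEvidence,
    PanelDefinition,
    PopulationEvidence,
    PREDICTORS,
    SPLICE_TOOLS,
    TriageDecision,
    VariantRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_variants_tsv",
    "write_variants_tsv",
    "read_variants_vcf",
    "DEFAULT_VCF_MAPPING",
    "read_panel_bed",
    "read_gene_list",
    "read_xhmm_calls",
    "read_exomedepth_calls",
    "read_popsv_table",
    "read_patients_tsv",
    "write_patients_tsv",
    "read_category_map",
    "write_decisions_tsv",
    "read_decisions_tsv",
    "write_summary_json",
    "coverage_summary",
    "CoverageSummary",
]

_CORE_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "depth",
    "alt_reads",
    "zygosity",
    "gnomad_ac",
    "gnomad_af",
    "gnomad_hom",
    "consequence",
    "clinvar",
    "provean",
]
_SPLICE_COLUMNS = [f"splice_{t}" for t in SPLICE_TOOLS]
_PRED_COLUMNS = [f"pred_{p}" for p in PREDICTORS]
VARIANT_COLUMNS = _CORE_COLUMNS + _SPLICE_COLUMNS + _PRED_COLUMNS


def _opt_int(x) -> Optional[int]:
    if x is None or (isinstance(x, float) and np.isnan(x)) or x == "":
        return None
    return int(x)


def _opt_float(x) -> Optional[float]:
    if x is None or x == "":
        return None
    x = float(x)
    return None if np.isnan(x) else x


def _record_from_row(row: Mapping) -> VariantRecord:
    preds = {}
    for p in PREDICTORS:
        v = row.get(f"pred_{p}")
        if isinstance(v, str) and v in ("D", "T"):
            preds[p] = v
    splice = {}
    for t in SPLICE_TOOLS:
        v = _opt_float(row.get(f"splice_{t}"))
        if v is not None:
            splice[t] = v
    zyg = row.get("zygosity")
    if not isinstance(zyg, str) or zyg == "":
        zyg = None
    return VariantRecord(
        sample_id=str(row["sample_id"]),
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        gene=str(row["gene"]),
        genotype=GenotypeEvidence(int(row["depth"]), int(row["alt_reads"]), zyg),
        population=PopulationEvidence(
            ac=_opt_int(row.get("gnomad_ac")),
            af=_opt_float(row.get("gnomad_af")),
            hom=_opt_int(row.get("gnomad_hom")),
        ),
        annotation=FunctionalAnnotation(
            consequence=Consequence(row["consequence"]),
            clinvar=ClinvarStatus(row.get("clinvar") or "absent"),
            predictor_calls=preds,
            provean=_opt_float(row.get("provean")),
            splice_scores=splice,
        ),
    )


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Read the flat variant table; invalid rows are dropped with a log entry."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "ref": str, "alt": str},
        float_precision="round_trip",
    )
    missing = [c for c in _CORE_COLUMNS if c not in df.columns and c not in
               ("zygosity", "gnomad_ac", "gnomad_af", "gnomad_hom", "provean", "clinvar")]
    if missing:
        raise ValueError(f"variant table is missing mandatory columns: {missing}")
    records: list[VariantRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            records.append(_record_from_row(row))
        except (ValueError, KeyError) as exc:
            logger.warning("rejected variant row %d: %s", i, exc)
    return records


def write_variants_tsv(variants: Sequence[VariantRecord], path: str | Path) -> None:
    rows = []
    for v in variants:
        row = {
            "sample_id": v.sample_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "depth": v.genotype.depth,
            "alt_reads": v.genotype.alt_reads,
            "zygosity": v.genotype.zygosity or "",
            "gnomad_ac": "" if v.population.ac is None else v.population.ac,
            "gnomad_af": "" if v.population.af is None else repr(v.population.af),
            "gnomad_hom": "" if v.population.hom is None else v.population.hom,
            "consequence": v.annotation.consequence.value,
            "clinvar": v.annotation.clinvar.value,
            "provean": "" if v.annotation.provean is None else repr(v.annotation.provean),
        }
        for t in SPLICE_TOOLS:
            s = v.annotation.splice_scores.get(t)
            row[f"splice_{t}"] = "" if s is None else repr(s)
        for p in PREDICTORS:
            row[f"pred_{p}"] = v.annotation.predictor_calls.get(p, "") or ""
        rows.append(row)
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


#: Default INFO-key mapping for VCF input; override keys as needed.
DEFAULT_VCF_MAPPING: dict[str, str] = {
    "gene": "GENE",
    "consequence": "CSQ_CLASS",
    "clinvar": "CLNSIG",
    "gnomad_ac": "GNOMAD_AC",
    "gnomad_af": "GNOMAD_AF",
    "gnomad_hom": "GNOMAD_HOM",
    "provean": "PROVEAN_SCORE",
    "splice_squirls": "SQUIRLS",
    "splice_spliceai": "SPLICEAI",
    "splice_ada": "ADA",
    "splice_rf": "RF",
    "predictors": "PRED_CALLS",  # format NAME:D|NAME:T|...
}


def read_variants_vcf(
    path: str | Path,
    mapping: Optional[Mapping[str, str]] = None,
) -> list[VariantRecord]:
    """Read per-sample variants from a VCF via cyvcf2.

    Multi-allelic sites are decomposed to one record per alternate allele.
    Depth/alt reads come from the per-sample FORMAT fields (AD preferred,
    DP as fallback for total depth).
    """
    from cyvcf2 import VCF

    m = dict(DEFAULT_VCF_MAPPING)
    if mapping:
        m.update(mapping)
    records: list[VariantRecord] = []
    vcf = VCF(str(path))
    samples = vcf.samples
    for var in vcf:
        info = dict(var.INFO)
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        for ai, alt in enumerate(var.ALT):
            for si, sample in enumerate(samples):
                if ad is not None:
                    alt_reads = int(ad[si][ai + 1])
                    depth = int(sum(x for x in ad[si] if x >= 0))
                elif dp is not None:
                    depth = int(dp[si][0])
                    alt_reads = depth  # no allele split available
                else:
                    logger.warning("no AD/DP for %s:%s; row rejected", var.CHROM, var.POS)
                    continue
                gts = var.genotypes[si]
                alleles = [g for g in gts[:-1] if g >= 0]
                if alleles and all(a == 0 for a in alleles):
                    continue  # hom-ref in this sample
                zyg = None
                if alleles:
                    zyg = "hom" if all(a == ai + 1 for a in alleles) else "het"
                preds = {}
                raw = info.get(m["predictors"])
                if raw:
                    for item in str(raw).split("|"):
                        if ":" in item:
                            name, call = item.rsplit(":", 1)
                            if call in ("D", "T"):
                                preds[name] = call
                splice = {}
                for t in SPLICE_TOOLS:
                    val = info.get(m[f"splice_{t}"])
                    if val is not None:
                        splice[t] = float(val)
                clin_raw = info.get(m["clinvar"])
                try:
                    clin = ClinvarStatus(str(clin_raw)) if clin_raw else ClinvarStatus.ABSENT
                except ValueError:
                    clin = ClinvarStatus.OTHER
                try:
                    records.append(
                        VariantRecord(
                            sample_id=sample,
                            chrom=var.CHROM,
                            pos=var.POS,
                            ref=var.REF,
                            alt=alt,
                            gene=str(info.get(m["gene"], "")),
                            genotype=GenotypeEvidence(depth, alt_reads, zyg),
                            population=PopulationEvidence(
                                ac=_opt_int(info.get(m["gnomad_ac"])),
                                af=_opt_float(info.get(m["gnomad_af"])),
                                hom=_opt_int(info.get(m["gnomad_hom"])),
                            ),
                            annotation=FunctionalAnnotation(
                                consequence=Consequence(str(info.get(m["consequence"], "other"))),
                                clinvar=clin,
                                predictor_calls=preds,
                                provean=_opt_float(info.get(m["provean"])),
                                splice_scores=splice,
                            ),
                        )
                    )
                except ValueError as exc:
                    logger.warning("rejected %s:%s %s>%s: %s", var.CHROM, var.POS, var.REF, alt, exc)
    return records


def read_panel_bed(path: str | Path, genes_path: Optional[str | Path] = None) -> PanelDefinition:
    """Load target regions from BED (0-based half-open, name column = gene)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED line needs chrom/start/end/gene: {line!r}")
            regions.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    genes = read_gene_list(genes_path) if genes_path else None
    return PanelDefinition(regions, genes)


def write_panel_bed(panel: PanelDefinition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, g in panel.regions():
            fh.write(f"{chrom}\t{s}\t{e}\t{g}\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def read_xhmm_calls(path: str | Path) -> list[CnvCall]:
    """XHMM-like table: sample, interval "chr:start-end" (1-based inclusive),
    type, Q_SOME."""
    df = pd.read_csv(path, sep="\t")
    calls = []
    for i, row in df.iterrows():
        try:
            chrom, rng = str(row["interval"]).split(":")
            s, e = rng.split("-")
            calls.append(
                CnvCall(
                    sample_id=str(row["sample"]),
                    chrom=chrom,
                    start=int(s) - 1,
                    end=int(e),
                    type=CnvType(str(row["type"]).upper()),
                    caller=Caller.A,
                    phred=float(row["Q_SOME"]),
                )
            )
        except (ValueError, KeyError) as exc:
            logger.warning("rejected caller-A row %d: %s", i, exc)
    return calls


def read_exomedepth_calls(path: str | Path) -> list[CnvCall]:
    """ExomeDepth-like table: sample, chrom, start, end (1-based inclusive),
    type, BF (interpreted on the caller-B Phred scale)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    calls = []
    for i, row in df.iterrows():
        try:
            calls.append(
                CnvCall(
                    sample_id=str(row["sample"]),
                    chrom=str(row["chrom"]),
                    start=int(row["start"]) - 1,
                    end=int(row["end"]),
                    type=CnvType(str(row["type"]).upper()),
                    caller=Caller.B,
                    phred=float(row["BF"]),
                )
            )
        except (ValueError, KeyError) as exc:
            logger.warning("rejected caller-B row %d: %s", i, exc)
    return calls


def read_popsv_table(path: str | Path) -> list[PopulationSv]:
    """BED-like population SV table: chrom, start, end, type, ac, af, source."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                PopulationSv(
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    type=CnvType(str(row["type"]).upper()),
                    ac=_opt_int(row.get("ac")),
                    af=_opt_float(row.get("af")),
                    source=str(row.get("source", "DGV")),
                )
            )
        except (ValueError, KeyError) as exc:
            logger.warning("rejected population SV row %d: %s", i, exc)
    return out


def write_cnv_calls(calls_a: Sequence[CnvCall], calls_b: Sequence[CnvCall],
                    path_a: str | Path, path_b: str | Path) -> None:
    rows_a = [
        {
            "sample": c.sample_id,
            "interval": f"{c.chrom}:{c.start + 1}-{c.end}",
            "type": c.type.value,
            "Q_SOME": c.phred,
        }
        for c in calls_a
    ]
    pd.DataFrame(rows_a, columns=["sample", "interval", "type", "Q_SOME"]).to_csv(
        path_a, sep="\t", index=False
    )
    rows_b = [
        {
            "sample": c.sample_id,
            "chrom": c.chrom,
            "start": c.start + 1,
            "end": c.end,
            "type": c.type.value,
            "BF": c.phred,
        }
        for c in calls_b
    ]
    pd.DataFrame(rows_b, columns=["sample", "chrom", "start", "end", "type", "BF"]).to_csv(
        path_b, sep="\t", index=False
    )


def write_popsv_table(popsv: Sequence[PopulationSv], path: str | Path) -> None:
    rows = [
        {
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "type": s.type.value,
            "ac": "" if s.ac is None else s.ac,
            "af": "" if s.af is None else repr(s.af),
            "source": s.source,
        }
        for s in popsv
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "type", "ac", "af", "source"]).to_csv(
        path, sep="\t", index=False
    )


def read_patients_tsv(
    path: str | Path, category_map: Optional[CategoryMap] = None
) -> list[PatientPhenotype]:
    """Patient table: patient_id, sex, hpo (pipe-separated), optional diagnosed."""
    df = pd.read_csv(path, sep="\t")
    patients = []
    for _, row in df.iterrows():
        hpo = str(row.get("hpo", "") or "")
        terms = [t for t in hpo.split("|") if t]
        patients.append(
            build_phenotype(
                patient_id=str(row["patient_id"]),
                sex=Sex(str(row["sex"])),
                hpo_terms=terms,
                diagnosed=bool(row.get("diagnosed", False)),
                category_map=category_map,
            )
        )
    return patients


def write_patients_tsv(patients: Sequence[Mapping], path: str | Path) -> None:
    rows = [
        {
            "patient_id": p["patient_id"],
            "sex": p["sex"],
            "hpo": "|".join(p["hpo_terms"]),
            "diagnosed": int(bool(p.get("diagnosed", False))),
        }
        for p in patients
    ]
    pd.DataFrame(rows, columns=["patient_id", "sex", "hpo", "diagnosed"]).to_csv(
        path, sep="\t", index=False
    )


def read_category_map(path: str | Path) -> CategoryMap:
    df = pd.read_csv(path, sep="\t")
    return CategoryMap(dict(zip(df["code"].astype(str), df["category"].astype(str))))


def write_category_map(cmap: CategoryMap, path: str | Path) -> None:
    pd.DataFrame(sorted(cmap.items()), columns=["code", "category"]).to_csv(
        path, sep="\t", index=False
    )


DECISION_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene",
    "status", "reasons", "artifact_flag",
]


def write_decisions_tsv(
    variants: Sequence[VariantRecord],
    decisions: Sequence[TriageDecision],
    path: str | Path,
) -> None:
    rows = [
        {
            "sample_id": v.sample_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "status": d.status.value,
            "reasons": ";".join(d.reasons),
            "artifact_flag": int(d.artifact_flag),
        }
        for v, d in zip(variants, decisions)
    ]
    pd.DataFrame(rows, columns=DECISION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_decisions_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})


def write_summary_json(summary: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


@dataclass(frozen=True)
class CoverageSummary:
    mean_depth: float
    frac_ge_10: float
    frac_ge_50: float
    zero_coverage_regions: tuple


def coverage_summary(
    depths: pd.DataFrame, panel: PanelDefinition
) -> dict[str, CoverageSummary]:
    """Per-sample coverage QC over panel positions.

    ``depths`` needs columns sample_id, chrom, pos (1-based), depth; only
    positions inside panel regions are considered.  Regions with no covered
    base in a sample are flagged as zero-coverage.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    out: dict[str, CoverageSummary] = {}
    for sample, sub in depths.groupby("sample_id"):
        mask = [
            panel.contains(str(c), int(p) - 1)
            for c, p in zip(sub["chrom"], sub["pos"])
        ]
        sub = sub[np.asarray(mask, dtype=bool)]
        d = sub["depth"].to_numpy(dtype=float)
        if len(d) == 0:
            out[str(sample)] = CoverageSummary(0.0, 0.0, 0.0, tuple(panel.regions()))
            continue
        zero_regions = []
        for chrom, s, e, g in panel.regions():
            in_region = [
                panel.gene_at(str(c), int(p) - 1) == g and s <= int(p) - 1 < e
                for c, p in zip(sub["chrom"], sub["pos"])
            ]
            region_depths = sub[np.asarray(in_region, dtype=bool)]["depth"]
            if len(region_depths) == 0 or (region_depths <= 0).all():
                zero_regions.append((chrom, s, e, g))
        out[str(sample)] = CoverageSummary(
            mean_depth=float(d.mean()),
            frac_ge_10=float((d >= 10).mean()),
            frac_ge_50=float((d >= 50).mean()),
            zero_coverage_regions=tuple(zero_regions),
        )
    return out
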