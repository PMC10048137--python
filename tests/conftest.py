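from __future__ import annotations

import pytest

from nddtriage.variant_model import (
    ClinvarStatus,
    Consequence,
    FilterThresholds,
    FunctionalAnnotation,
    GenotypeEvidence,
    PanelDefinition,
    PopulationEvidence,
    VariantRecord,
)


def make_variant(
    sample_id="S1",
    chrom="chr1",
    pos=1000,
    ref="A",
    alt="T",
    gene="GENE1",
    depth=100,
    alt_reads=50,
    zygosity=None,
    ac=None,
    af=None,
    hom=None,
    consequence=Consequence.MISSENSE,
    clinvar=ClinvarStatus.ABSENT,
    predictor_calls=None,
    provean=None,
    splice_scores=None,
) -> VariantRecord:
    """Convenience constructor with pass-everything defaults."""
    return VariantRecord(
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        genotype=GenotypeEvidence(depth, alt_reads, zygosity),
        population=PopulationEvidence(ac=ac, af=af, hom=hom),
        annotation=FunctionalAnnotation(
            consequence=consequence,
            clinvar=clinvar,
            predictor_calls=predictor_calls or {},
            provean=provean,
            splice_scores=splice_scores or {},
        ),
    )


@pytest.fixture
def thresholds() -> FilterThresholds:
    return FilterThresholds()


@pytest.fixture
def small_panel() -> PanelDefinition:
    # two genes, one exon each, already padded
    return PanelDefinition(
        [
            ("chr1", 980, 1200, "GENE1"),
            ("chr2", 5000, 5300, "GENE2"),
        ]
    )
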