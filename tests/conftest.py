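"""Shared fixtures: tiny hand-built pedigrees and variant tables."""

from __future__ import annotations

import pytest

from osteovar.model import (
    Affection,
    AnnotationProfile,
    ClinvarStatus,
    Consequence,
    MergedVariantTable,
    Pedigree,
    PedigreeMember,
    PredictorCall,
    VariantKey,
    VariantRecord,
    Zygosity,
)

AFFECTED = ("III1", "III4", "III5")
CONTROL = "II10"
OTHERS = ("II1", "III7")
ALL_SAMPLES = AFFECTED + (CONTROL,) + OTHERS


def make_annotation(
    gene="GENE1",
    consequence=Consequence.MISSENSE,
    splice_offset=None,
    aaf=None,
    predictors="DDDDD",
    cadd=25.0,
    gerp=4.0,
    acmg=4,
):
    """Compact annotation builder. ``predictors`` is a 5-char string of
    D/B/U for SIFT, Polyphen2, MutationTaster, MutationAssessor, VEST3;
    ``aaf`` a dict or a single gnomAD value."""
    from osteovar.model import AA_EFFECT_PREDICTORS

    code = {"D": PredictorCall.DELETERIOUS, "B": PredictorCall.BENIGN, "U": PredictorCall.UNKNOWN}
    if aaf is None:
        aaf_by_db = {}
    elif isinstance(aaf, dict):
        aaf_by_db = aaf
    else:
        aaf_by_db = {"gnomad": aaf}
    return AnnotationProfile(
        gene=gene,
        consequence=consequence,
        splice_offset=splice_offset,
        aaf_by_db=aaf_by_db,
        predictor_calls={
            name: code[ch] for name, ch in zip(AA_EFFECT_PREDICTORS, predictors)
        },
        cadd_phred=cadd,
        gerp_rs=gerp,
        acmg_class=acmg,
    )


def make_record(pos, genotype_string="HHH0.00", samples=ALL_SAMPLES, chrom="1",
                ref="A", alt="G", **ann_kwargs):
    """Variant record with genotypes encoded one char per sample:
    H=het, 0=hom_ref, A=hom_alt, .=missing."""
    zmap = {"H": Zygosity.HET, "0": Zygosity.HOM_REF, "A": Zygosity.HOM_ALT, ".": Zygosity.MISSING}
    genotypes = {
        sid: zmap[ch] for sid, ch in zip(samples, genotype_string.ljust(len(samples), "0"))
    }
    return VariantRecord(
        VariantKey(chrom, pos, ref, alt), make_annotation(**ann_kwargs), genotypes
    )


@pytest.fixture
def family_pedigree():
    members = [
        PedigreeMember("III1", "M", "III", Affection.AFFECTED, True),
        PedigreeMember("III4", "M", "III", Affection.AFFECTED, True),
        PedigreeMember("III5", "M", "III", Affection.AFFECTED, True),
        PedigreeMember("II10", "M", "II", Affection.UNAFFECTED, True),
        PedigreeMember("II1", "M", "II", Affection.UNKNOWN, True),
        PedigreeMember("III7", "F", "III", Affection.UNKNOWN, True),
    ]
    return Pedigree(members)


@pytest.fixture
def small_table():
    """Five variants, four samples (trio + control)."""
    samples = AFFECTED + (CONTROL,)
    records = [
        make_record(100, "HHH0", samples, gene="G1"),
        make_record(200, "HHHH", samples, gene="G2"),
        make_record(300, "0HH0", samples, gene="G3"),
        make_record(400, "HHH0", samples, gene="G4", consequence=Consequence.SYNONYMOUS),
        make_record(500, "AAA0", samples, gene="G5"),
    ]
    return MergedVariantTable(samples, records)
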