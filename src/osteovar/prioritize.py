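"""Sequential variant prioritization for a dominantly-inherited bone phenotype.

Six deterministic filter stages, applied in a fixed order to a merged
multi-sample variant table:

1. **Segregation** — keep variants heterozygous in every affected relative
   and absent (neither het nor hom-alt) in every unaffected control.
2. **Consequence** — keep protein-impacting classes: missense, splice
   acceptor/donor within a window into the intron, start loss, stop
   gain/loss, frameshift and inframe indels.
3. **Rarity** — keep variants with alternative allele frequency <= 1% in
   every population database reporting them.
4. **Deleteriousness** — keep missense variants called deleterious by a
   majority of the amino-acid-effect predictors, with scaled CADD above
   threshold, ACMG/AMP class >= likely-pathogenic, and conserved by GERP.
   Non-missense consequences pass through this stage unexamined.
5. **Blacklist** — drop documented false positives ("frequent hitters"),
   by gene symbol or exact variant key.
6. **Gene panel** — keep genes with a plausible role in bone biology.

Each stage is idempotent and never adds records; the runner emits a
:class:`~osteovar.model.FilterTrace` of per-stage SNV and indel counts.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Callable

from .model import (
    AA_EFFECT_PREDICTORS,
    Consequence,
    FilterTrace,
    MergedVariantTable,
    Pedigree,
    PredictorCall,
    VariantKey,
    VariantRecord,
    Zygosity,
)

log = logging.getLogger(__name__)

#: consequence classes retained by the consequence filter (splice classes
#: additionally require |splice_offset| <= splice_window)
RETAINED_CONSEQUENCES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.SPLICE_ACCEPTOR,
        Consequence.SPLICE_DONOR,
        Consequence.START_LOSS,
        Consequence.STOP_GAIN,
        Consequence.STOP_LOSS,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
    }
)

#: canonical stage names, in application order (the trace prepends "input")
STAGE_NAMES = (
    "segregation",
    "consequence",
    "rarity",
    "deleteriousness",
    "blacklist",
    "gene_panel",
)


class InheritanceModel(enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


class MissingAafPolicy(enum.Enum):
    TREAT_AS_RARE = "treat_as_rare"
    DROP = "drop"


class MissingGenotypePolicy(enum.Enum):
    FAIL_SEGREGATION = "fail_segregation"
    IGNORE_SAMPLE = "ignore_sample"


@dataclass
class FilterConfig:
    """Thresholds and policies for the six filter stages.

    Defaults reproduce the published pipeline: AAF <= 1% in all databases,
    scaled CADD > 15, ACMG class >= 4 (likely pathogenic), GERP >= 2.0,
    splice window of 10 nt into the intron, strict majority of the five
    amino-acid-effect predictors.
    """

    model: InheritanceModel = InheritanceModel.DOMINANT
    affected_ids: frozenset[str] = frozenset()
    unaffected_ids: frozenset[str] = frozenset()
    aaf_threshold: float = 0.01
    cadd_threshold: float = 15.0
    min_acmg: int = 4
    gerp_threshold: float = 2.0
    splice_window: int = 10
    blacklist: frozenset[str | VariantKey] = frozenset()
    gene_panel: frozenset[str] = frozenset()
    missing_aaf_policy: MissingAafPolicy = MissingAafPolicy.TREAT_AS_RARE
    missing_genotype_policy: MissingGenotypePolicy = (
        MissingGenotypePolicy.FAIL_SEGREGATION
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.aaf_threshold <= 1.0:
            raise ValueError("aaf_threshold must be in (0, 1]")
        if self.splice_window < 0:
            raise ValueError("splice_window must be >= 0")
        self.affected_ids = frozenset(self.affected_ids)
        self.unaffected_ids = frozenset(self.unaffected_ids)
        self.blacklist = frozenset(self.blacklist)
        self.gene_panel = frozenset(self.gene_panel)

    @classmethod
    def from_pedigree(cls, pedigree: Pedigree, **overrides) -> "FilterConfig":
        """Config with affected/unaffected sets taken from the sequenced
        pedigree members."""
        return cls(
            affected_ids=frozenset(pedigree.affected_sequenced()),
            unaffected_ids=frozenset(pedigree.unaffected_sequenced()),
            **overrides,
        )


def _filter(table: MergedVariantTable, keep: Callable[[VariantRecord], bool]) -> MergedVariantTable:
    return table.subset(rec for rec in table if keep(rec))


# ---------------------------------------------------------------------------
# stage predicates

def segregates(rec: VariantRecord, config: FilterConfig) -> bool:
    """Dominant-model segregation predicate for one record."""
    if config.model is not InheritanceModel.DOMINANT:
        raise NotImplementedError("only the dominant model is implemented")
    for sid in config.affected_ids:
        zyg = rec.genotypes[sid]
        if zyg is Zygosity.MISSING:
            if config.missing_genotype_policy is MissingGenotypePolicy.IGNORE_SAMPLE:
                continue
            return False
        if zyg is not Zygosity.HET:
            return False
    for sid in config.unaffected_ids:
        zyg = rec.genotypes[sid]
        if zyg is Zygosity.MISSING:
            continue  # absence of evidence never excludes on the control side
        if zyg.is_carrier:
            return False
    return True


def consequence_retained(rec: VariantRecord, config: FilterConfig) -> bool:
    ann = rec.annotation
    if ann.consequence not in RETAINED_CONSEQUENCES:
        return False
    if ann.consequence in (Consequence.SPLICE_ACCEPTOR, Consequence.SPLICE_DONOR):
        if ann.splice_offset is None:
            return False
        return abs(ann.splice_offset) <= config.splice_window
    return True


def is_rare(rec: VariantRecord, config: FilterConfig) -> bool:
    aafs = rec.annotation.aaf_by_db
    if not aafs:
        return config.missing_aaf_policy is MissingAafPolicy.TREAT_AS_RARE
    return max(aafs.values()) <= config.aaf_threshold


def predictor_majority_deleterious(rec: VariantRecord) -> bool:
    """Strict majority of non-unknown calls among the amino-acid-effect
    predictors; no informative call at all fails the rule."""
    calls = [
        rec.annotation.predictor_calls.get(name, PredictorCall.UNKNOWN)
        for name in AA_EFFECT_PREDICTORS
    ]
    informative = [c for c in calls if c is not PredictorCall.UNKNOWN]
    if not informative:
        return False
    n_del = sum(1 for c in informative if c is PredictorCall.DELETERIOUS)
    return n_del * 2 > len(informative)


def is_deleterious(rec: VariantRecord, config: FilterConfig) -> bool:
    """Conjunction of predictor majority, CADD, ACMG and conservation for
    missense records; other retained consequence classes pass through."""
    ann = rec.annotation
    if ann.consequence is not Consequence.MISSENSE:
        return True
    return (
        predictor_majority_deleterious(rec)
        and ann.cadd_phred > config.cadd_threshold
        and ann.acmg_class >= config.min_acmg
        and ann.gerp_rs >= config.gerp_threshold
    )


def in_blacklist(rec: VariantRecord, config: FilterConfig) -> bool:
    return rec.annotation.gene in config.blacklist or rec.key in config.blacklist


def in_gene_panel(rec: VariantRecord, config: FilterConfig) -> bool:
    return rec.annotation.gene in config.gene_panel


# ---------------------------------------------------------------------------
# stage operations

def filter_segregation(
    table: MergedVariantTable, pedigree: Pedigree, config: FilterConfig
) -> MergedVariantTable:
    """Retain variants compatible with dominant inheritance: heterozygous in
    all affected relatives, non-carrier in every unaffected control."""
    if not config.affected_ids:
        raise ValueError("no affected relatives configured: no segregation signal")
    known = set(table.sample_ids)
    for sid in config.affected_ids | config.unaffected_ids:
        if sid not in known:
            raise ValueError(f"pedigree member {sid!r} not in variant table samples")
        if sid not in {m.member_id for m in pedigree}:
            raise ValueError(f"sample {sid!r} not in pedigree")
    return _filter(table, lambda rec: segregates(rec, config))


def filter_consequence(table: MergedVariantTable, config: FilterConfig) -> MergedVariantTable:
    return _filter(table, lambda rec: consequence_retained(rec, config))


def filter_rarity(table: MergedVariantTable, config: FilterConfig) -> MergedVariantTable:
    return _filter(table, lambda rec: is_rare(rec, config))


def filter_deleteriousness(table: MergedVariantTable, config: FilterConfig) -> MergedVariantTable:
    return _filter(table, lambda rec: is_deleterious(rec, config))


def filter_blacklist(table: MergedVariantTable, config: FilterConfig) -> MergedVariantTable:
    return _filter(table, lambda rec: not in_blacklist(rec, config))


def filter_gene_panel(table: MergedVariantTable, config: FilterConfig) -> MergedVariantTable:
    return _filter(table, lambda rec: in_gene_panel(rec, config))


_STAGES: tuple[tuple[str, Callable], ...] = (
    ("consequence", filter_consequence),
    ("rarity", filter_rarity),
    ("deleteriousness", filter_deleteriousness),
    ("blacklist", filter_blacklist),
    ("gene_panel", filter_gene_panel),
)


def run_prioritization(
    table: MergedVariantTable, pedigree: Pedigree, config: FilterConfig
) -> tuple[MergedVariantTable, FilterTrace]:
    """Apply the six stages in order; return the shortlist and the trace.

    The trace starts with an ``input`` row, then one row per stage; SNV and
    indel counts are tracked separately and are non-increasing.
    """
    trace = FilterTrace()
    trace.append("input", *table.count_by_class())
    current = filter_segregation(table, pedigree, config)
    trace.append("segregation", *current.count_by_class())
    log.info("segregation: %d variants retained", len(current))
    for name, stage in _STAGES:
        current = stage(current, config)
        trace.append(name, *current.count_by_class())
        log.info("%s: %d variants retained", name, len(current))
    return current, trace
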