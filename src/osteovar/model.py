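"""Core domain types for family-based variant prioritization and cohort replication.

Coordinates are 1-based and fully closed throughout ("chrom: pos" in the
GRCh37 convention). A variant record joins a :class:`VariantKey` with its
:class:`AnnotationProfile` and one genotype call per sequenced sample.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

_ALLELE_CHARS = set("ACGT")


class Consequence(enum.Enum):
    """Functional consequence class of a variant on its transcript."""

    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_DONOR = "splice_donor"
    START_LOSS = "start_loss"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    INTRONIC = "intronic"
    OTHER = "other"


class PredictorCall(enum.Enum):
    DELETERIOUS = "deleterious"
    BENIGN = "benign"
    UNKNOWN = "unknown"


class ClinvarStatus(enum.Enum):
    NOT_REPORTED = "not_reported"
    BENIGN = "benign"
    UNCERTAIN_SIGNIFICANCE = "uncertain_significance"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC = "pathogenic"


class Zygosity(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def is_carrier(self) -> bool:
        """True when the sample carries at least one alternative allele."""
        return self in (Zygosity.HET, Zygosity.HOM_ALT)

    @property
    def alt_count(self) -> int:
        if self is Zygosity.MISSING:
            raise ValueError("missing genotype has no allele count")
        return {Zygosity.HOM_REF: 0, Zygosity.HET: 1, Zygosity.HOM_ALT: 2}[self]


class Affection(enum.Enum):
    UNKNOWN = 0
    UNAFFECTED = 1
    AFFECTED = 2


#: amino-acid-effect predictors whose majority vote drives the
#: deleteriousness filter; other scores (CADD, GERP) are thresholded apart.
AA_EFFECT_PREDICTORS = (
    "SIFT",
    "Polyphen2",
    "MutationTaster",
    "MutationAssessor",
    "VEST3",
)

AUX_PREDICTORS = ("MetaLR", "MetaSVM", "PROVEAN")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a biallelic variant: chromosome, 1-based position, REF, ALT."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _ALLELE_CHARS:
                raise ValueError(f"allele {allele!r} has characters outside ACGT")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class AnnotationProfile:
    """Per-variant annotation: gene context, population frequencies and
    deleteriousness evidence.

    ``aaf_by_db`` maps database name (e.g. ``gnomad``) to the alternative
    allele frequency observed there; a database with no entry means the
    variant is absent from it. ``predictor_calls`` carries the categorical
    deleterious/benign verdicts; ``acmg_class`` is the 1-5 ordinal
    pathogenicity class (4 = likely pathogenic, 5 = pathogenic).
    """

    gene: str
    transcript: str = ""
    consequence: Consequence = Consequence.OTHER
    splice_offset: int | None = None
    aaf_by_db: dict[str, float] = field(default_factory=dict)
    predictor_calls: dict[str, PredictorCall] = field(default_factory=dict)
    cadd_phred: float = 0.0
    gerp_rs: float = 0.0
    acmg_class: int = 3
    clinvar_status: ClinvarStatus = ClinvarStatus.NOT_REPORTED
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for db, aaf in self.aaf_by_db.items():
            if not 0.0 <= aaf <= 1.0:
                raise ValueError(f"AAF for {db} out of [0,1]: {aaf}")
        if self.acmg_class not in (1, 2, 3, 4, 5):
            raise ValueError(f"ACMG class must be 1..5, got {self.acmg_class}")
        if self.cadd_phred < 0:
            raise ValueError("scaled CADD cannot be negative")


@dataclass
class VariantRecord:
    key: VariantKey
    annotation: AnnotationProfile
    genotypes: dict[str, Zygosity]


class MergedVariantTable:
    """Multi-sample variant table: the substrate of every filter stage.

    Every record carries a call (possibly :attr:`Zygosity.MISSING`) for every
    sample in ``sample_ids``; variant keys are unique.
    """

    def __init__(self, sample_ids: Iterable[str], records: Iterable[VariantRecord] = ()):
        self.sample_ids: list[str] = list(sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.records: list[VariantRecord] = []
        self._index: dict[VariantKey, int] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: VariantRecord) -> None:
        if rec.key in self._index:
            raise ValueError(f"duplicate variant key {rec.key}")
        unknown = set(rec.genotypes) - set(self.sample_ids)
        if unknown:
            raise ValueError(f"genotype for unknown sample(s) {sorted(unknown)}")
        for sid in self.sample_ids:
            rec.genotypes.setdefault(sid, Zygosity.MISSING)
        self._index[rec.key] = len(self.records)
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._index

    def get(self, key: VariantKey) -> VariantRecord:
        return self.records[self._index[key]]

    def subset(self, keep: Iterable[VariantRecord]) -> "MergedVariantTable":
        """New table with the same samples and the given records (copied refs)."""
        return MergedVariantTable(self.sample_ids, keep)

    def count_by_class(self) -> tuple[int, int]:
        """(n_snvs, n_indels) in the table."""
        n_snv = sum(1 for r in self.records if r.key.is_snv)
        return n_snv, len(self.records) - n_snv

    def keys(self) -> list[VariantKey]:
        return [r.key for r in self.records]


@dataclass
class PedigreeMember:
    member_id: str
    sex: str  # "M" / "F" / "U"
    generation: str  # e.g. "II", "III"
    affection: Affection
    sequenced: bool


class Pedigree:
    """Family members with affection status and sequenced flags."""

    def __init__(self, members: Iterable[PedigreeMember]):
        self.members = list(members)
        ids = [m.member_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pedigree ids")
        self._by_id = {m.member_id: m for m in self.members}

    def __iter__(self) -> Iterator[PedigreeMember]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, member_id: str) -> PedigreeMember:
        return self._by_id[member_id]

    @property
    def sequenced_ids(self) -> list[str]:
        return [m.member_id for m in self.members if m.sequenced]

    def affected_sequenced(self) -> list[str]:
        return [
            m.member_id
            for m in self.members
            if m.sequenced and m.affection is Affection.AFFECTED
        ]

    def unaffected_sequenced(self) -> list[str]:
        return [
            m.member_id
            for m in self.members
            if m.sequenced and m.affection is Affection.UNAFFECTED
        ]


class Subgroup(enum.Enum):
    """Case-control strata: fracture cases, and non-fracture controls split by
    the worst LS/FN T-score (normal / osteopenic / osteoporotic)."""

    NORMAL = "normal"
    OSTEOPENIC = "osteopenic"
    OSTEOPOROTIC = "osteoporotic"
    FRACTURE = "fracture"


FRACTURE_SITES = ("wrist", "humerus", "hip", "vertebra")


@dataclass
class CohortSubject:
    """One postmenopausal woman from the replication cohort."""

    subject_id: str
    subgroup: Subgroup
    genotypes: dict[str, Zygosity]
    ls_bmd: float | None = None
    fn_bmd: float | None = None
    th_bmd: float | None = None
    ls_t: float | None = None
    fn_t: float | None = None
    th_t: float | None = None
    ls_z: float | None = None
    fn_z: float | None = None
    calcium: float | None = None
    alp: float | None = None
    albumin: float | None = None
    age: float | None = None
    fracture_sites: frozenset[str] = frozenset()
    calcium_supplement: bool = False

    def __post_init__(self) -> None:
        bad = set(self.fracture_sites) - set(FRACTURE_SITES)
        if bad:
            raise ValueError(f"unknown fracture site(s): {sorted(bad)}")
        has_fx = bool(self.fracture_sites)
        if has_fx != (self.subgroup is Subgroup.FRACTURE):
            raise ValueError(
                f"subject {self.subject_id}: subgroup {self.subgroup.value} "
                f"inconsistent with fracture sites {sorted(self.fracture_sites)}"
            )


@dataclass
class FilterTrace:
    """Ordered retained-variant counts per filter stage (SNVs and indels)."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def append(self, name: str, snv_count: int, indel_count: int) -> None:
        if snv_count < 0 or indel_count < 0:
            raise ValueError("counts must be non-negative")
        if self.stages:
            _, prev_snv, prev_indel = self.stages[-1]
            if snv_count > prev_snv or indel_count > prev_indel:
                raise ValueError(
                    f"stage {name!r} increases a count "
                    f"({prev_snv}/{prev_indel} -> {snv_count}/{indel_count})"
                )
        self.stages.append((name, snv_count, indel_count))

    @property
    def snv_counts(self) -> list[int]:
        return [s for _, s, _ in self.stages]

    @property
    def indel_counts(self) -> list[int]:
        return [i for _, _, i in self.stages]

    def __len__(self) -> int:
        return len(self.stages)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FilterTrace) and self.stages == other.stages
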