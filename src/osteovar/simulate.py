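"""Synthetic pedigree-scale and cohort-scale data generators.

The study's raw genomes and individual-level cohort data are not public,
so the pipeline is exercised on synthetic data with the same statistical
structure:

* :func:`simulate_pedigree_dataset` emulates a merged coding-variant table
  for 12 sequenced relatives of a two-generation family with three
  affected osteoporotic siblings and one unaffected control. Planted
  causal variants pass all six filter stages by construction; every
  background variant is built to fail first at a designated stage, and
  that stage is recorded in the truth record.
* :func:`simulate_cohort` emulates a ~1045-woman case-control collection
  (normal / osteopenic / osteoporotic / fracture subgroups) with
  genotypes drawn under Hardy-Weinberg equilibrium at configured allele
  frequencies and phenotypes drawn on the measurement scale with
  subgroup-specific location/scale and additive carrier shifts.

Both generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .model import (
    Affection,
    AnnotationProfile,
    ClinvarStatus,
    Consequence,
    CohortSubject,
    MergedVariantTable,
    Pedigree,
    PedigreeMember,
    PredictorCall,
    Subgroup,
    VariantKey,
    VariantRecord,
    Zygosity,
)
from .prioritize import STAGE_NAMES

_BASES = "ACGT"

#: two-generation family: 15 relatives, 12 sequenced; the three affected
#: osteoporotic brothers and the unaffected (normal-BMD) control drive the
#: segregation filter
DEFAULT_PEDIGREE = Pedigree(
    [
        PedigreeMember("II1", "M", "II", Affection.UNKNOWN, True),
        PedigreeMember("II4", "F", "II", Affection.UNKNOWN, True),
        PedigreeMember("II5", "F", "II", Affection.UNKNOWN, False),
        PedigreeMember("II7", "M", "II", Affection.UNKNOWN, True),
        PedigreeMember("II8", "M", "II", Affection.UNKNOWN, True),
        PedigreeMember("II10", "M", "II", Affection.UNAFFECTED, True),
        PedigreeMember("II11", "F", "II", Affection.UNKNOWN, False),
        PedigreeMember("III1", "M", "III", Affection.AFFECTED, True),
        PedigreeMember("III4", "M", "III", Affection.AFFECTED, True),
        PedigreeMember("III5", "M", "III", Affection.AFFECTED, True),
        PedigreeMember("III6", "M", "III", Affection.UNKNOWN, True),
        PedigreeMember("III7", "F", "III", Affection.UNKNOWN, True),
        PedigreeMember("III8", "F", "III", Affection.UNKNOWN, True),
        PedigreeMember("III9", "F", "III", Affection.UNKNOWN, True),
        PedigreeMember("III10", "M", "III", Affection.UNKNOWN, False),
    ]
)

DEFAULT_BLACKLIST = frozenset({"TTN", "MUC16", "FLG", "OBSCN", "HLA-DRB1"})
DEFAULT_GENE_PANEL = frozenset(
    {"SELP", "TGFB2", "ADAMTS20", "LRP5", "WNT1", "PLS3", "COL1A1", "SOST", "RUNX2", "ACAN"}
)


def _all_deleterious() -> dict[str, PredictorCall]:
    return {
        name: PredictorCall.DELETERIOUS
        for name in ("SIFT", "Polyphen2", "MutationTaster", "MutationAssessor", "VEST3")
    }


def _default_planted() -> list["PlantedVariant"]:
    """The three shortlisted familial variants with their published
    annotation profiles; extra sequenced carriers follow the family's
    confirmed segregation."""
    selp_pred = _all_deleterious()
    tgfb2_pred = _all_deleterious()
    adamts20_pred = _all_deleterious()
    adamts20_pred["SIFT"] = PredictorCall.BENIGN
    return [
        PlantedVariant(
            key=VariantKey("1", 169564040, "T", "C"),
            annotation=AnnotationProfile(
                gene="SELP",
                transcript="NM_003005.3",
                consequence=Consequence.MISSENSE,
                aaf_by_db={"gnomad": 0.0000756},
                predictor_calls=selp_pred,
                cadd_phred=23.5,
                gerp_rs=5.2,
                acmg_class=4,
                clinvar_status=ClinvarStatus.NOT_REPORTED,
            ),
            extra_carriers=frozenset({"II4", "III6"}),
        ),
        PlantedVariant(
            key=VariantKey("1", 218610804, "C", "T"),
            annotation=AnnotationProfile(
                gene="TGFB2",
                transcript="NM_001135599.2",
                consequence=Consequence.MISSENSE,
                aaf_by_db={"gnomad": 0.0000159},
                predictor_calls=tgfb2_pred,
                cadd_phred=25.0,
                gerp_rs=5.6,
                acmg_class=4,
                clinvar_status=ClinvarStatus.UNCERTAIN_SIGNIFICANCE,
            ),
            extra_carriers=frozenset({"II8", "III8"}),
        ),
        PlantedVariant(
            key=VariantKey("12", 43821128, "A", "T"),
            annotation=AnnotationProfile(
                gene="ADAMTS20",
                transcript="NM_025003.3",
                consequence=Consequence.MISSENSE,
                aaf_by_db={"gnomad": 0.0008091},
                predictor_calls=adamts20_pred,
                cadd_phred=24.3,
                gerp_rs=4.8,
                acmg_class=4,
                clinvar_status=ClinvarStatus.NOT_REPORTED,
            ),
            extra_carriers=frozenset({"III7", "III9"}),
        ),
    ]


@dataclass(frozen=True)
class PlantedVariant:
    """A causal variant built to survive all six filter stages: heterozygous
    in every affected relative, absent in the unaffected control, rare,
    deleterious and in a bone-relevant gene."""

    key: VariantKey
    annotation: AnnotationProfile
    extra_carriers: frozenset[str] = frozenset()


@dataclass
class PedigreeSimConfig:
    """Study-scale defaults: 42,851 background SNVs + 3 planted missense
    SNVs (42,854 total) and 1,957 background indels, with per-stage
    first-failure fractions matching the observed attrition of the real
    filtering run, so the default trace reproduces its shape exactly."""

    n_background_snvs: int = 42851
    n_background_indels: int = 1957
    pedigree: Pedigree = field(default_factory=lambda: DEFAULT_PEDIGREE)
    affected_ids: frozenset[str] = frozenset({"III1", "III4", "III5"})
    unaffected_ids: frozenset[str] = frozenset({"II10"})
    planted: list[PlantedVariant] = field(default_factory=_default_planted)
    #: fraction of background SNVs whose first failing stage is each filter
    snv_violation_mix: dict[str, float] = field(
        default_factory=lambda: {
            "segregation": 40952 / 42851,
            "consequence": 966 / 42851,
            "rarity": 902 / 42851,
            "deleteriousness": 1 / 42851,
            "blacklist": 1 / 42851,
            "gene_panel": 29 / 42851,
        }
    )
    indel_violation_mix: dict[str, float] = field(
        default_factory=lambda: {
            "segregation": 1902 / 1957,
            "consequence": 37 / 1957,
            "rarity": 0.0,
            "deleteriousness": 0.0,
            "blacklist": 0.0,
            "gene_panel": 18 / 1957,
        }
    )
    blacklist: frozenset[str] = DEFAULT_BLACKLIST
    gene_panel: frozenset[str] = DEFAULT_GENE_PANEL
    seed: int = 0

    def __post_init__(self) -> None:
        for mix in (self.snv_violation_mix, self.indel_violation_mix):
            if any(f < 0 for f in mix.values()):
                raise ValueError("violation-mix fractions must be non-negative")
            if sum(mix.values()) > 1 + 1e-9:
                raise ValueError("violation-mix fractions must sum to <= 1")
            unknown = set(mix) - set(STAGE_NAMES)
            if unknown:
                raise ValueError(f"unknown stage(s) in violation mix: {sorted(unknown)}")
        for pv in self.planted:
            if pv.annotation.gene in self.blacklist:
                raise ValueError(f"planted variant gene {pv.annotation.gene} is blacklisted")
            if pv.annotation.gene not in self.gene_panel:
                raise ValueError(
                    f"planted variant gene {pv.annotation.gene} missing from gene panel"
                )


@dataclass
class PedigreeSimTruth:
    planted_keys: list[VariantKey]
    first_fail_stage: dict[VariantKey, str]
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "planted": [str(k) for k in self.planted_keys],
            "first_fail_stage": {str(k): v for k, v in self.first_fail_stage.items()},
        }


def _largest_remainder(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Integer allocation of n items to categories, exact in total."""
    raw = {k: f * n for k, f in fractions.items()}
    counts = {k: int(v) for k, v in raw.items()}
    shortfall = n - sum(counts.values())
    by_rem = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in by_rem[:shortfall]:
        counts[k] += 1
    return counts


class _VariantFactory:
    def __init__(self, config: PedigreeSimConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.used_keys: set[VariantKey] = {pv.key for pv in config.planted}
        self.sample_ids = config.pedigree.sequenced_ids
        self.others = [
            s
            for s in self.sample_ids
            if s not in config.affected_ids and s not in config.unaffected_ids
        ]
        self._gene_counter = 0
        self._blacklist_cycle = sorted(config.blacklist)

    def _fresh_key(self, indel: bool) -> VariantKey:
        while True:
            chrom = str(self.rng.integers(1, 23))
            pos = int(self.rng.integers(1_000_000, 240_000_000))
            ref = _BASES[self.rng.integers(4)]
            if indel:
                if self.rng.random() < 0.5:
                    alt = ref + "".join(
                        _BASES[i] for i in self.rng.integers(0, 4, self.rng.integers(1, 5))
                    )
                else:
                    ref = ref + "".join(
                        _BASES[i] for i in self.rng.integers(0, 4, self.rng.integers(1, 5))
                    )
                    alt = ref[0]
            else:
                alt = _BASES[self.rng.integers(4)]
                while alt == ref:
                    alt = _BASES[self.rng.integers(4)]
            key = VariantKey(chrom, pos, ref, alt)
            if key not in self.used_keys:
                self.used_keys.add(key)
                return key

    def _background_gene(self) -> str:
        self._gene_counter += 1
        return f"BKG{self._gene_counter:05d}"

    # -- genotype patterns ---------------------------------------------------

    def _random_other_genotypes(self) -> dict[str, Zygosity]:
        out = {}
        for sid in self.others:
            out[sid] = Zygosity.HET if self.rng.random() < 0.3 else Zygosity.HOM_REF
        return out

    def segregating_genotypes(self) -> dict[str, Zygosity]:
        gts = self._random_other_genotypes()
        for sid in self.config.affected_ids:
            gts[sid] = Zygosity.HET
        for sid in self.config.unaffected_ids:
            gts[sid] = Zygosity.HOM_REF
        return gts

    def non_segregating_genotypes(self) -> dict[str, Zygosity]:
        gts = self._random_other_genotypes()
        affected = sorted(self.config.affected_ids)
        unaffected = sorted(self.config.unaffected_ids)
        mode = self.rng.choice(
            ["all_homref", "control_carrier", "affected_homref", "affected_homalt", "affected_missing"],
            p=[0.55, 0.15, 0.15, 0.08, 0.07],
        )
        for sid in affected:
            gts[sid] = Zygosity.HET
        for sid in unaffected:
            gts[sid] = Zygosity.HOM_REF
        if mode == "all_homref":
            for sid in affected:
                gts[sid] = Zygosity.HOM_REF
        elif mode == "control_carrier":
            target = unaffected[self.rng.integers(len(unaffected))]
            gts[target] = Zygosity.HET if self.rng.random() < 0.7 else Zygosity.HOM_ALT
        elif mode == "affected_homref":
            gts[affected[self.rng.integers(len(affected))]] = Zygosity.HOM_REF
        elif mode == "affected_homalt":
            gts[affected[self.rng.integers(len(affected))]] = Zygosity.HOM_ALT
        else:  # missing call in an affected fails under the default policy
            gts[affected[self.rng.integers(len(affected))]] = Zygosity.MISSING
        return gts

    # -- annotation components ----------------------------------------------

    def _rare_aafs(self) -> dict[str, float]:
        aafs = {}
        for db in ("dbsnp", "1000g", "esp6500", "gnomad"):
            if self.rng.random() < 0.8:
                aafs[db] = float(10 ** self.rng.uniform(-5, -2))
        return aafs

    def _common_aafs(self) -> dict[str, float]:
        aafs = self._rare_aafs()
        n_common = int(self.rng.integers(1, 4))
        dbs = self.rng.choice(["dbsnp", "1000g", "esp6500", "gnomad"], n_common, replace=False)
        for db in dbs:
            aafs[db] = float(self.rng.uniform(0.011, 0.5))
        return aafs

    def _deleterious_predictors(self) -> dict[str, PredictorCall]:
        from .model import AA_EFFECT_PREDICTORS

        n_del = int(self.rng.integers(3, 6))
        calls = {}
        order = list(AA_EFFECT_PREDICTORS)
        self.rng.shuffle(order)
        for i, name in enumerate(order):
            if i < n_del:
                calls[name] = PredictorCall.DELETERIOUS
            else:
                calls[name] = (
                    PredictorCall.BENIGN if self.rng.random() < 0.7 else PredictorCall.UNKNOWN
                )
        return calls

    def _benign_predictors(self) -> dict[str, PredictorCall]:
        from .model import AA_EFFECT_PREDICTORS

        return {
            name: PredictorCall.BENIGN if self.rng.random() < 0.8 else PredictorCall.UNKNOWN
            for name in AA_EFFECT_PREDICTORS
        }

    def _passing_consequence(self, indel: bool, force_missense: bool = False):
        if indel:
            cons = (
                Consequence.FRAMESHIFT
                if self.rng.random() < 0.6
                else Consequence.INFRAME_INDEL
            )
            return cons, None
        if force_missense or self.rng.random() < 0.85:
            return Consequence.MISSENSE, None
        cons = Consequence(
            self.rng.choice(
                ["splice_acceptor", "splice_donor", "start_loss", "stop_gain", "stop_loss"]
            )
        )
        offset = int(self.rng.integers(1, 11)) if cons.value.startswith("splice") else None
        return cons, offset

    def _failing_consequence(self, indel: bool):
        if indel:
            return Consequence.INTRONIC, None
        cons = Consequence(
            self.rng.choice(
                ["synonymous", "intronic", "other", "splice_donor", "splice_acceptor"],
                p=[0.45, 0.3, 0.1, 0.075, 0.075],
            )
        )
        offset = int(self.rng.integers(11, 60)) if cons.value.startswith("splice") else None
        return cons, offset

    def _passing_deleteriousness(self, ann_kwargs: dict) -> None:
        ann_kwargs["predictor_calls"] = self._deleterious_predictors()
        ann_kwargs["cadd_phred"] = float(self.rng.uniform(15.5, 45))
        ann_kwargs["acmg_class"] = int(self.rng.choice([4, 5], p=[0.8, 0.2]))
        ann_kwargs["gerp_rs"] = float(self.rng.uniform(2.0, 6.2))

    def _failing_deleteriousness(self, ann_kwargs: dict) -> None:
        self._passing_deleteriousness(ann_kwargs)
        clauses = ["predictors", "cadd", "acmg", "gerp"]
        broken = self.rng.choice(clauses, int(self.rng.integers(1, 4)), replace=False)
        if "predictors" in broken:
            ann_kwargs["predictor_calls"] = self._benign_predictors()
        if "cadd" in broken:
            ann_kwargs["cadd_phred"] = float(self.rng.uniform(0, 15))
        if "acmg" in broken:
            ann_kwargs["acmg_class"] = int(self.rng.integers(1, 4))
        if "gerp" in broken:
            ann_kwargs["gerp_rs"] = float(self.rng.uniform(-5, 1.9))

    # -- assembly -------------------------------------------------------------

    def background_variant(self, fail_stage: str, indel: bool) -> VariantRecord:
        key = self._fresh_key(indel)
        gene = self._background_gene()
        ann_kwargs: dict = {"gene": gene}
        if fail_stage == "segregation":
            gts = self.non_segregating_genotypes()
            cons, offset = (
                self._passing_consequence(indel)
                if self.rng.random() < 0.1
                else self._failing_consequence(indel)
            )
            ann_kwargs["aaf_by_db"] = (
                self._rare_aafs() if self.rng.random() < 0.2 else self._common_aafs()
            )
        else:
            gts = self.segregating_genotypes()
            if fail_stage == "consequence":
                cons, offset = self._failing_consequence(indel)
                ann_kwargs["aaf_by_db"] = self._common_aafs()
            else:
                cons, offset = self._passing_consequence(
                    indel, force_missense=fail_stage == "deleteriousness"
                )
                if fail_stage == "rarity":
                    ann_kwargs["aaf_by_db"] = self._common_aafs()
                else:
                    ann_kwargs["aaf_by_db"] = self._rare_aafs()
                    if cons is Consequence.MISSENSE:
                        if fail_stage == "deleteriousness":
                            self._failing_deleteriousness(ann_kwargs)
                        else:
                            self._passing_deleteriousness(ann_kwargs)
                    if fail_stage == "blacklist":
                        ann_kwargs["gene"] = self._blacklist_cycle[
                            self.rng.integers(len(self._blacklist_cycle))
                        ]
        ann_kwargs["consequence"] = cons
        ann_kwargs["splice_offset"] = offset
        return VariantRecord(key, AnnotationProfile(**ann_kwargs), gts)

    def planted_record(self, pv: PlantedVariant) -> VariantRecord:
        gts = {sid: Zygosity.HOM_REF for sid in self.sample_ids}
        for sid in self.config.affected_ids:
            gts[sid] = Zygosity.HET
        for sid in pv.extra_carriers:
            if sid in gts:
                gts[sid] = Zygosity.HET
        return VariantRecord(pv.key, pv.annotation, gts)


def simulate_pedigree_dataset(
    config: PedigreeSimConfig | None = None, seed: int | None = None
) -> tuple[MergedVariantTable, Pedigree, PedigreeSimTruth]:
    """Generate a merged multi-sample variant table plus its truth record.

    Planted variants survive every filter stage by construction; each
    background variant is built to fail first at the stage recorded for it
    in the truth record (under the default filter thresholds).
    """
    config = config or PedigreeSimConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    factory = _VariantFactory(config, rng)
    table = MergedVariantTable(config.pedigree.sequenced_ids)
    first_fail: dict[VariantKey, str] = {}

    for pv in config.planted:
        table.add(factory.planted_record(pv))

    for mix, n, indel in (
        (config.snv_violation_mix, config.n_background_snvs, False),
        (config.indel_violation_mix, config.n_background_indels, True),
    ):
        counts = _largest_remainder(mix, n)
        for stage in STAGE_NAMES:
            for _ in range(counts.get(stage, 0)):
                rec = factory.background_variant(stage, indel)
                first_fail[rec.key] = stage
                table.add(rec)

    truth = PedigreeSimTruth(
        planted_keys=[pv.key for pv in config.planted],
        first_fail_stage=first_fail,
        seed=config.seed,
    )
    return table, config.pedigree, truth


# ---------------------------------------------------------------------------
# cohort simulation

#: per-subgroup phenotype medians and interquartile ranges on the
#: measurement scale, patterned on the reference-genotype distributions of
#: the replication cohort (BMD in g/cm^2, calcium mmol/L, ALP U/L,
#: albumin g/L)
DEFAULT_PHENOTYPE_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "normal": {
        "ls_bmd": (1.13, 0.18),
        "fn_bmd": (0.89, 0.12),
        "th_bmd": (1.00, 0.15),
        "calcium": (2.40, 0.14),
        "alp": (165.0, 65.0),
        "albumin": (44.0, 3.7),
    },
    "osteopenic": {
        "ls_bmd": (0.92, 0.15),
        "fn_bmd": (0.74, 0.13),
        "th_bmd": (0.80, 0.15),
        "calcium": (2.40, 0.14),
        "alp": (157.0, 59.0),
        "albumin": (43.8, 3.9),
    },
    "osteoporotic": {
        "ls_bmd": (0.88, 0.15),
        "fn_bmd": (0.70, 0.13),
        "th_bmd": (0.78, 0.15),
        "calcium": (2.40, 0.14),
        "alp": (157.0, 59.0),
        "albumin": (43.8, 3.9),
    },
    "fracture": {
        "ls_bmd": (0.91, 0.19),
        "fn_bmd": (0.69, 0.14),
        "th_bmd": (0.76, 0.15),
        "calcium": (2.34, 0.17),
        "alp": (154.0, 63.0),
        "albumin": (42.2, 4.7),
    },
}

_IQR_TO_SD = 1.349  # IQR of a normal distribution in units of its SD


@dataclass
class CohortSimConfig:
    """Defaults emulate the replication collection: 1045 postmenopausal
    women in four subgroups (normal 229, osteopenic 266, osteoporotic 282,
    fracture 268), three variants at their observed collection-wide allele
    frequencies, phenotype medians/IQRs per subgroup."""

    n_subjects: int = 1045
    subgroup_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "normal": 229 / 1045,
            "osteopenic": 266 / 1045,
            "osteoporotic": 282 / 1045,
            "fracture": 268 / 1045,
        }
    )
    aaf: dict[str, float] = field(
        default_factory=lambda: {"SELP": 0.011, "TGFB2": 0.002, "ADAMTS20": 0.028}
    )
    #: fraction of subjects with a failed genotyping call, per variant
    genotype_missing_rate: dict[str, float] = field(
        default_factory=lambda: {"ADAMTS20": 33 / 1045}
    )
    phenotype_model: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PHENOTYPE_MODEL.items()}
    )
    #: additive shift of a phenotype per copy of the alternative allele
    carrier_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"ADAMTS20": {"th_bmd": -0.09, "calcium": -0.03}}
    )
    calcium_supplement_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for v, p in self.aaf.items():
            if not 0.0 <= p <= 0.5:
                raise ValueError(f"aaf for {v} must be in [0, 0.5]")
        total = sum(self.subgroup_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("subgroup fractions must sum to 1")


@dataclass
class CohortSimTruth:
    genotype_counts: dict[str, dict[str, tuple[int, int, int]]]
    carrier_effects: dict[str, dict[str, float]]
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "genotype_counts": {
                v: {g: list(c) for g, c in per.items()}
                for v, per in self.genotype_counts.items()
            },
            "carrier_effects": self.carrier_effects,
        }


def _truncated_normal(rng, loc, scale, low, high, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(loc, scale, size)
        ok = draw[(draw >= low) & (draw <= high)]
        take = min(ok.size, size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _subgroup_t_scores(rng, subgroup: str, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LS/FN/TH T-scores consistent with the subgroup's BMD classification
    (worst LS/FN site: normal >= -1.0; osteopenic in (-2.5, -1.0);
    osteoporotic <= -2.5; fracture unconstrained)."""
    if subgroup == "normal":
        ls = _truncated_normal(rng, 0.3, 0.9, -0.99, 4.0, n)
        fn = _truncated_normal(rng, 0.2, 0.9, -0.99, 4.0, n)
    elif subgroup == "osteopenic":
        ls = _truncated_normal(rng, -1.5, 0.6, -2.49, 0.5, n)
        fn = _truncated_normal(rng, -1.4, 0.6, -2.49, 0.5, n)
        bump = np.minimum(ls, fn) > -1.0  # worst site must be osteopenic
        ls[bump] = rng.uniform(-2.4, -1.01, bump.sum())
    elif subgroup == "osteoporotic":
        ls = _truncated_normal(rng, -2.9, 0.5, -5.0, -1.0, n)
        fn = _truncated_normal(rng, -2.4, 0.7, -5.0, 0.0, n)
        bump = np.minimum(ls, fn) > -2.5
        ls[bump] = rng.uniform(-3.5, -2.5, bump.sum())
    else:
        ls = rng.normal(-1.8, 1.1, n)
        fn = rng.normal(-1.8, 1.0, n)
    th = (ls + fn) / 2 + rng.normal(0, 0.3, n)
    return ls, fn, th


def simulate_cohort(
    config: CohortSimConfig | None = None, seed: int | None = None
) -> tuple[list[CohortSubject], CohortSimTruth]:
    """Generate a synthetic case-control cohort plus its truth record."""
    config = config or CohortSimConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    subgroup_counts = _largest_remainder(config.subgroup_fractions, config.n_subjects)

    subjects: list[CohortSubject] = []
    genotype_counts: dict[str, dict[str, list[int]]] = {
        v: {g: [0, 0, 0] for g in list(subgroup_counts) + ["whole"]} for v in config.aaf
    }
    sid_counter = 0
    for subgroup_name in ("normal", "osteopenic", "osteoporotic", "fracture"):
        n = subgroup_counts.get(subgroup_name, 0)
        if n == 0:
            continue
        subgroup = Subgroup(subgroup_name)
        ls_t, fn_t, th_t = _subgroup_t_scores(rng, subgroup_name, n)
        age_loc = {"normal": 58, "osteopenic": 62, "osteoporotic": 66, "fracture": 66}[
            subgroup_name
        ]
        ages = _truncated_normal(rng, age_loc, 8, 41, 79, n)
        model = config.phenotype_model[subgroup_name]
        phenos = {}
        for name, (median, iqr) in model.items():
            phenos[name] = rng.normal(median, iqr / _IQR_TO_SD, n)
        genotypes_by_variant = {}
        for variant, p in config.aaf.items():
            probs = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
            draws = rng.choice(3, size=n, p=probs)
            missing_rate = config.genotype_missing_rate.get(variant, 0.0)
            if missing_rate:
                draws = draws.astype(float)
                draws[rng.random(n) < missing_rate] = np.nan
            genotypes_by_variant[variant] = draws
        supplements = rng.random(n) < config.calcium_supplement_rate
        for i in range(n):
            sid_counter += 1
            gts = {}
            for variant, draws in genotypes_by_variant.items():
                value = draws[i]
                if np.isnan(value):
                    gts[variant] = Zygosity.MISSING
                else:
                    zyg = (Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT)[int(value)]
                    gts[variant] = zyg
                    genotype_counts[variant][subgroup_name][int(value)] += 1
                    genotype_counts[variant]["whole"][int(value)] += 1
            subject_phenos = {name: float(vals[i]) for name, vals in phenos.items()}
            for variant, effects in config.carrier_effects.items():
                zyg = gts.get(variant, Zygosity.MISSING)
                if zyg is Zygosity.MISSING:
                    continue
                for pheno, shift in effects.items():
                    subject_phenos[pheno] += shift * zyg.alt_count
            if subgroup is Subgroup.FRACTURE:
                sites = frozenset(
                    rng.choice(
                        ["wrist", "humerus", "hip", "vertebra"],
                        size=int(rng.integers(1, 3)),
                        replace=False,
                        p=[0.45, 0.2, 0.1, 0.25],
                    )
                )
            else:
                sites = frozenset()
            subjects.append(
                CohortSubject(
                    subject_id=f"S{sid_counter:05d}",
                    subgroup=subgroup,
                    genotypes=gts,
                    ls_bmd=subject_phenos["ls_bmd"],
                    fn_bmd=subject_phenos["fn_bmd"],
                    th_bmd=subject_phenos["th_bmd"],
                    ls_t=float(ls_t[i]),
                    fn_t=float(fn_t[i]),
                    th_t=float(th_t[i]),
                    ls_z=float(ls_t[i] + 0.8),
                    fn_z=float(fn_t[i] + 0.8),
                    calcium=subject_phenos["calcium"],
                    alp=subject_phenos["alp"],
                    albumin=subject_phenos["albumin"],
                    age=float(ages[i]),
                    fracture_sites=sites,
                    calcium_supplement=bool(supplements[i]),
                )
            )
    truth = CohortSimTruth(
        genotype_counts={
            v: {g: tuple(c) for g, c in per.items()} for v, per in genotype_counts.items()
        },
        carrier_effects={v: dict(e) for v, e in config.carrier_effects.items()},
        seed=config.seed,
    )
    return subjects, truth
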