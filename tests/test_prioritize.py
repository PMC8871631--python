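"""Filter-stage semantics, ordering and oracle equivalence."""

from __future__ import annotations

import numpy as np
import pytest

from osteovar.model import (
    Consequence,
    MergedVariantTable,
    PredictorCall,
    VariantKey,
    Zygosity,
)
from osteovar.prioritize import (
    FilterConfig,
    MissingAafPolicy,
    MissingGenotypePolicy,
    filter_blacklist,
    filter_consequence,
    filter_deleteriousness,
    filter_gene_panel,
    filter_rarity,
    filter_segregation,
    run_prioritization,
)

from conftest import AFFECTED, ALL_SAMPLES, CONTROL, make_record


def config(**kwargs):
    kwargs.setdefault("affected_ids", frozenset(AFFECTED))
    kwargs.setdefault("unaffected_ids", frozenset({CONTROL}))
    return FilterConfig(**kwargs)


def table(*records):
    return MergedVariantTable(ALL_SAMPLES, records)


def keys(t):
    return {str(k) for k in t.keys()}


# ---------------------------------------------------------------------------
# segregation

def test_dominant_segregation_retains_het_affecteds_homref_control(family_pedigree):
    t = table(make_record(100, "HHH000"))
    out = filter_segregation(t, family_pedigree, config())
    assert len(out) == 1


@pytest.mark.parametrize(
    "pattern, reason",
    [
        ("HHHH00", "control heterozygous"),
        ("HHHA00", "control homozygous alternative"),
        ("0HH000", "one affected hom-ref"),
        ("HAH000", "one affected hom-alt"),
        ("000000", "no carrier at all"),
        (".HH000", "missing affected call under the default policy"),
    ],
)
def test_dominant_segregation_removals(family_pedigree, pattern, reason):
    out = filter_segregation(table(make_record(100, pattern)), family_pedigree, config())
    assert len(out) == 0, reason


def test_missing_affected_call_kept_under_ignore_sample_policy(family_pedigree):
    t = table(make_record(100, ".HH000"))
    cfg = config(missing_genotype_policy=MissingGenotypePolicy.IGNORE_SAMPLE)
    assert len(filter_segregation(t, family_pedigree, cfg)) == 1


def test_missing_control_call_never_excludes(family_pedigree):
    out = filter_segregation(table(make_record(100, "HHH.00")), family_pedigree, config())
    assert len(out) == 1


def test_segregation_requires_affected_ids(family_pedigree):
    with pytest.raises(ValueError, match="affected"):
        filter_segregation(
            table(make_record(100, "HHH000")),
            family_pedigree,
            FilterConfig(affected_ids=frozenset()),
        )


def test_segregation_twenty_variant_fixture_hand_enumerated(family_pedigree):
    """Exhaustive manual enumeration: exactly 6 of 20 patterns segregate."""
    segregating = ["HHH000", "HHH0H0", "HHH00H", "HHH0HH", "HHH0AH", "HHH.H0"]
    failing = [
        "000000", "HHHH00", "HHHA00", "0HH000", "H0H000", "HH0000",
        "AHH000", "HAH000", "HHA000", ".HH000", "H.H000", "HH.000",
        "0000HH", "HHHHHH",
    ]
    records = [
        make_record(100 + i, pattern) for i, pattern in enumerate(segregating + failing)
    ]
    out = filter_segregation(table(*records), family_pedigree, config())
    assert keys(out) == {f"1:{100 + i}:A>G" for i in range(len(segregating))}


# ---------------------------------------------------------------------------
# consequence

@pytest.mark.parametrize(
    "cons, offset, kept",
    [
        (Consequence.MISSENSE, None, True),
        (Consequence.SYNONYMOUS, None, False),
        (Consequence.INTRONIC, None, False),
        (Consequence.OTHER, None, False),
        (Consequence.STOP_GAIN, None, True),
        (Consequence.START_LOSS, None, True),
        (Consequence.FRAMESHIFT, None, True),
        (Consequence.INFRAME_INDEL, None, True),
        (Consequence.SPLICE_DONOR, 10, True),
        (Consequence.SPLICE_DONOR, 11, False),
        (Consequence.SPLICE_ACCEPTOR, -10, True),
        (Consequence.SPLICE_ACCEPTOR, None, False),
    ],
)
def test_consequence_filter(cons, offset, kept):
    t = table(make_record(100, consequence=cons, splice_offset=offset))
    assert len(filter_consequence(t, config())) == int(kept)


# ---------------------------------------------------------------------------
# rarity

def test_rarity_keeps_rare_in_all_databases():
    t = table(make_record(100, aaf=0.0000756))
    assert len(filter_rarity(t, config())) == 1


def test_rarity_is_a_conjunction_over_databases():
    aafs = {"gnomad": 0.02, "dbsnp": 0.001, "1000g": 0.001, "esp6500": 0.001}
    t = table(make_record(100, aaf=aafs))
    assert len(filter_rarity(t, config())) == 0


def test_rarity_boundary_inclusive():
    assert len(filter_rarity(table(make_record(100, aaf=0.01)), config())) == 1
    assert len(filter_rarity(table(make_record(100, aaf=0.0101)), config())) == 0


@pytest.mark.parametrize(
    "policy, kept",
    [(MissingAafPolicy.TREAT_AS_RARE, 1), (MissingAafPolicy.DROP, 0)],
)
def test_rarity_missing_everywhere_follows_policy(policy, kept):
    t = table(make_record(100, aaf={}))
    assert len(filter_rarity(t, config(missing_aaf_policy=policy))) == kept


# ---------------------------------------------------------------------------
# deleteriousness

@pytest.mark.parametrize(
    "predictors, cadd, acmg, gerp, kept",
    [
        ("DDDDD", 23.5, 4, 4.0, True),   # unanimous deleterious
        ("BDDDD", 24.3, 4, 4.0, True),   # one benign, majority holds
        ("BBDDD", 24.3, 4, 4.0, True),   # 3/5 strict majority
        ("BBBDD", 24.3, 4, 4.0, False),  # majority benign
        ("BBBBB", 10.0, 4, 4.0, False),
        ("UUUDB", 24.3, 4, 4.0, False),  # 1D/1B informative: no strict majority
        ("UUUDD", 24.3, 4, 4.0, True),   # 2D/0B informative
        ("UUUUU", 24.3, 4, 4.0, False),  # nothing informative
        ("DDDDD", 15.0, 4, 4.0, False),  # CADD threshold is strict
        ("DDDDD", 23.5, 3, 4.0, False),  # below likely-pathogenic
        ("DDDDD", 23.5, 5, 4.0, True),
        ("DDDDD", 23.5, 4, 1.9, False),  # not conserved
        ("DDDDD", 23.5, 4, 2.0, True),   # conservation boundary inclusive
    ],
)
def test_deleteriousness_conjunction_on_missense(predictors, cadd, acmg, gerp, kept):
    t = table(make_record(100, predictors=predictors, cadd=cadd, acmg=acmg, gerp=gerp))
    assert len(filter_deleteriousness(t, config())) == int(kept)


def test_deleteriousness_passes_non_missense_through():
    t = table(
        make_record(100, consequence=Consequence.STOP_GAIN, predictors="BBBBB", cadd=1.0, acmg=1, gerp=0.0),
        make_record(200, consequence=Consequence.FRAMESHIFT, predictors="UUUUU", cadd=0.0, acmg=1, gerp=-3.0),
    )
    assert len(filter_deleteriousness(t, config())) == 2


# ---------------------------------------------------------------------------
# blacklist / gene panel

def test_empty_blacklist_is_identity(small_table):
    out = filter_blacklist(small_table, config())
    assert keys(out) == keys(small_table)


def test_blacklist_removes_by_gene_and_by_key():
    t = table(
        make_record(100, gene="TTN"),
        make_record(200, gene="GOOD"),
        make_record(300, gene="ALSOGOOD"),
    )
    cfg = config(blacklist=frozenset({"TTN", VariantKey("1", 300, "A", "G")}))
    assert keys(filter_blacklist(t, cfg)) == {"1:200:A>G"}


def test_blacklist_removes_one_of_thirtythree():
    records = [make_record(100 + i, gene=f"G{i}") for i in range(33)]
    cfg = config(blacklist=frozenset({"G7"}))
    assert len(filter_blacklist(table(*records), cfg)) == 32


def test_gene_panel_retains_only_panel_genes():
    panel = {"SELP", "TGFB2", "ADAMTS20"}
    records = [make_record(100 + i, gene=f"BKG{i}") for i in range(29)]
    records += [make_record(500 + i, gene=g) for i, g in enumerate(sorted(panel))]
    out = filter_gene_panel(table(*records), config(gene_panel=frozenset(panel)))
    assert {r.annotation.gene for r in out} == panel


def test_gene_panel_empty_and_full(small_table):
    assert len(filter_gene_panel(small_table, config(gene_panel=frozenset()))) == 0
    genes = frozenset(r.annotation.gene for r in small_table)
    assert keys(filter_gene_panel(small_table, config(gene_panel=genes))) == keys(small_table)


# ---------------------------------------------------------------------------
# runner: ordering, monotonicity, idempotence, oracle equivalence

def _random_table(rng, n=40):
    records = []
    for i in range(n):
        pattern = "".join(rng.choice(list("H0A."), 6, p=[0.35, 0.45, 0.1, 0.1]))
        cons = Consequence(
            rng.choice([c.value for c in Consequence])
        )
        offset = int(rng.integers(-20, 21)) if cons.value.startswith("splice") else None
        aaf = (
            {}
            if rng.random() < 0.2
            else {"gnomad": float(rng.uniform(0, 0.05))}
        )
        records.append(
            make_record(
                100 + i,
                pattern,
                gene=rng.choice(["SELP", "TTN", "BKG1", "BKG2"]),
                consequence=cons,
                splice_offset=offset,
                aaf=aaf,
                predictors="".join(rng.choice(list("DBU"), 5)),
                cadd=float(rng.uniform(0, 40)),
                gerp=float(rng.uniform(-5, 6)),
                acmg=int(rng.integers(1, 6)),
            )
        )
    return table(*records)


def _oracle_keep(rec, cfg):
    """Independent per-record predicate over all six stages, evaluated
    directly from the published filtering rules."""
    gts = rec.genotypes
    if any(gts[s] != Zygosity.HET for s in cfg.affected_ids):
        if not (
            cfg.missing_genotype_policy is MissingGenotypePolicy.IGNORE_SAMPLE
            and all(gts[s] in (Zygosity.HET, Zygosity.MISSING) for s in cfg.affected_ids)
        ):
            return False
    if any(gts[s] in (Zygosity.HET, Zygosity.HOM_ALT) for s in cfg.unaffected_ids):
        return False
    ann = rec.annotation
    ok_cons = ann.consequence in {
        Consequence.MISSENSE, Consequence.START_LOSS, Consequence.STOP_GAIN,
        Consequence.STOP_LOSS, Consequence.FRAMESHIFT, Consequence.INFRAME_INDEL,
    } or (
        ann.consequence in (Consequence.SPLICE_ACCEPTOR, Consequence.SPLICE_DONOR)
        and ann.splice_offset is not None
        and abs(ann.splice_offset) <= cfg.splice_window
    )
    if not ok_cons:
        return False
    if ann.aaf_by_db:
        if any(v > cfg.aaf_threshold for v in ann.aaf_by_db.values()):
            return False
    elif cfg.missing_aaf_policy is MissingAafPolicy.DROP:
        return False
    if ann.consequence is Consequence.MISSENSE:
        votes = [c for c in ann.predictor_calls.values() if c is not PredictorCall.UNKNOWN]
        n_del = sum(1 for c in votes if c is PredictorCall.DELETERIOUS)
        if not votes or 2 * n_del <= len(votes):
            return False
        if not (ann.cadd_phred > cfg.cadd_threshold and ann.acmg_class >= cfg.min_acmg
                and ann.gerp_rs >= cfg.gerp_threshold):
            return False
    if ann.gene in cfg.blacklist or rec.key in cfg.blacklist:
        return False
    return ann.gene in cfg.gene_panel


def test_runner_matches_manual_stage_composition_and_oracle(family_pedigree):
    rng = np.random.default_rng(42)
    cfg = config(blacklist=frozenset({"TTN"}), gene_panel=frozenset({"SELP", "BKG1"}))
    for _ in range(10):
        t = _random_table(rng)
        shortlist, trace = run_prioritization(t, family_pedigree, cfg)
        # manual composition in stage order
        manual = filter_segregation(t, family_pedigree, cfg)
        for stage in (filter_consequence, filter_rarity, filter_deleteriousness,
                      filter_blacklist, filter_gene_panel):
            manual = stage(manual, cfg)
        assert keys(shortlist) == keys(manual)
        # independent brute-force predicate oracle
        assert keys(shortlist) == {str(r.key) for r in t if _oracle_keep(r, cfg)}
        # trace is monotone in both columns
        assert trace.snv_counts == sorted(trace.snv_counts, reverse=True)
        assert trace.indel_counts == sorted(trace.indel_counts, reverse=True)


def test_each_stage_is_idempotent(family_pedigree):
    rng = np.random.default_rng(7)
    cfg = config(blacklist=frozenset({"TTN"}), gene_panel=frozenset({"SELP"}))
    t = _random_table(rng, n=60)
    seg = filter_segregation(t, family_pedigree, cfg)
    assert keys(filter_segregation(seg, family_pedigree, cfg)) == keys(seg)
    for stage in (filter_consequence, filter_rarity, filter_deleteriousness,
                  filter_blacklist, filter_gene_panel):
        once = stage(t, cfg)
        assert keys(stage(once, cfg)) == keys(once)


def test_all_benign_table_gives_empty_shortlist_and_monotone_trace(family_pedigree):
    records = [
        make_record(100 + i, "HHH000", consequence=Consequence.SYNONYMOUS)
        for i in range(10)
    ]
    shortlist, trace = run_prioritization(table(*records), family_pedigree, config())
    assert len(shortlist) == 0
    assert trace.snv_counts[0] == 10 and trace.snv_counts[-1] == 0


def test_constructed_survivor_counts_appear_in_trace(family_pedigree):
    """Fixture built stage-by-stage with known survivors: 20 in, then
    12, 8, 5, 4, 3, 1 after the successive stages."""
    panel = frozenset({"KEEP"})
    blacklist = frozenset({"BAD"})
    recs = []
    pos = iter(range(100, 10000, 10))
    # 8 fail segregation
    for _ in range(8):
        recs.append(make_record(next(pos), "HHHH00", gene="KEEP"))
    # 4 fail consequence
    for _ in range(4):
        recs.append(make_record(next(pos), "HHH000", gene="KEEP",
                                consequence=Consequence.SYNONYMOUS))
    # 3 fail rarity
    for _ in range(3):
        recs.append(make_record(next(pos), "HHH000", gene="KEEP", aaf=0.3))
    # 1 fails deleteriousness
    recs.append(make_record(next(pos), "HHH000", gene="KEEP", cadd=3.0, aaf=0.001))
    # 1 fails blacklist
    recs.append(make_record(next(pos), "HHH000", gene="BAD", aaf=0.001))
    # 2 fail panel
    for _ in range(2):
        recs.append(make_record(next(pos), "HHH000", gene="OTHER", aaf=0.001))
    # 1 survives everything
    recs.append(make_record(next(pos), "HHH000", gene="KEEP", aaf=0.001))
    cfg = config(blacklist=blacklist, gene_panel=panel)
    shortlist, trace = run_prioritization(table(*recs), family_pedigree, cfg)
    assert trace.snv_counts == [20, 12, 8, 5, 4, 3, 1]
    assert len(shortlist) == 1
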