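"""Reported summary counts from the Malta Osteoporotic Fracture Study (MOFS).

MOFS is a case-control collection of 1045 Maltese postmenopausal women:
fracture cases plus non-fracture controls stratified by BMD T-score into
normal, osteopenic and osteoporotic subgroups. Three rare missense
variants shortlisted from a familial osteoporosis pedigree — *SELP*
c.2177T>C, *TGF-β2* c.1136C>T and *ADAMTS20* c.4090A>T — were genotyped
across the collection.

Individual-level MOFS data are not public; what is reproducible from the
published record are the statistics recomputable from its summary counts.
This module carries those counts so the replication statistics can be
recomputed from scratch: genotype counts per subgroup, the 2x2 cell sets
of the BMD/fracture odds-ratio analyses, and the serum-calcium tertile
cell sets. All counts are inputs, not results.
"""

from __future__ import annotations

VARIANTS = ("SELP", "TGFB2", "ADAMTS20")

#: genotype counts (hom-ref, het, hom-alt) per variant and subgroup;
#: "osteopenic"/"osteoporotic" are non-fracture women classified by BMD
GENOTYPE_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "SELP": {
        "normal": (226, 3, 0),
        "osteopenic": (259, 3, 4),
        "osteoporotic": (280, 1, 1),
        "fracture": (263, 4, 1),
        "whole": (1028, 11, 6),
    },
    "TGFB2": {
        "normal": (228, 1, 0),
        "osteopenic": (265, 1, 0),
        "osteoporotic": (282, 0, 0),
        "fracture": (265, 3, 0),
        "whole": (1040, 5, 0),
    },
    "ADAMTS20": {
        "normal": (205, 13, 0),
        "osteopenic": (247, 11, 0),
        "osteoporotic": (258, 18, 0),
        "fracture": (245, 15, 0),
        "whole": (955, 57, 0),
    },
}

#: 2x2 cell sets (a, b, c, d) for the crude odds-ratio analyses, laid out
#: [[a, b], [c, d]] with rows = genotype class (reference first) and
#: columns = (control, case); OR = (a*d)/(b*c). Outcomes: low BMD
#: (osteopenia + osteoporosis) at each site among non-fracture women, and
#: all-type / wrist low-trauma fracture versus all non-fracture women.
OR_CELLS: dict[str, tuple[int, int, int, int]] = {
    "selp_ls": (331, 4, 434, 8),
    "adamts20_ls": (301, 409, 20, 22),
    "selp_fn": (318, 6, 447, 6),
    "adamts20_fn": (293, 16, 417, 26),
    "selp_th": (459, 8, 306, 4),
    "adamts20_th": (426, 24, 284, 18),
    "selp_fracture": (765, 12, 263, 5),
    "adamts20_fracture": (710, 42, 245, 15),
    "adamts20_wrist": (710, 42, 107, 7),
}

#: serum-calcium tertile analysis for ADAMTS20: (n_hom_ref, n_het) per
#: tertile of the control-anchored calcium distribution; the highest
#: tertile is the reference stratum
CALCIUM_TERTILE_COUNTS: dict[str, tuple[int, int]] = {
    "highest": (342, 10),
    "intermediate": (285, 25),
    "lowest": (328, 22),
}


def tertile_or_cells(tertile: str) -> tuple[int, int, int, int]:
    """2x2 cells (a, b, c, d) contrasting a tertile against the reference
    (highest) tertile: rows = tertile, columns = genotype (hom-ref, het)."""
    if tertile == "highest":
        raise ValueError("highest tertile is the reference stratum")
    a, b = CALCIUM_TERTILE_COUNTS["highest"]
    c, d = CALCIUM_TERTILE_COUNTS[tertile]
    return (a, b, c, d)
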