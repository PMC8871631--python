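"""Assembly of the replication-statistics report tables.

:func:`association_report` computes, from a cohort of subjects:

* genotype and allele frequencies per variant and subgroup;
* the exact Hardy-Weinberg test in the normal-BMD control group;
* carrier-collapsed crude and adjusted odds ratios for low BMD at each
  site (among non-fracture women), all-type fracture and wrist fracture;
* genotype-phenotype medians with Mann-Whitney tests in normal-BMD
  controls;
* odds ratios across control-anchored tertiles of the biochemical
  phenotypes.

:func:`render_report` writes the tables as TSV files with the display
rounding used throughout (odds ratios and CI bounds to 2 decimal places,
frequencies to 3, half-up); analyses that cannot be computed (zero
carriers, fewer carriers than the regression minimum) are rendered "NC"
with a footnote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import CohortSubject, FilterTrace, Subgroup, Zygosity
from .stats import (
    FreqTable,
    Tertile,
    assign_tertiles,
    genotype_allele_frequencies,
    hwe_exact_test,
    logistic_fit,
    mann_whitney_u,
    tertile_spec,
    two_by_two_or,
)

BMD_SITES = ("ls", "fn", "th")
BIOCHEM_PHENOS = ("calcium", "alp", "albumin")


@dataclass
class AssociationConfig:
    variants: tuple[str, ...] = ("SELP", "TGFB2", "ADAMTS20")
    #: pool het and hom-alt into one carrier exposure class
    carrier_collapse: bool = True
    #: fewer informative carriers than this skips regression for a variant
    min_carriers: int = 6
    alpha: float = 0.05


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding for display (3.005 -> 3.01 at 2 d.p.)."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _carrier(subject: CohortSubject, variant: str, collapse: bool) -> int | None:
    zyg = subject.genotypes.get(variant, Zygosity.MISSING)
    if zyg is Zygosity.MISSING:
        return None
    if collapse:
        return int(zyg.is_carrier)
    return zyg.alt_count


def _low_at_site(subject: CohortSubject, site: str) -> bool | None:
    t = getattr(subject, f"{site}_t")
    if t is None:
        return None
    return t < -1.0


def _or_row(variant: str, outcome: str, cells, result, note: str = "") -> dict:
    return {
        "variant": variant,
        "outcome": outcome,
        "n_ref_control": cells[0],
        "n_ref_case": cells[1],
        "n_carrier_control": cells[2],
        "n_carrier_case": cells[3],
        "or": result.or_estimate if result else float("nan"),
        "ci_low": result.ci_low if result else float("nan"),
        "ci_high": result.ci_high if result else float("nan"),
        "p": result.p_wald if result else float("nan"),
        "note": note,
    }


def association_report(
    cohort: Sequence[CohortSubject],
    variants: Sequence[str] | None = None,
    config: AssociationConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Compute the full set of replication tables (see module docstring).

    Returns a dict of DataFrames keyed ``frequencies``, ``hwe``,
    ``odds_ratios``, ``phenotypes``, ``tertiles``.
    """
    config = config or AssociationConfig()
    if variants is not None:
        config = AssociationConfig(
            variants=tuple(variants),
            carrier_collapse=config.carrier_collapse,
            min_carriers=config.min_carriers,
            alpha=config.alpha,
        )
    cohort = list(cohort)
    normals = [s for s in cohort if s.subgroup is Subgroup.NORMAL]
    non_fracture = [s for s in cohort if s.subgroup is not Subgroup.FRACTURE]

    # -- frequencies and HWE -------------------------------------------------
    freq_rows = []
    hwe_rows = []
    for variant in config.variants:
        for subgroup in list(Subgroup) + [None]:
            ft = genotype_allele_frequencies(cohort, variant, subgroup)
            freq_rows.append(
                {
                    "variant": variant,
                    "subgroup": subgroup.value if subgroup else "whole",
                    "n_hom_ref": ft.n_hom_ref,
                    "n_het": ft.n_het,
                    "n_hom_alt": ft.n_hom_alt,
                    "aaf": ft.aaf,
                }
            )
        ft = genotype_allele_frequencies(cohort, variant, Subgroup.NORMAL)
        if ft.n_total:
            hwe = hwe_exact_test(ft.n_hom_ref, ft.n_het, ft.n_hom_alt)
            hwe_rows.append(
                {"variant": variant, "subgroup": "normal", "p_exact": hwe.p_exact}
            )

    # -- odds ratios ----------------------------------------------------------
    or_rows = []
    for variant in config.variants:
        outcomes: list[tuple[str, list[CohortSubject], list[bool]]] = []
        for site in BMD_SITES:
            pool, flags = [], []
            for s in non_fracture:
                low = _low_at_site(s, site)
                if low is not None:
                    pool.append(s)
                    flags.append(low)
            outcomes.append((f"low_bmd_{site}", pool, flags))
        outcomes.append(
            (
                "fracture_all",
                cohort,
                [s.subgroup is Subgroup.FRACTURE for s in cohort],
            )
        )
        wrist_pool = [
            s
            for s in cohort
            if s.subgroup is not Subgroup.FRACTURE or "wrist" in s.fracture_sites
        ]
        outcomes.append(
            ("fracture_wrist", wrist_pool, [bool(s.fracture_sites) for s in wrist_pool])
        )
        for outcome_name, pool, case_flags in outcomes:
            exposures, cases = [], []
            for s, flag in zip(pool, case_flags):
                e = _carrier(s, variant, config.carrier_collapse)
                if e is not None:
                    exposures.append(min(e, 1))
                    cases.append(int(flag))
            exposures_arr = np.array(exposures)
            cases_arr = np.array(cases)
            a = int(((exposures_arr == 0) & (cases_arr == 0)).sum())
            b = int(((exposures_arr == 0) & (cases_arr == 1)).sum())
            c = int(((exposures_arr == 1) & (cases_arr == 0)).sum())
            d = int(((exposures_arr == 1) & (cases_arr == 1)).sum())
            n_carriers = c + d
            if n_carriers == 0:
                or_rows.append(
                    _or_row(variant, outcome_name, (a, b, c, d), None, "no_carriers")
                )
                continue
            if n_carriers < config.min_carriers:
                or_rows.append(
                    _or_row(
                        variant, outcome_name, (a, b, c, d), None, "skipped_low_carriers"
                    )
                )
                continue
            crude = two_by_two_or(a, b, c, d, alpha=config.alpha)
            row = _or_row(variant, outcome_name, (a, b, c, d), crude)
            # adjusted model: age for BMD outcomes; age + site BMD for fractures
            covariates = {"age": []}
            extra = BMD_SITES if outcome_name.startswith("fracture") else ()
            for site in extra:
                covariates[f"{site}_bmd"] = []
            ys, es = [], []
            for s, flag in zip(pool, case_flags):
                e = _carrier(s, variant, config.carrier_collapse)
                covs = [s.age] + [getattr(s, f"{site}_bmd") for site in extra]
                if e is None or any(v is None for v in covs):
                    continue
                ys.append(int(flag))
                es.append(min(e, 1))
                covariates["age"].append(s.age)
                for site in extra:
                    covariates[f"{site}_bmd"].append(getattr(s, f"{site}_bmd"))
            try:
                fit = logistic_fit(ys, es, covariates, alpha=config.alpha)
                term = fit.term("exposure")
                row["adj_or"] = term.odds_ratio
                row["adj_ci_low"] = term.ci_low
                row["adj_ci_high"] = term.ci_high
                row["adj_p"] = term.p_value
            except ValueError:
                row["note"] = (row["note"] + ";adjusted_not_computable").strip(";")
            or_rows.append(row)

    # -- genotype-phenotype comparisons in normal-BMD controls ----------------
    pheno_rows = []
    for variant in config.variants:
        for pheno in ("ls_bmd", "fn_bmd", "th_bmd") + BIOCHEM_PHENOS:
            ref_vals, car_vals = [], []
            for s in normals:
                e = _carrier(s, variant, config.carrier_collapse)
                value = getattr(s, pheno)
                if e is None or value is None:
                    continue
                (car_vals if e else ref_vals).append(value)
            row = {
                "variant": variant,
                "phenotype": pheno,
                "n_ref": len(ref_vals),
                "n_carrier": len(car_vals),
                "median_ref": float(np.median(ref_vals)) if ref_vals else float("nan"),
                "median_carrier": float(np.median(car_vals)) if car_vals else float("nan"),
                "p_mannwhitney": float("nan"),
                "note": "",
            }
            if len(car_vals) >= config.min_carriers and ref_vals:
                _, p = mann_whitney_u(ref_vals, car_vals)
                row["p_mannwhitney"] = p
            else:
                row["note"] = "skipped_low_carriers"
            pheno_rows.append(row)

    # -- biochemical tertiles --------------------------------------------------
    tertile_rows = []
    for variant in config.variants:
        for pheno in BIOCHEM_PHENOS:
            reference = [
                getattr(s, pheno) for s in normals if getattr(s, pheno) is not None
            ]
            if len(set(reference)) < 3:
                continue
            spec = tertile_spec(reference)
            strata: dict[Tertile, list[CohortSubject]] = {t: [] for t in Tertile}
            for s in cohort:
                value = getattr(s, pheno)
                if value is not None:
                    strata[spec.label(value)].append(s)

            def counts(tertile: Tertile) -> tuple[int, int]:
                n_ref = n_car = 0
                for s in strata[tertile]:
                    e = _carrier(s, variant, config.carrier_collapse)
                    if e == 0:
                        n_ref += 1
                    elif e:
                        n_car += 1
                return n_ref, n_car

            a, b = counts(Tertile.HIGHEST)
            for tertile in (Tertile.INTERMEDIATE, Tertile.LOWEST):
                c, d = counts(tertile)
                row = {
                    "variant": variant,
                    "phenotype": pheno,
                    "tertile": tertile.value,
                    "boundary_low": spec.boundaries[0],
                    "boundary_high": spec.boundaries[1],
                    "n_ref_reference_tertile": a,
                    "n_carrier_reference_tertile": b,
                    "n_ref": c,
                    "n_carrier": d,
                    "note": "",
                }
                if min(b + d, 1) == 0 or (b + d) < config.min_carriers:
                    row.update(
                        {"or": float("nan"), "ci_low": float("nan"),
                         "ci_high": float("nan"), "p": float("nan"),
                         "note": "skipped_low_carriers"}
                    )
                else:
                    res = two_by_two_or(a, b, c, d, alpha=config.alpha)
                    row.update(
                        {"or": res.or_estimate, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "p": res.p_wald}
                    )
                    # adjusted: this tertile vs reference, age + supplements
                    ys, es, ages, supp = [], [], [], []
                    for s in strata[Tertile.HIGHEST] + strata[tertile]:
                        e = _carrier(s, variant, config.carrier_collapse)
                        if e is None or s.age is None:
                            continue
                        ys.append(int(spec.label(getattr(s, pheno)) is tertile))
                        es.append(min(e, 1))
                        ages.append(s.age)
                        supp.append(int(s.calcium_supplement))
                    try:
                        fit = logistic_fit(
                            ys, es, {"age": ages, "supplement": supp}, alpha=config.alpha
                        )
                        term = fit.term("exposure")
                        row["adj_or"] = term.odds_ratio
                        row["adj_p"] = term.p_value
                    except ValueError:
                        row["note"] = "adjusted_not_computable"
                tertile_rows.append(row)

    return {
        "frequencies": pd.DataFrame(freq_rows),
        "hwe": pd.DataFrame(hwe_rows),
        "odds_ratios": pd.DataFrame(or_rows),
        "phenotypes": pd.DataFrame(pheno_rows),
        "tertiles": pd.DataFrame(tertile_rows),
    }


# ---------------------------------------------------------------------------
# rendering

_NC_FOOTNOTE = "# NC = not computable (no or too few carriers for analysis)\n"


def _format_df(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        ndigits = 3 if col in ("aaf", "p", "adj_p", "p_exact", "p_mannwhitney") else 2
        out[col] = out[col].map(
            lambda x: "NC" if isinstance(x, float) and math.isnan(x) else f"{round_half_up(x, ndigits):.{ndigits}f}"
        )
    return out


def render_report(
    outdir,
    trace: FilterTrace | None = None,
    tables: dict[str, pd.DataFrame] | None = None,
) -> list[Path]:
    """Write the filter trace and association tables as TSV files.

    Emits ``trace.tsv`` plus ``frequencies.tsv``, ``hwe.tsv``,
    ``odds_ratios.tsv``, ``phenotypes.tsv`` and ``tertiles.tsv`` (for the
    tables provided). Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if trace is not None:
        from .io import write_filter_trace

        path = outdir / "trace.tsv"
        write_filter_trace(trace, path)
        written.append(path)
    for name, df in (tables or {}).items():
        path = outdir / f"{name}.tsv"
        rendered = _format_df(df)
        with open(path, "w") as fh:
            if any("NC" in rendered[c].astype(str).values for c in rendered.columns):
                fh.write(_NC_FOOTNOTE)
            rendered.to_csv(fh, sep="\t", index=False)
        written.append(path)
    return written
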