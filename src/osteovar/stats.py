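"""Case-control replication statistics.

Genotype/allele frequencies, the exact Hardy-Weinberg test, 2x2 odds
ratios with Wald confidence intervals, Mann-Whitney genotype-phenotype
comparisons, control-anchored tertiles, logistic regression and WHO-style
BMD classification.

Conventions
-----------
* 2x2 tables are laid out rows = exposure (row 1 reference, row 2 exposed),
  columns = outcome (column 1 control, column 2 case); the odds ratio is
  the cross-product ``(a*d)/(b*c)`` for cells ``[[a, b], [c, d]]``, i.e.
  the odds of being a case among the exposed over the reference row.
* Confidence intervals and p-values for odds ratios are Wald on the log
  scale; no continuity correction unless requested.
* Tertile boundaries use linear-interpolation quantiles (numpy default,
  "type 7") of the reference distribution; values on a boundary go to the
  lower interval.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .model import CohortSubject, Subgroup, Zygosity

Z_95 = sps.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# frequencies

@dataclass(frozen=True)
class FreqTable:
    """Genotype counts and the implied alternative allele frequency."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    subgroup: str = ""

    def __post_init__(self) -> None:
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def aaf(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return (self.n_het + 2 * self.n_hom_alt) / (2 * self.n_total)

    def fractions(self) -> tuple[float, float, float]:
        n = self.n_total
        return (self.n_hom_ref / n, self.n_het / n, self.n_hom_alt / n)


def genotype_allele_frequencies(
    cohort: Sequence[CohortSubject],
    variant_name: str,
    subgroup_filter: Subgroup | None = None,
) -> FreqTable:
    """Genotype counts and AAF for one variant, optionally within a subgroup.

    Subjects with a missing genotype are excluded from the denominator.
    """
    counts = {Zygosity.HOM_REF: 0, Zygosity.HET: 0, Zygosity.HOM_ALT: 0}
    for s in cohort:
        if subgroup_filter is not None and s.subgroup is not subgroup_filter:
            continue
        zyg = s.genotypes.get(variant_name, Zygosity.MISSING)
        if zyg is not Zygosity.MISSING:
            counts[zyg] += 1
    return FreqTable(
        counts[Zygosity.HOM_REF],
        counts[Zygosity.HET],
        counts[Zygosity.HOM_ALT],
        subgroup=subgroup_filter.value if subgroup_filter else "all",
    )


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test

@dataclass(frozen=True)
class HWEResult:
    p_exact: float
    observed: tuple[int, int, int]
    allele_counts: tuple[int, int]


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> HWEResult:
    """Exact Hardy-Weinberg test conditional on the observed allele counts.

    Enumerates every heterozygote count compatible with the allele totals
    and sums the conditional probabilities of configurations no more likely
    than the observed one (the exact test of Wigginton, Cutler & Abecasis).
    A monomorphic sample gives p = 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("empty sample")
    n_alt = n_het + 2 * n_hom_alt
    n_ref = 2 * n - n_alt
    rare = min(n_alt, n_ref)
    if rare == 0:
        return HWEResult(1.0, (n_hom_ref, n_het, n_hom_alt), (n_ref, n_alt))

    # log P(het = h | n, allele counts), up to a constant shared by all h
    def log_weight(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            h * math.log(2)
            - gammaln(h + 1)
            - gammaln(hom_rare + 1)
            - gammaln(hom_common + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = np.array([log_weight(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[list(hets).index(n_het)]
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return HWEResult(min(p, 1.0), (n_hom_ref, n_het, n_hom_alt), (n_ref, n_alt))


# ---------------------------------------------------------------------------
# 2x2 odds ratios

@dataclass(frozen=True)
class TwoByTwoResult:
    or_estimate: float
    ci_low: float
    ci_high: float
    p_wald: float
    cells: tuple[float, float, float, float]

    @property
    def finite(self) -> bool:
        return math.isfinite(self.or_estimate) and math.isfinite(self.ci_low)


def two_by_two_or(
    a: float,
    b: float,
    c: float,
    d: float,
    alpha: float = 0.05,
    continuity_correction: float = 0.0,
) -> TwoByTwoResult:
    """Odds ratio with Wald CI and p for the table ``[[a, b], [c, d]]``.

    Rows are exposure (reference, exposed), columns outcome (control,
    case): OR = (a*d)/(b*c). Any zero cell gives a non-finite estimate
    unless ``continuity_correction`` (e.g. the Haldane-Anscombe 0.5) is
    added to every cell.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    cells = (a, b, c, d)
    if continuity_correction and 0 in cells:
        a, b, c, d = (x + continuity_correction for x in cells)
    if 0 in (a, b, c, d):
        return TwoByTwoResult(float("nan"), float("nan"), float("nan"), float("nan"), cells)
    or_est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z_crit = sps.norm.ppf(1 - alpha / 2)
    log_or = math.log(or_est)
    ci_low = math.exp(log_or - z_crit * se)
    ci_high = math.exp(log_or + z_crit * se)
    p = 2 * sps.norm.sf(abs(log_or) / se)
    return TwoByTwoResult(or_est, ci_low, ci_high, float(p), cells)


# ---------------------------------------------------------------------------
# Mann-Whitney U

def _u_statistic(values_a: np.ndarray, values_b: np.ndarray) -> float:
    pooled = np.concatenate([values_a, values_b])
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    n_a = len(values_a)
    r_a = ranks[:n_a].sum()
    return float(r_a - n_a * (n_a + 1) / 2)


def mann_whitney_u(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exact_limit: int = 16,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with mid-rank tie handling.

    For pooled samples of at most ``exact_limit`` observations the null
    distribution of U is enumerated exactly over all group assignments
    (ties included); larger samples use the normal approximation with the
    tie-corrected variance. The two-sided p is the null probability of a U
    at least as far from its mean n_a*n_b/2 as the observed one, which
    reduces to the usual doubled one-sided p for tie-free data.

    Returns ``(U_of_first_group, p_two_sided)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    u_obs = _u_statistic(a, b)
    if np.ptp(pooled) == 0:
        return u_obs, 1.0
    n_a, n_b = a.size, b.size
    mu = n_a * n_b / 2
    if n_a + n_b <= exact_limit:
        ranks = sps.rankdata(pooled)
        offset = n_a * (n_a + 1) / 2
        dev_obs = abs(u_obs - mu)
        n_extreme = 0
        n_total = 0
        for idx in combinations(range(n_a + n_b), n_a):
            u = ranks[list(idx)].sum() - offset
            n_total += 1
            if abs(u - mu) >= dev_obs - 1e-9:
                n_extreme += 1
        return u_obs, n_extreme / n_total
    # tie-corrected normal approximation (no continuity correction, to stay
    # consistent with the tie-corrected variance)
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n_a * n_b / 12 * (n + 1 - tie_term)
    z = (u_obs - mu) / math.sqrt(var)
    return u_obs, float(2 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# tertiles

class Tertile(enum.Enum):
    LOWEST = "lowest"
    INTERMEDIATE = "intermediate"
    HIGHEST = "highest"


@dataclass(frozen=True)
class TertileSpec:
    """Two cut points anchored in a reference distribution."""

    boundaries: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.boundaries[0] < self.boundaries[1]:
            raise ValueError("tertile boundaries must be strictly increasing")

    def label(self, value: float) -> Tertile:
        if value <= self.boundaries[0]:
            return Tertile.LOWEST
        if value <= self.boundaries[1]:
            return Tertile.INTERMEDIATE
        return Tertile.HIGHEST


def tertile_spec(reference_values: Sequence[float]) -> TertileSpec:
    ref = np.asarray(reference_values, dtype=float)
    if np.unique(ref).size < 3:
        raise ValueError("reference distribution needs >= 3 distinct values")
    lo, hi = np.quantile(ref, [1 / 3, 2 / 3])  # linear interpolation (type 7)
    if not lo < hi:
        raise ValueError("degenerate reference distribution for tertiles")
    return TertileSpec((float(lo), float(hi)))


def assign_tertiles(
    reference_values: Sequence[float], all_values: Sequence[float]
) -> list[Tertile]:
    """Label each value by its tertile of the reference distribution."""
    spec = tertile_spec(reference_values)
    return [spec.label(v) for v in np.asarray(all_values, dtype=float)]


# ---------------------------------------------------------------------------
# logistic regression

@dataclass(frozen=True)
class LogisticTerm:
    name: str
    coef: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class LogisticFit:
    terms: tuple[LogisticTerm, ...]
    converged: bool
    separation: bool

    def term(self, name: str) -> LogisticTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def logistic_fit(
    outcome: Sequence[int],
    exposure: Sequence[float],
    covariates: Mapping[str, Sequence[float]] | None = None,
    alpha: float = 0.05,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome on an
    exposure plus optional covariates, with Wald ORs/CIs per term.

    A diverging exposure coefficient (complete or quasi-separation) is
    flagged and its CI reported non-finite.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    cols = {"exposure": np.asarray(exposure, dtype=float)}
    for name, vals in (covariates or {}).items():
        cols[name] = np.asarray(vals, dtype=float)
    design = np.column_stack([np.ones_like(y)] + list(cols.values()))
    names = ["intercept"] + list(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    with np.errstate(all="ignore"):
        model = sm.Logit(y, design)
        try:
            res = model.fit(disp=0, maxiter=100, tol=1e-10)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            res = model.fit(method="bfgs", disp=0, maxiter=200)
            converged = False
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
    z_crit = sps.norm.ppf(1 - alpha / 2)
    separation = bool(np.any(np.abs(params) > 15) or not converged)
    terms = []
    for name, beta, se in zip(names, params, bse):
        blown = separation and abs(beta) > 15
        if blown or not math.isfinite(se) or se <= 0:
            terms.append(
                LogisticTerm(name, float(beta), float("nan"), float("nan"), float("nan"), float("nan"))
            )
            continue
        terms.append(
            LogisticTerm(
                name,
                float(beta),
                math.exp(beta),
                math.exp(beta - z_crit * se),
                math.exp(beta + z_crit * se),
                float(2 * sps.norm.sf(abs(beta) / se)),
            )
        )
    return LogisticFit(tuple(terms), converged, separation)


# ---------------------------------------------------------------------------
# BMD classification

class BMDCategory(enum.Enum):
    NORMAL = "normal"
    OSTEOPENIA = "osteopenia"
    OSTEOPOROSIS = "osteoporosis"


class ScoreBasis(enum.Enum):
    T_SCORE = "t_score"
    Z_SCORE = "z_score"


@dataclass(frozen=True)
class BMDStatus:
    status: BMDCategory
    basis: ScoreBasis


def classify_bmd_status(
    t_scores: Mapping[str, float],
    z_scores: Mapping[str, float],
    age: float,
    postmenopausal: bool = False,
) -> BMDStatus:
    """WHO-style BMD classification at the spine/femoral-neck sites.

    Postmenopausal women and anyone over 50 are graded on T-scores
    (osteoporosis T <= -2.5, osteopenia -2.5 < T < -1.0, else normal);
    younger subjects are graded on Z-scores (osteoporosis Z <= -2.0),
    falling back to the T-score osteopenia/normal cutoffs otherwise.
    The worst available site governs.
    """
    t_scores = {k: v for k, v in t_scores.items() if v is not None}
    z_scores = {k: v for k, v in z_scores.items() if v is not None}
    if not t_scores and not z_scores:
        raise ValueError("no BMD scores provided")
    use_t = postmenopausal or age > 50

    def t_grade() -> BMDCategory:
        worst = min(t_scores.values())
        if worst <= -2.5:
            return BMDCategory.OSTEOPOROSIS
        if worst < -1.0:
            return BMDCategory.OSTEOPENIA
        return BMDCategory.NORMAL

    if use_t:
        if not t_scores:
            raise ValueError("T-score basis requested but no T-scores given")
        return BMDStatus(t_grade(), ScoreBasis.T_SCORE)
    if z_scores and min(z_scores.values()) <= -2.0:
        return BMDStatus(BMDCategory.OSTEOPOROSIS, ScoreBasis.Z_SCORE)
    if t_scores:
        grade = t_grade()
        if grade is BMDCategory.OSTEOPOROSIS:
            grade = BMDCategory.OSTEOPENIA  # T <= -2.5 alone is not diagnostic pre-50
        return BMDStatus(grade, ScoreBasis.Z_SCORE)
    return BMDStatus(BMDCategory.NORMAL, ScoreBasis.Z_SCORE)
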