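"""Pairwise comorbidity risk combinatorics for case-control cohorts.

Implements the supervised stage: preprocessing filters, the *pairwise
overall test* (odds ratio of the outcome for carrying both members of a
comorbidity pair versus everyone else), the *pairwise directionality
test* (the doubly-exposed group against each singly-exposed group),
Benjamini-Hochberg FDR correction within each test family, and
cross-dataset replication matching.

Odds ratios use the cross-product ratio with a Haldane-Anscombe 0.5
continuity correction when any cell is zero; 95% confidence intervals
are Woolf logit intervals on the (possibly corrected) cells; p-values
come from the two-sided Fisher exact test on the uncorrected counts
(a chi-square alternative is switchable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortMatrix
from .errors import ComputationError, DataValidationError

__all__ = [
    "TwoByTwo",
    "OrResult",
    "PairRiskResult",
    "ReplicatedPairSet",
    "odds_ratio_ci",
    "bh_adjust",
    "filter_zero_comorbidity_patients",
    "filter_low_prevalence",
    "pairwise_overall_test",
    "pairwise_directionality_test",
    "replicate_pairs",
    "single_comorbidity_or",
    "cohort_summary",
    "results_to_table",
]


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 outcome-by-exposure counts.

    a = exposed cases, b = exposed controls,
    c = unexposed cases, d = unexposed controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataValidationError("2x2 counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise DataValidationError("2x2 table is empty")


@dataclass
class OrResult:
    """Odds ratio with Woolf 95% CI and (raw, FDR-adjusted) p-values."""

    or_point: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_fdr: float | None = None

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_fdr is not None and self.p_fdr < alpha


@dataclass
class PairRiskResult:
    """All test results for one unordered comorbidity pair (one table row)."""

    comorbidity_a: str
    comorbidity_b: str
    overall: OrResult | None
    ab_vs_a: OrResult | None = None
    ab_vs_b: OrResult | None = None
    significant_overall: bool = False
    direction_pattern: str | None = None  # both | a_only | b_only | neither

    @property
    def key(self) -> frozenset:
        return frozenset((self.comorbidity_a, self.comorbidity_b))


@dataclass
class ReplicatedPairSet:
    """Pairs significant in both datasets with identical risk direction."""

    pairs: list[tuple[str, str, PairRiskResult, PairRiskResult]]
    unique_comorbidities: set[str] = field(default_factory=set)


def odds_ratio_ci(
    t: TwoByTwo, alpha: float = 0.05, p_method: str = "fisher"
) -> OrResult:
    """Cross-product OR, Woolf CI, and a two-sided exact p-value.

    When any cell is zero, 0.5 is added to every cell (Haldane-Anscombe)
    for the OR and CI; the p-value always uses the uncorrected counts.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ComputationError(
            f"odds ratio undefined: degenerate margin in table {(a, b, c, d)}"
        )
    if min(a, b, c, d) == 0:
        af, bf, cf, df = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        af, bf, cf, df = float(a), float(b), float(c), float(d)
    or_point = (af * df) / (bf * cf)
    z = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / af + 1 / bf + 1 / cf + 1 / df)
    ci_low = math.exp(math.log(or_point) - z * se)
    ci_high = math.exp(math.log(or_point) + z * se)
    if p_method == "fisher":
        _, p_raw = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    elif p_method == "chi2":
        chi2 = stats.chi2_contingency([[a, b], [c, d]], correction=False)
        p_raw = chi2.pvalue
    else:
        raise DataValidationError(f"unknown p_method {p_method!r}")
    return OrResult(or_point, ci_low, ci_high, float(p_raw))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_zero_comorbidity_patients(cohort: CohortMatrix) -> CohortMatrix:
    """Drop patients carrying none of the comorbidities; order preserved."""
    return cohort.subset_patients(cohort.X.sum(axis=1) > 0)


def filter_low_prevalence(
    cohort: CohortMatrix,
    threshold: float = 0.01,
    mode: str = "individual",
) -> tuple[CohortMatrix, list[str]]:
    """Remove low-prevalence comorbidity columns, then newly-empty patients.

    ``mode="individual"`` (default) removes every column whose own
    prevalence is below ``threshold``.  ``mode="combined"`` removes the
    largest prefix of prevalence-ascending columns whose *union* of
    carriers stays below ``threshold`` of patients (the literal reading of
    "together occurred in less than 1%").  Removed labels are returned
    sorted by prevalence ascending.
    """
    if not 0 < threshold < 1:
        raise DataValidationError("threshold must lie in (0, 1)")
    if cohort.n_patients == 0:
        raise DataValidationError("cohort is empty")
    prev = cohort.X.mean(axis=0)
    order = np.argsort(prev, kind="stable")
    if mode == "individual":
        removed_idx = [int(i) for i in order if prev[i] < threshold]
    elif mode == "combined":
        removed_idx = []
        union = np.zeros(cohort.n_patients, dtype=bool)
        for i in order:
            trial = union | cohort.X[:, i].astype(bool)
            if trial.mean() < threshold:
                removed_idx.append(int(i))
                union = trial
            else:
                break
    else:
        raise DataValidationError(f"unknown prevalence filter mode {mode!r}")
    removed = [cohort.comorbidity_names[i] for i in removed_idx]
    keep = [n for n in cohort.comorbidity_names if n not in removed]
    out = cohort.subset_comorbidities(keep)
    out = filter_zero_comorbidity_patients(out)
    return out, removed


def _pair_tables(cohort: CohortMatrix) -> dict[tuple[int, int], TwoByTwo]:
    """Overall-test 2x2 tables for every unordered column pair via matmul."""
    case = cohort.is_case
    Xc = cohort.X[case].astype(np.int64)
    Xn = cohort.X[~case].astype(np.int64)
    co_case = Xc.T @ Xc
    co_ctrl = Xn.T @ Xn
    n_cases, n_ctrl = Xc.shape[0], Xn.shape[0]
    k = cohort.n_comorbidities
    tables = {}
    for i in range(k):
        for j in range(i + 1, k):
            a = int(co_case[i, j])
            b = int(co_ctrl[i, j])
            tables[(i, j)] = TwoByTwo(a, b, n_cases - a, n_ctrl - b)
    return tables


def pairwise_overall_test(
    cohort: CohortMatrix, alpha: float = 0.05, p_method: str = "fisher"
) -> list[PairRiskResult]:
    """OR of the outcome for carrying both members of each pair vs the rest.

    FDR (Benjamini-Hochberg) is applied over the full family of testable
    pairs; degenerate pairs (a margin of zero) are recorded with
    ``overall=None`` and excluded from the family.
    """
    if cohort.n_comorbidities < 2:
        raise DataValidationError("need >= 2 comorbidities")
    if cohort.n_cases == 0 or cohort.n_controls == 0:
        raise DataValidationError("need both cases and controls")
    names = cohort.comorbidity_names
    results: list[PairRiskResult] = []
    testable: list[int] = []
    for (i, j), table in _pair_tables(cohort).items():
        try:
            orr = odds_ratio_ci(table, alpha=alpha, p_method=p_method)
        except ComputationError:
            results.append(PairRiskResult(names[i], names[j], None))
            continue
        testable.append(len(results))
        results.append(PairRiskResult(names[i], names[j], orr))
    if testable:
        adj = bh_adjust([results[idx].overall.p_raw for idx in testable])
        for idx, p in zip(testable, adj):
            results[idx].overall.p_fdr = float(p)
            results[idx].significant_overall = bool(p < alpha)
    return results


def _directional_table(
    cohort: CohortMatrix, first: str, second: str
) -> TwoByTwo:
    """Exposure = has both; reference = has `first` but not `second`."""
    both = cohort.column(first) & cohort.column(second)
    only = cohort.column(first) & ~cohort.column(second)
    case = cohort.is_case
    return TwoByTwo(
        int((both & case).sum()), int((both & ~case).sum()),
        int((only & case).sum()), int((only & ~case).sum()),
    )


def pairwise_directionality_test(
    cohort: CohortMatrix,
    pairs: list[PairRiskResult],
    alpha: float = 0.05,
    p_method: str = "fisher",
) -> list[PairRiskResult]:
    """Attach the two direction sub-tests to overall-significant pairs.

    Sub-test (1) contrasts A&B against A-without-B; sub-test (2) against
    B-without-A (disjoint reference groups).  FDR is applied separately
    within each sub-test family; ``direction_pattern`` records which are
    significant after adjustment.
    """
    fams: dict[str, list[tuple[PairRiskResult, OrResult]]] = {"a": [], "b": []}
    for pr in pairs:
        if not pr.significant_overall:
            raise DataValidationError(
                "directionality test expects overall-significant pairs"
            )
        for which, first, second in (
            ("a", pr.comorbidity_a, pr.comorbidity_b),
            ("b", pr.comorbidity_b, pr.comorbidity_a),
        ):
            table = _directional_table(cohort, first, second)
            try:
                orr = odds_ratio_ci(table, alpha=alpha, p_method=p_method)
            except ComputationError:
                orr = None  # empty reference stratum: untestable
            if which == "a":
                pr.ab_vs_a = orr
            else:
                pr.ab_vs_b = orr
            if orr is not None:
                fams[which].append((pr, orr))
    for fam in fams.values():
        if fam:
            adj = bh_adjust([orr.p_raw for _, orr in fam])
            for (_, orr), p in zip(fam, adj):
                orr.p_fdr = float(p)
    for pr in pairs:
        sig_a = pr.ab_vs_a is not None and pr.ab_vs_a.significant(alpha)
        sig_b = pr.ab_vs_b is not None and pr.ab_vs_b.significant(alpha)
        pr.direction_pattern = (
            "both" if sig_a and sig_b
            else "a_only" if sig_a
            else "b_only" if sig_b
            else "neither"
        )
    return pairs


def _oriented_pattern(pr: PairRiskResult, key_order: tuple[str, str]) -> str:
    """direction_pattern re-expressed relative to a fixed (A, B) ordering."""
    if pr.direction_pattern in (None, "both", "neither"):
        return pr.direction_pattern or "none"
    same = (pr.comorbidity_a, pr.comorbidity_b) == key_order
    if same:
        return pr.direction_pattern
    return "a_only" if pr.direction_pattern == "b_only" else "b_only"


def replicate_pairs(
    train: list[PairRiskResult], repl: list[PairRiskResult]
) -> ReplicatedPairSet:
    """Pairs significant in both datasets with identical direction pattern.

    Patterns are compared after aligning the (A, B) orientation of the two
    result rows; ``neither`` never replicates.
    """
    repl_by_key = {pr.key: pr for pr in repl}
    kept: list[tuple[str, str, PairRiskResult, PairRiskResult]] = []
    for pr in train:
        other = repl_by_key.get(pr.key)
        if other is None or not (pr.significant_overall and other.significant_overall):
            continue
        order = (pr.comorbidity_a, pr.comorbidity_b)
        pat_t = _oriented_pattern(pr, order)
        pat_r = _oriented_pattern(other, order)
        if pat_t == pat_r and pat_t not in ("neither", "none"):
            kept.append((pr.comorbidity_a, pr.comorbidity_b, pr, other))
    uniq = {a for a, _, _, _ in kept} | {b for _, b, _, _ in kept}
    return ReplicatedPairSet(kept, uniq)


def single_comorbidity_or(
    cohort: CohortMatrix, alpha: float = 0.05
) -> dict[str, OrResult]:
    """Per-comorbidity OR of the outcome (carrier vs non-carrier), with FDR."""
    out: dict[str, OrResult] = {}
    case = cohort.is_case
    for name in cohort.comorbidity_names:
        has = cohort.column(name)
        table = TwoByTwo(
            int((has & case).sum()), int((has & ~case).sum()),
            int((~has & case).sum()), int((~has & ~case).sum()),
        )
        try:
            out[name] = odds_ratio_ci(table, alpha=alpha)
        except ComputationError:
            continue
    if out:
        adj = bh_adjust([r.p_raw for r in out.values()])
        for r, p in zip(out.values(), adj):
            r.p_fdr = float(p)
    return out


def cohort_summary(cohort: CohortMatrix) -> dict:
    """Patient counts, per-comorbidity prevalence, median comorbidity count."""
    if cohort.n_patients == 0:
        return {
            "n_patients": 0, "n_cases": 0, "n_controls": 0,
            "prevalence": {}, "median_comorbidities": None,
        }
    row_sums = cohort.X.sum(axis=1)
    return {
        "n_patients": cohort.n_patients,
        "n_cases": cohort.n_cases,
        "n_controls": cohort.n_controls,
        "prevalence": dict(
            zip(cohort.comorbidity_names, cohort.X.mean(axis=0).tolist())
        ),
        "median_comorbidities": float(np.median(row_sums)),
    }


def _fmt(orr: OrResult | None) -> tuple[str, str]:
    if orr is None:
        return "NA", "NA"
    return (
        f"{orr.or_point:.2f} ({orr.ci_low:.2f}-{orr.ci_high:.2f})",
        "NA" if orr.p_fdr is None else f"{orr.p_fdr:.3g}",
    )


def results_to_table(
    results: list[PairRiskResult],
    replicated: ReplicatedPairSet | None = None,
) -> pd.DataFrame:
    """Flat table of pair results mirroring the published layout."""
    repl_keys = (
        {frozenset((a, b)) for a, b, _, _ in replicated.pairs}
        if replicated is not None else set()
    )
    rows = []
    for pr in results:
        o_or, o_p = _fmt(pr.overall)
        a_or, a_p = _fmt(pr.ab_vs_a)
        b_or, b_p = _fmt(pr.ab_vs_b)
        rows.append({
            "comorbidity_a": pr.comorbidity_a,
            "comorbidity_b": pr.comorbidity_b,
            "overall_or_ci": o_or, "overall_fdr_p": o_p,
            "ab_vs_a_or_ci": a_or, "ab_vs_a_fdr_p": a_p,
            "ab_vs_b_or_ci": b_or, "ab_vs_b_fdr_p": b_p,
            "significant_overall": pr.significant_overall,
            "direction_pattern": pr.direction_pattern or "",
            "replicated": pr.key in repl_keys,
        })
    return pd.DataFrame(rows)
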