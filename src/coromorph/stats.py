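"""Cohort-comparison statistics.

The battery applied to two cohorts: chi-square probes on pooled,
normalized counts (a df=1 goodness-of-fit against equal expectation
for totals, an r x 2 contingency table for binned frequencies), a
Shapiro-Wilk-gated location test (Student's t when both groups test
normal, Mann-Whitney otherwise), and Pearson correlation for the
asymmetry-angle relation. Significance criterion: p < 0.05.

Normalized counts may be non-integer; they enter the chi-square
formulas as-is (normalization happens before testing by design). No
continuity correction is applied anywhere: the equal-expectation
df=1 reading without correction is the one that reproduces the
published significance levels from the published count pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "CountComparison",
    "chi2_equal_counts",
    "chi2_frequency_table",
    "compare_continuous",
    "GroupComparisonReport",
    "build_group_report",
]

ALPHA = 0.05


@dataclass(frozen=True)
class CountComparison:
    observed: tuple[float, float]
    chi2: float
    df: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def chi2_equal_counts(a: float, b: float) -> CountComparison:
    """Goodness-of-fit of the pair (a, b) against equal expectation.

    chi2 = (a-e)^2/e + (b-e)^2/e with e = (a+b)/2, df = 1, two-sided p
    from the chi-square distribution; no continuity correction.
    Accepts normalized (non-integer) counts.
    """
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0:
        raise ValueError("both counts are zero")
    e = (a + b) / 2.0
    chi2 = (a - e) ** 2 / e + (b - e) ** 2 / e
    return CountComparison((float(a), float(b)), float(chi2), 1, float(sps.chi2.sf(chi2, 1)))


def _pool_sparse(table: np.ndarray, min_expected: float):
    """Merge adjacent bins until every expected cell count reaches
    ``min_expected``; returns (pooled table, merge bookkeeping)."""
    rows = [table[i].copy() for i in range(len(table))]
    merged = [[i] for i in range(len(rows))]

    def expected(rs):
        t = np.array(rs, dtype=float)
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()

    while len(rows) > 2:
        exp = expected(rows)
        bad = np.where((exp < min_expected).any(axis=1))[0]
        if bad.size == 0:
            break
        i = int(bad[0])
        j = i + 1 if i + 1 < len(rows) else i - 1
        lo, hi = min(i, j), max(i, j)
        rows[lo] = rows[lo] + rows[hi]
        merged[lo] = merged[lo] + merged[hi]
        del rows[hi], merged[hi]
    return np.array(rows, dtype=float), merged


def chi2_frequency_table(counts_a, counts_b, min_expected: float = 1.0):
    """r x 2 contingency chi-square over aligned frequency bins.

    Adjacent bins with expected counts below ``min_expected`` are
    pooled first (the merge map is returned). df = r - 1. Returns
    ``(chi2, df, p, pooling)``.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("bin grids are not aligned")
    table = np.column_stack([a, b])
    table = table[table.sum(axis=1) > 0]
    if len(table) < 2:
        raise ValueError("fewer than 2 usable bins")
    pooled, merge_map = _pool_sparse(table, min_expected)
    exp = np.outer(pooled.sum(axis=1), pooled.sum(axis=0)) / pooled.sum()
    chi2 = float(np.sum((pooled - exp) ** 2 / exp))
    df = len(pooled) - 1
    return chi2, df, float(sps.chi2.sf(chi2, df)), merge_map


def compare_continuous(group_a, group_b, alpha: float = ALPHA):
    """Normality-gated two-sample location test.

    Shapiro-Wilk on each group at ``alpha``; when both pass, the
    two-tailed unpaired Student's t-test; otherwise Mann-Whitney.
    Returns ``(test_name, statistic, p)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return "t-test", 0.0, 1.0  # identical constant groups
    normal = all(np.ptp(g) > 0 and sps.shapiro(g).pvalue > alpha for g in (a, b))
    if normal:
        res = sps.ttest_ind(a, b)
        return "t-test", float(res.statistic), float(res.pvalue)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return "mann-whitney", float(res.statistic), float(res.pvalue)


@dataclass
class ComparisonRow:
    variable: str
    test: str
    statistic: float
    p: float
    direction: str = ""  # "A>B" / "B>A" / ""
    detail: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass
class GroupComparisonReport:
    """Every cohort contrast of the analysis, one row per variable."""

    group_a: str
    group_b: str
    rows: list[ComparisonRow]

    def row(self, variable: str) -> ComparisonRow:
        for r in self.rows:
            if r.variable == variable:
                return r
        raise KeyError(variable)

    @property
    def flagged(self) -> list[str]:
        """Significant between-group differences (within-group
        descriptors like the per-cohort correlations are excluded)."""
        return [
            r.variable
            for r in self.rows
            if r.significant and not r.variable.startswith("asymmetry_angle_pearson")
        ]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "variable": r.variable,
                    "test": r.test,
                    "statistic": r.statistic,
                    "p": r.p,
                    "direction": r.direction,
                    "significant": r.significant,
                }
                for r in self.rows
            ]
        )


def _direction(a: float, b: float) -> str:
    return "A>B" if a > b else "B>A" if b > a else ""


def build_group_report(cohort_a, cohort_b, min_expected: float = 1.0) -> GroupComparisonReport:
    """Assemble the full two-cohort comparison.

    ``cohort_a``/``cohort_b`` are :class:`~coromorph.pipeline.CohortResult`
    objects. Compares: segment totals and ring-unit totals (equal-count
    chi-square on normalized pooled counts), the ring-unit diameter
    frequency profile (contingency chi-square), per-order mean flow
    length and lumen area plus first-order lumen area (gated location
    tests on per-network values), each anomaly class, and reports each
    cohort's asymmetry-angle Pearson correlation.
    """
    if not cohort_a.analyses or not cohort_b.analyses:
        raise ValueError("cannot compare an empty cohort")
    rows: list[ComparisonRow] = []

    for name, attr in [("segment_count", "segment_total"), ("ring_unit_total", "ring_total")]:
        a, b = getattr(cohort_a, attr)(), getattr(cohort_b, attr)()
        c = chi2_equal_counts(a, b)
        rows.append(ComparisonRow(name, "chi2-equal", c.chi2, c.p, _direction(a, b),
                                  {"observed": c.observed, "df": c.df}))

    ha, hb = cohort_a.diameter_histogram(), cohort_b.diameter_histogram()
    grid = np.union1d(ha.bin_centers_um, hb.bin_centers_um)

    def on_grid(h):
        out = np.zeros(len(grid))
        idx = np.searchsorted(grid, h.bin_centers_um)
        out[idx] = h.counts
        return out

    chi2, df, p, pooling = chi2_frequency_table(on_grid(ha), on_grid(hb), min_expected)
    rows.append(ComparisonRow("ring_diameter_frequencies", "chi2-contingency", chi2, p,
                              "", {"df": df, "pooled_bins": pooling}))

    for variable, col in [
        ("first_order_lumen_area", "lumen_area_um2"),
        ("order1_4_flow_length", "flow_length_um"),
    ]:
        sel = (lambda d: d.branch_order == 1) if "first" in variable else (
            lambda d: d.branch_order.between(1, 4)
        )
        va = cohort_a.per_network_mean(col, sel)
        vb = cohort_b.per_network_mean(col, sel)
        if len(va) < 3 or len(vb) < 3:
            rows.append(ComparisonRow(variable, "insufficient-n", float("nan"),
                                      float("nan"),
                                      _direction(float(np.mean(va)), float(np.mean(vb)))))
        else:
            test, stat, p = compare_continuous(va, vb)
            rows.append(ComparisonRow(variable, test, stat, p,
                                      _direction(float(np.mean(va)), float(np.mean(vb)))))

    ra, rb = cohort_a.anomalies(), cohort_b.anomalies()
    for cls in ra.counts:
        a, b = ra.counts[cls], rb.counts[cls]
        if a + b == 0:
            rows.append(ComparisonRow(f"anomaly_{cls}", "chi2-equal", 0.0, 1.0))
            continue
        c = chi2_equal_counts(a, b)
        rows.append(ComparisonRow(f"anomaly_{cls}", "chi2-equal", c.chi2, c.p, _direction(a, b)))
    c = chi2_equal_counts(max(ra.sum_of_all, 1e-12), max(rb.sum_of_all, 1e-12))
    rows.append(ComparisonRow("anomaly_sum_of_all", "chi2-equal", c.chi2, c.p,
                              _direction(ra.sum_of_all, rb.sum_of_all)))

    for label, cohort in [("A", cohort_a), ("B", cohort_b)]:
        try:
            r, p, slope = cohort.asymmetry_angle()
            rows.append(ComparisonRow(f"asymmetry_angle_pearson_{label}", "pearson", r, p,
                                      detail={"slope": slope}))
        except ValueError:
            pass
    return GroupComparisonReport(cohort_a.name, cohort_b.name, rows)
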