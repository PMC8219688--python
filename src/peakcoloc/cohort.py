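"""2x2 cross-tabulation and chi-squared association test for cohort data.

Built for immunohistochemistry cohorts cross-tabulated as two marker-level
groups (rows, e.g. low/high γ-tubulin) against a second marker's status
(columns, e.g. PCNA high/low). The default test is Pearson chi-squared
without continuity correction; Yates' correction is available. An exact
Monte-Carlo label-permutation p-value is provided as an independent check
of the analytic one.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Union

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "Chi2Result",
    "chi2_2x2",
    "group_proportions",
    "mc_permutation_pvalue",
    "read_table_csv",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns the second marker's
    high/low status (first column = high)."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, str] = ("high", "low")

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins_positive(self) -> bool:
        m = self.counts
        return bool(m.sum(0).min() > 0 and m.sum(1).min() > 0)


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    correction_used: bool
    odds_ratio: float  # (a*d)/(b*c); inf when b*c == 0 and a*d > 0
    odds_ratio_degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "correction_used": self.correction_used,
            "odds_ratio": self.odds_ratio,
        }


def chi2_2x2(table: ContingencyTable2x2, yates: bool = False) -> Chi2Result:
    """Pearson chi-squared test of association on a 2x2 table (df = 1).

    No continuity correction by default; pass ``yates=True`` for Yates'
    correction (always <= the uncorrected statistic). Raises on a zero row or
    column margin. A zero cell makes the odds ratio degenerate (0 or inf),
    flagged on the result.
    """
    if not table.margins_positive():
        raise ValueError("chi-squared test requires every row and column margin > 0")
    statistic, p, df, _ = stats.chi2_contingency(table.counts, correction=yates)
    ad, bc = table.a * table.d, table.b * table.c
    degenerate = ad == 0 or bc == 0
    if bc == 0:
        oratio = float("inf") if ad > 0 else float("nan")
    else:
        oratio = ad / bc
    return Chi2Result(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p),
        correction_used=yates,
        odds_ratio=oratio,
        odds_ratio_degenerate=degenerate,
    )


def group_proportions(table: ContingencyTable2x2) -> dict[str, dict]:
    """Per-group fraction in the first (high) column, with counts echoed."""
    out = {}
    for label, hi, lo in (
        (table.row_labels[0], table.a, table.b),
        (table.row_labels[1], table.c, table.d),
    ):
        n = hi + lo
        if n == 0:
            raise ValueError(f"group {label!r} has zero total")
        out[label] = {"n_high": hi, "n": n, "fraction_high": hi / n}
    return out


def mc_permutation_pvalue(
    table: ContingencyTable2x2,
    n_perm: int = 100_000,
    seed: int | None = None,
    yates: bool = False,
) -> float:
    """Monte-Carlo label-permutation p-value for the chi-squared statistic.

    Permuting group labels with margins fixed makes the a-cell hypergeometric,
    so the null is sampled by drawing ``a ~ Hypergeometric`` and recomputing
    the statistic from the fixed margins — exactly equivalent to shuffling the
    label column ``n_perm`` times, at a fraction of the cost. Uses the add-one
    estimator with ties counted.
    """
    if not table.margins_positive():
        raise ValueError("permutation test requires every margin > 0")
    r1 = table.a + table.b
    r2 = table.c + table.d
    c1 = table.a + table.c
    rng = np.random.default_rng(seed)
    a = rng.hypergeometric(r1, r2, c1, size=n_perm)

    def stat(a_arr):
        a_arr = np.asarray(a_arr, dtype=np.float64)
        b = r1 - a_arr
        c = c1 - a_arr
        d = r2 - c
        n = r1 + r2
        e = np.array([r1 * c1, r1 * (n - c1), r2 * c1, r2 * (n - c1)], dtype=np.float64) / n
        obs = np.stack([a_arr, b, c, d])
        dev = np.abs(obs - e[:, None])
        if yates:
            dev = np.maximum(dev - 0.5, 0.0)
        return (dev**2 / e[:, None]).sum(axis=0)

    observed = stat([table.a])[0]
    null = stat(a)
    return float((np.sum(null >= observed - 1e-12) + 1) / (n_perm + 1))


def read_table_csv(source: Union[str, Path, IO[str]]) -> ContingencyTable2x2:
    """Read a 2x2 table from CSV: header ``group,<col1>,<col2>`` then two rows
    ``label,count,count``."""
    own = isinstance(source, (str, Path))
    fh = open(source, "rt", newline="") if own else source
    try:
        rows = [r for r in csv.reader(fh) if r and any(f.strip() for f in r)]
    finally:
        if own:
            fh.close()
    if len(rows) != 3 or any(len(r) < 3 for r in rows):
        raise ValueError("expected a header row plus two data rows of 'label,count,count'")
    col_labels = (rows[0][1].strip(), rows[0][2].strip())
    try:
        a, b = int(rows[1][1]), int(rows[1][2])
        c, d = int(rows[2][1]), int(rows[2][2])
    except ValueError:
        raise ValueError("counts must be integers") from None
    return ContingencyTable2x2(
        a, b, c, d,
        row_labels=(rows[1][0].strip(), rows[2][0].strip()),
        col_labels=col_labels,
    )
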