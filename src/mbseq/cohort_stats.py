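"""Exact and classical tests for cohort contingency tables.

The centrepiece is the Freeman-Halton extension of Fisher's exact test to
r x c tables, computed by full enumeration of all tables with the observed
margins under the multivariate hypergeometric null. The two-sided p-value
follows the minimum-likelihood convention: it sums the probabilities of
every margin-fixed table whose probability does not exceed that of the
observed table (ties included). On a 2x2 input this reduces exactly to
Fisher's exact test.

Also provided: the Pearson chi-square for r x c tables (with the df=2
closed form ``exp(-chi2/2)`` available as an analytic cross-check), and
pooled-variance Student t-tests computed either from raw samples or from
published group summaries (n, mean, SD) — the form needed to reproduce a
test from a table of summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma, sqrt
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "GroupSummary",
    "TestResult",
    "fisher_2x2",
    "freeman_halton",
    "chi_square_rxc",
    "t_test_summary",
    "build_compound_table",
    "monte_carlo_exact_p",
    "read_cohort_tsv",
    "cohort_report",
]

_ENUMERATION_GUARD = 10**7
_TIE_LOG_EPS = 1e-7  # relative tolerance when comparing table likelihoods


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of non-negative integer counts with labelled margins."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = self.array
        if arr.ndim != 2 or arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match labels")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.sum() == 0:
            raise ValueError("table total must be positive")

    @classmethod
    def from_counts(
        cls,
        counts,
        row_labels=None,
        col_labels=None,
    ) -> "ContingencyTable":
        arr = np.asarray(counts, dtype=np.int64)
        rows = tuple(row_labels or [f"r{i}" for i in range(arr.shape[0])])
        cols = tuple(col_labels or [f"c{j}" for j in range(arr.shape[1])])
        return cls(rows, cols, tuple(tuple(int(x) for x in row) for row in arr))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @property
    def row_margins(self) -> np.ndarray:
        return self.array.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.array.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.array.sum())


@dataclass(frozen=True)
class GroupSummary:
    """Published group summary: size, mean and sample standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")


@dataclass(frozen=True)
class TestResult:
    method: str
    p_value: float
    statistic: float | None = None
    sidedness: str = "two-sided"
    df: float | None = None


# ---------------------------------------------------------------------------
# Exact tests by enumeration
# ---------------------------------------------------------------------------


def _log_factorials(n: int) -> np.ndarray:
    return np.array([lgamma(k + 1) for k in range(n + 1)])


def _table_logprob(cells: np.ndarray, lf: np.ndarray, const: float) -> float:
    """Log multivariate-hypergeometric probability given the margin constant.

    ``const`` is ``sum lf[row margins] + sum lf[col margins] - lf[N]``; the
    table-specific part is ``-sum lf[cells]``.
    """
    return const - float(lf[cells].sum())


def _enumerate_tables(row_margins, col_margins):
    """Yield every non-negative integer table with the given margins."""
    r = len(row_margins)

    def fill(i: int, remaining_cols: np.ndarray, rows: list):
        if i == r - 1:
            if (remaining_cols >= 0).all():
                yield rows + [remaining_cols.copy()]
            return
        target = row_margins[i]

        def compositions(j: int, left: int, row: np.ndarray):
            if j == len(remaining_cols) - 1:
                if left <= remaining_cols[j]:
                    row[j] = left
                    yield row
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                row[j] = v
                yield from compositions(j + 1, left - v, row)

        row = np.zeros(len(remaining_cols), dtype=np.int64)
        for filled in compositions(0, target, row):
            yield from fill(i + 1, remaining_cols - filled, rows + [filled.copy()])

    yield from fill(0, np.asarray(col_margins, dtype=np.int64), [])


def _enumeration_bound(row_margins, col_margins) -> float:
    """Upper bound on the number of margin-fixed tables (compositions)."""
    c = len(col_margins)
    bound = 1.0
    for margin in row_margins[:-1]:
        # compositions of `margin` into c parts
        bound *= exp(
            lgamma(margin + c) - lgamma(margin + 1) - lgamma(c)
        )
    return bound


def freeman_halton(table: ContingencyTable) -> TestResult:
    """Exact (Fisher-Freeman-Halton) test for an r x c table.

    Enumerates all tables sharing the observed margins; the p-value sums
    the multivariate-hypergeometric probabilities of tables no more likely
    than the one observed (ties included). The enumerated probabilities
    are checked to sum to one within 1e-9 on every call. Tables too large
    to enumerate (bound > 1e7 states) raise ``ValueError`` advising the
    Monte-Carlo fallback (:func:`monte_carlo_exact_p`).
    """
    arr = table.array
    rm, cm = table.row_margins, table.col_margins
    if (rm == 0).any() or (cm == 0).any():
        raise ValueError("all margins must be positive")
    if _enumeration_bound(rm, cm) > _ENUMERATION_GUARD:
        raise ValueError(
            "table too large for full enumeration; use monte_carlo_exact_p"
        )
    lf = _log_factorials(table.total)
    const = float(lf[rm].sum() + lf[cm].sum() - lf[table.total])
    logp_obs = _table_logprob(arr, lf, const)

    p = 0.0
    total = 0.0
    threshold = logp_obs + _TIE_LOG_EPS
    for cells in _enumerate_tables(rm, cm):
        logp = _table_logprob(np.asarray(cells), lf, const)
        prob = exp(logp)
        total += prob
        if logp <= threshold:
            p += prob
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"enumerated probabilities sum to {total!r}, not 1")
    return TestResult(method="freeman_halton", p_value=min(p, 1.0))


def fisher_2x2(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Uses the minimum-likelihood convention via the same enumeration as
    :func:`freeman_halton` (to which it is identical on 2x2 input), and
    reports the sample odds ratio as the statistic.
    """
    arr = table.array
    if arr.shape != (2, 2):
        raise ValueError("fisher_2x2 requires a 2x2 table")
    (a, b), (c, d) = arr
    odds = float("inf") if b * c == 0 else a * d / (b * c)
    inner = freeman_halton(table)
    return TestResult(method="fisher_2x2", p_value=inner.p_value, statistic=odds)


def monte_carlo_exact_p(
    table: ContingencyTable, n_draws: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo estimate of the exact p with its binomial standard error.

    Samples margin-fixed tables from the multivariate hypergeometric null
    (Patefield algorithm via :func:`scipy.stats.random_table`) and counts
    the fraction no more likely than the observed table.
    """
    arr = table.array
    lf = _log_factorials(table.total)
    rm, cm = table.row_margins, table.col_margins
    const = float(lf[rm].sum() + lf[cm].sum() - lf[table.total])
    logp_obs = _table_logprob(arr, lf, const)
    rng = np.random.default_rng(seed)
    draws = sps.random_table(rm, cm).rvs(n_draws, random_state=rng).astype(np.int64)
    logps = const - lf[draws].sum(axis=(1, 2))
    hits = int((logps <= logp_obs + _TIE_LOG_EPS).sum())
    p = hits / n_draws
    se = sqrt(max(p * (1 - p), 1e-12) / n_draws)
    return p, se


# ---------------------------------------------------------------------------
# Classical tests
# ---------------------------------------------------------------------------


def chi_square_rxc(table: ContingencyTable) -> TestResult:
    """Pearson chi-square for an r x c table, df = (r-1)(c-1).

    The p-value is the chi-square upper tail; for df=2 it equals the
    closed form ``exp(-chi2/2)``, which serves as an analytic cross-check.
    Zero expected cells raise ``ValueError``.
    """
    arr = table.array.astype(float)
    rm, cm = table.row_margins, table.col_margins
    if (rm == 0).any() or (cm == 0).any():
        raise ValueError("all margins must be positive")
    expected = np.outer(rm, cm) / table.total
    if (expected == 0).any():
        raise ValueError("zero expected cell")
    chi2 = float(((arr - expected) ** 2 / expected).sum())
    df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    return TestResult(
        method="chi_square", p_value=float(sps.chi2.sf(chi2, df)),
        statistic=chi2, df=df,
    )


def t_test_summary(g1: GroupSummary, g2: GroupSummary) -> TestResult:
    """Pooled-variance Student t-test from group summaries.

    df = n1 + n2 - 2, two-sided. Equal means give t = 0, p = 1.
    """
    df = g1.n + g2.n - 2
    pooled_var = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    se = sqrt(pooled_var * (1 / g1.n + 1 / g2.n))
    if se == 0:
        t = 0.0 if g1.mean == g2.mean else float("inf")
    else:
        t = (g1.mean - g2.mean) / se
    p = float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return TestResult(method="t_test_pooled", p_value=p, statistic=t, df=df)


# ---------------------------------------------------------------------------
# Compound-mutation tables and the cohort report
# ---------------------------------------------------------------------------

GENOTYPES = ("L858R", "exon19del", "G719X")


def _normalise_genotype(genotype: str) -> str:
    if genotype in ("G719A", "G719S", "G719C", "G719X"):
        return "G719X"
    if genotype in GENOTYPES:
        return genotype
    raise ValueError(f"unknown genotype {genotype!r}")


def build_compound_table(records: list[tuple[str, str]]) -> ContingencyTable:
    """3 x 2 genotype-by-status table from (genotype, compound|single) records.

    Row order is fixed (L858R, exon19del, G719X); columns are compound,
    single. G719A/S/C genotypes collapse into G719X.
    """
    if not records:
        raise ValueError("no cohort records")
    counts = {g: [0, 0] for g in GENOTYPES}
    for genotype, status in records:
        g = _normalise_genotype(genotype)
        if status == "compound":
            counts[g][0] += 1
        elif status == "single":
            counts[g][1] += 1
        else:
            raise ValueError(f"unknown compound status {status!r}")
    return ContingencyTable.from_counts(
        [counts[g] for g in GENOTYPES],
        row_labels=GENOTYPES,
        col_labels=("compound", "single"),
    )


_COHORT_COLUMNS = [
    "sample_id", "genotype", "compound_status", "age", "sex", "smoking",
    "tumor_size_mm", "pstage",
]


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    """Load a cohort table, validating columns and per-line content."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for lineno, row in enumerate(frame.itertuples(index=False), 2):
        try:
            _normalise_genotype(row.genotype)
            if row.compound_status not in ("single", "compound"):
                raise ValueError(f"bad compound_status {row.compound_status!r}")
            float(row.age)
            float(row.tumor_size_mm)
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
    frame["age"] = frame["age"].astype(float)
    frame["tumor_size_mm"] = frame["tumor_size_mm"].astype(float)
    return frame


def _split_summary(frame: pd.DataFrame, column: str) -> tuple[GroupSummary, GroupSummary]:
    groups = []
    for status in ("single", "compound"):
        values = frame.loc[frame["compound_status"] == status, column]
        groups.append(GroupSummary(len(values), float(values.mean()), float(values.std(ddof=1))))
    return tuple(groups)


def cohort_report(frame: pd.DataFrame) -> pd.DataFrame:
    """One test per clinicopathological comparison, single vs compound.

    Categorical characteristics get exact tests (Fisher 2x2 for binary
    rows, Freeman-Halton for the genotype and stage rows — the stage row
    additionally reports the Pearson chi-square); age and tumor size get
    pooled t-tests from the group summaries.
    """
    rows = []

    def crosstab(column: str, level_order: list[str]) -> ContingencyTable:
        counts = [
            [
                int(((frame[column] == level) & (frame["compound_status"] == status)).sum())
                for status in ("single", "compound")
            ]
            for level in level_order
        ]
        return ContingencyTable.from_counts(
            counts, row_labels=level_order, col_labels=("single", "compound")
        )

    for column in ("age", "tumor_size_mm"):
        g_single, g_compound = _split_summary(frame, column)
        res = t_test_summary(g_single, g_compound)
        rows.append((column, res.method, res.statistic, res.p_value))

    for column, levels in (("sex", ["male", "female"]), ("smoking", ["no", "yes"])):
        res = fisher_2x2(crosstab(column, levels))
        rows.append((column, res.method, res.statistic, res.p_value))

    genotype_records = list(zip(frame["genotype"], frame["compound_status"]))
    res = freeman_halton(build_compound_table(genotype_records))
    rows.append(("genotype", res.method, res.statistic, res.p_value))

    stage_levels = [s for s in ("IA", "IB", "II-III") if (frame["pstage"] == s).any()]
    stage_table = crosstab("pstage", stage_levels)
    res = chi_square_rxc(stage_table)
    rows.append(("pstage", res.method, res.statistic, res.p_value))
    res = freeman_halton(stage_table)
    rows.append(("pstage", res.method, res.statistic, res.p_value))

    return pd.DataFrame(rows, columns=["comparison", "method", "statistic", "p_value"])
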