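"""Two-group statistical battery for subject-level brain entropy.

Implements the comparisons reported for an ADHD-vs-control cohort: a
two-sample t-test on BEN, Mann-Whitney U (normal approximation with tie
correction) on age and BEN, Pearson's chi-squared on the gender-by-group
2x2 table (no continuity correction), the phi coefficient, and the
point-biserial correlation between BEN and group membership.

Sign conventions for the binary correlations depend on how the two levels
of each variable are coded; :class:`Coding` makes that explicit.  The
default coding (male=1/female=2, control=1/ADHD=2) reproduces the signs a
standard SPSS-style analysis of this design prints: negative gender-group
and BEN-group correlations when the ADHD group is mostly male and has the
lower entropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps


class DegenerateTableError(ValueError):
    """A 2x2 table with a zero margin cannot be tested."""


@dataclass(frozen=True)
class Coding:
    """Numeric codes for the two binary variables."""

    gender_codes: tuple[tuple[str, int], ...] = (("male", 1), ("female", 2))
    group_codes: tuple[tuple[str, int], ...] = (("control", 1), ("ADHD", 2))

    @property
    def gender(self) -> dict[str, int]:
        return dict(self.gender_codes)

    @property
    def group(self) -> dict[str, int]:
        return dict(self.group_codes)


DEFAULT_CODING = Coding()


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Gender-by-group counts: rows = (ADHD, control), cols = (male, female)."""

    a: int  # ADHD male
    b: int  # ADHD female
    c: int  # control male
    d: int  # control female

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) marginal totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @classmethod
    def from_labels(cls, groups: Sequence[str], genders: Sequence[str],
                    coding: Coding = DEFAULT_CODING) -> "ContingencyTable2x2":
        g = np.asarray(groups, dtype=object)
        s = np.asarray(genders, dtype=object)
        if g.shape != s.shape:
            raise ValueError("groups and genders must have equal length")
        return cls(
            a=int(((g == "ADHD") & (s == "male")).sum()),
            b=int(((g == "ADHD") & (s == "female")).sum()),
            c=int(((g == "control") & (s == "male")).sum()),
            d=int(((g == "control") & (s == "female")).sum()),
        )


class Chi2Result(NamedTuple):
    chi2: float
    p: float


class PhiResult(NamedTuple):
    r: float
    p: float


class TTestResult(NamedTuple):
    t: float
    p: float
    df: float


class MannWhitneyResult(NamedTuple):
    u: float
    z: float
    p: float


class CorrelationResult(NamedTuple):
    r: float
    p: float


def chi_square_2x2(table: ContingencyTable2x2) -> Chi2Result:
    """Pearson chi-squared on a 2x2 table, no continuity correction.

    chi2 = sum (O - E)^2 / E over the four cells with expected counts from
    the product of the margins; p from the chi-squared distribution with one
    degree of freedom.  Raises :class:`DegenerateTableError` on a zero
    margin (an expected count of zero).
    """
    r1, r2, c1, c2 = table.margins
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateTableError(f"degenerate table: zero margin in {table}")
    n = table.total
    obs = table.as_array()
    expected = np.outer([r1, r2], [c1, c2]) / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return Chi2Result(chi2, float(sps.chi2.sf(chi2, df=1)))


def phi_coefficient(table: ContingencyTable2x2,
                    coding: Coding = DEFAULT_CODING) -> PhiResult:
    """Signed phi coefficient of a gender-by-group 2x2 table.

    phi is the Pearson correlation of the two coded binary variables over
    all N subjects; its magnitude satisfies |phi| = sqrt(chi2 / N) exactly.
    The sign follows the coding: with the default (male=1/female=2,
    control=1/ADHD=2), a male-dominated ADHD group yields a negative phi.
    The p-value is the usual correlation test, t = r sqrt(N-2)/sqrt(1-r^2)
    with N-2 degrees of freedom.
    """
    r1, r2, c1, c2 = table.margins
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateTableError(f"degenerate table: zero margin in {table}")
    # (ad - bc)/sqrt of margins is the correlation when the ADHD row and the
    # male column carry the *higher* codes; flip for the actual coding.
    raw = (table.a * table.d - table.b * table.c) / np.sqrt(
        float(r1) * r2 * c1 * c2
    )
    sign = np.sign(
        (coding.group["ADHD"] - coding.group["control"])
        * (coding.gender["male"] - coding.gender["female"])
    )
    r = float(sign * raw)
    n = table.total
    if n <= 2 or abs(r) >= 1.0:
        return PhiResult(r, 0.0 if abs(r) >= 1.0 else float("nan"))
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return PhiResult(r, float(2.0 * sps.t.sf(abs(t), df=n - 2)))


def t_test_two_sample(x: Sequence[float], y: Sequence[float],
                      equal_var: bool = True) -> TTestResult:
    """Two-sample t-test (pooled by default; Welch with equal_var=False)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    df = x.size + y.size - 2 if equal_var else float(res.df)
    return TTestResult(float(res.statistic), float(res.pvalue), float(df))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Mann-Whitney U with tie-corrected normal-approximation Z.

    U counts pairs (x_i, y_j) with x_i > y_j plus half-ties (the U of the
    first sample).  Z = (U - n1 n2 / 2) / sigma with the tie-corrected
    variance; two-sided p from the normal distribution.  With the first
    sample stochastically smaller, Z is negative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    u = float(sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic").statistic)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    if n < 2:
        raise ValueError("need at least two observations in total")
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    mu = n1 * n2 / 2.0
    if var <= 0:  # all observations tied
        return MannWhitneyResult(u, 0.0, 1.0)
    z = (u - mu) / np.sqrt(var)
    return MannWhitneyResult(u, float(z), float(2.0 * sps.norm.sf(abs(z))))


def point_biserial(values: Sequence[float], groups: Sequence[str],
                   coding: Coding = DEFAULT_CODING) -> CorrelationResult:
    """Point-biserial correlation between a continuous value and group.

    Pearson correlation of the values against the numeric group codes;
    p via t = r sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups, dtype=object)
    if v.shape != g.shape:
        raise ValueError("values and groups must have equal length")
    levels = set(g.tolist())
    if len(levels) < 2:
        raise ValueError("both groups must be represented")
    if v.size < 3:
        raise ValueError("need at least 3 subjects")
    codes = np.array([coding.group[str(lbl)] for lbl in g], dtype=float)
    vc = v - v.mean()
    cc = codes - codes.mean()
    denom = np.sqrt((vc**2).sum() * (cc**2).sum())
    if denom == 0:
        return CorrelationResult(0.0, 1.0)
    r = float((vc * cc).sum() / denom)
    if abs(r) >= 1.0:
        return CorrelationResult(r, 0.0)
    t = r * np.sqrt(v.size - 2) / np.sqrt(1.0 - r * r)
    return CorrelationResult(r, float(2.0 * sps.t.sf(abs(t), df=v.size - 2)))


# ---------------------------------------------------------------------------
# power analysis (two-sample t)
# ---------------------------------------------------------------------------

def analytic_ttest_power(mean1: float, sd1: float, n1: int,
                         mean2: float, sd2: float, n2: int,
                         alpha: float = 0.05) -> float:
    """Analytic power of the pooled two-sample t-test at the given design.

    Uses the noncentral-t distribution with df = n1 + n2 - 2 and
    noncentrality ncp = (mean1 - mean2) / (s_p sqrt(1/n1 + 1/n2)), where
    s_p is the pooled standard deviation — the denominator the pooled test
    actually uses.  Exact under equal variances; a standard approximation
    otherwise.
    """
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    ncp = (mean1 - mean2) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp))


def simulate_ttest_rejection(mean1: float, sd1: float, n1: int,
                             mean2: float, sd2: float, n2: int,
                             alpha: float = 0.05, n_reps: int = 2000,
                             seed: int = 0) -> float:
    """Monte-Carlo rejection frequency of the pooled two-sample t-test.

    Draws ``n_reps`` pairs of normal samples at the stated means/SDs and
    returns the fraction rejecting at level ``alpha`` (two-sided), computed
    with a vectorized pooled-variance t statistic.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(mean1, sd1, size=(n_reps, n1))
    y = rng.normal(mean2, sd2, size=(n_reps, n2))
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * vx + (n2 - 1) * vy) / (n1 + n2 - 2)
    t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    crit = sps.t.ppf(1.0 - alpha / 2.0, n1 + n2 - 2)
    return float((np.abs(t) > crit).mean())
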