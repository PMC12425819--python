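"""Exact and resampling statistics for two-cohort mutation-frequency studies.

The central object is a labelled contingency table of mutated/wild-type counts
per cohort.  2x2 tables are tested with Fisher's exact test using the
probability-mass two-sided rule (the convention of R's ``fisher.test`` and
``scipy.stats.fisher_exact``): the two-sided P value is the sum of point
probabilities of all tables, with the observed margins, whose probability does
not exceed that of the observed table (within a relative tie tolerance of
1e-7).  Larger tables are tested by Monte Carlo sampling of fixed-margin
tables.  Confounder-stratified comparisons use an exact conditional
(CMH-type) combined test: under the null of a common odds ratio of one, the
total number of group-1 successes across strata is distributed as the
convolution of per-stratum central hypergeometric laws; strata with a zero
row or column margin carry no information and are dropped.

Observed mutation frequencies k/n carry a Beta(k+1, n-k+1) posterior under a
uniform prior; its standard deviation is the error bar used throughout the
frequency plots.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: relative tolerance when comparing point probabilities for the two-sided rule
TIE_RTOL = 1e-7

SIDEDNESS = ("two_sided", "less", "greater")


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of nonnegative integer counts with axis labels.

    Rows are groups (e.g. cohorts), columns are outcomes (e.g. mutated /
    wild type).
    """

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"table must be at least 2x2, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("table entries must be nonnegative")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("table entries must be integers")
            arr = np.round(arr).astype(np.int64)
        object.__setattr__(self, "counts", arr.astype(np.int64))
        if self.row_labels and len(self.row_labels) != arr.shape[0]:
            raise ValueError("row_labels length mismatch")
        if self.col_labels and len(self.col_labels) != arr.shape[1]:
            raise ValueError("col_labels length mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.counts.shape)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test (P value plus method metadata)."""

    p_value: float
    method: str
    sidedness: str = "two_sided"
    statistic: float | None = None
    odds_ratio: float | None = None
    mc_iterations: int | None = None
    mc_se: float | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class FrequencyEstimate:
    """Observed mutation frequency k/n with Beta-distribution uncertainty.

    The standard deviation is that of Beta(k+1, n-k+1), the posterior of the
    frequency under a uniform prior.
    """

    k: int
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ValueError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")

    @property
    def freq(self) -> float:
        return self.k / self.n if self.n else math.nan

    @property
    def beta_a(self) -> int:
        return self.k + 1

    @property
    def beta_b(self) -> int:
        return self.n - self.k + 1

    @property
    def sd(self) -> float:
        return beta_sd(self.k, self.n)


def beta_sd(k: int, n: int) -> float:
    """Standard deviation of Beta(k+1, n-k+1).

    Closed form sqrt(a*b / ((a+b)^2 (a+b+1))) with a = k+1, b = n-k+1.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    a, b = k + 1.0, n - k + 1.0
    return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))


# ---------------------------------------------------------------------------
# Fisher's exact test, 2x2
# ---------------------------------------------------------------------------


def _as_2x2(table) -> np.ndarray:
    arr = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    arr = np.asarray(arr, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("table entries must be nonnegative")
    return arr


def hypergeom_support_pmf(n1: int, n2: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and pmf of the number of group-1 successes given fixed margins.

    For a 2x2 table with row sums (n1, n2) and first-column sum m, the upper
    left cell a follows the central hypergeometric law on
    [max(0, m-n2), min(m, n1)].
    """
    if n1 < 0 or n2 < 0 or not (0 <= m <= n1 + n2):
        raise ValueError(f"invalid margins n1={n1}, n2={n2}, m={m}")
    lo, hi = max(0, m - n2), min(m, n1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n1 + n2, m, n1)
    return support, pmf


def fisher_pvalues_all_tables(
    n1: int, n2: int, m: int, sidedness: str = "two_sided"
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher P value for every allocation a compatible with the margins.

    Returns (support, pvalues) where pvalues[i] is the P value of the table
    [[a, n1-a], [m-a, n2-m+a]] for a = support[i].  Vectorised so the power
    scan and exhaustive sweeps stay cheap.
    """
    if sidedness not in SIDEDNESS:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    support, pmf = hypergeom_support_pmf(n1, n2, m)
    if sidedness == "less":
        pvals = np.cumsum(pmf)
    elif sidedness == "greater":
        pvals = np.cumsum(pmf[::-1])[::-1]
    else:
        order = np.argsort(pmf, kind="stable")
        sorted_pmf = pmf[order]
        csum = np.cumsum(sorted_pmf)
        # for each a, total mass of outcomes with pmf <= pmf[a] * (1 + tol)
        idx = np.searchsorted(sorted_pmf, pmf * (1.0 + TIE_RTOL), side="right")
        pvals = csum[idx - 1]
    return support, np.minimum(pvals, 1.0)


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    num, den = a * d, b * c
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


def fisher_2x2(table, sidedness: str = "two_sided") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    Rows are groups, columns are (success, failure).  ``less`` tests for a
    deficit of successes in the first row.  The odds ratio is the
    unconditional sample estimate (a*d)/(b*c); zero cells give 0 or infinity.
    """
    arr = _as_2x2(table)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    n1, n2, m = a + b, c + d, a + c
    support, pvals = fisher_pvalues_all_tables(n1, n2, m, sidedness)
    p = float(pvals[np.searchsorted(support, a)])
    return TestResult(
        p_value=p,
        method="fisher_exact",
        sidedness=sidedness,
        statistic=float(a),
        odds_ratio=_sample_odds_ratio(a, b, c, d),
    )


# ---------------------------------------------------------------------------
# Fisher's exact test, r x c, Monte Carlo
# ---------------------------------------------------------------------------


def _log_table_prob(arr: np.ndarray) -> float:
    """Log point probability of an r x c table under fixed margins."""
    from scipy.special import gammaln

    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    n = arr.sum()
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(arr + 1).sum()
    )


def fisher_rxc_mc(
    table, iterations: int = 1_000_000, seed: int | None = None
) -> TestResult:
    """Monte Carlo Fisher test for tables larger than 2x2.

    Samples fixed-margin tables (Patefield's algorithm via
    ``scipy.stats.random_table``) and estimates
    P = (1 + #{sampled tables at least as extreme}) / (iterations + 1),
    where "as extreme" means point probability not exceeding the observed
    one (within the same tie tolerance as the 2x2 rule).  The add-one
    estimator keeps P strictly positive.
    """
    arr = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    arr = np.asarray(arr, dtype=np.int64)
    if np.any(arr < 0):
        raise ValueError("table entries must be nonnegative")
    if arr.shape == (2, 2):
        logger.info("fisher_rxc_mc received a 2x2 table; delegating to fisher_2x2")
        return fisher_2x2(arr)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    # degenerate margins admit a single table
    if (rows > 0).sum() < 2 or (cols > 0).sum() < 2:
        return TestResult(
            p_value=1.0, method="fisher_mc", mc_iterations=0, mc_se=0.0, seed=seed
        )
    from scipy.special import gammaln

    rng = np.random.default_rng(seed)
    obs_logp = _log_table_prob(arr)
    cutoff = obs_logp + math.log1p(TIE_RTOL)
    const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(arr.sum() + 1)
    dist = sps.random_table(rows, cols)
    hits = 0
    batch = 100_000
    done = 0
    while done < iterations:
        k = min(batch, iterations - done)
        samples = dist.rvs(size=k, random_state=rng)
        logp = const - gammaln(samples + 1).sum(axis=(1, 2))
        hits += int(np.count_nonzero(logp <= cutoff))
        done += k
    p = (1 + hits) / (iterations + 1)
    se = math.sqrt(p * (1 - p) / iterations)
    return TestResult(
        p_value=p,
        method="fisher_mc",
        mc_iterations=iterations,
        mc_se=se,
        seed=seed,
    )


def fisher_rxc_enumerate(table) -> float:
    """Exact r x c Fisher P by exhaustive enumeration of fixed-margin tables.

    Feasible only for tiny margins; used as the oracle for the Monte Carlo
    estimator.
    """
    arr = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    arr = np.asarray(arr, dtype=np.int64)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)

    def weight(t: np.ndarray) -> int:
        w = 1
        for x in t.ravel():
            w *= math.factorial(int(x))
        return w

    # enumerate tables row by row
    def fill(row_idx: int, remaining_cols: np.ndarray, acc: list[np.ndarray]):
        if row_idx == len(rows) - 1:
            yield acc + [remaining_cols.copy()]
            return
        target = rows[row_idx]

        def comps(slots: int, total: int, caps: np.ndarray):
            if slots == 1:
                if total <= caps[0]:
                    yield [total]
                return
            for v in range(min(total, caps[0]) + 1):
                for rest in comps(slots - 1, total - v, caps[1:]):
                    yield [v] + rest

        for combo in comps(len(cols), int(target), remaining_cols):
            yield from fill(
                row_idx + 1, remaining_cols - np.array(combo), acc + [np.array(combo)]
            )

    inv_obs = weight(arr)  # probability ∝ 1/prod(cell!)
    num = 0
    den = 0
    from fractions import Fraction

    for t in fill(0, cols.copy(), []):
        tab = np.array(t)
        w = Fraction(1, weight(tab))
        den += w
        if weight(tab) >= inv_obs:  # prob(tab) <= prob(obs)
            num += w
    return float(num / den)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Stratified exact (CMH-type) test
# ---------------------------------------------------------------------------


def stratified_fisher(tables: Sequence, sidedness: str = "two_sided") -> TestResult:
    """Exact conditional combined test across 2x2 strata.

    Under the null of no association in any stratum, the total number of
    group-1 successes S is the sum of independent central hypergeometric
    variables, one per stratum, each conditioned on its margins.  Strata
    with a zero row or column margin are uninformative and are excluded.
    One-sided P values are tails of the convolved law; the two-sided P value
    follows the same probability-mass rule as the 2x2 test.
    """
    if sidedness not in SIDEDNESS:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if not tables:
        raise ValueError("need at least one stratum")
    pmfs: list[np.ndarray] = []
    offsets: list[int] = []
    observed = 0
    n_dropped = 0
    for t in tables:
        arr = _as_2x2(t)
        rows = arr.sum(axis=1)
        cols = arr.sum(axis=0)
        if (rows == 0).any() or (cols == 0).any():
            n_dropped += 1
            continue
        n1, n2, m = int(rows[0]), int(rows[1]), int(cols[0])
        support, pmf = hypergeom_support_pmf(n1, n2, m)
        pmfs.append(pmf)
        offsets.append(int(support[0]))
        observed += int(arr[0, 0])
    if n_dropped:
        logger.info("stratified_fisher: dropped %d zero-marginal strata", n_dropped)
    if not pmfs:
        raise ValueError("no informative strata (all have a zero margin)")
    conv = pmfs[0]
    for pmf in pmfs[1:]:
        conv = np.convolve(conv, pmf)
    lo = sum(offsets)
    support = np.arange(lo, lo + len(conv))
    idx = int(observed - lo)
    if sidedness == "less":
        p = float(conv[: idx + 1].sum())
    elif sidedness == "greater":
        p = float(conv[idx:].sum())
    else:
        p = float(conv[conv <= conv[idx] * (1.0 + TIE_RTOL)].sum())
    return TestResult(
        p_value=min(p, 1.0),
        method="stratified_fisher_exact",
        sidedness=sidedness,
        statistic=float(observed),
        extra={"n_strata_used": len(pmfs), "n_strata_dropped": n_dropped},
    )


# ---------------------------------------------------------------------------
# Co-occurrence / mutual exclusivity
# ---------------------------------------------------------------------------


def cooccurrence(a: Sequence[bool], b: Sequence[bool]) -> TestResult:
    """Fisher test for co-occurrence of two binary per-sample events.

    Odds ratio > 1 indicates co-occurrence, < 1 mutual exclusivity.
    """
    av = np.asarray(a, dtype=bool)
    bv = np.asarray(b, dtype=bool)
    if av.shape != bv.shape or av.ndim != 1:
        raise ValueError("inputs must be 1-D boolean vectors of equal length")
    t = np.array(
        [
            [int(np.sum(av & bv)), int(np.sum(av & ~bv))],
            [int(np.sum(~av & bv)), int(np.sum(~av & ~bv))],
        ]
    )
    res = fisher_2x2(t, "two_sided")
    return TestResult(
        p_value=res.p_value,
        method="cooccurrence_fisher",
        sidedness="two_sided",
        odds_ratio=res.odds_ratio,
        extra={"table": t.tolist()},
    )


# ---------------------------------------------------------------------------
# Rank-based and correlation tests
# ---------------------------------------------------------------------------

_ALT = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


def rank_sum(x: Sequence[float], y: Sequence[float], sidedness: str = "two_sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when the smaller sample has at most 8
    observations and there are no ties; tie-corrected normal approximation
    otherwise.
    """
    if sidedness not in SIDEDNESS:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size == 0 or yv.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([xv, yv])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(xv.size, yv.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(xv, yv, alternative=_ALT[sidedness], method=method)
    return TestResult(
        p_value=float(min(res.pvalue, 1.0)),
        method=f"wilcoxon_rank_sum_{method}",
        sidedness=sidedness,
        statistic=float(res.statistic),
        extra={"median_x": float(np.median(xv)), "median_y": float(np.median(yv))},
    )


def shift_compare(x: Sequence[float], y: Sequence[float], shift: int = 0,
                  sidedness: str = "two_sided") -> TestResult:
    """Rank-sum comparison of (x + shift) versus y.

    Used to ask whether an observed deficit in per-sample event counts is
    larger than a fixed number of events.
    """
    if shift < 0:
        raise ValueError("shift must be nonnegative")
    xv = np.asarray(x, dtype=float) + shift
    res = rank_sum(xv, y, sidedness)
    return TestResult(
        p_value=res.p_value,
        method=f"shift_compare(shift={shift})",
        sidedness=sidedness,
        statistic=res.statistic,
        extra=res.extra,
    )


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with two-sided P from the t transform (n-2 df)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("inputs must have equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(xv) == 0 or np.var(yv) == 0:
        raise ValueError("zero variance in an input")
    r, p = sps.pearsonr(xv, yv)
    return TestResult(
        p_value=float(p), method="pearson", sidedness="two_sided", statistic=float(r)
    )
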