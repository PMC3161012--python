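"""Hypergeometric random-walk statistics for conversion detection.

A triplet test compares one paralog pair (primary sequence vs. its paralog)
against the primary's ortholog in an outgroup species, column by column over
the paralog alignment.  An *informative site* is a column where exactly one
of {paralog, ortholog} matches the primary base:

* **down** step: primary == paralog != ortholog.  Paralogs agreeing where the
  ortholog does not is the signature of conversion, so a converted tract is a
  run of down steps.
* **up** step: primary == ortholog != paralog, the expected pattern when the
  duplication predates the outgroup split.

The cumulative score over informative sites is a random walk whose step
order, under the no-conversion null, is uniform over all orderings of the
observed m up and n down steps (a hypergeometric random walk H_{m,n}).  The
*maximum descent* k — the largest peak-to-subsequent-trough drop — marks the
candidate converted region, and its P-value is the exact probability that
H_{m,n} shows a descent >= k by chance.

For conversions covering (nearly) the whole paralog there is no flanking
region and the descent test degenerates, so an alternative criterion scores
the same counts with a binomial upper tail on n, with success probability
p = min(0.5, n/(n+m)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "StepSeries",
    "MaxDescent",
    "TestResult",
    "classify_site",
    "build_triplet_walk",
    "combine_quadruplet",
    "collapse_magnitudes",
    "maximum_descent",
    "max_descent_pvalue",
    "binomial_coverage_pvalue",
    "infer_direction",
]

_ACGT = frozenset(b"ACGT")
_ACGT_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class StepSeries:
    """Ordered informative-site steps over paralog-alignment columns.

    ``signs`` holds +1 (up) / -1 (down); ``magnitudes`` are 1 for triplet
    walks and may be 2 after quadruplet combining.  ``m``/``n`` are the total
    up/down magnitudes (a magnitude-2 step counts as two unit steps).
    """

    columns: np.ndarray
    signs: np.ndarray
    magnitudes: np.ndarray
    total_columns: int

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=np.int64)
        self.signs = np.asarray(self.signs, dtype=np.int64)
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.int64)
        if not (len(self.columns) == len(self.signs) == len(self.magnitudes)):
            raise ValueError("step arrays differ in length")
        if len(self.columns) > 1 and not np.all(np.diff(self.columns) > 0):
            raise ValueError("step columns must be strictly increasing")
        if len(self.signs) and not np.all(np.isin(self.signs, (-1, 1))):
            raise ValueError("signs must be +-1")
        if len(self.magnitudes) and not np.all(np.isin(self.magnitudes, (1, 2))):
            raise ValueError("magnitudes must be 1 or 2")

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def m(self) -> int:
        """Total up magnitude."""
        return int(self.magnitudes[self.signs > 0].sum())

    @property
    def n(self) -> int:
        """Total down magnitude."""
        return int(self.magnitudes[self.signs < 0].sum())

    def counts_in(self, start_col: int, end_col: int) -> tuple[int, int]:
        """(m, n) magnitudes among steps with column in [start_col, end_col]."""
        sel = (self.columns >= start_col) & (self.columns <= end_col)
        up = int(self.magnitudes[sel & (self.signs > 0)].sum())
        down = int(self.magnitudes[sel & (self.signs < 0)].sum())
        return up, down


@dataclass(frozen=True)
class MaxDescent:
    """Maximum peak-to-subsequent-trough drop of a walk.

    ``start_col``/``end_col`` are the alignment columns of the first and last
    steps of the descent (both are down steps); both are None for k == 0.
    """

    k: int
    start_col: Optional[int] = None
    end_col: Optional[int] = None

    @property
    def empty(self) -> bool:
        return self.k == 0


@dataclass
class TestResult:
    """Outcome of a conversion test on one paralog pair and outgroup."""

    p_value: float
    criterion: int
    interval: MaxDescent
    m: int
    n: int
    direction: str = "unknown"  # "row1->row2" | "row2->row1" | "unknown"
    direction_p: Optional[float] = None
    p_binom_param: Optional[float] = None


def classify_site(base_primary: str, base_paralog: str, base_ortholog: str) -> str:
    """Classify one alignment column as 'up', 'down', or 'neutral'.

    Down when the primary matches its paralog but not the ortholog (the
    conversion-like pattern); up when it matches the ortholog but not the
    paralog.  All three bases must be unambiguous nucleotides.
    """
    triple = (base_primary.upper(), base_paralog.upper(), base_ortholog.upper())
    if any(ord(b) not in _ACGT for b in triple):
        raise ValueError(f"classify_site needs unambiguous nucleotides, got {triple}")
    p, par, orth = triple
    if p == par and p != orth:
        return "down"
    if p == orth and p != par:
        return "up"
    return "neutral"


def build_triplet_walk(
    paralog, projection: np.ndarray, primary_row: int
) -> StepSeries:
    """Step series of the triplet [primary, paralog, ortholog-projection].

    ``projection`` gives the outgroup base (uint8 code, 0 = uncovered) per
    paralog-alignment column, as produced by
    :func:`paraconv.io.project_onto_paralog_columns` for ``primary_row``.
    Columns with any gap, ambiguity code, or uncovered projection contribute
    no step.
    """
    prim = paralog._chars(primary_row)
    par = paralog._chars(2 if primary_row == 1 else 1)
    orth = np.asarray(projection, dtype=np.uint8)
    if len(orth) != len(paralog):
        raise ValueError("projection length must equal alignment length")
    ok = np.isin(prim, _ACGT_ARR) & np.isin(par, _ACGT_ARR) & np.isin(orth, _ACGT_ARR)
    down = ok & (prim == par) & (prim != orth)
    up = ok & (prim == orth) & (prim != par)
    cols = np.flatnonzero(up | down)
    signs = np.where(up[cols], 1, -1)
    return StepSeries(cols, signs, np.ones(len(cols), dtype=np.int64), len(paralog))


def combine_quadruplet(walk1: StepSeries, walk2: StepSeries) -> StepSeries:
    """Merge the two triplet walks of a quadruplet test.

    Columns stepped in only one triplet keep magnitude 1; columns stepped in
    both get a single magnitude-2 step.  A column up in one triplet and down
    in the other cannot arise (both triplets share the paralog-match
    condition) and raises.
    """
    if walk1.total_columns != walk2.total_columns:
        raise ValueError("walks must index the same paralog alignment")
    cols = np.union1d(walk1.columns, walk2.columns)
    s1 = np.zeros(len(cols), dtype=np.int64)
    s2 = np.zeros(len(cols), dtype=np.int64)
    s1[np.searchsorted(cols, walk1.columns)] = walk1.signs * walk1.magnitudes
    s2[np.searchsorted(cols, walk2.columns)] = walk2.signs * walk2.magnitudes
    if np.any((s1 * s2) < 0):
        raise ValueError(
            "a column is up in one triplet and down in the other; "
            "the two triplets share their paralogous nucleotides so this "
            "indicates inconsistent inputs"
        )
    total = s1 + s2
    keep = total != 0
    cols, total = cols[keep], total[keep]
    return StepSeries(
        cols, np.sign(total), np.abs(total), walk1.total_columns
    )


def collapse_magnitudes(walk: StepSeries) -> StepSeries:
    """One unit step per informative column, keeping signs.

    The exact null of :func:`max_descent_pvalue` assumes the steps are
    exchangeable; the items that are exchangeable under the no-conversion
    null are the informative *columns*, not the expanded unit magnitudes
    (a magnitude-2 step would expand into two glued unit steps, which a
    uniform reordering would separate).  Quadruplet tests therefore collapse
    magnitudes before computing (m, n, k) and the P-value.
    """
    return StepSeries(
        walk.columns,
        walk.signs,
        np.ones(len(walk), dtype=np.int64),
        walk.total_columns,
    )


def maximum_descent(walk: StepSeries) -> MaxDescent:
    """Largest drop from a running maximum to its subsequent minimum.

    k = max over i < j of (height_i - height_j).  On ties the first
    (leftmost) maximal descent is reported; its interval runs from the first
    step after the peak to the step reaching the minimum.
    """
    if len(walk) == 0:
        return MaxDescent(0)
    values = walk.signs * walk.magnitudes
    heights = np.concatenate(([0], np.cumsum(values)))
    runmax = np.maximum.accumulate(heights)
    drawdown = runmax - heights
    k = int(drawdown.max())
    if k == 0:
        return MaxDescent(0)
    j = int(np.argmax(drawdown >= k))  # first index reaching depth k
    peak_val = runmax[j]
    # last attainment of the running max before j: the descent itself
    i = j - int(np.argmax(heights[: j + 1][::-1] == peak_val))
    # steps i+1 .. j (1-based over heights) are the descent; map to columns.
    return MaxDescent(k, int(walk.columns[i]), int(walk.columns[j - 1]))


def _survival_numpy(m: int, n: int, k: int) -> float:
    total = m + n
    # dp[d, w]: probability downs-used == d and drawdown == w (< k), walk alive
    dp = np.zeros((n + 1, k))
    dp[0, 0] = 1.0
    d_idx = np.arange(n + 1, dtype=np.float64)
    for t in range(total):
        rem = total - t
        pd = np.clip((n - d_idx) / rem, 0.0, 1.0)[:, None]
        up_part = dp * (1.0 - pd)
        down_part = dp * pd
        new = np.zeros_like(dp)
        # up step: drawdown w -> max(w - 1, 0)
        new[:, 0] = up_part[:, 0]
        if k > 1:
            new[:, 0] += up_part[:, 1]
            new[:, 1 : k - 1] += up_part[:, 2:k]
        # down step: drawdown w -> w + 1, dying at k
        new[1:, 1:] += down_part[:-1, : k - 1]
        dp = new
    return float(dp.sum())


def _survival_kernel(m: int, n: int, k: int) -> float:  # pragma: no cover
    # overwritten by the numba-compiled version below when available
    return _survival_numpy(m, n, k)


try:  # optional JIT of the DP inner loops; the numpy path is equivalent
    from numba import njit as _njit

    @_njit(cache=True)
    def _survival_kernel(m, n, k):  # type: ignore[no-redef]  # noqa: F811
        total = m + n
        dp = np.zeros((n + 1, k))
        new = np.zeros((n + 1, k))
        dp[0, 0] = 1.0
        for t in range(total):
            rem = total - t
            d_lo = t - m if t - m > 0 else 0
            d_hi = t if t < n else n
            new[:, :] = 0.0
            for d in range(d_lo, d_hi + 1):
                pd = (n - d) / rem
                pu = 1.0 - pd
                w_hi = d if d < k - 1 else k - 1
                for w in range(0, w_hi + 1):
                    mass = dp[d, w]
                    if mass == 0.0:
                        continue
                    # up step: drawdown shrinks toward 0
                    new[d, w - 1 if w > 0 else 0] += mass * pu
                    # down step: drawdown grows, dying at k
                    if w + 1 < k:
                        new[d + 1, w + 1] += mass * pd
            dp, new = new, dp
        return dp.sum()

except ImportError:  # pragma: no cover
    pass


@lru_cache(maxsize=200_000)
def max_descent_pvalue(m: int, n: int, k: int) -> float:
    """Exact P(max descent of H_{m,n} >= k) under random step order.

    Computed by a lattice dynamic program over (steps placed, down steps
    used, current drawdown < k), i.e. the survival probability of never
    reaching drawdown k, using the hypergeometric step probabilities of
    drawing without replacement from m up and n down steps.  Handles m + n
    in the thousands.
    """
    if m < 0 or n < 0 or k < 0:
        raise ValueError("m, n, k must be non-negative")
    if k == 0:
        return 1.0
    if k > n:
        return 0.0
    if m == 0:
        return 1.0  # all downs: descent is n >= k
    survival = float(_survival_kernel(int(m), int(n), int(k)))
    return float(min(max(1.0 - survival, 0.0), 1.0))


def binomial_coverage_pvalue(m: int, n: int) -> tuple[float, float]:
    """Binomial upper tail P(X >= n), X ~ Bin(m+n, p), p = min(0.5, n/(n+m)).

    The whole-paralog (criterion 2) test: with the duplication predating the
    speciation, the per-site down probability is at most 0.5, and p is
    estimated from the observed counts.  Returns ``(p_value, p)``.
    """
    if m < 0 or n < 0:
        raise ValueError("m and n must be non-negative")
    if m + n == 0:
        raise ValueError("no informative sites (m + n == 0)")
    p = min(0.5, n / (n + m))
    p_value = float(stats.binom.sf(n - 1, m + n, p))
    return min(p_value, 1.0), p


def infer_direction(
    walk1: StepSeries,
    walk2: StepSeries,
    shared: MaxDescent,
    alpha: float = 0.05,
) -> tuple[str, Optional[float]]:
    """Donor/recipient call from the two triplets of a quadruplet test.

    Within the shared descent interval the recipient's own ortholog has
    diverged at paralog-age distance (its tract was overwritten), so the
    recipient's triplet shows the *higher* proportion of down
    (paralog-match) steps.  The two proportions are compared with Fisher's
    exact test; an insignificant difference yields "unknown".

    ``walk1`` must be the triplet with row 1 as primary and ``walk2`` the one
    with row 2 as primary.  Directions are reported donor->recipient.
    """
    if shared.empty or shared.start_col is None:
        return "unknown", None
    m1, n1 = walk1.counts_in(shared.start_col, shared.end_col)
    m2, n2 = walk2.counts_in(shared.start_col, shared.end_col)
    if m1 + n1 == 0 or m2 + n2 == 0:
        return "unknown", None
    q1, q2 = n1 / (m1 + n1), n2 / (m2 + n2)
    if q1 == q2:
        return "unknown", None
    _, p = stats.fisher_exact([[n1, m1], [n2, m2]])
    if p >= alpha:
        return "unknown", float(p)
    # higher down-proportion -> that triplet's primary is the recipient
    direction = "row2->row1" if q1 > q2 else "row1->row2"
    return direction, float(p)
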