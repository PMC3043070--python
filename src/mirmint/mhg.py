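"""Minimum-hypergeometric (mHG) ranked-list enrichment.

Given a ranked universe of N genes of which B belong to a set H, the
binary membership vector lambda has prefix counts b_n. The mHG score is

    s = min_{1 <= n <= N}  HGT(b_n; N, B, n)

where HGT(b; N, B, n) = P(X >= b) for X hypergeometric (population N,
B successes, n draws). The exact p-value P(mHG <= s) over all C(N, B)
equiprobable arrangements of lambda is computed by dynamic programming
over the (n, b) lattice with the sub-threshold cells absorbed into the
rejection event, so no correction for the threshold optimization is
needed. All tail computations run in log space for numerical stability;
mass that first enters the rejection region is accumulated directly,
which keeps tiny p-values accurate (no 1 - survival cancellation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb, lgamma
from typing import Sequence

import numpy as np
import pandas as pd

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

logger = logging.getLogger(__name__)

__all__ = [
    "RankedLabelVector",
    "EnrichmentResult",
    "hypergeometric_tail",
    "log_hypergeometric_tail",
    "mhg_statistic",
    "mhg_exact_pvalue",
    "mhg_exact_pvalue_rational",
    "mhg_test",
    "enrich_ranked_list",
]

# log-scale slack when deciding whether a lattice cell's tail reaches the
# observed minimum; absorbs double-precision noise in tail evaluation
_LOG_TOL = 1e-9
_TINY = float(np.finfo(float).tiny)


@dataclass
class RankedLabelVector:
    """Binary membership vector over a ranked universe."""

    lam: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=np.int64)
        if self.lam.ndim != 1 or self.lam.size == 0:
            raise ValueError("label vector must be non-empty 1-D")
        if not np.all((self.lam == 0) | (self.lam == 1)):
            raise ValueError("label vector must be binary")

    @property
    def N(self) -> int:
        return int(self.lam.size)

    @property
    def B(self) -> int:
        return int(self.lam.sum())

    def prefix_counts(self) -> np.ndarray:
        """b_n for n = 1..N."""
        return np.cumsum(self.lam)


@dataclass
class EnrichmentResult:
    set_name: str
    s: float
    n_star: int
    b_star: int
    p_exact: float
    q: float
    direction: str  # 'correlated' | 'anti-correlated' | 'ranked'


def log_hypergeometric_tail(b: int, N: int, B: int, n: int) -> float:
    """log P(X >= b) for hypergeometric X ~ (population N, successes B,
    draws n), exact -inf/0.0 at the boundaries."""
    _check_hgt_args(b, N, B, n)
    if b <= max(0, n - (N - B)):
        return 0.0
    if b > min(n, B):
        return -math.inf
    G = _lgamma_table(N)
    return _log_tail_scalar(G, N, B, n, b)


def hypergeometric_tail(b: int, N: int, B: int, n: int) -> float:
    """P(X >= b); computed in log space then exponentiated."""
    return math.exp(log_hypergeometric_tail(b, N, B, n))


def _check_hgt_args(b: int, N: int, B: int, n: int) -> None:
    if N < 0 or not 0 <= B <= N or not 0 <= n <= N or b < 0:
        raise ValueError(f"invalid hypergeometric parameters b={b} N={N} B={B} n={n}")


@lru_cache(maxsize=64)
def _lgamma_table(N: int) -> np.ndarray:
    # G[i] = log(i!)
    return np.array([lgamma(i + 1) for i in range(N + 1)])


@njit(cache=True)
def _log_tail_scalar(G, N, B, n, b):  # pragma: no cover - numba kernel
    const = G[N] - G[B] - G[N - B]
    hi = min(n, B)
    acc = -np.inf
    for j in range(b, hi + 1):
        lp = G[n] - G[j] - G[n - j] + G[N - n] - G[B - j] - G[N - n - B + j] - const
        if lp > acc:
            acc = lp + np.log1p(np.exp(acc - lp))
        else:
            acc = acc + np.log1p(np.exp(lp - acc))
    return acc


@njit(cache=True)
def _row_log_tails(G, N, B, n, tails):  # pragma: no cover - numba kernel
    """Fill tails[b] = log HGT(b; N, B, n) for b in [lo, hi] by one
    reverse log-sum-exp accumulation over the row's pmf; returns (lo, hi)."""
    const = G[N] - G[B] - G[N - B]
    lo = n - (N - B)
    if lo < 0:
        lo = 0
    hi = min(n, B)
    acc = -np.inf
    for j in range(hi, lo - 1, -1):
        lp = G[n] - G[j] - G[n - j] + G[N - n] - G[B - j] - G[N - n - B + j] - const
        if lp > acc:
            acc = lp + np.log1p(np.exp(acc - lp))
        else:
            acc = acc + np.log1p(np.exp(lp - acc))
        tails[j] = acc
    tails[lo] = 0.0  # X >= lo is certain; pin to avoid accumulated rounding
    return lo, hi


@njit(cache=True)
def _stat_kernel(G, N, B, prefix):  # pragma: no cover - numba kernel
    """(log_s, n_star, b_star): minimum log tail over prefix cuts.

    For fixed b the tail increases strictly with n, so the minimum is
    attained where the path increments (lambda_n = 1); only those cells
    are evaluated. An all-ones-late vector attains s = 1, reported at
    the smallest cut n = 1.
    """
    best = np.inf
    n_star = 1
    b_star = int(prefix[0])
    for idx in range(N):
        n = idx + 1
        if idx > 0 and prefix[idx] == prefix[idx - 1]:
            continue
        b = int(prefix[idx])
        lo = n - (N - B)
        if lo < 0:
            lo = 0
        if b <= lo:
            lt = 0.0
        else:
            lt = _log_tail_scalar(G, N, B, n, b)
        if lt < best:
            best = lt
            n_star = n
            b_star = b
    if best >= 0.0:  # no cut beats tail 1; smallest-n tie-break
        return 0.0, 1, int(prefix[0])
    return best, n_star, b_star


@njit(cache=True)
def _path_log_tails(G, N, B, prefix):  # pragma: no cover - numba kernel
    """log HGT(b_n; N, B, n) for n = 1..N along the observed path."""
    out = np.empty(N)
    tails = np.empty(B + 1)
    for idx in range(N):
        n = idx + 1
        b = prefix[idx]
        lo, hi = _row_log_tails(G, N, B, n, tails)
        if b <= lo:
            out[idx] = 0.0
        else:
            out[idx] = tails[b]
    return out


@njit(cache=True)
def _mhg_pvalue_kernel(G, N, B, log_s, log_tol):  # pragma: no cover
    """P(mHG <= s) by forward DP over the (n, b) lattice.

    alive[b] holds the probability that a random arrangement has b ones
    in its length-n prefix and has not yet entered the rejection region
    {cells with log tail <= log_s + tol}; mass entering the region is
    moved to the event accumulator at its first hit.
    """
    if B == 0 or B == N:
        return 1.0 if log_s >= -log_tol else 0.0
    const = G[N] - G[B] - G[N - B]
    alive = np.zeros(B + 1)
    alive[0] = 1.0
    event = 0.0
    thresh = log_s + log_tol
    for n in range(1, N + 1):
        nxt = np.zeros(B + 1)
        lo_prev = max(0, (n - 1) - (N - B))
        hi_prev = min(n - 1, B)
        remaining = N - (n - 1)
        mass = 0.0
        for b in range(lo_prev, hi_prev + 1):
            a = alive[b]
            if a == 0.0:
                continue
            mass += a
            p1 = (B - b) / remaining
            if b + 1 <= B:
                nxt[b + 1] += a * p1
            nxt[b] += a * (1.0 - p1)
        if mass == 0.0:
            break  # every path already hit the rejection region
        # absorb cells of this row whose tail reaches the threshold; the
        # tail decreases in b, so accumulate the row's pmf from the top
        # and stop at the first cell above the threshold
        lo = max(0, n - (N - B))
        hi = min(n, B)
        bmin = lo
        acc = -np.inf
        for b in range(hi, lo - 1, -1):
            lp = G[n] - G[b] - G[n - b] + G[N - n] - G[B - b] - G[N - n - B + b] - const
            if lp > acc:
                acc = lp + np.log1p(np.exp(acc - lp))
            else:
                acc = acc + np.log1p(np.exp(lp - acc))
            lt = 0.0 if b == lo else acc
            if lt > thresh:
                bmin = b + 1
                break
        for b in range(bmin, hi + 1):
            event += nxt[b]
            nxt[b] = 0.0
        alive = nxt
    if event > 1.0:
        event = 1.0
    return event


def mhg_statistic(v: RankedLabelVector) -> tuple[float, int, int]:
    """mHG score: (s, n_star, b_star) with s the minimum hypergeometric
    tail over all prefix cuts n = 1..N; ties broken by the smallest n."""
    log_s, n_star, b_star = _mhg_statistic_log(v)
    return math.exp(log_s), n_star, b_star


def _mhg_statistic_log(v: RankedLabelVector) -> tuple[float, int, int]:
    N, B = v.N, v.B
    if B == 0:
        return 0.0, 1, 0  # every tail equals 1
    G = _lgamma_table(N)
    prefix = v.prefix_counts()
    log_s, n_star, b_star = _stat_kernel(G, N, B, prefix)
    return float(log_s), int(n_star), int(b_star)


def mhg_exact_pvalue(s: float, N: int, B: int) -> float:
    """Exact P(mHG <= s) over all C(N, B) arrangements, by lattice DP.

    ``s`` should be an attained tail value (as returned by
    :func:`mhg_statistic`); a small log-scale tolerance absorbs rounding
    in the comparison of lattice-cell tails against s.
    """
    if not 0 < s <= 1:
        raise ValueError("s must lie in (0, 1]")
    if not 0 <= B <= N or N < 1:
        raise ValueError("need 0 <= B <= N, N >= 1")
    if B == 0:
        return 1.0
    G = _lgamma_table(N)
    p = float(_mhg_pvalue_kernel(G, N, B, math.log(s), _LOG_TOL))
    return max(p, _TINY)


def _mhg_exact_pvalue_from_log(log_s: float, N: int, B: int) -> float:
    if B == 0:
        return 1.0
    G = _lgamma_table(N)
    return max(float(_mhg_pvalue_kernel(G, N, B, log_s, _LOG_TOL)), _TINY)


def mhg_test(v: RankedLabelVector) -> tuple[float, int, int, float]:
    """One-stop mHG test: returns (s, n_star, b_star, p_exact)."""
    log_s, n_star, b_star = _mhg_statistic_log(v)
    p = _mhg_exact_pvalue_from_log(log_s, v.N, v.B)
    s = math.exp(log_s)
    if p < s:  # p >= s analytically; enforce under rounding
        p = s
    return s, n_star, b_star, min(p, 1.0)


def attainable_level(alpha: float, N: int, B: int) -> float:
    """The exact null probability P(p_exact <= alpha): the largest
    attainable mHG p-value not exceeding ``alpha``.

    The mHG p-value is a discrete statistic; this is the level a nominal
    cutoff ``alpha`` actually realizes, used to center calibration
    checks. Found by bisecting the sorted set of attainable tail values
    (the HGT values of all lattice cells) against the exact DP p-value.
    """
    if B == 0:
        return 0.0 if alpha < 1 else 1.0
    G = _lgamma_table(N)
    cand = []
    tails = np.empty(B + 1)
    for n in range(1, N + 1):
        lo, hi = _row_log_tails(G, N, B, n, tails)
        cand.extend(tails[lo : hi + 1])
    cand = np.unique(np.asarray(cand))
    best = 0.0
    lo_i, hi_i = 0, len(cand) - 1
    while lo_i <= hi_i:
        mid = (lo_i + hi_i) // 2
        p = _mhg_exact_pvalue_from_log(float(cand[mid]), N, B)
        if p <= alpha:
            best = p
            lo_i = mid + 1
        else:
            hi_i = mid - 1
    return best


# -- exact big-rational mode (test oracle for moderate N) --------------------


@lru_cache(maxsize=None)
def _tail_count(b: int, N: int, B: int, n: int) -> int:
    """sum_{j>=b} C(n, j) C(N-n, B-j): numerator of HGT over C(N, B)."""
    return sum(comb(n, j) * comb(N - n, B - j) for j in range(b, min(n, B) + 1))


def mhg_statistic_rational(v: RankedLabelVector) -> Fraction:
    N, B = v.N, v.B
    if B == 0:
        return Fraction(1)
    denom = comb(N, B)
    prefix = v.prefix_counts()
    best = Fraction(1)
    for n in range(1, N + 1):
        t = Fraction(_tail_count(int(prefix[n - 1]), N, B, n), denom)
        if t < best:
            best = t
    return best


def mhg_exact_pvalue_rational(s: Fraction, N: int, B: int) -> Fraction:
    """Exact rational P(mHG <= s) by integer lattice-path counting
    (paths avoiding cells with tail <= s); intended as an independent
    slow-but-exact mode for moderate N."""
    if B == 0:
        return Fraction(1)
    denom = comb(N, B)

    def rejected(n: int, b: int) -> bool:
        return _tail_count(b, N, B, n) * s.denominator <= s.numerator * denom

    dp = [0] * (B + 1)
    if rejected(0, 0):
        return Fraction(1)
    dp[0] = 1
    for n in range(1, N + 1):
        new = [0] * (B + 1)
        lo = max(0, n - (N - B))
        hi = min(n, B)
        for b in range(lo, hi + 1):
            if rejected(n, b):
                continue
            new[b] = dp[b] + (dp[b - 1] if b > 0 else 0)
        dp = new
    return Fraction(denom - dp[B], denom)


# -- gene-set enrichment over a ranked list ----------------------------------


def build_label_vector(
    ranked_genes: Sequence[str], members: Sequence[str]
) -> RankedLabelVector:
    member_set = set(members)
    return RankedLabelVector(
        np.fromiter((g in member_set for g in ranked_genes), dtype=np.int64)
    )


def enrich_ranked_list(
    ranking,
    sets,
    direction: str = "ranked",
) -> pd.DataFrame:
    """mHG enrichment of each gene set within a ranked gene list.

    ``ranking`` is a :class:`~mirmint.pivot.RankedList` or a plain
    sequence of gene ids (best rank first). Each set is intersected with
    the ranking universe; sets with empty intersection are skipped with
    a logged warning. BH-FDR ``q`` is computed across the tested sets.
    Rows sorted ascending by ``p_exact``, ties by set name.
    """
    genes = list(getattr(ranking, "genes", ranking))
    if not genes:
        raise ValueError("empty ranking universe")
    universe = set(genes)
    rows = []
    for name in sets.names():
        members = [g for g in sets.members(name) if g in universe]
        if not members:
            logger.warning("gene set %r has empty intersection with universe", name)
            continue
        v = build_label_vector(genes, members)
        s, n_star, b_star, p = mhg_test(v)
        rows.append(
            {
                "set_name": name,
                "s": s,
                "n_star": n_star,
                "b_star": b_star,
                "p_exact": p,
                "direction": direction,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    from .tnom import bh_fdr

    df["q"] = bh_fdr(df["p_exact"].to_numpy())
    df = df.sort_values(["p_exact", "set_name"], kind="mergesort").reset_index(
        drop=True
    )
    return df[["set_name", "s", "n_star", "b_star", "p_exact", "q", "direction"]]
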