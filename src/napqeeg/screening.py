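"""Cohort-level correlation screening.

Two kinds of screens are performed against per-subject covariates (age,
dementia-scale score, cognitive test scores):

* scalar sleep variables (macrostructure, per-state LZC) -- Spearman rank
  correlations with two-stage adaptive Benjamini-Krieger-Yekutieli (BKY)
  false-discovery-rate adjustment within each results table;
* frequency-resolved variables (relative power, Fisher-z coherence) -- a
  bin-to-bin Spearman screen on the 0.25 Hz grid, with multiplicity handled
  by Rueger's-areas cluster significance: a maximal run of adjacent bins with
  p < 0.05 is significant as a whole iff at least half of its p-values are
  below 0.05/2 and at least a third are below 0.05/3.

Subjects missing a variable (e.g., a state never entered) are dropped
pairwise; screens with fewer than four complete pairs are flagged as not
computable rather than estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ALPHA",
    "RUGER_HALF",
    "RUGER_THIRD",
    "CorrelationResult",
    "FDRResult",
    "RugerArea",
    "BinwiseScreenResult",
    "spearman",
    "spearman_matrix",
    "bky_adjust",
    "ruger_decide",
    "extract_areas",
    "binwise_screen",
]

#: conventional significance level; the Rueger sub-thresholds derive from it
ALPHA = 0.05
RUGER_HALF = ALPHA / 2.0
RUGER_THIRD = ALPHA / 3.0

MIN_PAIRS = 4


@dataclass
class CorrelationResult:
    variable: str
    by_variable: str
    rho: float
    p_raw: float
    n_pairs: int
    q: float = np.nan
    computable: bool = True
    reason: str = ""


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with pairwise deletion of missing values.

    rho uses average ranks (ties averaged); the two-sided p-value comes from
    the t approximation t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of
    freedom, except that |rho| = 1 (where the t statistic diverges) is
    assigned its exact permutation tail 2/n!.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < MIN_PAIRS:
        return CorrelationResult(
            "", "", np.nan, np.nan, n, computable=False,
            reason=f"only {n} complete pairs (< {MIN_PAIRS})",
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            "", "", np.nan, np.nan, n, computable=False,
            reason="zero variance in one variable",
        )
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-12:
        rho = float(np.sign(rho))
        p = min(1.0, 2.0 / math.factorial(n))
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult("", "", rho, p, n)


def spearman_matrix(responses: np.ndarray, covariate: np.ndarray):
    """Vectorized per-column Spearman of an (n_subjects, n_vars) matrix.

    Missing entries (NaN) are deleted pairwise per column.  Returns
    ``(rho, p, n)`` arrays; columns with < 4 pairs or zero variance are NaN.
    """
    responses = np.asarray(responses, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    n_vars = responses.shape[1]
    rho = np.full(n_vars, np.nan)
    p = np.full(n_vars, np.nan)
    npairs = np.zeros(n_vars, dtype=int)
    # group columns by missingness pattern so complete matrices rank in bulk
    miss = np.isnan(responses) | np.isnan(covariate)[:, None]
    patterns: dict[bytes, list[int]] = {}
    for j in range(n_vars):
        patterns.setdefault(miss[:, j].tobytes(), []).append(j)
    for key, cols in patterns.items():
        mask = ~np.frombuffer(key, dtype=bool)
        n = int(mask.sum())
        npairs[np.array(cols)] = n
        if n < MIN_PAIRS:
            continue
        c = covariate[mask]
        if np.ptp(c) == 0:
            continue
        rc = stats.rankdata(c)
        sub = responses[np.ix_(mask, cols)]
        rr = stats.rankdata(sub, axis=0)
        rc0 = rc - rc.mean()
        rr0 = rr - rr.mean(axis=0)
        denom = np.sqrt((rc0 @ rc0) * (rr0 * rr0).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (rc0 @ rr0) / denom
        r[denom == 0] = np.nan  # zero-variance response column
        r = np.clip(r, -1.0, 1.0)
        tied = np.abs(r) >= 1.0 - 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
        pcol = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        pcol[tied] = min(1.0, 2.0 / math.factorial(n))
        rho[np.array(cols)] = r
        p[np.array(cols)] = pcol
    return rho, p, npairs


# ---------------------------------------------------------------------------
# two-stage adaptive FDR (Benjamini, Krieger & Yekutieli)
# ---------------------------------------------------------------------------

@dataclass
class FDRResult:
    p_raw: np.ndarray
    q: np.ndarray
    reject: np.ndarray
    level: float


def _bh_reject(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the linear step-up (BH) procedure."""
    m = len(p_sorted)
    crit = level * (np.arange(1, m + 1) / m)
    passed = np.nonzero(p_sorted <= crit)[0]
    return 0 if len(passed) == 0 else int(passed[-1]) + 1


def _two_stage_reject_count(p_sorted: np.ndarray, level: float) -> int:
    """Rejections of the BKY two-stage step-up at FDR ``level``.

    Stage 1: BH at level' = level / (1 + level).  If it rejects nothing or
    everything, stop.  Otherwise estimate m0 = m - r1 and run BH at
    level' * m / m0.
    """
    m = len(p_sorted)
    lvl1 = level / (1.0 + level)
    r1 = _bh_reject(p_sorted, lvl1)
    if r1 == 0 or r1 == m:
        return r1
    lvl2 = lvl1 * m / (m - r1)
    return _bh_reject(p_sorted, lvl2)


def bky_adjust(p_values, level: float = ALPHA) -> FDRResult:
    """Two-stage adaptive FDR adjustment.

    q-values are defined operationally as the smallest FDR level at which the
    full two-stage procedure rejects the test (found by bisection; rejection
    is monotone in the level), then made monotone nondecreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    m = len(p)
    q_sorted = np.empty(m)
    for i in range(m):
        # smallest level at which test (i) [sorted] is rejected
        lo, hi = 0.0, 1.0
        if _two_stage_reject_count(p_sorted, hi) <= i:
            q_sorted[i] = 1.0
            continue
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if _two_stage_reject_count(p_sorted, mid) > i:
                hi = mid
            else:
                lo = mid
        q_sorted[i] = hi
    q_sorted = np.maximum.accumulate(q_sorted)  # monotone in p
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    reject = np.zeros(m, dtype=bool)
    r = _two_stage_reject_count(p_sorted, level)
    reject[order[:r]] = True
    return FDRResult(p_raw=p, q=q, reject=reject, level=level)


# ---------------------------------------------------------------------------
# Rueger's areas
# ---------------------------------------------------------------------------

@dataclass
class RugerArea:
    """A maximal run of adjacent frequency bins all with p < 0.05."""

    f_lo: float
    f_hi: float
    p_values: np.ndarray
    frac_below_half: float
    frac_below_third: float
    significant: bool

    @property
    def n_bins(self) -> int:
        return len(self.p_values)


def ruger_decide(p_values, f_lo: float = np.nan, f_hi: float = np.nan) -> RugerArea:
    """Decide one contiguous cluster of conventionally significant bins.

    The cluster is significant as a whole iff at least half of its p-values
    are strictly below 0.05/2 = 0.025 and at least a third are strictly below
    0.05/3 ~= 0.0167.  Every member must satisfy p < 0.05; a single-bin
    cluster is legal (one p < 0.05/3 bin passes both fractions).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("a cluster must contain at least one p-value")
    if np.any(p >= ALPHA) or np.any(np.isnan(p)):
        raise ValueError("malformed cluster: every member must have p < 0.05")
    n = len(p)
    frac_half = float(np.sum(p < RUGER_HALF)) / n
    frac_third = float(np.sum(p < RUGER_THIRD)) / n
    significant = (frac_half >= 0.5) and (frac_third >= 1.0 / 3.0)
    return RugerArea(f_lo, f_hi, p, frac_half, frac_third, significant)


def extract_areas(bins: np.ndarray, p: np.ndarray) -> list[RugerArea]:
    """All maximal runs of adjacent bins with p < 0.05, each decided."""
    bins = np.asarray(bins, dtype=float)
    p = np.asarray(p, dtype=float)
    sig = (p < ALPHA) & ~np.isnan(p)
    areas: list[RugerArea] = []
    i = 0
    n = len(p)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1]:
            j += 1
        areas.append(ruger_decide(p[i : j + 1], bins[i], bins[j]))
        i = j + 1
    return areas


@dataclass
class BinwiseScreenResult:
    covariate: str
    response: str
    bins: np.ndarray
    rho: np.ndarray
    p_raw: np.ndarray
    n_pairs: np.ndarray
    areas: list[RugerArea] = field(default_factory=list)
    computable: bool = True
    reason: str = ""

    @property
    def significant_areas(self) -> list[RugerArea]:
        return [a for a in self.areas if a.significant]


def binwise_screen(
    responses: np.ndarray,
    covariate,
    bins,
    *,
    covariate_name: str = "",
    response_name: str = "",
) -> BinwiseScreenResult:
    """Bin-to-bin Spearman screen of a spectrum matrix against one covariate.

    ``responses`` is (n_subjects, n_bins); subjects whose row is entirely
    missing (state never entered) are dropped whole.  Rueger areas are
    extracted from the per-bin p-values.
    """
    responses = np.asarray(responses, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    bins = np.asarray(bins, dtype=float)
    if responses.shape[0] != len(covariate):
        raise ValueError("responses and covariate must align on subjects")
    if responses.shape[1] != len(bins):
        raise ValueError("responses and bins must align on frequency")
    keep = ~(np.isnan(responses).all(axis=1) | np.isnan(covariate))
    sub = responses[keep]
    cov = covariate[keep]
    nb = len(bins)
    if keep.sum() < MIN_PAIRS:
        return BinwiseScreenResult(
            covariate_name, response_name, bins,
            np.full(nb, np.nan), np.full(nb, np.nan),
            np.full(nb, int(keep.sum())), [],
            computable=False,
            reason=f"only {int(keep.sum())} subjects with this state (< {MIN_PAIRS})",
        )
    if np.ptp(cov) == 0:
        return BinwiseScreenResult(
            covariate_name, response_name, bins,
            np.full(nb, np.nan), np.full(nb, np.nan),
            np.full(nb, int(keep.sum())), [],
            computable=False, reason="constant covariate",
        )
    rho, p, npairs = spearman_matrix(sub, cov)
    areas = extract_areas(bins, p)
    return BinwiseScreenResult(
        covariate_name, response_name, bins, rho, p, npairs, areas
    )
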