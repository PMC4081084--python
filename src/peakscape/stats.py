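"""Enrichment and distribution tests used by the pipeline.

The 2x2 chi-square uses the closed-form Pearson statistic with df = 1
(optional Yates continuity correction, off by default — reported p-values
here are raw, uncorrected for multiplicity).  The Wilcoxon rank-sum test
enumerates the exact null distribution for small untied samples
(n + m <= 12) and otherwise falls back to the tie-corrected normal
approximation.  Proportion intervals are Wilson score intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats as sps

MACHINE_P_FLOOR = 2.2e-16


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value outside [0,1]: {self.p_value}")

    def p_text(self) -> str:
        """Human-readable p; values below the double floor print as an
        inequality, matching common statistical-software output."""
        return f"< {MACHINE_P_FLOOR:g}" if self.p_value < MACHINE_P_FLOOR else f"{self.p_value:.4g}"

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "p_text": self.p_text(),
            "method": self.method,
            **self.details,
        }


def chisq_2x2(table, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 count table.

    ``statistic = N (ad - bc)^2 / (r1 r2 c1 c2)`` with df = 1; with the
    Yates correction |ad - bc| is shrunk by N/2 (floored at 0).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table entries must be non-negative integers")
    a, b, c, d = t.ravel()
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError(
            "a marginal of the 2x2 table is zero; use an exact test instead"
        )
    dev = abs(a * d - b * c)
    if continuity_correction:
        dev = max(dev - n / 2.0, 0.0)
    stat = n * dev * dev / (r1 * r2 * c1 * c2)
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(stat, p, "Pearson chi-square (df=1)"
                      + (", Yates-corrected" if continuity_correction else ""),
                      {"df": 1, "n": int(n)})


def _rank(values: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def wilcoxon_rank_sum(x, y, two_sided: bool = True) -> TestResult:
    """Two-sample Wilcoxon rank-sum test on the rank sum W of ``x``.

    Exact p by enumeration of all C(n+m, n) rank assignments when
    n + m <= 12 and there are no ties; otherwise a normal approximation
    with the usual tie correction of the variance and a 0.5 continuity
    correction.  The two-sided exact p is ``P(|W - E[W]| >= |w - E[W]|)``;
    one-sided p is the tail containing w.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = _rank(combined)
    w = float(ranks[:n].sum())
    total = n + m
    mu = n * (total + 1) / 2.0
    has_ties = len(np.unique(combined)) < total

    if total <= 12 and not has_ties:
        # exact: W under H0 is the sum of a uniformly random n-subset of 1..N
        dev = abs(w - mu)
        hits = 0
        low_tail = 0
        high_tail = 0
        for subset in combinations(range(1, total + 1), n):
            s = sum(subset)
            if abs(s - mu) >= dev - 1e-9:
                hits += 1
            if s <= w + 1e-9:
                low_tail += 1
            if s >= w - 1e-9:
                high_tail += 1
        n_total = comb(total, n)
        if two_sided:
            p = hits / n_total
        else:
            p = (low_tail if w <= mu else high_tail) / n_total
        return TestResult(w, min(p, 1.0), "Wilcoxon rank-sum (exact)",
                          {"n": n, "m": m})

    # normal approximation with tie correction and continuity correction
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n * m / 12.0 * ((total + 1) - tie_term / (total * (total - 1)))
    if var == 0:
        return TestResult(w, 1.0, "Wilcoxon rank-sum (normal approximation)",
                          {"n": n, "m": m, "note": "all observations tied"})
    z = (w - mu) / sqrt(var)
    z_cc = max(abs(w - mu) - 0.5, 0.0) / sqrt(var)
    if two_sided:
        p = 2.0 * float(sps.norm.sf(z_cc))
    else:
        p = float(sps.norm.sf(z_cc))
    return TestResult(w, min(p, 1.0), "Wilcoxon rank-sum (normal approximation)",
                      {"n": n, "m": m, "z": z})


def proportion_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if trials <= 0:
        raise ValueError(f"trials must be > 0, got {trials}")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes {successes} outside [0, {trials}]")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0,1), got {level}")
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    phat = successes / trials
    denom = 1.0 + z * z / trials
    center = (phat + z * z / (2 * trials)) / denom
    half = z * sqrt(phat * (1 - phat) / trials + z * z / (4 * trials * trials)) / denom
    # at the degenerate counts the bound is analytically exact
    lo = 0.0 if successes == 0 else max(0.0, center - half)
    hi = 1.0 if successes == trials else min(1.0, center + half)
    return (lo, hi)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional utility; the pipeline reports raw p)."""
    p = np.asarray(list(p_values), dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n, dtype=float)
    running = 1.0
    for i in range(n - 1, -1, -1):
        rank = i + 1
        running = min(running, p[order[i]] * n / rank)
        adj[order[i]] = running
    return adj
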