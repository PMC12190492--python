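"""Group-level statistics for per-cell contractility readouts.

Two-tailed Mann–Whitney U (exact by enumeration for small tie-free samples,
normal approximation with tie and continuity correction otherwise), the
unpaired t-test computed from printed summary statistics (mean, SEM, n),
mean ± SEM summaries, and fold-ratios of group means. Cells are treated as
the sampling unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "ComparisonResult",
    "mann_whitney_u",
    "unpaired_t_from_summary",
    "group_summary",
    "fold_ratio",
    "significance_stars",
    "render_comparison_text",
]

EXACT_MAX_COMBINED_N = 16


@dataclass
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError(f"sample {self.label!r} is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"sample {self.label!r} contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class ComparisonResult:
    statistic_name: str
    statistic_value: float
    p_value: float
    n_a: int
    n_b: int
    method: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def _u_exact_counts(n_a: int, n_b: int) -> np.ndarray:
    """Null distribution of U_a by subset-sum dynamic programming.

    ``counts[u]`` is the number of rank assignments (subsets of size n_a of
    ranks 1..n) whose U statistic equals u, u in 0..n_a*n_b.
    """
    n = n_a + n_b
    max_sum = n_a * n_b + n_a * (n_a + 1) // 2
    ways = np.zeros((n_a + 1, max_sum + 1), dtype=np.int64)
    ways[0, 0] = 1
    for rank in range(1, n + 1):
        for k in range(min(rank, n_a), 0, -1):
            ways[k, rank:] += ways[k - 1, :-rank or None]
    offset = n_a * (n_a + 1) // 2
    return ways[n_a, offset:offset + n_a * n_b + 1]


def mann_whitney_u(a: GroupSample, b: GroupSample) -> ComparisonResult:
    """Two-tailed Mann–Whitney U test.

    U is computed from midranks; the exact two-tailed p-value
    ``min(1, 2·min(P(U ≤ u), P(U ≥ u)))`` is obtained from the enumerated
    null distribution when ``n_a + n_b ≤ 16`` and there are no ties,
    otherwise the normal approximation with tie correction and continuity
    correction is used. The method actually applied is recorded.
    """
    pooled = np.concatenate([a.values, b.values])
    ranks = sps.rankdata(pooled)
    n_a, n_b = a.n, b.n
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size

    if n_a + n_b <= EXACT_MAX_COMBINED_N and not has_ties:
        counts = _u_exact_counts(n_a, n_b)
        total = counts.sum()
        u_int = int(round(u_a))
        p_le = counts[: u_int + 1].sum() / total
        p_ge = counts[u_int:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        n = n_a + n_b
        mu = n_a * n_b / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1.0))
        var = n_a * n_b / 12.0 * (n + 1.0 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            # continuity correction, toward the mean
            z = (u_a - mu - 0.5 * np.sign(u_a - mu)) / np.sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "normal-approximation"
    return ComparisonResult("U", u_a, p, n_a, n_b, method)


def unpaired_t_from_summary(mean_a: float, sem_a: float, n_a: int,
                            mean_b: float, sem_b: float, n_b: int,
                            welch: bool = False) -> ComparisonResult:
    """Unpaired two-tailed t-test from summary statistics (mean, SEM, n).

    ``t = (mean_a − mean_b) / √(sem_a² + sem_b²)`` with the classic
    Student degrees of freedom ``n_a + n_b − 2``; ``welch=True`` switches
    to Welch–Satterthwaite degrees of freedom.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sem_a < 0 or sem_b < 0:
        raise ValueError("SEMs must be non-negative")
    se2 = sem_a ** 2 + sem_b ** 2
    if se2 == 0:
        if mean_a == mean_b:
            return ComparisonResult("t", 0.0, 1.0, n_a, n_b, "student-t")
        raise ValueError("zero SEMs with unequal means: t undefined")
    t = (mean_a - mean_b) / np.sqrt(se2)
    if welch:
        df = se2 ** 2 / (sem_a ** 4 / (n_a - 1) + sem_b ** 4 / (n_b - 1))
        method = "welch-t"
    else:
        df = n_a + n_b - 2
        method = "student-t"
    p = min(1.0, 2.0 * sps.t.sf(abs(t), df))
    return ComparisonResult("t", float(t), float(p), n_a, n_b, method)


def group_summary(sample: GroupSample) -> tuple[float, float, int]:
    """Mean, SEM (sd with n−1 denominator over √n), and n for one group."""
    n = sample.n
    mean = float(sample.values.mean())
    if n == 1:
        warnings.warn("SEM undefined for a single value; reporting 0",
                      stacklevel=2)
        return mean, 0.0, 1
    sem = float(sample.values.std(ddof=1) / np.sqrt(n))
    return mean, sem, n


def fold_ratio(mean_a: float, mean_b: float) -> float:
    """Ratio of group means; both means must be positive."""
    if mean_b <= 0:
        raise ValueError("denominator mean must be positive")
    if mean_a <= 0:
        raise ValueError("numerator mean must be positive")
    return mean_a / mean_b


def significance_stars(p: float) -> str:
    """Significance label: *** p<0.001, ** p<0.01, * p<0.05, else n.s."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def render_comparison_text(a: GroupSample, b: GroupSample,
                           result: ComparisonResult, quantity: str = "value") -> str:
    """Plain-text summary block: group means ± SEM, n, statistic, p, stars."""
    lines = [f"Comparison of {quantity}"]
    for s in (a, b):
        m, sem, n = group_summary(s)
        lines.append(f"  {s.label}: {m:.4g} ± {sem:.4g} (mean ± SEM, n = {n})")
    lines.append(
        f"  {result.statistic_name} = {result.statistic_value:.4g}, "
        f"p = {result.p_value:.3g} ({result.method}) "
        f"{significance_stars(result.p_value)}"
    )
    return "\n".join(lines)
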