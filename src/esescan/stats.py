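"""Statistics layer: empirical p-values, normalized density, exact binomial,
Goodman–Kruskal gamma with a shuffle null, partial rank correlation, and
Holm's step-down adjustment.

All empirical p-values use the add-one rule p = (n_extreme + 1) / (m + 1)
with ties counted as extreme, so the smallest attainable p is 1/(m+1) and 0
is never returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class EmpiricalTest:
    observed: float
    n_extreme: int
    m: int
    p: float
    tail: str

    @property
    def floor(self) -> float:
        return 1.0 / (self.m + 1)


def empirical_p(observed: float, null_values, tail: str = "greater") -> EmpiricalTest:
    """Rank-based tail probability of an observation in a simulated null."""
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if tail == "greater":
        n_extreme = int(np.count_nonzero(null >= observed))
    elif tail == "less":
        n_extreme = int(np.count_nonzero(null <= observed))
    else:
        raise ValueError(f"tail must be 'greater' or 'less', got {tail!r}")
    m = int(null.size)
    return EmpiricalTest(float(observed), n_extreme, m, (n_extreme + 1) / (m + 1), tail)


@dataclass(frozen=True)
class DensityResult:
    """Observed density against a simulated null: ND and both tail p-values.

    ND = (observed - null_mean) / null_mean; -1 iff observed is 0 with a
    positive null mean; nan (undefined-marked) when the null mean is 0.
    """

    observed: float
    null_mean: float
    nd: float
    p_enrich: float
    p_depletion: float
    m: int


def normalized_density(observed: float, null_values) -> DensityResult:
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    mean = float(null.mean())
    if mean <= 0:
        return DensityResult(float(observed), mean, float("nan"),
                             float("nan"), float("nan"), int(null.size))
    nd = (observed - mean) / mean
    return DensityResult(
        float(observed),
        mean,
        float(nd),
        empirical_p(observed, null, "greater").p,
        empirical_p(observed, null, "less").p,
        int(null.size),
    )


def binomial_exact_p(k: int, n: int, p0: float, tail: str = "greater") -> float:
    """Exact upper-tail binomial probability P(X >= k)."""
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if tail != "greater":
        raise ValueError("only the upper tail is defined here")
    return float(sps.binom.sf(k - 1, n, p0))


@dataclass(frozen=True)
class TrendResult:
    statistic: float
    p_raw: float
    p_adjusted: float = float("nan")

    @property
    def undefined(self) -> bool:
        return math.isnan(self.statistic)


def _concordance_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    prod = sx * sy
    upper = np.triu_indices(len(x), k=1)
    c = int(np.count_nonzero(prod[upper] > 0))
    d = int(np.count_nonzero(prod[upper] < 0))
    return c, d


def gk_gamma(
    x,
    y,
    n_shuffles: int = 10000,
    rng: np.random.Generator | None = None,
    sided: str = "one",
) -> TrendResult:
    """Goodman–Kruskal's gamma with a shuffle-null empirical p-value.

    gamma = (C - D) / (C + D) over untied pairs. The p-value shuffles one
    vector ``n_shuffles`` times; ``sided='one'`` counts simulants whose gamma
    matches or exceeds the observed value in the observed direction,
    ``sided='two'`` compares |gamma|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 2")
    c, d = _concordance_counts(x, y)
    if c + d == 0:
        return TrendResult(float("nan"), float("nan"))
    gamma = (c - d) / (c + d)
    if n_shuffles <= 0:
        return TrendResult(gamma, float("nan"))
    if rng is None:
        rng = np.random.default_rng()
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        cs, ds = _concordance_counts(x, rng.permutation(y))
        null[i] = (cs - ds) / (cs + ds) if cs + ds else 0.0
    if sided == "two":
        test = empirical_p(abs(gamma), np.abs(null), "greater")
    elif gamma >= 0:
        test = empirical_p(gamma, null, "greater")
    else:
        test = empirical_p(gamma, null, "less")
    return TrendResult(gamma, test.p)


def _rank(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v)


def partial_rank_correlation(x, y, control) -> TrendResult:
    """First-order partial Spearman correlation of x and y given one control.

    Pearson correlations of the rank-transformed variables are combined as
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); the p-value
    uses the t approximation with n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(control, dtype=float)
    n = len(x)
    if not (len(y) == len(z) == n) or n < 4:
        raise ValueError("need equal-length vectors of length >= 4")
    rx, ry, rz = _rank(x), _rank(y), _rank(z)

    def corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    r_xy, r_xz, r_yz = corr(rx, ry), corr(rx, rz), corr(ry, rz)
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        return TrendResult(float("nan"), float("nan"))
    r = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r = max(-1.0, min(1.0, r))
    df = n - 3
    if abs(r) == 1.0:
        return TrendResult(r, 0.0)
    t = r * math.sqrt(df / (1 - r * r))
    p = 2 * sps.t.sf(abs(t), df)
    return TrendResult(r, float(p))


def holm_adjust(p_values) -> list[float]:
    """Holm's step-down multiple-testing adjustment, capped at 1, monotone."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return []
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (n - rank) * p[idx])
        running = max(running, val)
        adjusted[idx] = running
    return adjusted.tolist()
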