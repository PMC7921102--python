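"""Permutation hypothesis testing with Bonferroni correction.

Group comparisons use two-sided permutation tests on the absolute
difference of group means (or medians).  The full label arrangement space is
enumerated exactly when small enough; otherwise a Monte-Carlo estimate with
the add-one (permutation-inclusive) estimator avoids p = 0.  P values below
the resampling accuracy (1e-5 by default) are reported as "< accuracy".
The Bonferroni correction is applied as a prefactor and deliberately not
clipped at 1; corrected values above 1 read as "not significant".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "PermutationResult",
    "permutation_test",
    "bonferroni",
    "resample_match",
    "running_average",
    "RunningAverage",
]

DEFAULT_ACCURACY = 1e-5


@dataclass
class PermutationResult:
    p_raw: float
    observed: float
    n_resamples: int
    exact: bool
    accuracy: float = DEFAULT_ACCURACY
    m_comparisons: int = 1

    @property
    def p_corrected(self) -> float:
        """Bonferroni-corrected p value (prefactor, may exceed 1)."""
        return self.m_comparisons * self.p_raw

    @property
    def below_resolution(self) -> bool:
        return self.p_raw < self.accuracy

    def display(self) -> str:
        p = self.p_corrected
        if p < self.accuracy:
            return f"< {self.accuracy:g}"
        return f"{p:g}" + (" (n.s.)" if p >= 0.05 else "")


def _stat(x: np.ndarray, y: np.ndarray, statistic: str) -> float:
    if statistic == "mean":
        return abs(float(x.mean() - y.mean()))
    if statistic == "median":
        return abs(float(np.median(x) - np.median(y)))
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_test(group_x: Sequence[float], group_y: Sequence[float],
                     n_resamples: int = 100_000,
                     rng: Optional[np.random.Generator] = None,
                     statistic: str = "mean",
                     m_comparisons: int = 1) -> PermutationResult:
    """Two-sided permutation test on |difference of group summaries|.

    When the number of distinct label arrangements C(n_x + n_y, n_x) is at
    most ``n_resamples`` the p value is computed by exact enumeration
    (fraction of arrangements with statistic >= observed); otherwise by
    Monte-Carlo resampling with the add-one estimator
    ``p = (1 + #extreme) / (R + 1)``.
    """
    x = np.asarray(group_x, float)
    y = np.asarray(group_y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    obs = _stat(x, y, statistic)
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    total = comb(n, nx)
    eps = 1e-12 * max(1.0, obs)
    if total <= n_resamples:
        hits = 0
        idx_all = frozenset(range(n))
        for ix in combinations(range(n), nx):
            sel = np.fromiter(ix, int, nx)
            rest = np.fromiter(idx_all.difference(ix), int, n - nx)
            if _stat(pooled[sel], pooled[rest], statistic) >= obs - eps:
                hits += 1
        return PermutationResult(hits / total, obs, total, True,
                                 m_comparisons=m_comparisons)
    if rng is None:
        rng = np.random.default_rng()
    hits = 0
    chunk = max(1, min(n_resamples, int(2e7) // max(n, 1)))
    done = 0
    while done < n_resamples:
        k = min(chunk, n_resamples - done)
        perm = np.argsort(rng.random((k, n)), axis=1)
        shuffled = pooled[perm]
        a = shuffled[:, :nx]
        b = shuffled[:, nx:]
        if statistic == "mean":
            stats = np.abs(a.mean(axis=1) - b.mean(axis=1))
        else:
            stats = np.abs(np.median(a, axis=1) - np.median(b, axis=1))
        hits += int((stats >= obs - eps).sum())
        done += k
    p = (1 + hits) / (n_resamples + 1)
    return PermutationResult(p, obs, n_resamples, False,
                             m_comparisons=m_comparisons)


def bonferroni(p_raw: float, m_comparisons: int) -> float:
    """Bonferroni prefactor correction, not clipped at 1."""
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    return m_comparisons * p_raw


def resample_match(group_x: Sequence[float], group_y: Sequence[float],
                   n_experiment: int, reps: int = 100,
                   rng: Optional[np.random.Generator] = None,
                   n_resamples: int = 10_000,
                   statistic: str = "mean") -> dict:
    """Permutation tests on subsamples matched to an experimental n.

    Each repetition subsamples both groups (without replacement) to
    ``n_experiment`` values before testing; summarizes the p distribution
    so simulation ensembles can be compared at experimental sample sizes.
    """
    x = np.asarray(group_x, float)
    y = np.asarray(group_y, float)
    if n_experiment > x.size or n_experiment > y.size:
        raise ValueError("n_experiment exceeds available values")
    if rng is None:
        rng = np.random.default_rng()
    if n_experiment == x.size and n_experiment == y.size:
        reps = 1
    ps = []
    for _ in range(reps):
        xs = rng.choice(x, n_experiment, replace=False) if n_experiment < x.size else x
        ys = rng.choice(y, n_experiment, replace=False) if n_experiment < y.size else y
        ps.append(permutation_test(xs, ys, n_resamples, rng, statistic).p_raw)
    ps = np.asarray(ps)
    return {
        "p_median": float(np.median(ps)),
        "p_mean": float(ps.mean()),
        "p_values": ps,
        "reps": int(reps),
        "n_experiment": int(n_experiment),
    }


@dataclass
class RunningAverage:
    centers: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray


def running_average(x: Sequence[float], y: Sequence[float],
                    window: float = 0.1, min_n: int = 30,
                    step: float = 0.01) -> RunningAverage:
    """Sliding-window mean +/- SEM of y over x.

    Window centers sit on a regular grid of spacing ``step``; windows with
    fewer than ``min_n`` points are omitted (gaps in the curve).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size == 0:
        return RunningAverage(np.array([]), np.array([]), np.array([]),
                              np.array([], int))
    lo = np.floor(x.min() / step) * step
    hi = np.ceil(x.max() / step) * step
    centers = np.arange(lo, hi + step / 2, step)
    out_c, out_m, out_s, out_n = [], [], [], []
    half = window / 2.0
    for c in centers:
        sel = (x >= c - half) & (x <= c + half)
        n = int(sel.sum())
        if n < min_n:
            continue
        vals = y[sel]
        out_c.append(c)
        out_m.append(float(vals.mean()))
        out_s.append(float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0)
        out_n.append(n)
    return RunningAverage(np.asarray(out_c), np.asarray(out_m),
                          np.asarray(out_s), np.asarray(out_n, int))
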