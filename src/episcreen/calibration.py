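"""Permutation null of the battery-wide minimum p-value and the beta-fit
family-wise significance threshold; QQ expectations.

The most significant p-value of a battery of m (generally correlated) tests
follows a beta distribution under the global null; its parameters are
estimated from per-permutation minimum p-values obtained by re-running the
whole battery on phenotype-permuted data (genotypes untouched, preserving LD).
The family-wise 0.05 significance threshold is the point t with
P(min p <= t) = 0.05 under the fitted beta — for m independent uniform tests
this reproduces the closed form 1 - 0.95^(1/m), and is numerically close to
the Bonferroni level 0.05/m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import GenotypeMatrix
from .pairtests import TwoLocusInteraction

__all__ = [
    "NullTopDistribution",
    "QQExpectation",
    "run_battery",
    "permute_min_p",
    "fit_beta",
    "significance_threshold",
    "threshold_convergence",
    "qq_expectation",
]

MIN_FIT_SIZE = 30  # smallest permutation count the beta fit accepts


@dataclass
class NullTopDistribution:
    """Per-permutation minimum p-values and the fitted beta null."""

    min_p_per_perm: np.ndarray
    n_tests: int = 0
    beta_a: float = np.nan
    beta_b: float = np.nan
    p_lists: np.ndarray | None = None  # optional (n_perm, m) full batteries

    @property
    def n_perm(self) -> int:
        return len(self.min_p_per_perm)

    def fit(self) -> "NullTopDistribution":
        self.beta_a, self.beta_b = fit_beta(self.min_p_per_perm)
        return self

    def threshold(self, fwer: float = 0.05) -> float:
        if not np.isfinite(self.beta_a):
            self.fit()
        return significance_threshold(self, fwer)


@dataclass
class QQExpectation:
    """Null expectation and 95% envelope of ranked p-values."""

    expected: np.ndarray  # per-rank mean of the k-th order statistic
    lower: np.ndarray
    upper: np.ndarray


def run_battery(g: GenotypeMatrix, pairs: list[tuple[str, str]], test: str,
                y: np.ndarray | None = None) -> np.ndarray:
    """p-values for all pairs under one phenotype vector (NaN = infeasible)."""
    y = g.phenotype if y is None else y
    out = np.empty(len(pairs))
    for k, (a, b) in enumerate(pairs):
        r = TwoLocusInteraction(g.column(a), g.column(b), y, names=(a, b)).fit(test)
        out[k] = r.p if r.feasible else np.nan
    return out


def permute_min_p(g: GenotypeMatrix, pairs: list[tuple[str, str]], test: str,
                  n_perm: int, seed: int = 0,
                  keep_all: bool = False) -> NullTopDistribution:
    """Null distribution of the battery minimum p-value.

    Each permutation shuffles the phenotype labels once globally (the
    genotype matrix, hence inter-SNP correlation, is untouched) and re-runs
    the full battery; the minimum feasible p is recorded. A permutation in
    which every pair is infeasible records min_p = 1 with a warning.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if g.phenotype is None:
        raise ValueError("phenotype required")
    rng = np.random.default_rng(seed)
    mins = np.empty(n_perm)
    all_p = np.full((n_perm, len(pairs)), np.nan) if keep_all else None
    for it in range(n_perm):
        y = rng.permutation(g.phenotype)
        ps = run_battery(g, pairs, test, y=y)
        if keep_all:
            all_p[it] = ps
        if np.all(np.isnan(ps)):
            warnings.warn(f"permutation {it}: all pairs infeasible; min_p=1")
            mins[it] = 1.0
        else:
            mins[it] = np.nanmin(ps)
    return NullTopDistribution(mins, n_tests=len(pairs), p_lists=all_p)


def fit_beta(min_ps: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Beta(a, b) fit on (0, 1), method-of-moments start.

    For the minimum of m independent uniform p-values the truth is
    Beta(1, m).
    """
    x = np.asarray(min_ps, dtype=float)
    if len(x) < MIN_FIT_SIZE:
        raise ValueError(f"need >= {MIN_FIT_SIZE} values, got {len(x)}")
    if np.any((x <= 0) | (x > 1)):
        raise ValueError("min p-values must lie in (0, 1]")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all values equal")
    m, v = x.mean(), x.var()
    # method of moments; guard v against the boundary
    v = max(v, 1e-12)
    common = m * (1 - m) / v - 1
    a0 = max(m * common, 1e-3)
    b0 = max((1 - m) * common, 1e-3)
    x = np.clip(x, 1e-300, 1 - 1e-12)
    a, b, _, _ = stats.beta.fit(x, a0, b0, floc=0, fscale=1)
    return float(a), float(b)


def significance_threshold(dist: NullTopDistribution, fwer: float = 0.05) -> float:
    """Family-wise significance level: the fwer-quantile (toward zero) of the
    fitted minimum-p beta, so that P(min p <= t | H0) = fwer."""
    if not 0.0 < fwer < 1.0:
        raise ValueError("fwer must be in (0, 1)")
    if not (np.isfinite(dist.beta_a) and np.isfinite(dist.beta_b)):
        raise ValueError("beta parameters not fitted; call .fit() first")
    return float(stats.beta.ppf(fwer, dist.beta_a, dist.beta_b))


def threshold_convergence(min_ps: np.ndarray,
                          checkpoints: list[int] | None = None,
                          fwer: float = 0.05) -> list[tuple[int, float]]:
    """Threshold recomputed on growing prefixes of the permutation stream.

    Default checkpoints: round numbers from the minimum fitting size up to
    the full permutation count. Demonstrates the rapid stabilisation of the
    estimate with permutation number.
    """
    min_ps = np.asarray(min_ps, dtype=float)
    n = len(min_ps)
    if checkpoints is None:
        grid = [30, 50, 100, 200, 300, 500, 1000, 2000, 5000, 10000]
        checkpoints = [c for c in grid if c < n] + [n]
    curve = []
    for c in checkpoints:
        if c < MIN_FIT_SIZE or c > n:
            raise ValueError(f"checkpoint {c} outside [{MIN_FIT_SIZE}, {n}]")
        a, b = fit_beta(min_ps[:c])
        d = NullTopDistribution(min_ps[:c], beta_a=a, beta_b=b)
        curve.append((c, significance_threshold(d, fwer)))
    return curve


def qq_expectation(p_lists: np.ndarray | list[np.ndarray]) -> QQExpectation:
    """Null expectation of ranked p-values from permuted batteries.

    Per rank k, the expectation is the mean of the k-th order statistic
    across permutations; the envelope the 2.5/97.5 percentiles. Permutations
    with differing feasible counts are aligned on the common length with a
    warning.
    """
    rows = [np.sort(np.asarray(p)[~np.isnan(np.asarray(p, dtype=float))])
            for p in p_lists]
    if len(rows) < 20:
        raise ValueError("need >= 20 permutations")
    lengths = {len(r) for r in rows}
    m = min(lengths)
    if m == 0:
        raise ValueError("a permutation has no feasible tests")
    if len(lengths) > 1:
        warnings.warn(f"ragged batteries; aligning on common length {m}")
        rows = [r[:m] for r in rows]
    mat = np.vstack(rows)
    return QQExpectation(expected=mat.mean(axis=0),
                         lower=np.percentile(mat, 2.5, axis=0),
                         upper=np.percentile(mat, 97.5, axis=0))
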