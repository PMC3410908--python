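"""Detectable-interaction-effect power surfaces for two-locus screens.

Power is expressed as the minimum interaction odds ratio the design detects
with a target probability (default 80%) at the analysis-specific significance
level. The analytic route builds the *expected* case/control x 9
compound-genotype table under a two-locus logistic model with no marginal
effects and the candidate interaction OR, conditions the expected counts on
the case and control totals (retrospective ascertainment), and

* for likelihood-ratio tests takes the deviance of the null fit to the
  expected table as the noncentrality of a noncentral chi-square;
* for the allelic contrast takes the expected z as the mean of a unit-normal.

Control genotype frequencies use the rare-disease limit (controls mirror the
source population); a finite prevalence can be supplied instead. A
simulation route (repeated cohort draws through the actual tests) serves as
an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit

from ._coding import INTERACTION_MODELS, code_main, hwe_genotype_probs
from .cohort import (CohortConfig, DiseaseModel, InteractionTerm, SnpSpec,
                     simulate_case_control)
from .pairtests import (TwoLocusTable, _allelic_z, _full_reduced_designs,
                        test_allelic, test_genotypic, test_model_constrained)

__all__ = ["PowerQuery", "PowerSurface", "power_at", "detectable_or",
           "power_surface"]

MIN_ALPHA = 1e-30
OR_MAX = 20.0


@dataclass(frozen=True)
class PowerQuery:
    """Design settings for one power computation.

    ``test``: "genotypic" (model-free LRT), "allelic" (collapsed 2x2 z
    contrast) or "matched" (1-df LRT with the same coding as ``model``).
    ``prevalence``: disease prevalence in the source population; 0 means the
    rare-disease limit.
    """

    n_cases: int = 2967
    n_controls: int = 3075
    maf1: float = 0.2
    maf2: float = 0.2
    model: str = "addxadd"
    alpha: float = 1.51e-6
    power: float = 0.8
    test: str = "genotypic"
    prevalence: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.alpha < MIN_ALPHA:
            raise ValueError(f"alpha below {MIN_ALPHA:g} is outside the "
                             "normal/chi-square approximation guard")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power target must be in (0, 1)")
        for m in (self.maf1, self.maf2):
            if not 0.0 < m <= 0.5:
                raise ValueError("MAFs must be in (0, 0.5]")
        if self.model not in INTERACTION_MODELS:
            raise ValueError(f"model must be one of {INTERACTION_MODELS}")
        if self.test not in ("genotypic", "allelic", "matched"):
            raise ValueError("test must be genotypic, allelic or matched")
        if not 0.0 <= self.prevalence < 1.0:
            raise ValueError("prevalence must be in [0, 1)")


@dataclass
class PowerSurface:
    """Grid of minimum detectable interaction ORs over (MAF1, MAF2)."""

    maf1_grid: np.ndarray
    maf2_grid: np.ndarray
    detectable: np.ndarray  # (len(maf1), len(maf2)); NaN = beyond OR_MAX
    query: PowerQuery

    def to_frame(self):
        import pandas as pd
        rows = [(m1, m2, self.detectable[i, j])
                for i, m1 in enumerate(self.maf1_grid)
                for j, m2 in enumerate(self.maf2_grid)]
        return pd.DataFrame(rows, columns=["maf1", "maf2", "detectable_or"])


def expected_table(query: PowerQuery, interaction_or: float) -> np.ndarray:
    """Expected (2, 3, 3) cell counts conditioned on case/control totals.

    Genotype frequencies are Hardy-Weinberg products; per-cell disease odds
    follow the logistic model with zero marginal effects and log-OR
    ln(interaction_or) on the coded product.
    """
    gamma = np.log(interaction_or)
    pg = np.outer(hwe_genotype_probs(query.maf1), hwe_genotype_probs(query.maf2))
    i = np.arange(3)
    x = np.outer(code_main(i, query.model), code_main(i, query.model))
    if query.prevalence == 0.0:
        # rare-disease limit: P(g|case) ∝ p(g) e^{γx}, P(g|control) = p(g)
        case = pg * np.exp(gamma * x)
        ctrl = pg.copy()
    else:
        b0 = _solve_intercept(pg, x, gamma, query.prevalence)
        risk = expit(b0 + gamma * x)
        case = pg * risk
        ctrl = pg * (1.0 - risk)
    case *= query.n_cases / case.sum()
    ctrl *= query.n_controls / ctrl.sum()
    return np.stack([ctrl, case])


def _solve_intercept(pg: np.ndarray, x: np.ndarray, gamma: float,
                     prevalence: float) -> float:
    from scipy.optimize import brentq
    f = lambda b0: float((pg * expit(b0 + gamma * x)).sum()) - prevalence
    return brentq(f, -40.0, 40.0)


def _collapse_expected(table: np.ndarray) -> np.ndarray:
    """Allele-pair collapsing of an expected (fractional) (2, 3, 3) table."""
    out = np.empty((2, 2, 2))
    for g in (0, 1):
        c = table[g]
        out[g] = [[4 * c[0, 0] + 2 * c[0, 1] + 2 * c[1, 0] + c[1, 1],
                   4 * c[0, 2] + 2 * c[0, 1] + 2 * c[1, 2] + c[1, 1]],
                  [4 * c[2, 0] + 2 * c[1, 0] + 2 * c[2, 1] + c[1, 1],
                   4 * c[2, 2] + 2 * c[2, 1] + 2 * c[1, 2] + c[1, 1]]]
    return out


def _lrt_noncentrality(table: np.ndarray, test: str, model: str) -> tuple[float, int]:
    """Deviance of the null fit to the expected table = LRT noncentrality."""
    ctrl, case = table[0], table[1]
    cells = np.argwhere((ctrl + case) > 0)
    cs = case[tuple(cells.T)]
    ct = ctrl[tuple(cells.T)]
    if test == "genotypic":
        full, reduced = _full_reduced_designs(cells)
        df = int(np.linalg.matrix_rank(full) - np.linalg.matrix_rank(reduced))
    else:  # matched 1-df
        i, j = cells[:, 0], cells[:, 1]
        c1, c2 = code_main(i, model), code_main(j, model)
        reduced = np.column_stack([np.ones(len(cells)), c1, c2])
        df = 1
    import warnings
    with warnings.catch_warnings():
        # at OR=1 the null fit reproduces the expected table exactly, which
        # statsmodels reports as perfect prediction; that is the intended case
        warnings.simplefilter("ignore")
        fit = sm.GLM(np.column_stack([cs, ct]), reduced,
                     family=sm.families.Binomial()).fit(maxiter=200, tol=1e-10)
    if test == "matched":
        # noncentrality = deviance difference of the two fits; the full
        # (reduced + product) model reproduces the generating model exactly
        # (marginal effects 0), so its deviance on the expected table is 0
        pass
    return max(float(fit.deviance), 0.0), df


def power_at(query: PowerQuery, interaction_or: float,
             method: str = "analytic", n_reps: int = 500,
             seed: int = 0) -> float:
    """Probability of a p-value below ``query.alpha`` at the given
    interaction OR.

    ``method="analytic"`` uses noncentral chi-square / normal theory on the
    expected table; ``method="simulation"`` draws ``n_reps`` cohorts through
    the actual test implementation and reports the rejection fraction.
    """
    if interaction_or < 1.0:
        raise ValueError("interaction_or must be >= 1")
    if method == "simulation":
        return _power_sim(query, interaction_or, n_reps, seed)
    if method != "analytic":
        raise ValueError("method must be 'analytic' or 'simulation'")

    table = expected_table(query, interaction_or)
    if query.test == "allelic":
        z0, _ = _allelic_z(_collapse_expected(table))
        zc = stats.norm.isf(query.alpha / 2.0)
        return float(stats.norm.sf(zc - z0) + stats.norm.cdf(-zc - z0))
    ncp, df = _lrt_noncentrality(table, query.test, query.model)
    crit = stats.chi2.isf(query.alpha, df)
    return float(stats.ncx2.sf(crit, df, ncp))


def _power_sim(query: PowerQuery, interaction_or: float, n_reps: int,
               seed: int) -> float:
    specs = (SnpSpec("s1", query.maf1), SnpSpec("s2", query.maf2))
    prev = query.prevalence if query.prevalence > 0 else 0.01
    model = DiseaseModel(
        intercept=float(logit(prev)),
        interaction_terms=(InteractionTerm("s1", "s2", query.model,
                                           float(np.log(interaction_or))),))
    rng = np.random.default_rng(seed)
    hits = 0
    n_feasible = 0
    for _ in range(n_reps):
        cfg = CohortConfig(query.n_cases, query.n_controls, specs, model,
                           seed=int(rng.integers(2**31)))
        g = simulate_case_control(cfg)
        tab_or_data = g
        from .pairtests import compound_table
        tab = compound_table(g.column("s1"), g.column("s2"), g.phenotype)
        if query.test == "genotypic":
            r = test_genotypic(tab)
        elif query.test == "allelic":
            r = test_allelic(tab)
        else:
            r = test_model_constrained(g.column("s1"), g.column("s2"),
                                       g.phenotype, query.model)
        if r.feasible:
            n_feasible += 1
            hits += r.p < query.alpha
    return hits / max(n_feasible, 1)


def detectable_or(query: PowerQuery, tol: float = 1e-3) -> float:
    """Minimum interaction OR reaching the target power (analytic route).

    Bisection on OR in [1, 20]; result rounded to 2 decimals. Returns
    ``inf`` when the target is unreachable at OR = 20 (report as "> 20").
    """
    target = query.power
    # expanding bracket from OR=1: keeps the expected table in the regime
    # where the IRLS null fit is well behaved
    lo, hi = 1.0, 1.05
    while power_at(query, hi) < target:
        lo = hi
        hi = 1.0 + 2.0 * (hi - 1.0)
        if hi > OR_MAX:
            return float("inf")
    while True:
        mid = 0.5 * (lo + hi)
        p = power_at(query, mid)
        if abs(p - target) <= tol or (hi - lo) < 1e-6:
            return round(mid, 2)
        if p < target:
            lo = mid
        else:
            hi = mid


def power_surface(query: PowerQuery, maf_grid: np.ndarray,
                  maf2_grid: np.ndarray | None = None) -> PowerSurface:
    """Detectable-OR surface over a MAF grid (same grid on both axes unless
    ``maf2_grid`` is given)."""
    maf1 = np.asarray(maf_grid, dtype=float)
    maf2 = maf1 if maf2_grid is None else np.asarray(maf2_grid, dtype=float)
    for grid in (maf1, maf2):
        if np.any((grid <= 0) | (grid > 0.5)):
            raise ValueError("grid MAFs must be in (0, 0.5]")
    out = np.empty((len(maf1), len(maf2)))
    for i, m1 in enumerate(maf1):
        for j, m2 in enumerate(maf2):
            out[i, j] = detectable_or(replace(query, maf1=float(m1),
                                              maf2=float(m2)))
    return PowerSurface(maf1, maf2, out, query)
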