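"""Pairwise SNP-SNP interaction tests on case-control data.

Two main tests are provided, mirroring the two standard screening strategies:

* ``genotypic`` (Test A): a model-free likelihood-ratio test contrasting the
  frequencies of the 9 two-locus compound genotypes in cases versus controls,
  implemented as logistic regression with and without interaction indicator
  terms (4 df when all 9 compound genotypes are observed).
* ``allelic`` (Test B): a fast approximate test that collapses each group's
  3x3 genotype table to a 2x2 allele-combination table and compares the
  allelic odds ratio between cases and controls with a normal z statistic.

Also provided: the case-only variant of the allelic test (valid only when the
two loci are independent in the source population) and 1-df model-constrained
LRTs (additive x additive, dominant x dominant, recessive x recessive), which
return the interaction log-OR estimate and its SE for downstream
meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from ._coding import INTERACTION_MODELS, code_main
from .cohort import MISSING

__all__ = [
    "TwoLocusTable",
    "PairTestResult",
    "compound_table",
    "test_genotypic",
    "test_allelic",
    "test_case_only",
    "test_model_constrained",
    "TwoLocusInteraction",
]


@dataclass
class TwoLocusTable:
    """Case/control cross-tabulation of the 9 two-locus compound genotypes.

    ``counts[g, i, j]`` is the number of subjects in group g (0=control,
    1=case) with dosage i at locus A and j at locus B. ``allele_collapsed[g]``
    is the derived 2x2 allele-combination table [[n11, n12], [n21, n22]] where
    index 1 denotes the major and 2 the minor allele: each subject contributes
    4 allele pairs (2 alleles at each locus crossed), the double heterozygote
    splitting one pair into each cell.
    """

    counts: np.ndarray  # (2, 3, 3) int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 3, 3):
            raise ValueError("counts must have shape (2, 3, 3)")

    @property
    def allele_collapsed(self) -> np.ndarray:
        """(2, 2, 2) array of per-group collapsed allele-combination counts."""
        n = self.counts
        out = np.empty((2, 2, 2), dtype=np.int64)
        for g in (0, 1):
            c = n[g]
            n11 = 4 * c[0, 0] + 2 * c[0, 1] + 2 * c[1, 0] + c[1, 1]
            n12 = 4 * c[0, 2] + 2 * c[0, 1] + 2 * c[1, 2] + c[1, 1]
            n21 = 4 * c[2, 0] + 2 * c[1, 0] + 2 * c[2, 1] + c[1, 1]
            n22 = 4 * c[2, 2] + 2 * c[2, 1] + 2 * c[1, 2] + c[1, 1]
            out[g] = [[n11, n12], [n21, n22]]
        return out

    @property
    def n_subjects(self) -> int:
        return int(self.counts.sum())


@dataclass
class PairTestResult:
    """Result of one pairwise interaction test.

    ``method`` is one of genotypic / allelic / case_only / addxadd / domxdom /
    recxrec. 1-df methods carry the interaction log-OR estimate and SE; the
    4-df genotypic LRT does not (its df varies with the observed cells).
    """

    snp_a: str
    snp_b: str
    method: str
    statistic: float = np.nan
    df: int = 0
    p: float = np.nan
    beta_int: float = np.nan
    se_int: float = np.nan
    feasible: bool = True
    reason: str = ""

    def summary(self) -> str:
        lines = [
            f"Pair interaction test  [{self.method}]",
            f"  pair:       {self.snp_a} x {self.snp_b}",
        ]
        if self.feasible:
            lines.append(f"  statistic:  {self.statistic:.4f}  (df={self.df})")
            lines.append(f"  p-value:    {self.p:.4g}")
            if np.isfinite(self.beta_int):
                lines.append(f"  log-OR:     {self.beta_int:.4f}  (SE {self.se_int:.4f})"
                             f"  OR={np.exp(self.beta_int):.3f}")
        else:
            lines.append(f"  infeasible: {self.reason}")
        return "\n".join(lines)


def _pairwise_complete(g1: np.ndarray, g2: np.ndarray,
                       y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g1 = np.asarray(g1, dtype=np.int64)
    g2 = np.asarray(g2, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if not (g1.shape == g2.shape == y.shape):
        raise ValueError("g1, g2, y must have equal length")
    keep = (g1 != MISSING) & (g2 != MISSING)
    return g1[keep], g2[keep], y[keep]


def compound_table(g1: np.ndarray, g2: np.ndarray, y: np.ndarray) -> TwoLocusTable:
    """Cross-tabulate dosage pairs by case status (pairwise-complete)."""
    g1, g2, y = _pairwise_complete(g1, g2, y)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both cases and controls required")
    counts = np.zeros((2, 3, 3), dtype=np.int64)
    np.add.at(counts, (y, g1, g2), 1)
    return TwoLocusTable(counts)


# -- Test A: model-free genotypic LRT ----------------------------------------

def _full_reduced_designs(cells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Design matrices for the observed compound-genotype cells.

    ``cells`` is (k, 2) of (i, j) dosage pairs. Reduced: intercept + 2
    indicator columns per locus (reference: homozygous major). Full: reduced
    plus the 4 product-indicator columns.
    """
    i, j = cells[:, 0], cells[:, 1]
    a1, a2 = (i == 1).astype(float), (i == 2).astype(float)
    b1, b2 = (j == 1).astype(float), (j == 2).astype(float)
    ones = np.ones(len(cells))
    reduced = np.column_stack([ones, a1, a2, b1, b2])
    full = np.column_stack([reduced, a1 * b1, a1 * b2, a2 * b1, a2 * b2])
    return full, reduced


def test_genotypic(table: TwoLocusTable, snp_a: str = "A",
                   snp_b: str = "B") -> PairTestResult:
    """Model-free interaction LRT on the 2x9 compound-genotype table.

    Compares logistic fits with and without the interaction indicator
    columns. Interaction columns that are not identified because compound
    genotypes are unobserved are dropped, reducing the degrees of freedom
    (computed as the rank difference of the two designs on the observed
    cells); with all 9 cells observed the full model is saturated and df=4.
    """
    res = PairTestResult(snp_a, snp_b, "genotypic")
    n = table.counts
    pooled = n.sum(axis=0)
    locus_a = pooled.sum(axis=1)
    locus_b = pooled.sum(axis=0)
    if (locus_a > 0).sum() < 2 or (locus_b > 0).sum() < 2:
        res.feasible = False
        res.reason = "monomorphic locus"
        return res

    obs = np.argwhere(pooled > 0)
    cases = n[1][tuple(obs.T)].astype(float)
    ctrls = n[0][tuple(obs.T)].astype(float)
    full, reduced = _full_reduced_designs(obs)
    df = int(np.linalg.matrix_rank(full) - np.linalg.matrix_rank(reduced))
    if df == 0:
        res.feasible = False
        res.reason = "no estimable interaction columns"
        return res

    # Full model is saturated on the observed cells once rank-deficient
    # interaction columns are accounted for, so the LRT equals the deviance
    # of the main-effects fit.
    try:
        fit = sm.GLM(np.column_stack([cases, ctrls]), reduced,
                     family=sm.families.Binomial()).fit(maxiter=200, tol=1e-10)
        converged = fit.converged
        deviance = float(fit.deviance)
    except Exception as exc:  # singular / separation pathologies
        res.feasible = False
        res.reason = f"main-effects fit failed: {exc}"
        return res
    if not converged or not np.isfinite(deviance):
        res.feasible = False
        res.reason = "main-effects fit did not converge"
        return res

    res.statistic = max(deviance, 0.0)
    res.df = df
    res.p = float(stats.chi2.sf(res.statistic, df))
    return res


# -- Test B: allelic contrast ------------------------------------------------

def _allelic_z(collapsed: np.ndarray) -> tuple[float, float]:
    """z statistic contrasting ln OR between the two groups of a (2,2,2)
    collapsed table, and its (implicit unit) scale; returns (z, p)."""
    ctrl, case = collapsed[0].astype(float), collapsed[1].astype(float)
    ln_or_case = np.log(case[0, 0] * case[1, 1] / (case[0, 1] * case[1, 0]))
    ln_or_ctrl = np.log(ctrl[0, 0] * ctrl[1, 1] / (ctrl[0, 1] * ctrl[1, 0]))
    se = np.sqrt((1.0 / case).sum() + (1.0 / ctrl).sum())
    z = (ln_or_case - ln_or_ctrl) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def test_allelic(table: TwoLocusTable, snp_a: str = "A",
                 snp_b: str = "B") -> PairTestResult:
    """Allelic interaction contrast (fast-epistasis style).

    Feasible only when all 8 collapsed allele-combination cells are positive,
    which fails for low minor allele frequencies.
    """
    res = PairTestResult(snp_a, snp_b, "allelic", df=1)
    collapsed = table.allele_collapsed
    if (collapsed <= 0).any():
        res.feasible = False
        res.reason = "low allele frequencies"
        res.df = 0
        return res
    z, p = _allelic_z(collapsed)
    case = collapsed[1].astype(float)
    ctrl = collapsed[0].astype(float)
    res.beta_int = float(np.log(case[0, 0] * case[1, 1] / (case[0, 1] * case[1, 0]))
                         - np.log(ctrl[0, 0] * ctrl[1, 1] / (ctrl[0, 1] * ctrl[1, 0])))
    res.se_int = float(np.sqrt((1.0 / case).sum() + (1.0 / ctrl).sum()))
    res.statistic = z
    res.p = p
    return res


def test_case_only(table: TwoLocusTable, snp_a: str = "A",
                   snp_b: str = "B") -> PairTestResult:
    """Case-only allelic interaction test.

    Uses the allelic association between loci within cases alone; a valid
    interaction test only when the loci are independent in the source
    population — under LD between loci it rejects even without interaction.
    """
    res = PairTestResult(snp_a, snp_b, "case_only", df=1)
    case = table.allele_collapsed[1].astype(float)
    if (case <= 0).any():
        res.feasible = False
        res.reason = "low allele frequencies"
        res.df = 0
        return res
    beta = float(np.log(case[0, 0] * case[1, 1] / (case[0, 1] * case[1, 0])))
    se = float(np.sqrt((1.0 / case).sum()))
    res.beta_int, res.se_int = beta, se
    res.statistic = beta / se
    res.p = float(2.0 * stats.norm.sf(abs(res.statistic)))
    return res


# -- 1-df model-constrained LRTs ---------------------------------------------

def test_model_constrained(g1: np.ndarray, g2: np.ndarray, y: np.ndarray,
                           model: str, snp_a: str = "A",
                           snp_b: str = "B") -> PairTestResult:
    """1-df LRT for a coded interaction product added to the two-main-effect
    logistic model; main effects use the coding matched to the model.

    Returns the interaction log-OR and SE (Wald) alongside the LRT p.
    """
    if model not in INTERACTION_MODELS:
        raise ValueError(f"model must be one of {INTERACTION_MODELS}")
    res = PairTestResult(snp_a, snp_b, model, df=1)
    g1, g2, y = _pairwise_complete(g1, g2, y)
    x1 = code_main(g1, model)
    x2 = code_main(g2, model)
    prod = x1 * x2
    if np.all(prod == prod[0]):
        res.feasible = False
        res.df = 0
        res.reason = "constant interaction term"
        return res

    # aggregate to the <=9 compound cells for a fast weighted fit
    cell = g1 * 3 + g2
    n_case = np.bincount(cell[y == 1], minlength=9).astype(float)
    n_ctrl = np.bincount(cell[y == 0], minlength=9).astype(float)
    obs = (n_case + n_ctrl) > 0
    i, j = np.divmod(np.arange(9)[obs], 3)
    c1 = code_main(i, model)
    c2 = code_main(j, model)
    x_red = np.column_stack([np.ones(obs.sum()), c1, c2])
    x_full = np.column_stack([x_red, c1 * c2])
    endog = np.column_stack([n_case[obs], n_ctrl[obs]])
    try:
        fit_full = sm.GLM(endog, x_full, family=sm.families.Binomial()).fit(
            maxiter=200, tol=1e-10)
        fit_red = sm.GLM(endog, x_red, family=sm.families.Binomial()).fit(
            maxiter=200, tol=1e-10)
    except Exception as exc:
        res.feasible = False
        res.reason = f"fit failed: {exc}"
        return res
    if not (fit_full.converged and fit_red.converged):
        res.feasible = False
        res.reason = "fit did not converge"
        return res
    lrt = float(fit_red.deviance - fit_full.deviance)
    res.statistic = max(lrt, 0.0)
    res.p = float(stats.chi2.sf(res.statistic, 1))
    res.beta_int = float(fit_full.params[-1])
    res.se_int = float(fit_full.bse[-1])
    return res


class TwoLocusInteraction:
    """Model object for one SNP pair: interaction of two dosage vectors with
    case/control status.

    Examples
    --------
    >>> m = TwoLocusInteraction(g1, g2, y, names=("rs1", "rs2"))
    >>> r = m.fit(method="genotypic")
    >>> print(r.summary())
    """

    def __init__(self, g1: np.ndarray, g2: np.ndarray, y: np.ndarray,
                 names: tuple[str, str] = ("A", "B")):
        self.g1, self.g2, self.y = _pairwise_complete(g1, g2, y)
        self.names = names

    @classmethod
    def from_matrix(cls, g, snp_a: str, snp_b: str) -> "TwoLocusInteraction":
        """Build from a phenotyped GenotypeMatrix and two SNP ids."""
        if g.phenotype is None:
            raise ValueError("GenotypeMatrix has no phenotype")
        return cls(g.column(snp_a), g.column(snp_b), g.phenotype,
                   names=(snp_a, snp_b))

    @property
    def table(self) -> TwoLocusTable:
        return compound_table(self.g1, self.g2, self.y)

    def fit(self, method: str = "genotypic") -> PairTestResult:
        a, b = self.names
        if method == "genotypic":
            return test_genotypic(self.table, a, b)
        if method == "allelic":
            return test_allelic(self.table, a, b)
        if method == "case_only":
            return test_case_only(self.table, a, b)
        if method in INTERACTION_MODELS:
            return test_model_constrained(self.g1, self.g2, self.y, method, a, b)
        raise ValueError(f"unknown method {method!r}")
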