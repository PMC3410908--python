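"""Battery-level model object: a screen of pairwise interaction tests with
permutation-calibrated family-wise significance."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import (NullTopDistribution, permute_min_p, run_battery,
                          significance_threshold)
from .cohort import GenotypeMatrix
from .meta import select_for_validation
from .pairtests import PairTestResult, TwoLocusInteraction

__all__ = ["InteractionScreen", "ScreenResults"]


class InteractionScreen:
    """A battery of pairwise interaction tests on one cohort.

    Parameters
    ----------
    g : GenotypeMatrix
        Phenotyped cohort.
    pairs : list of (snp_a, snp_b)
        Pairs to test (e.g. from :func:`episcreen.selection.enumerate_pairs`).
    test : str
        "genotypic", "allelic", "case_only" or a 1-df model name.
    """

    def __init__(self, g: GenotypeMatrix, pairs: list[tuple[str, str]],
                 test: str = "genotypic"):
        if g.phenotype is None:
            raise ValueError("phenotyped cohort required")
        self.g = g
        self.pairs = list(pairs)
        self.test = test

    def fit(self) -> "ScreenResults":
        results = [
            TwoLocusInteraction.from_matrix(self.g, a, b).fit(self.test)
            for a, b in self.pairs
        ]
        return ScreenResults(self, results)


class ScreenResults:
    """Fitted screen: per-pair results plus significance calibration."""

    def __init__(self, model: InteractionScreen, results: list[PairTestResult]):
        self.model = model
        self.results = results
        self.null: NullTopDistribution | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results])

    @property
    def p_values(self) -> np.ndarray:
        return np.array([r.p if r.feasible else np.nan for r in self.results])

    @property
    def min_p(self) -> float:
        p = self.p_values
        return float(np.nanmin(p)) if np.any(~np.isnan(p)) else float("nan")

    @property
    def n_feasible(self) -> int:
        return int(sum(r.feasible for r in self.results))

    def calibrate(self, n_perm: int = 200, seed: int = 0,
                  keep_all: bool = False) -> "ScreenResults":
        """Run the permutation null and fit the beta top-result model."""
        self.null = permute_min_p(self.model.g, self.model.pairs,
                                  self.model.test, n_perm, seed,
                                  keep_all=keep_all).fit()
        return self

    def threshold(self, fwer: float = 0.05) -> float:
        if self.null is None:
            raise ValueError("call .calibrate() first")
        return significance_threshold(self.null, fwer)

    def significant(self, fwer: float = 0.05) -> list[PairTestResult]:
        t = self.threshold(fwer)
        return [r for r in self.results if r.feasible and r.p <= t]

    def validation_candidates(self, fwer: float = 0.05,
                              window: float = 1e3) -> list[PairTestResult]:
        return select_for_validation(self.results, self.threshold(fwer), window)

    def summary(self, fwer: float = 0.05) -> str:
        lines = [
            "Pairwise interaction screen",
            f"  test:             {self.model.test}",
            f"  pairs tested:     {len(self.results)} "
            f"({len(self.results) - self.n_feasible} infeasible)",
            f"  minimum p:        {self.min_p:.4g}",
        ]
        if self.null is not None:
            t = self.threshold(fwer)
            lines += [
                f"  permutations:     {self.null.n_perm}",
                f"  beta(a, b):       ({self.null.beta_a:.3f}, "
                f"{self.null.beta_b:.1f})",
                f"  threshold (FWER {fwer:g}): {t:.4g}",
                f"  significant:      {len(self.significant(fwer))}",
            ]
        return "\n".join(lines)
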