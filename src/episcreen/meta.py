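"""Discovery -> validation carry-forward and fixed-effects meta-analysis.

Pairs whose discovery interaction p-value lies within three orders of
magnitude of the analysis-specific significance threshold are brought
forward; validation applies a Bonferroni-corrected per-pair level; the two
studies' interaction log-ORs are combined by inverse-variance weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pairtests import PairTestResult

__all__ = ["MetaResult", "select_for_validation",
           "bonferroni_validation_alpha", "fixed_effects_meta"]


@dataclass
class MetaResult:
    snp_a: str
    snp_b: str
    beta_combined: float
    se_combined: float
    p_combined: float
    per_study: list[tuple[float, float]] = field(default_factory=list)
    heterogeneity_q: float = np.nan  # reported, not tested
    note: str = ""


def select_for_validation(results: list[PairTestResult],
                          threshold: float,
                          window: float = 1e3) -> list[PairTestResult]:
    """Feasible pairs with p <= threshold * window, ascending by p."""
    sel = [r for r in results
           if r.feasible and np.isfinite(r.p) and r.p <= threshold * window]
    return sorted(sel, key=lambda r: (r.p, r.snp_a, r.snp_b))


def bonferroni_validation_alpha(n_pairs: int, alpha: float = 0.05) -> float:
    """Per-pair validation significance level 0.05/n (e.g. 47 pairs ->
    ~0.0011)."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    return alpha / n_pairs


def fixed_effects_meta(estimates: list[tuple[float, float]],
                       snp_a: str = "A", snp_b: str = "B") -> MetaResult:
    """Inverse-variance fixed-effects combination of (log-OR, SE) pairs."""
    if not estimates:
        raise ValueError("no estimates")
    for _, se in estimates:
        if not se > 0:
            raise ValueError("all SEs must be positive")
    if len(estimates) == 1:
        b, s = estimates[0]
        return MetaResult(snp_a, snp_b, float(b), float(s),
                          float(2 * stats.norm.sf(abs(b / s))),
                          per_study=list(estimates),
                          note="single study: returned unchanged")
    betas = np.array([b for b, _ in estimates], dtype=float)
    w = np.array([1.0 / (s * s) for _, s in estimates])
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    p = float(2 * stats.norm.sf(abs(beta / se)))
    q = float((w * (betas - beta) ** 2).sum())
    return MetaResult(snp_a, snp_b, beta, se, p,
                      per_study=list(estimates), heterogeneity_q=q)
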