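"""Marginal screening, LD pruning, tier construction and pair enumeration.

The screen is organised in four tiers ("Analyses"):

1. within the biologically annotated risk-factor (CVRF) SNP set;
2. annotated set x SNPs with moderate marginal disease association (p <= 1e-3);
3a. within the moderate marginal set;
3b. within the weak marginal set (p <= 1e-2), excluding pairs already covered
    (directly or through LD proxies) by earlier tiers.

Within and across tiers SNPs are required to be mutually independent at
LD r^2 < 0.5; a SNP in LD with an earlier tier's SNP is dropped but remembered
as a *proxy* of it, so that pairs it would have formed count as already
tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import MISSING, GenotypeMatrix

__all__ = [
    "SnpRecord",
    "AnalysisPlan",
    "single_snp_test",
    "marginal_screen",
    "ld_r2",
    "ld_prune",
    "enumerate_pairs",
    "build_tiers",
]


@dataclass
class SnpRecord:
    """Per-SNP metadata used by the tiering logic."""

    id: str
    chrom: str = "0"
    pos: int = 0
    alleles: tuple[str, str] = ("A", "B")  # (major, minor)
    maf: float = np.nan
    tier: str = "none"
    marginal_p: float = np.nan

    def __post_init__(self) -> None:
        if np.isfinite(self.marginal_p) and not 0.0 < self.marginal_p <= 1.0:
            raise ValueError(f"{self.id}: marginal_p must be in (0, 1]")


@dataclass
class AnalysisPlan:
    """One tier's pair-testing plan.

    ``set_b is None`` means within-set enumeration of ``set_a``; otherwise
    all cross pairs set_a x set_b. ``excluded_pairs`` holds canonical
    (sorted) id pairs captured by earlier tiers.
    """

    analysis_id: str
    set_a: list[str]
    set_b: list[str] | None = None
    test: str = "genotypic"
    excluded_pairs: set[tuple[str, str]] = field(default_factory=set)


def single_snp_test(g: np.ndarray, y: np.ndarray) -> float:
    """1-df allelic trend test of disease association (Cochran-Armitage /
    logistic score test on dosage); two-sided p.

    Closed-form score test: robust to the separation pathologies an MLE fit
    hits on extreme tables.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = g != MISSING
    g, y = g[keep], y[keep]
    if y.min() == y.max():
        raise ValueError("both cases and controls required")
    if g.min() == g.max():
        raise ValueError("monomorphic SNP")
    ybar = y.mean()
    u = float(np.sum(g * (y - ybar)))
    v = float(ybar * (1 - ybar) * np.sum((g - g.mean()) ** 2))
    chi2 = u * u / v
    return float(stats.chi2.sf(chi2, 1))


def marginal_screen(g: GenotypeMatrix) -> list[SnpRecord]:
    """Trend-test every SNP; monomorphic SNPs get marginal_p = NaN and are
    excluded from tiers downstream."""
    if g.phenotype is None:
        raise ValueError("phenotype required")
    records = []
    for j, snp in enumerate(g.snp_ids):
        meta = g.snp_meta.get(snp, {})
        try:
            p = single_snp_test(g.dosages[:, j], g.phenotype)
        except ValueError:
            p = np.nan
        records.append(SnpRecord(id=snp, maf=g.maf(snp),
                                 tier=meta.get("tier", "none"), marginal_p=p))
    return records


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of dosages over
    pairwise-complete samples."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    keep = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[keep], g2[keep]
    if g1.size < 2:
        raise ValueError("need at least 2 overlapping non-missing samples")
    if g1.min() == g1.max() or g2.min() == g2.max():
        raise ValueError("zero-variance dosage vector")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


def _sort_key(rec: SnpRecord):
    # NaN p sorts last; ties broken by id for determinism
    p = rec.marginal_p if np.isfinite(rec.marginal_p) else np.inf
    return (p, rec.id)


def ld_prune(records: list[SnpRecord], g: GenotypeMatrix, r2_max: float = 0.5,
             prior_keep: list[str] | None = None) -> list[SnpRecord]:
    """Greedy LD pruning in ascending marginal-p order.

    A SNP is kept iff its r^2 with every previously kept SNP — and with every
    SNP in ``prior_keep`` (earlier tiers) — is below ``r2_max``. Smaller
    marginal p wins ties/duplicates; output order follows the scan order.
    """
    prior = list(prior_keep or [])
    kept: list[SnpRecord] = []
    kept_cols = [g.column(s) for s in prior]
    for rec in sorted(records, key=_sort_key):
        col = g.column(rec.id)
        try:
            independent = all(ld_r2(col, other) < r2_max for other in kept_cols)
        except ValueError:
            independent = False  # monomorphic: cannot assess, drop
        if independent:
            kept.append(rec)
            kept_cols.append(col)
    return kept


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def enumerate_pairs(plan: AnalysisPlan) -> list[tuple[str, str]]:
    """Materialise a plan's pair list.

    Within-set: all n(n-1)/2 unordered pairs; cross-set: |A| x |B| pairs
    (sets must be disjoint). Excluded pairs are removed; output is
    lexicographically ordered and canonical (smaller id first).
    """
    a = sorted(plan.set_a)
    if len(set(a)) != len(a):
        raise ValueError("duplicate ids in set_a")
    pairs: list[tuple[str, str]] = []
    if plan.set_b is None:
        for i in range(len(a)):
            for j in range(i + 1, len(a)):
                pairs.append((a[i], a[j]))
    else:
        b = sorted(plan.set_b)
        if set(a) & set(b):
            raise ValueError("set_a and set_b overlap in cross-set mode")
        pairs = [_canon(x, z) for x in a for z in b]
        pairs.sort()
    if plan.excluded_pairs:
        excl = {_canon(*p) for p in plan.excluded_pairs}
        pairs = [p for p in pairs if p not in excl]
    return pairs


def build_tiers(records: list[SnpRecord], g: GenotypeMatrix,
                thresholds: tuple[float, float] = (1e-3, 1e-2),
                r2_max: float = 0.5) -> list[AnalysisPlan]:
    """Construct the four tier plans with LD pruning, proxy tracking and
    cross-tier pair deduplication.

    Returns plans for analyses "1", "2", "3a", "3b" (a tier that ends up
    empty still yields a plan, with a warning).
    """
    t_mod, t_weak = sorted(thresholds)
    usable = [r for r in records if np.isfinite(r.marginal_p)]

    # --- Analysis 1: annotated (CVRF) SNPs, pruned among themselves
    cvrf = [r for r in usable if r.tier != "none"]
    a1_kept = ld_prune(cvrf, g, r2_max)
    a1_ids = [r.id for r in a1_kept]

    # proxy map: dropped SNP -> the earlier-kept SNP it tags (r^2 >= r2_max)
    proxy: dict[str, str] = {s: s for s in a1_ids}

    def _assign_proxies(candidates: list[SnpRecord], kept_ids: list[str]) -> None:
        for rec in candidates:
            if rec.id in proxy:
                continue
            col = g.column(rec.id)
            for s in kept_ids:
                try:
                    if ld_r2(col, g.column(s)) >= r2_max:
                        proxy[rec.id] = s
                        break
                except ValueError:
                    continue

    # --- Analysis 2 / 3a: moderate marginal set, pruned, minus A1 proxies
    moderate = [r for r in usable if r.marginal_p <= t_mod]
    mod_pruned = ld_prune(moderate, g, r2_max)  # independent set (incl. A1 overlaps)
    _assign_proxies(mod_pruned, a1_ids)
    mod_ids = [r.id for r in mod_pruned
               if r.id not in a1_ids and proxy.get(r.id, r.id) not in a1_ids]
    for s in mod_ids:
        proxy[s] = s

    plans = [
        AnalysisPlan("1", a1_ids, None, test="genotypic"),
        AnalysisPlan("2", mod_ids, a1_ids, test="genotypic"),
        AnalysisPlan("3a", mod_ids, None, test="allelic"),
    ]

    # pairs covered so far, at proxy-class level
    covered: set[tuple[str, str]] = set()
    for plan in plans:
        for p in enumerate_pairs(plan):
            covered.add(_canon(proxy.get(p[0], p[0]), proxy.get(p[1], p[1])))

    # --- Analysis 3b: weak marginal set, pruned, proxies of earlier keeps
    # dropped at SNP level; remaining overlap handled at pair level
    weak = [r for r in usable if r.marginal_p <= t_weak]
    weak_pruned = ld_prune(weak, g, r2_max)
    _assign_proxies(weak_pruned, a1_ids)
    b_ids = [r.id for r in weak_pruned
             if proxy.get(r.id, r.id) not in a1_ids or r.id in a1_ids]
    b_ids = [s for s in b_ids if s not in a1_ids]  # A1 SNPs themselves excluded
    excluded = set()
    for x, z in ((x, z) for i, x in enumerate(sorted(b_ids))
                 for z in sorted(b_ids)[i + 1:]):
        if _canon(proxy.get(x, x), proxy.get(z, z)) in covered:
            excluded.add(_canon(x, z))
    plans.append(AnalysisPlan("3b", b_ids, None, test="allelic",
                              excluded_pairs=excluded))

    for plan in plans:
        if not plan.set_a:
            warnings.warn(f"Analysis {plan.analysis_id}: empty tier, zero pairs")
    return plans
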